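"""Assimilation-temperature (AT) curve quality control.

Leaf photosynthesis measured along a temperature ramp should trace a
single-peaked thermal performance curve.  Two objective criteria decide
whether a measured curve is usable:

1. **Modality** — a cubic smoothing spline (smoothing chosen by
   generalised cross-validation) is fitted to the curve; more than one
   maximum of the smoothed function (stomatal oscillations, instrument
   trouble) excludes the curve.
2. **Optimum location** — the Sharpe-Schoolfield model with
   high-temperature deactivation, in its explicit-Topt
   reparameterisation, is fitted by multi-start nonlinear least squares;
   a fitted optimum outside the measured leaf-temperature range
   (strictly below the minimum or above the maximum) excludes the curve,
   since the data then cannot constrain the peak.

The rate model, with temperatures in Kelvin and Boltzmann's constant
k = 8.617e-5 eV/K:

    r(T) = r_tref * exp(-E/k * (1/T - 1/Tref))
           / (1 + E/(Ed - E) * exp(Ed/k * (1/Topt - 1/T)))

where ``r_tref`` is the rate at the reference temperature Tref (20 degC
here), ``E`` the activation energy (eV), ``Ed`` the deactivation energy
(eV, Ed > E) and ``Topt`` the temperature of the rate maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "ATCurve",
    "ATQCResult",
    "FitFailedError",
    "sharpe_schoolfield",
    "spline_modality",
    "fit_topt",
    "qc_decision",
]

BOLTZMANN_EV = 8.617333262e-5  # eV K^-1
TREF_K = 293.15  # 20 degC reference temperature


class FitFailedError(RuntimeError):
    """Raised when every start of the thermal-model fit fails."""


@dataclass(frozen=True)
class ATCurve:
    """One assimilation-temperature series."""

    curve_id: str
    species: str
    site_id: str
    leaf_temp: np.ndarray  # deg C
    assim: np.ndarray  # µmol m^-2 s^-1
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        temp = np.asarray(self.leaf_temp, dtype=float)
        assim = np.asarray(self.assim, dtype=float)
        object.__setattr__(self, "leaf_temp", temp)
        object.__setattr__(self, "assim", assim)
        if temp.shape != assim.shape or temp.ndim != 1:
            raise ValueError("leaf_temp and assim must be 1-D of equal length")
        if temp.size < 20:
            raise ValueError(f"need >= 20 points, got {temp.size}")
        if np.ptp(temp) <= 0:
            raise ValueError("leaf_temp span must be positive")


@dataclass(frozen=True)
class ATQCResult:
    """Keep/exclude decision for one curve, with the reason."""

    curve_id: str
    decision: str  # keep | exclude
    reason: str  # none | multimodal | topt_out_of_range | fit_failed
    fitted_topt: float | None
    n_spline_maxima: int | None


def sharpe_schoolfield(
    temp_K: np.ndarray | float,
    r_tref: float,
    E: float,
    Ed: float,
    topt_K: float,
    tref_K: float = TREF_K,
) -> np.ndarray:
    """Thermal performance rate with high-temperature deactivation."""
    T = np.asarray(temp_K, dtype=float)
    k = BOLTZMANN_EV
    boltz = r_tref * np.exp(-E / k * (1.0 / T - 1.0 / tref_K))
    inact = 1.0 + E / (Ed - E) * np.exp(Ed / k * (1.0 / topt_K - 1.0 / T))
    return boltz / inact


#: A maximum must rise above its surrounding valleys by this fraction of
#: the smoothed curve's amplitude to count as a separate mode.
_PROMINENCE_FRAC = 0.05


def _count_grid_maxima(y: np.ndarray, prominence_frac: float = _PROMINENCE_FRAC) -> int:
    """Maxima of a gridded function; plateaus count once, boundaries count.

    Residual wiggles that survive smoothing are not modes: a maximum only
    counts when it is prominent relative to the curve's overall amplitude.
    """
    amplitude = float(np.ptp(y))
    if amplitude == 0.0:
        return 1  # constant function: one (degenerate) maximum
    floor = float(y.min()) - amplitude
    padded = np.concatenate([[floor], y, [floor]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * amplitude)
    return max(int(peaks.size), 1)


def spline_modality(curve: ATCurve, grid_size: int = 512) -> int:
    """Number of maxima of the GCV-smoothed curve on a dense grid.

    Duplicate temperatures are averaged before the spline fit (the
    smoothing-spline solver needs strictly increasing abscissae).
    Boundary maxima count, so a strictly monotone curve reports 1.
    """
    order = np.argsort(curve.leaf_temp, kind="stable")
    x, y = curve.leaf_temp[order], curve.assim[order]
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        sums = np.zeros(ux.size)
        counts = np.zeros(ux.size)
        np.add.at(sums, inv, y)
        np.add.at(counts, inv, 1.0)
        x, y = ux, sums / counts
    spline = make_smoothing_spline(x, y)  # lam chosen by GCV
    grid = np.linspace(x[0], x[-1], grid_size)
    return _count_grid_maxima(spline(grid))


def _fit_once(
    temp_K: np.ndarray, assim: np.ndarray, topt0_K: float
) -> tuple[np.ndarray, float] | None:
    scale = float(np.max(np.abs(assim))) or 1.0

    def resid(p: np.ndarray) -> np.ndarray:
        r_tref, E, Ed, topt = p
        return sharpe_schoolfield(temp_K, r_tref, E, Ed, topt) - assim

    x0 = np.array([scale, 0.6, 3.0, topt0_K])
    try:
        res = least_squares(
            resid,
            x0,
            bounds=(
                [1e-6 * scale, 0.01, 0.02, temp_K.min() - 20.0],
                [1e3 * scale, 10.0, 30.0, temp_K.max() + 25.0],
            ),
            method="trf",
            max_nfev=2000,
        )
    except Exception:
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    if res.x[2] <= res.x[1]:  # Ed <= E: deactivation regime lost
        return None
    return res.x, float(np.sum(res.fun**2))


def fit_topt(curve: ATCurve, n_starts: int = 6) -> tuple[float, np.ndarray]:
    """Fit the thermal model by deterministic multi-start least squares.

    Starting optima are spread uniformly over the measured temperature
    range (plus one start above it, for curves still rising at the upper
    end); the best converged fit wins.  Returns ``(topt_C, params)``
    with ``params = (r_tref, E, Ed, topt_K)``.
    """
    temp_K = curve.leaf_temp + 273.15
    starts = np.linspace(temp_K.min(), temp_K.max(), n_starts - 1)
    starts = np.append(starts, temp_K.max() + 10.0)
    best: tuple[np.ndarray, float] | None = None
    for t0 in starts:
        out = _fit_once(temp_K, curve.assim, float(t0))
        if out is not None and (best is None or out[1] < best[1]):
            best = out
    if best is None:
        raise FitFailedError(f"curve {curve.curve_id}: all fit starts failed")
    params = best[0]
    return float(params[3] - 273.15), params


def qc_decision(curve: ATCurve) -> ATQCResult:
    """Apply both exclusion criteria, modality first."""
    try:
        n_maxima = spline_modality(curve)
    except Exception:
        return ATQCResult(curve.curve_id, "exclude", "fit_failed", None, None)
    if n_maxima > 1:
        return ATQCResult(curve.curve_id, "exclude", "multimodal", None, n_maxima)
    try:
        topt, _ = fit_topt(curve)
    except FitFailedError:
        return ATQCResult(curve.curve_id, "exclude", "fit_failed", None, n_maxima)
    tmin, tmax = float(curve.leaf_temp.min()), float(curve.leaf_temp.max())
    if topt < tmin or topt > tmax:
        return ATQCResult(
            curve.curve_id, "exclude", "topt_out_of_range", topt, n_maxima
        )
    return ATQCResult(curve.curve_id, "keep", "none", topt, n_maxima)
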