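"""Closed-chamber CO2 flux estimation.

A chamber closure yields a ~180 s CO2 concentration time series at 1 Hz.
After trimming the disturbed first and last seconds, the series is fitted
to the exponential equilibration model

    C(t) = Cm + a (t - tz) + (Cz - Cm) exp(-b (t - tz))

where ``Cm`` is the concentration once the chamber headspace approaches
equilibrium with a residual linear drift ``a``, ``b`` is the equilibration
rate, ``Cz`` is the concentration at the (fitted) time origin ``tz``, with
C(tz) = Cz by construction.  ``Cz`` is fixed beforehand as the ordinary
least-squares intercept of the first 15 s of the retained window, and
(Cm, a, b, tz) are found by minimising the RMSE of the residuals with a
derivative-free simplex search.  The instantaneous slope at tz,

    C'(tz) = a + b (Cm - Cz),

is converted to an areal flux with the ideal-gas factor P V / (R T A) and
expressed in mmol m^-2 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
from scipy import optimize, stats

from .config import ChamberSpec

__all__ = [
    "ConcentrationSeries",
    "ExponentialFit",
    "SeriesTooShortError",
    "exponential_model",
    "trim_series",
    "estimate_cz",
    "fit_exponential",
    "flux_from_slope",
]

#: µmol m^-2 s^-1 -> mmol m^-2 h^-1
_UMOL_S_TO_MMOL_H = 3600.0 / 1000.0


class SeriesTooShortError(ValueError):
    """Raised when a concentration series is too short to fit."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """One chamber closure: CO2 readings with environmental covariates.

    ``t`` is seconds since chamber closure (strictly increasing, nominally
    1 Hz) and ``conc`` the CO2 mole fraction in ppm.  ``air_temp_K`` is the
    mean chamber air temperature over the series, Kelvin.  ``kind``
    distinguishes transparent-chamber (NEE) from darkened-chamber (ER)
    closures.
    """

    flux_id: str
    kind: str  # "NEE" | "ER"
    t: np.ndarray
    conc: np.ndarray
    air_temp_K: float = 293.15
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "conc", conc)
        if self.kind not in ("NEE", "ER"):
            raise ValueError(f"kind must be 'NEE' or 'ER', got {self.kind!r}")
        if t.shape != conc.shape or t.ndim != 1:
            raise ValueError("t and conc must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(conc)):
            raise ValueError("concentrations must be finite")
        if self.air_temp_K <= 0:
            raise ValueError(f"air_temp_K must be > 0, got {self.air_temp_K}")

    @property
    def start_conc(self) -> float:
        """First retained concentration reading, ppm."""
        return float(self.conc[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted parameters and diagnostics of the chamber model."""

    Cm: float
    a: float
    b: float
    tz: float
    Cz: float
    rmse: float
    slope_at_tz: float
    pearson_r: float
    converged: bool

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")


def exponential_model(
    t: np.ndarray, Cm: float, a: float, b: float, tz: float, Cz: float
) -> np.ndarray:
    """Evaluate the chamber equilibration model C(t)."""
    t = np.asarray(t, dtype=float)
    return Cm + a * (t - tz) + (Cz - Cm) * np.exp(-b * (t - tz))


def trim_series(
    series: ConcentrationSeries, head_s: float = 10.0, tail_s: float = 10.0
) -> ConcentrationSeries:
    """Drop the disturbed head and tail of a closure.

    The retained window is ``[t0 + head_s, t_end - tail_s]`` where ``t0``
    is the first raw timestamp; timestamps keep the original
    since-closure origin, so a 180-reading closure at 1 Hz retains 160
    readings.  Raises :class:`SeriesTooShortError` when fewer than 30 s
    would remain.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("head_s and tail_s must be >= 0")
    if series.duration <= head_s + tail_s + 30.0:
        raise SeriesTooShortError(
            f"series {series.flux_id}: {series.duration:.0f} s is too short to "
            f"trim {head_s:.0f}+{tail_s:.0f} s and keep 30 s"
        )
    t0, t_end = series.t[0], series.t[-1]
    keep = (series.t >= t0 + head_s) & (series.t <= t_end - tail_s)
    return replace(series, t=series.t[keep], conc=series.conc[keep])


def estimate_cz(
    series: ConcentrationSeries, window_s: float = 15.0
) -> tuple[float, float]:
    """OLS intercept and slope over the first ``window_s`` seconds.

    The regression uses time since the start of the retained window, so
    the intercept is the fitted concentration at the first retained
    reading — the natural anchor for Cz.
    """
    u = series.t - series.t[0]
    mask = u < window_s
    if int(mask.sum()) < 2:
        raise ValueError(
            f"need >= 2 readings in the first {window_s:g} s, got {int(mask.sum())}"
        )
    design = np.column_stack([np.ones(int(mask.sum())), u[mask]])
    (intercept, slope), *_ = np.linalg.lstsq(design, series.conc[mask], rcond=None)
    return float(intercept), float(slope)


def _initial_guess(series: ConcentrationSeries) -> np.ndarray:
    # Cm from the tail (closest to equilibrium), a from the overall trend,
    # b at mid-range, tz at the window start.
    n_tail = min(10, len(series))
    cm0 = float(series.conc[-n_tail:].mean())
    a0 = float(np.polyfit(series.t, series.conc, 1)[0])
    return np.array([cm0, a0, 0.1, float(series.t[0])])


def fit_exponential(
    series: ConcentrationSeries,
    init: np.ndarray | None = None,
    cz_window_s: float = 15.0,
) -> ExponentialFit:
    """Fit (Cm, a, b, tz) by simplex minimisation of the residual RMSE.

    ``series`` must already be trimmed.  Cz is held fixed at the
    first-window OLS intercept.  Non-convergence of the optimiser is
    reported through ``converged`` rather than raised; the QC stage turns
    it into a flag.
    """
    cz, _ = estimate_cz(series, window_s=cz_window_s)
    t, conc = series.t, series.conc

    def rmse(p: np.ndarray) -> float:
        cm, a, b, tz = p
        resid = exponential_model(t, cm, a, b, tz, cz) - conc
        val = np.sqrt(np.mean(resid * resid))
        return val if np.isfinite(val) else 1e30

    x0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(series)
    res = optimize.minimize(
        rmse,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
    )
    cm, a, b, tz = (float(v) for v in res.x)
    slope = a + b * (cm - cz)
    if np.std(conc) == 0.0:
        r = 0.0  # constant series carries no trend
    else:
        r = float(stats.pearsonr(t, conc).statistic)
    return ExponentialFit(
        Cm=cm,
        a=a,
        b=b,
        tz=tz,
        Cz=cz,
        rmse=float(res.fun),
        slope_at_tz=float(slope),
        pearson_r=r,
        converged=bool(res.success),
    )


def flux_from_slope(
    slope_ppm_s: float, chamber: ChamberSpec, air_temp_K: float
) -> float:
    """Convert a concentration slope to an areal flux.

    flux = slope * P V / (R T A), with ppm read as µmol mol^-1, giving
    µmol m^-2 s^-1, then scaled to mmol m^-2 h^-1 (x 3.6).
    """
    if air_temp_K <= 0:
        raise ValueError(f"air_temp_K must be > 0, got {air_temp_K}")
    mol_air = chamber.pressure_atm * chamber.volume_L / (chamber.R * air_temp_K)
    flux_umol_m2_s = slope_ppm_s * mol_air / chamber.area_m2
    return flux_umol_m2_s * _UMOL_S_TO_MMOL_H
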