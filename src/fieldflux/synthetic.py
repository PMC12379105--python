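"""Synthetic raw-data generators with known ground truth.

Every raw input the pipeline consumes can be simulated here: chamber CO2
concentration series (including a closed library of injected failure
modes, each of which maps to exactly one QC flag), whole diurnal flux
campaigns, leaf-sample envelope tables with injected threshold
violations, assimilation-temperature curves of known modality and
optimum, and microclimate logger series with out-of-range values.

All generators are pure functions of (scenario, seed): the same inputs
reproduce byte-identical outputs.  Ground truth (generating parameters
and the QC flag each record should receive) travels with the output so
that recall/precision of the downstream QC can be computed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .chamber import ConcentrationSeries, exponential_model
from .config import FOLDED_SPECIES, FluxQCThresholds
from .thermal import ATCurve, sharpe_schoolfield

__all__ = [
    "FluxScenario",
    "FluxDistribution",
    "Campaign",
    "TraitScenario",
    "ATScenario",
    "generate_flux_series",
    "generate_diurnal_campaign",
    "generate_trait_table",
    "generate_at_curve",
    "generate_microclimate",
]

FAILURE_MODES = (
    "none",
    "high_start",
    "low_start",
    "nonmonotone_noise",
    "negative_er_slope",
    "b_artefact",
)

#: QC flag each failure mode must receive at zero noise.
INTENDED_FLAG = {
    "none": "okflux",
    "high_start": "start_error",
    "low_start": "start_error",
    "nonmonotone_noise": "zero",
    "negative_er_slope": "discard",
    "b_artefact": "discard",
}


@dataclass(frozen=True)
class FluxScenario:
    """Generating parameters for one synthetic chamber closure.

    The defaults reproduce a well-behaved transparent-chamber closure:
    180 s at 1 Hz, equilibrating from 400 ppm towards 450 ppm.  The
    failure modes override parameters as needed (see
    :func:`generate_flux_series`).
    """

    true_Cm: float = 450.0  # ppm
    true_a: float = 0.02  # ppm s^-1
    true_b: float = 0.05  # s^-1
    true_tz: float = 10.0  # s
    true_Cz: float = 400.0  # ppm
    noise_sd: float = 0.0  # ppm
    duration: float = 180.0  # s
    sampling_rate: float = 1.0  # Hz
    start_conc: float = 400.0  # ppm; used by the start-error modes
    failure_mode: str = "none"
    kind: str = "NEE"
    seed: int = 0
    air_temp_K: float = 293.15

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.sampling_rate <= 0:
            raise ValueError(
                f"sampling_rate must be > 0, got {self.sampling_rate}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.failure_mode not in FAILURE_MODES:
            raise ValueError(f"failure_mode must be one of {FAILURE_MODES}")
        thr = FluxQCThresholds()
        if self.failure_mode == "high_start" and self.start_conc <= thr.start_max:
            raise ValueError(
                f"start_conc must exceed {thr.start_max} ppm for high_start"
            )
        if self.failure_mode == "low_start" and self.start_conc >= thr.start_min:
            raise ValueError(
                f"start_conc must be below {thr.start_min} ppm for low_start"
            )


def _effective_params(sc: FluxScenario) -> tuple[float, float, float, float, float, str]:
    """Apply the failure-mode overrides to the generating parameters."""
    cm, a, b, tz, cz, kind = (
        sc.true_Cm,
        sc.true_a,
        sc.true_b,
        sc.true_tz,
        sc.true_Cz,
        sc.kind,
    )
    mode = sc.failure_mode
    if mode in ("high_start", "low_start"):
        # Shift the whole curve so the first retained reading (= Cz when
        # tz coincides with the 10 s trim head) sits at start_conc.
        cm, cz, tz = sc.start_conc + (cm - cz), sc.start_conc, 10.0
    elif mode == "b_artefact":
        # Optimiser-artefact regime: b outside [0, 1) with a clear trend,
        # so |r| > 0.5 and the flux must be discarded.  The trend must
        # dominate the initial transient for the correlation to hold.
        b = max(b, 1.5)
        a = max(a, 0.3)
    elif mode == "nonmonotone_noise":
        # A fast mixing transient with no sustained trend: a bad fit
        # (b >= 1) that is uncorrelated with time, hence replaced by 0.
        a, b, cm = 0.0, 1.5, cz + 15.0
    elif mode == "negative_er_slope":
        # Apparent CO2 uptake in the dark: impossible, hence a bad fit;
        # the monotone decline makes |r| > 0.5, so it is discarded.
        kind = "ER"
        a, cm = -abs(sc.true_a) - 0.005, cz - 30.0
    return cm, a, b, tz, cz, kind


def generate_flux_series(scenario: FluxScenario) -> ConcentrationSeries:
    """Emit one raw (untrimmed) chamber closure.

    With ``failure_mode='none'`` and ``noise_sd=0`` the series satisfies
    the equilibration model exactly at every timestamp.  The effective
    generating parameters and the intended QC flag are recorded under
    ``metadata['truth']``.
    """
    cm, a, b, tz, cz, kind = _effective_params(scenario)
    n = int(round(scenario.duration * scenario.sampling_rate))
    t = np.arange(n) / scenario.sampling_rate
    conc = exponential_model(t, cm, a, b, tz, cz)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        conc = conc + rng.normal(0.0, scenario.noise_sd, size=n)
    truth = {
        "Cm": cm,
        "a": a,
        "b": b,
        "tz": tz,
        "Cz": cz,
        "slope_at_tz": a + b * (cm - cz),
        "failure_mode": scenario.failure_mode,
        "intended_flag": INTENDED_FLAG[scenario.failure_mode],
    }
    return ConcentrationSeries(
        flux_id=f"sim_{scenario.seed}",
        kind=kind,
        t=t,
        conc=conc,
        air_temp_K=scenario.air_temp_K,
        metadata={"truth": truth},
    )


@dataclass(frozen=True)
class FluxDistribution:
    """Sampling distribution over flux scenarios for campaign simulation.

    ``b`` is drawn log-uniformly (equilibration time constants from tens
    of seconds to several minutes), the equilibration amplitude
    ``Cm - Cz`` and residual drift ``a`` uniformly; ER closures always
    release CO2 (positive slope), NEE closures take either sign.
    ``failure_weights`` gives the probability of each injected failure
    mode; the remainder is well-behaved.
    """

    a_range: tuple[float, float] = (0.005, 0.05)
    b_range: tuple[float, float] = (0.002, 0.05)
    dC_range: tuple[float, float] = (10.0, 80.0)
    cz_mean: float = 421.0
    cz_sd: float = 15.0
    noise_sd: float = 1.0
    duration: float = 180.0
    sampling_rate: float = 1.0
    failure_weights: Mapping[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, kind: str = "NEE") -> FluxScenario:
        modes = [m for m in self.failure_weights if m != "none"]
        probs = [self.failure_weights[m] for m in modes]
        if sum(probs) > 1:
            raise ValueError("failure_weights must sum to <= 1")
        mode = "none"
        if modes:
            u, acc = rng.uniform(), 0.0
            for m, p in zip(modes, probs):
                acc += p
                if u < acc:
                    mode = m
                    break
        if mode == "negative_er_slope" and kind != "ER":
            mode = "none"  # only a darkened-chamber closure can show this
        sign = 1.0 if kind == "ER" else (1.0 if rng.uniform() < 0.5 else -1.0)
        a = sign * rng.uniform(*self.a_range)
        lo, hi = np.log(self.b_range[0]), np.log(self.b_range[1])
        b = float(np.exp(rng.uniform(lo, hi)))
        dc = sign * rng.uniform(*self.dC_range)
        cz = float(np.clip(rng.normal(self.cz_mean, self.cz_sd), 331.0, 511.0))
        start = 560.0 if mode == "high_start" else 300.0 if mode == "low_start" else cz
        return FluxScenario(
            true_Cm=cz + dc,
            true_a=a,
            true_b=b,
            true_tz=10.0,
            true_Cz=cz,
            noise_sd=self.noise_sd,
            duration=self.duration,
            sampling_rate=self.sampling_rate,
            start_conc=start,
            failure_mode=mode,
            kind=kind,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


@dataclass(frozen=True)
class Campaign:
    """A simulated diurnal campaign: raw closures, schedule, truth table."""

    series: tuple[ConcentrationSeries, ...]
    schedule: tuple[Mapping[str, Any], ...]
    truth: pd.DataFrame


def generate_diurnal_campaign(
    n_sites: int = 1,
    n_rounds: int = 24,
    scenarios: FluxDistribution | None = None,
    missing_rounds: Sequence[int] = (),
    seed: int = 0,
    plots_per_site: int = 3,
    start: datetime = datetime(2022, 7, 25, 12, 0),
) -> Campaign:
    """Simulate hourly paired NEE/ER closures over a diurnal cycle.

    Each non-missing round yields exactly one NEE and one ER closure per
    plot, sharing covariates.  ``missing_rounds`` lists round indices
    skipped in the field (applied at every plot); the schedule still
    contains them so the QC stage can emit placeholders.
    """
    if n_rounds > 24:
        raise ValueError(f"n_rounds must be <= 24, got {n_rounds}")
    if len(set(missing_rounds)) != len(missing_rounds):
        raise ValueError("missing_rounds contains duplicate round indices")
    if not set(missing_rounds) <= set(range(n_rounds)):
        raise ValueError("missing_rounds must be round indices < n_rounds")
    dist = scenarios or FluxDistribution()
    rng = np.random.default_rng(seed)

    series: list[ConcentrationSeries] = []
    schedule: list[dict[str, Any]] = []
    truth_rows: list[dict[str, Any]] = []
    flux_nr = 0
    for site_i in range(n_sites):
        site = f"Site{site_i + 1}"
        for plot_i in range(plots_per_site):
            warming = "W" if plot_i % 2 else "A"
            turf = f"{site}_P{plot_i + 1}{warming}"
            for rnd in range(n_rounds):
                when = start + timedelta(hours=rnd)
                slot = {
                    "turfID": turf,
                    "round": rnd,
                    "datetime": when,
                    "origSiteID": site,
                    "destSiteID": site,
                    "warming": warming,
                }
                schedule.append(slot)
                if rnd in missing_rounds:
                    continue
                hour = when.hour + when.minute / 60.0
                par = max(0.0, 1500.0 * np.sin(np.pi * (hour - 4.0) / 16.0))
                temp_soil = 10.0 + 4.0 * np.sin(np.pi * (hour - 6.0) / 12.0)
                for kind in ("NEE", "ER"):
                    flux_nr += 1
                    sc = replace(dist.draw(rng, kind=kind), seed=int(rng.integers(0, 2**31 - 1)))
                    s = generate_flux_series(sc)
                    meta = dict(s.metadata)
                    meta.update(slot, PARavg=par if kind == "NEE" else 0.0,
                                temp_soil=temp_soil)
                    s = replace(s, flux_id=str(flux_nr), metadata=meta)
                    series.append(s)
                    truth_rows.append(
                        {
                            "fluxID": s.flux_id,
                            "type": kind,
                            "turfID": turf,
                            "round": rnd,
                            **meta["truth"],
                        }
                    )
    return Campaign(
        series=tuple(series),
        schedule=tuple(schedule),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Leaf trait envelopes


@dataclass(frozen=True)
class TraitScenario:
    """Generating parameters for a synthetic leaf-sample envelope table.

    ``violation_rates`` maps threshold names (``ldmc``, ``sla_low``,
    ``sla_high``, ``nitrogen``) to the probability that a sample is drawn
    beyond that plausibility limit; at most one violation is injected per
    sample.
    """

    n_samples: int = 100
    species_pool: tuple[str, ...] = (
        "Achillea millefolium",
        "Alchemilla alpina",
        "Vaccinium vitis-idaea",
        "Agrostis capillaris",
        *sorted(FOLDED_SPECIES),
    )
    leaf_count_range: tuple[int, int] = (1, 5)
    violation_rates: Mapping[str, float] = field(default_factory=dict)
    leaf_loss_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be > 0, got {self.n_samples}")
        bad = set(self.violation_rates) - {"ldmc", "sla_low", "sla_high", "nitrogen"}
        if bad:
            raise ValueError(f"unknown violation_rates keys: {sorted(bad)}")
        if sum(self.violation_rates.values()) > 1:
            raise ValueError("violation_rates must sum to <= 1")


def generate_trait_table(scenario: TraitScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit an envelope-style leaf-sample table plus its ground truth.

    Returns ``(samples, truth)``.  ``samples`` has one row per leaf
    sample with bulk masses, the *scanned* area (half the true area for
    folded-leaf graminoids) and raw thickness readings.  ``truth``
    records the known per-leaf SLA/LDMC/area and the intended validation
    flag (empty string when none).
    """
    rng = np.random.default_rng(scenario.seed)
    folded = FOLDED_SPECIES
    viol_names = list(scenario.violation_rates)
    viol_probs = np.array([scenario.violation_rates[k] for k in viol_names])

    rows, truth_rows = [], []
    for i in range(scenario.n_samples):
        sid = f"SYN{i:05d}"
        species = str(rng.choice(scenario.species_pool))
        n_leaves = int(rng.integers(scenario.leaf_count_range[0],
                                    scenario.leaf_count_range[1] + 1))
        n_at_dry = n_leaves
        if n_leaves > 1 and rng.uniform() < scenario.leaf_loss_rate:
            n_at_dry = n_leaves - 1

        violation = ""
        if viol_names:
            u, acc = rng.uniform(), 0.0
            for name, p in zip(viol_names, viol_probs):
                acc += p
                if u < acc:
                    violation = name
                    break

        area_leaf = float(rng.lognormal(np.log(5.0), 0.5))  # cm^2 per leaf
        sla = float(rng.uniform(80.0, 300.0))  # cm^2 g^-1
        ldmc = float(rng.uniform(0.15, 0.5))  # g g^-1
        nitrogen = float(rng.uniform(1.0, 4.0))  # %
        if violation == "sla_low":
            sla = float(rng.uniform(1.0, 4.9))
        elif violation == "sla_high":
            sla = float(rng.uniform(505.0, 600.0))
        elif violation == "ldmc":
            ldmc = float(rng.uniform(1.02, 1.3))
        elif violation == "nitrogen":
            nitrogen = float(rng.uniform(6.5, 8.0))

        dry_leaf = area_leaf / sla
        wet_leaf = dry_leaf / ldmc
        true_area = area_leaf * n_leaves
        scanned = true_area / 2.0 if species in folded else true_area
        n_thick = int(rng.integers(1, 4))
        thickness = rng.normal(0.25, 0.03, size=3)
        thickness[n_thick:] = np.nan

        rows.append(
            {
                "ID": sid,
                "species": species,
                "n_leaves": n_leaves,
                "n_leaves_at_dry": n_at_dry,
                "wet_mass": wet_leaf * n_leaves,
                "dry_mass": dry_leaf * n_at_dry,
                "scanned_area": scanned,
                "thickness_1": thickness[0],
                "thickness_2": thickness[1],
                "thickness_3": thickness[2],
                "plant_height": float(rng.uniform(2.0, 40.0)),
                "C_percent": float(rng.normal(45.0, 2.0)),
                "N_percent": nitrogen,
                "P_percent": float(rng.uniform(0.1, 0.4)),
                "siteID": "SiteA",
                "turfID": f"T{i % 10}",
            }
        )
        truth_rows.append(
            {
                "ID": sid,
                "species": species,
                "true_sla": sla,
                "true_ldmc": ldmc,
                "true_area_cm2": true_area,
                "true_area_per_leaf_cm2": area_leaf,
                "true_nitrogen_percent": nitrogen,
                "intended_flag": violation,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Assimilation-temperature curves


@dataclass(frozen=True)
class ATScenario:
    """Generating parameters for one assimilation-temperature curve."""

    modality: str = "unimodal"  # unimodal | bimodal | monotone
    true_topt: float = 22.0  # deg C
    temp_range: tuple[float, float] = (8.0, 40.0)
    noise_sd: float = 0.0  # µmol m^-2 s^-1
    #: Readings per ramp: the instrument logs every 2 s over a ~33 min
    #: temperature ramp, i.e. ~990 points per curve.
    n_points: int = 990
    peak_assim: float = 12.0  # µmol m^-2 s^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("unimodal", "bimodal", "monotone"):
            raise ValueError(
                f"modality must be unimodal, bimodal or monotone, got "
                f"{self.modality!r}"
            )
        if self.n_points < 20:
            raise ValueError(f"n_points must be >= 20, got {self.n_points}")
        if self.temp_range[1] <= self.temp_range[0]:
            raise ValueError("temp_range must have positive span")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_at_curve(scenario: ATScenario) -> ATCurve:
    """Emit one AT curve with a known keep/exclude ground truth.

    Unimodal curves follow the thermal performance model itself (so the
    optimum-recovery round trip is exact at zero noise); bimodal curves
    superpose two separated thermal peaks (e.g. stomatal oscillation);
    monotone curves rise over the whole measured range, putting the true
    optimum beyond it.
    """
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.temp_range
    temps = np.linspace(lo, hi, scenario.n_points)
    if scenario.modality == "unimodal":
        assim = sharpe_schoolfield(
            temps + 273.15,
            r_tref=1.0,
            E=0.8,
            Ed=3.5,
            topt_K=scenario.true_topt + 273.15,
        )
        assim = assim / assim.max() * scenario.peak_assim
        in_range = lo <= scenario.true_topt <= hi
        decision = "keep" if in_range else "exclude"
        reason = "none" if in_range else "topt_out_of_range"
    elif scenario.modality == "bimodal":
        c1, c2 = lo + 0.3 * (hi - lo), lo + 0.75 * (hi - lo)
        w = (hi - lo) / 12.0
        assim = scenario.peak_assim * np.exp(-0.5 * ((temps - c1) / w) ** 2)
        assim = assim + 0.8 * scenario.peak_assim * np.exp(
            -0.5 * ((temps - c2) / w) ** 2
        )
        decision, reason = "exclude", "multimodal"
    else:  # monotone: optimum lies beyond the measured range
        assim = scenario.peak_assim * (
            np.exp(0.06 * (temps - hi)) - 0.5 * np.exp(0.06 * (lo - hi))
        )
        decision, reason = "exclude", "topt_out_of_range"
    if scenario.noise_sd > 0:
        assim = assim + rng.normal(0.0, scenario.noise_sd, size=temps.size)
    return ATCurve(
        curve_id=f"at_{scenario.seed}",
        species="synthetic",
        site_id="SiteA",
        leaf_temp=temps,
        assim=assim,
        metadata={
            "truth": {
                "modality": scenario.modality,
                "true_topt": scenario.true_topt,
                "intended_decision": decision,
                "intended_reason": reason,
            }
        },
    )


# ---------------------------------------------------------------------------
# Microclimate loggers

_MICRO_VARIABLES = (
    "air_temperature",
    "ground_temperature",
    "soil_temperature",
    "soil_moisture",
)

#: violation name -> (variable, flag, sampler of an out-of-range value)
_MICRO_VIOLATIONS = {
    "air_max": ("air_temperature", "cut_Tmax_air", (30.5, 38.0)),
    "ground_max": ("ground_temperature", "cut_Tmax_ground", (35.5, 42.0)),
    "soil_max": ("soil_temperature", "cut_Tmax_soil", (20.5, 26.0)),
    "soil_min": ("soil_temperature", "cut_Tmin_soil", (0.0, 4.5)),
    "moisture_min": ("soil_moisture", "cut_min_moist", (-5.0, -0.1)),
}


def generate_microclimate(
    n_loggers: int = 2,
    window: tuple[datetime, datetime] = (
        datetime(2022, 7, 24, 0, 0),
        datetime(2022, 7, 26, 0, 0),
    ),
    violation_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a 15-min microclimate logger table with labelled violations.

    Output is long format (one row per logger, timestamp and climate
    variable) with the published logger-table columns plus an ``intended_flag`` ground
    truth column (empty string for in-range values).  ``violation_rates``
    maps ``air_max``, ``ground_max``, ``soil_max``, ``soil_min`` and
    ``moisture_min`` to per-reading injection probabilities.
    """
    rates = dict(violation_rates or {})
    bad = set(rates) - set(_MICRO_VIOLATIONS)
    if bad:
        raise ValueError(f"unknown violation_rates keys: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    start, end = window
    if end <= start:
        raise ValueError("window end must be after window start")
    times = pd.date_range(start, end, freq="15min", inclusive="left")
    hours = np.asarray(times.hour + times.minute / 60.0, dtype=float)

    rows = []
    for li in range(n_loggers):
        logger = f"9{li:07d}"
        base = {
            "air_temperature": 14.0 + 8.0 * np.sin(np.pi * (hours - 7.0) / 12.0),
            "ground_temperature": 12.0 + 5.0 * np.sin(np.pi * (hours - 8.0) / 12.0),
            "soil_temperature": 10.0 + 1.5 * np.sin(np.pi * (hours - 10.0) / 12.0),
            "soil_moisture": np.full(times.size, 25.0) + 3.0 * np.sin(
                np.arange(times.size) / 40.0
            ),
        }
        for var in _MICRO_VARIABLES:
            values = base[var] + rng.normal(0.0, 0.2, size=times.size)
            flags = np.array([""] * times.size, dtype=object)
            for name, rate in rates.items():
                v_var, v_flag, (v_lo, v_hi) = _MICRO_VIOLATIONS[name]
                if v_var != var or rate <= 0:
                    continue
                hit = rng.uniform(size=times.size) < rate
                free = hit & (flags == "")
                values[free] = rng.uniform(v_lo, v_hi, size=int(free.sum()))
                flags[free] = v_flag
            for ts, value, intended in zip(times, values, flags):
                rows.append(
                    {
                        "datetime": ts,
                        "loggerID": logger,
                        "turfID": f"T{li}",
                        "origSiteID": "SiteA",
                        "destSiteID": "SiteA",
                        "warming": "A",
                        "datetime_in": start,
                        "datetime_out": end,
                        "climate_variable": var,
                        "value": float(value),
                        "intended_flag": intended,
                    }
                )
    return pd.DataFrame(rows)
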