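"""Self-validation batteries: parameter recovery and QC agreement studies.

Each function simulates raw data with the synthetic generators under the
package's committed study conditions, runs the corresponding pipeline
stage, and measures recovery or agreement against the generators' ground
truth.  The batteries are deterministic given their seed and are used by
both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .chamber import fit_exponential, trim_series
from .fluxqc import process_campaign
from .synthetic import (
    ATScenario,
    FluxDistribution,
    generate_at_curve,
    generate_diurnal_campaign,
    generate_flux_series,
)
from .thermal import fit_topt, qc_decision

__all__ = [
    "slope_recovery_battery",
    "campaign_qc_battery",
    "at_qc_battery",
    "topt_recovery_battery",
]

#: Injection rates used for the failure-mode campaign battery.
CAMPAIGN_FAILURE_WEIGHTS = {
    "high_start": 0.08,
    "low_start": 0.08,
    "nonmonotone_noise": 0.08,
    "negative_er_slope": 0.08,
    "b_artefact": 0.08,
}


def slope_recovery_battery(
    n: int = 200, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Relative slope errors over ``n`` simulated well-behaved closures.

    Scenarios are drawn from the default campaign distribution
    (equilibration rate log-uniform on [0.002, 0.05] s^-1, amplitude
    10-80 ppm, drift 0.005-0.05 ppm/s) at the requested noise level; each
    closure is trimmed and fitted, and the fitted slope at tz is compared
    with the generating closed-form slope a + b (Cm - Cz).
    """
    dist = FluxDistribution(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    errors = np.empty(n)
    for i in range(n):
        series = generate_flux_series(dist.draw(rng))
        fit = fit_exponential(trim_series(series))
        true_slope = series.metadata["truth"]["slope_at_tz"]
        errors[i] = abs(fit.slope_at_tz - true_slope) / abs(true_slope)
    return errors


def campaign_qc_battery(seed: int = 0, n_rounds: int = 12):
    """Run the full flux pipeline on a zero-noise failure-mode campaign.

    Returns ``(agreement, partition_exact, campaign, records)`` where
    ``agreement`` is the fraction of closures whose QC flag matches the
    injected label and ``partition_exact`` verifies that every scheduled
    (plot, round, type) slot yields exactly one record.
    """
    dist = FluxDistribution(noise_sd=0.0, failure_weights=CAMPAIGN_FAILURE_WEIGHTS)
    campaign = generate_diurnal_campaign(
        n_sites=1, n_rounds=n_rounds, scenarios=dist, missing_rounds=[5],
        seed=seed,
    )
    records = process_campaign(campaign.series, schedule=campaign.schedule)
    intended = dict(zip(campaign.truth["fluxID"], campaign.truth["intended_flag"]))
    hits = sum(
        1 for r in records if r.flux_id in intended and r.flag == intended[r.flux_id]
    )
    agreement = hits / len(intended)
    slots = {(r.turf_id, r.round, r.type) for r in records}
    partition_exact = (
        len(records) == len(slots) == len(campaign.schedule) * 3
    )
    return agreement, partition_exact, campaign, records


def _at_battery_scenario(i: int, rng: np.random.Generator) -> ATScenario:
    kind = ("unimodal", "unimodal", "bimodal", "monotone")[i % 4]
    if kind == "unimodal":
        interior = (i // 4) % 2 == 0
        topt = float(rng.uniform(15, 32)) if interior else float(rng.uniform(46, 55))
    else:
        topt = 22.0
    return ATScenario(
        modality=kind,
        true_topt=topt,
        noise_sd=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def at_qc_battery(
    n: int = 100, noise_frac: float = 0.05, seed: int = 0
) -> float:
    """Fraction of AT curves whose QC decision matches the injected label.

    The battery cycles through unimodal curves with interior (15-32 degC)
    and exterior (46-55 degC) optima, bimodal curves, and monotone
    curves, all over an 8-40 degC measured range with additive noise of
    ``noise_frac`` times the peak assimilation.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n):
        scenario = _at_battery_scenario(i, rng)
        scenario = replace(
            scenario, noise_sd=noise_frac * scenario.peak_assim
        )
        curve = generate_at_curve(scenario)
        result = qc_decision(curve)
        hits += result.decision == curve.metadata["truth"]["intended_decision"]
    return hits / n


def topt_recovery_battery(
    n: int = 10, noise_frac: float = 0.01, seed: int = 0
) -> np.ndarray:
    """Absolute Topt errors (degC) on low-noise unimodal curves."""
    rng = np.random.default_rng(seed)
    errors = np.empty(n)
    for i in range(n):
        topt = float(rng.uniform(15, 32))
        scenario = ATScenario(
            modality="unimodal",
            true_topt=topt,
            noise_sd=noise_frac * 12.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fitted, _ = fit_topt(generate_at_curve(scenario))
        errors[i] = abs(fitted - topt)
    return errors
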