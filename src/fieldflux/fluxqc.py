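"""Flux quality control, NEE/ER/GPP partitioning and diurnal correction.

Every fitted chamber closure receives exactly one quality flag from a
fixed decision tree:

1. ``start_error`` — the closure started at an implausible concentration
   (outside 421 ± 100 ppm), e.g. the operator breathed near the inlet.
2. A *bad fit* is any of: equilibration rate b outside [0, 1) (an
   optimiser artefact), an ER closure with a negative slope (vegetation
   cannot take up CO2 in the dark), or optimiser non-convergence.
3. Bad fit with a real time trend (|Pearson r| > 0.5) — ``discard``.
4. Bad fit without a trend — the variation is instrument noise, the flux
   is ``zero`` (value replaced by 0).
5. Otherwise ``okflux`` with the converted flux value.

GPP = NEE - ER (negative GPP = atmospheric uptake).  CO2 pooled in the
canopy before a transparent-chamber closure inflates night-time GPP, so
each site's 24 h cycle is shifted so that its most positive GPP equals
zero; the applied offset is kept as provenance and the correction can be
disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Any, Iterable, Mapping, Sequence

from .chamber import (
    ConcentrationSeries,
    ExponentialFit,
    fit_exponential,
    flux_from_slope,
    trim_series,
)
from .config import ChamberSpec, FluxQCThresholds, PipelineConfig

__all__ = [
    "FluxRecord",
    "FLAGS",
    "classify",
    "process_series",
    "process_campaign",
    "mark_weird",
    "compute_gpp",
    "night_correct_gpp",
    "detect_missing_rounds",
]

#: Full flag vocabulary of the flux dataset.
FLAGS = (
    "okflux",
    "start_error",
    "discard",
    "weird_flux",
    "zero",
    "zeroER",
    "zeroNEE",
    "missing_round",
)

#: Flags whose records carry no flux value.
_ABSENT_FLAGS = frozenset({"start_error", "discard", "weird_flux", "missing_round"})


@dataclass(frozen=True)
class FluxRecord:
    """One NEE, ER or GPP value with its QC flag and plot metadata."""

    flux_id: str
    type: str  # "NEE" | "ER" | "GPP"
    flux_value: float | None
    flag: str
    turf_id: str = ""
    orig_site_id: str = ""
    dest_site_id: str = ""
    warming: str = "A"
    datetime: datetime | None = None
    round: int | None = None
    par_avg: float | None = None
    temp_soil: float | None = None
    temp_airavg: float | None = None
    #: Diurnal-baseline offset subtracted from this GPP value (provenance).
    gpp_offset: float | None = None

    def __post_init__(self) -> None:
        if self.type not in ("NEE", "ER", "GPP"):
            raise ValueError(f"type must be NEE, ER or GPP, got {self.type!r}")
        if self.flag not in FLAGS:
            raise ValueError(f"unknown flag {self.flag!r}")
        if (self.flux_value is None) != (self.flag in _ABSENT_FLAGS):
            raise ValueError(
                f"flag {self.flag!r} is inconsistent with "
                f"flux_value={self.flux_value!r}"
            )
        if self.flag == "zero" and self.flux_value != 0.0:
            raise ValueError("flag 'zero' requires flux_value == 0")


def classify(
    fit: ExponentialFit,
    series: ConcentrationSeries,
    chamber: ChamberSpec | None = None,
    thresholds: FluxQCThresholds | None = None,
) -> tuple[str, float | None]:
    """Run the flag decision tree on one fitted closure.

    Returns ``(flag, flux_value)`` where the value is ``None`` for
    removed fluxes and exactly ``0.0`` for trendless bad fits.
    """
    chamber = chamber or ChamberSpec()
    thresholds = thresholds or FluxQCThresholds()

    start = series.start_conc
    if not (thresholds.start_min <= start <= thresholds.start_max):
        return "start_error", None

    bad_fit = (
        fit.b >= thresholds.b_max
        or fit.b < 0
        or (series.kind == "ER" and fit.slope_at_tz < 0)
        or not fit.converged
    )
    if bad_fit:
        if abs(fit.pearson_r) > thresholds.r_cut:
            return "discard", None
        return "zero", 0.0
    return "okflux", flux_from_slope(fit.slope_at_tz, chamber, series.air_temp_K)


def process_series(
    series: ConcentrationSeries, config: PipelineConfig | None = None
) -> FluxRecord:
    """Trim, fit, classify and convert one raw closure into a record."""
    config = config or PipelineConfig()
    trimmed = trim_series(series, config.trim_head_s, config.trim_tail_s)
    fit = fit_exponential(trimmed, cz_window_s=config.cz_window_s)
    flag, value = classify(fit, trimmed, config.chamber, config.flux_qc)
    meta = series.metadata
    return FluxRecord(
        flux_id=series.flux_id,
        type=series.kind,
        flux_value=value,
        flag=flag,
        turf_id=str(meta.get("turfID", "")),
        orig_site_id=str(meta.get("origSiteID", "")),
        dest_site_id=str(meta.get("destSiteID", "")),
        warming=str(meta.get("warming", "A")),
        datetime=meta.get("datetime"),
        round=meta.get("round"),
        par_avg=meta.get("PARavg"),
        temp_soil=meta.get("temp_soil"),
        temp_airavg=series.air_temp_K - 273.15,
    )


def mark_weird(
    records: Sequence[FluxRecord], flux_ids: Iterable[str]
) -> list[FluxRecord]:
    """Apply the analyst's visual-inspection override list.

    Any flag except ``missing_round`` is replaced by ``weird_flux`` and
    the value removed.  Unknown IDs produce a warning, not an error.
    """
    wanted = set(flux_ids)
    known = {r.flux_id for r in records}
    for missing in sorted(wanted - known):
        warnings.warn(f"mark_weird: unknown fluxID {missing!r}", stacklevel=2)
    out = []
    for rec in records:
        if rec.flux_id in wanted and rec.flag != "missing_round":
            rec = replace(rec, flag="weird_flux", flux_value=None)
        out.append(rec)
    return out


def compute_gpp(nee: FluxRecord, er: FluxRecord) -> FluxRecord:
    """GPP = NEE - ER for one paired (plot, round) slot.

    Flag propagation: both okflux -> okflux; a zero-flagged NEE (checked
    first) -> ``zeroNEE``; a zero-flagged ER -> ``zeroER``; a value-less
    member blocks GPP with that member's flag.
    """
    if nee.type != "NEE" or er.type != "ER":
        raise ValueError(f"expected an (NEE, ER) pair, got ({nee.type}, {er.type})")
    if (nee.turf_id, nee.round) != (er.turf_id, er.round):
        raise ValueError(
            f"pairing mismatch: NEE ({nee.turf_id!r}, round {nee.round}) vs "
            f"ER ({er.turf_id!r}, round {er.round})"
        )

    if nee.flux_value is None or er.flux_value is None:
        blocker = nee if nee.flux_value is None else er
        flag, value = blocker.flag, None
    elif nee.flag == "zero":
        flag, value = "zeroNEE", nee.flux_value - er.flux_value
    elif er.flag == "zero":
        flag, value = "zeroER", nee.flux_value - er.flux_value
    else:
        flag, value = "okflux", nee.flux_value - er.flux_value

    return replace(
        nee,
        flux_id=f"{nee.flux_id}+{er.flux_id}",
        type="GPP",
        flux_value=value,
        flag=flag,
    )


def _cycle_key(rec: FluxRecord, site_start: Mapping[str, datetime]) -> tuple:
    if rec.datetime is not None:
        cycle = int(
            (rec.datetime - site_start[rec.dest_site_id]) // timedelta(hours=24)
        )
    else:
        cycle = 0
    return (rec.dest_site_id, cycle)


def night_correct_gpp(
    records: Sequence[FluxRecord], enabled: bool = True
) -> list[FluxRecord]:
    """Re-baseline GPP per site x 24 h cycle so max(GPP) = 0.

    Cycle boundaries run from each site's first measurement, not calendar
    midnight (campaigns started mid-day).  Only valued GPP records are
    shifted; flags are untouched and the subtracted offset is stored on
    each shifted record.  With ``enabled=False`` the records are returned
    unchanged.
    """
    if not enabled:
        return list(records)

    gpp_valued = [
        r for r in records if r.type == "GPP" and r.flux_value is not None
    ]
    site_start: dict[str, datetime] = {}
    for rec in gpp_valued:
        if rec.datetime is None:
            continue
        prev = site_start.get(rec.dest_site_id)
        if prev is None or rec.datetime < prev:
            site_start[rec.dest_site_id] = rec.datetime

    offsets: dict[tuple, float] = {}
    for rec in gpp_valued:
        key = _cycle_key(rec, site_start)
        offsets[key] = max(offsets.get(key, float("-inf")), rec.flux_value)

    out = []
    for rec in records:
        if rec.type == "GPP" and rec.flux_value is not None:
            offset = offsets[_cycle_key(rec, site_start)]
            rec = replace(
                rec, flux_value=rec.flux_value - offset, gpp_offset=offset
            )
        out.append(rec)
    return out


def detect_missing_rounds(
    records: Sequence[FluxRecord],
    schedule: Iterable[Mapping[str, Any]],
    types: Sequence[str] = ("NEE", "ER", "GPP"),
) -> list[FluxRecord]:
    """Add a ``missing_round`` placeholder for every unfilled slot.

    ``schedule`` lists the planned (turfID, round) slots with their
    metadata; each slot is expected to yield one record per flux type.
    """
    present = {(r.turf_id, r.round, r.type) for r in records}
    out = list(records)
    for slot in schedule:
        turf, rnd = str(slot["turfID"]), int(slot["round"])
        for flux_type in types:
            if (turf, rnd, flux_type) in present:
                continue
            out.append(
                FluxRecord(
                    flux_id=f"missing_{turf}_{rnd}_{flux_type}",
                    type=flux_type,
                    flux_value=None,
                    flag="missing_round",
                    turf_id=turf,
                    orig_site_id=str(slot.get("origSiteID", "")),
                    dest_site_id=str(slot.get("destSiteID", "")),
                    warming=str(slot.get("warming", "A")),
                    datetime=slot.get("datetime"),
                    round=rnd,
                )
            )
    return out


def process_campaign(
    series: Iterable[ConcentrationSeries],
    schedule: Iterable[Mapping[str, Any]] | None = None,
    config: PipelineConfig | None = None,
    weird_flux_ids: Iterable[str] = (),
) -> list[FluxRecord]:
    """Full flux pipeline: fit + QC each closure, pair into GPP, flag
    missing rounds and apply the diurnal GPP correction."""
    config = config or PipelineConfig()
    records = [process_series(s, config) for s in series]
    records = mark_weird(records, weird_flux_ids)

    by_slot: dict[tuple, dict[str, FluxRecord]] = {}
    for rec in records:
        by_slot.setdefault((rec.turf_id, rec.round), {})[rec.type] = rec
    for slot in by_slot.values():
        if "NEE" in slot and "ER" in slot:
            records.append(compute_gpp(slot["NEE"], slot["ER"]))

    if schedule is not None:
        records = detect_missing_rounds(records, schedule)
    return night_correct_gpp(records, enabled=config.night_correction)
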