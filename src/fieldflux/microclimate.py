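"""Microclimate logger QC.

Four-sensor loggers record near-surface air (15 cm), ground (0 cm) and
soil (-8 cm) temperature plus soil moisture every 15 min.  Processing
trims each logger's series to its deployment window and nulls readings
beyond plausibility limits: -40..30 degC (air), -40..35 degC (ground),
5..20 degC (soil), moisture >= 0 %.  Boundary-equal values are kept (the
limits are strict).  Flagged rows stay in the raw view with their values
nulled; the clean view drops them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import MicroclimateRanges

__all__ = [
    "MICRO_FLAGS",
    "trim_to_deployment",
    "apply_thresholds",
    "calibrate_moisture",
]

logger = logging.getLogger(__name__)

MICRO_FLAGS = (
    "cut_Tmin_air",
    "cut_Tmax_air",
    "cut_Tmin_ground",
    "cut_Tmax_ground",
    "cut_Tmin_soil",
    "cut_Tmax_soil",
    "cut_min_moist",
)


def trim_to_deployment(records: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with datetime_in <= datetime <= datetime_out (closed)."""
    dt = pd.to_datetime(records["datetime"])
    keep = (dt >= pd.to_datetime(records["datetime_in"])) & (
        dt <= pd.to_datetime(records["datetime_out"])
    )
    out = records.loc[keep].reset_index(drop=True)
    if out.empty and not records.empty:
        logger.warning("trim_to_deployment: no readings inside deployment window")
    return out


def apply_thresholds(
    records: pd.DataFrame, ranges: MicroclimateRanges | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and null out-of-range readings; return (raw, clean).

    ``raw`` keeps every row, with the flag set and the value nulled for
    out-of-range readings; ``clean`` contains only in-range rows.
    """
    rng = ranges or MicroclimateRanges()
    raw = records.copy().reset_index(drop=True)
    if "flag" not in raw.columns:
        raw["flag"] = ""
    value = raw["value"].astype(float)
    var = raw["climate_variable"]

    checks = (
        ("air_temperature", value < rng.air_min, "cut_Tmin_air"),
        ("air_temperature", value > rng.air_max, "cut_Tmax_air"),
        ("ground_temperature", value < rng.ground_min, "cut_Tmin_ground"),
        ("ground_temperature", value > rng.ground_max, "cut_Tmax_ground"),
        ("soil_temperature", value < rng.soil_min, "cut_Tmin_soil"),
        ("soil_temperature", value > rng.soil_max, "cut_Tmax_soil"),
        ("soil_moisture", value < rng.moisture_min, "cut_min_moist"),
    )
    flagged = pd.Series(False, index=raw.index)
    for variable, bad, flag in checks:
        mask = (var == variable) & bad & raw["value"].notna()
        flagged |= mask
        raw.loc[mask, "flag"] = flag
    raw.loc[flagged, "value"] = np.nan

    clean = raw.loc[~flagged & raw["value"].notna()].reset_index(drop=True)
    return raw, clean


def calibrate_moisture(
    raw_counts: np.ndarray | pd.Series, coefficients: dict[str, list[float]],
    soil_class: str = "silt_loam",
) -> np.ndarray:
    """Convert raw moisture counts to volumetric % via a soil-class polynomial.

    ``coefficients[soil_class]`` holds polynomial coefficients in
    descending order (numpy convention); the derivation of the
    coefficients is instrument-specific and accepted as opaque input.
    """
    if soil_class not in coefficients:
        raise KeyError(
            f"no moisture calibration coefficients for soil class {soil_class!r}"
        )
    counts = np.asarray(raw_counts, dtype=float)
    return np.polyval(np.asarray(coefficients[soil_class], dtype=float), counts)
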