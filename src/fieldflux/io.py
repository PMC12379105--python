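"""Readers and writers for the published table schemas.

Everything is plain UTF-8 CSV with ISO-8601 datetimes and decimal
points.  Schema violations (missing columns) raise :class:`SchemaError`
naming the offending columns, so a malformed file fails loudly at the
boundary rather than deep in the pipeline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chamber import ConcentrationSeries
from .config import ChamberSpec
from .fluxqc import FluxRecord
from .thermal import ATCurve, ATQCResult

__all__ = [
    "SchemaError",
    "FLUX_SERIES_COLUMNS",
    "FLUX_TABLE_COLUMNS",
    "TRAIT_TABLE_COLUMNS",
    "AT_CURVE_COLUMNS",
    "MICROCLIMATE_COLUMNS",
    "read_flux_series_csv",
    "write_flux_series_csv",
    "flux_records_to_frame",
    "write_flux_table",
    "read_flux_table",
    "write_trait_table",
    "read_trait_table",
    "read_at_curves_csv",
    "write_at_curves_csv",
    "write_at_results",
    "read_microclimate_csv",
    "write_microclimate_csv",
    "read_chamber_config",
    "clean_filename",
]


class SchemaError(ValueError):
    """A file does not match its declared table schema."""


FLUX_SERIES_COLUMNS = (
    "fluxID", "datetime", "seconds", "conc_ppm", "temp_air", "temp_soil", "par",
)
FLUX_TABLE_COLUMNS = (
    "datetime", "time", "origSiteID", "destSiteID", "turfID", "warming",
    "type", "fluxID", "flux_value", "PARavg", "temp_soil", "temp_airavg", "flag",
)
TRAIT_TABLE_COLUMNS = (
    "ID", "species", "trait", "value", "flag", "problem", "comment",
    "merged", "ID_merged",
)
AT_CURVE_COLUMNS = ("curveID", "leaf_temp_C", "assim_umol_m2_s")
MICROCLIMATE_COLUMNS = (
    "datetime", "loggerID", "turfID", "origSiteID", "destSiteID", "warming",
    "datetime_in", "datetime_out", "climate_variable", "value", "flag",
)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_flux_series_csv(path: str | Path) -> list[ConcentrationSeries]:
    """Read per-reading chamber closures (one or more fluxIDs per file)."""
    df = pd.read_csv(path)
    _require_columns(df, FLUX_SERIES_COLUMNS, str(path))
    out = []
    for flux_id, grp in df.groupby("fluxID", sort=False):
        grp = grp.sort_values("seconds")
        kind = str(grp["kind"].iloc[0]) if "kind" in grp.columns else "NEE"
        meta = {
            "datetime": pd.to_datetime(grp["datetime"].iloc[0]).to_pydatetime(),
            "temp_soil": float(grp["temp_soil"].mean()),
            "PARavg": float(grp["par"].mean()),
        }
        for key in ("turfID", "origSiteID", "destSiteID", "warming", "round"):
            if key in grp.columns:
                meta[key] = grp[key].iloc[0]
        out.append(
            ConcentrationSeries(
                flux_id=str(flux_id),
                kind=kind,
                t=grp["seconds"].to_numpy(float),
                conc=grp["conc_ppm"].to_numpy(float),
                air_temp_K=float(grp["temp_air"].mean()) + 273.15,
                metadata=meta,
            )
        )
    return out


def write_flux_series_csv(
    series: Iterable[ConcentrationSeries], path: str | Path
) -> None:
    frames = []
    for s in series:
        meta = s.metadata
        n = len(s)
        frame = pd.DataFrame(
            {
                "fluxID": s.flux_id,
                "datetime": meta.get("datetime"),
                "seconds": s.t,
                "conc_ppm": s.conc,
                "temp_air": s.air_temp_K - 273.15,
                "temp_soil": meta.get("temp_soil", np.nan),
                "par": meta.get("PARavg", np.nan),
                "kind": s.kind,
            }
        )
        for key in ("turfID", "origSiteID", "destSiteID", "warming", "round"):
            if key in meta:
                frame[key] = [meta[key]] * n
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def flux_records_to_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    """Flux records as the published flux-table schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "datetime": r.datetime.isoformat(sep=" ") if r.datetime else "",
                "time": r.datetime.time().isoformat() if r.datetime else "",
                "origSiteID": r.orig_site_id,
                "destSiteID": r.dest_site_id,
                "turfID": r.turf_id,
                "warming": r.warming,
                "type": r.type,
                "fluxID": r.flux_id,
                "flux_value": np.nan if r.flux_value is None else r.flux_value,
                "PARavg": np.nan if r.par_avg is None else r.par_avg,
                "temp_soil": np.nan if r.temp_soil is None else r.temp_soil,
                "temp_airavg": np.nan if r.temp_airavg is None else r.temp_airavg,
                "flag": r.flag,
            }
        )
    return pd.DataFrame(rows, columns=list(FLUX_TABLE_COLUMNS))


def write_flux_table(records: Iterable[FluxRecord], path: str | Path) -> None:
    flux_records_to_frame(records).to_csv(path, index=False)


def read_flux_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fluxID": str})
    _require_columns(df, FLUX_TABLE_COLUMNS, str(path))
    return df


def write_trait_table(records: pd.DataFrame, path: str | Path) -> None:
    _require_columns(records, TRAIT_TABLE_COLUMNS[:4], "trait table")
    records.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"ID": str, "flag": str, "problem": str, "comment": str},
        keep_default_na=False, na_values=[""],
    )
    _require_columns(df, TRAIT_TABLE_COLUMNS[:4], str(path))
    for col in ("flag", "problem", "comment", "ID_merged"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def read_at_curves_csv(path: str | Path) -> list[ATCurve]:
    df = pd.read_csv(path)
    _require_columns(df, AT_CURVE_COLUMNS, str(path))
    out = []
    for curve_id, grp in df.groupby("curveID", sort=False):
        out.append(
            ATCurve(
                curve_id=str(curve_id),
                species=str(grp["species"].iloc[0]) if "species" in grp.columns else "",
                site_id=str(grp["siteID"].iloc[0]) if "siteID" in grp.columns else "",
                leaf_temp=grp["leaf_temp_C"].to_numpy(float),
                assim=grp["assim_umol_m2_s"].to_numpy(float),
            )
        )
    return out


def write_at_curves_csv(curves: Iterable[ATCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "curveID": c.curve_id,
                    "leaf_temp_C": c.leaf_temp,
                    "assim_umol_m2_s": c.assim,
                    "species": c.species,
                    "siteID": c.site_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_at_results(results: Iterable[ATQCResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "curveID": r.curve_id,
                "decision": r.decision,
                "reason": r.reason,
                "fitted_topt": np.nan if r.fitted_topt is None else r.fitted_topt,
                "n_spline_maxima": r.n_spline_maxima,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def read_microclimate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        parse_dates=["datetime", "datetime_in", "datetime_out"],
        dtype={"loggerID": str},
    )
    _require_columns(df, MICROCLIMATE_COLUMNS[:10], str(path))
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    return df


def write_microclimate_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_chamber_config(path: str | Path) -> ChamberSpec:
    """Chamber geometry from a plain key-value file.

    Lines are ``key = value`` with ``#`` comments; required keys are
    ``pressure_atm``, ``volume_L`` and ``area_m2``.
    """
    values: dict[str, float] = {}
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: malformed line {raw_line!r}")
        key, _, value = line.partition("=")
        values[key.strip()] = float(value.strip())
    missing = {"pressure_atm", "volume_L", "area_m2"} - set(values)
    if missing:
        raise SchemaError(f"{path}: missing chamber keys {sorted(missing)}")
    return ChamberSpec(
        pressure_atm=values["pressure_atm"],
        volume_L=values["volume_L"],
        area_m2=values["area_m2"],
    )


def clean_filename(
    nr: str, experiment: str, variable: str, years: str, project: str = "fieldflux"
) -> str:
    """Clean-data file name: nr_project_clean_experiment_variable_years.csv."""
    return f"{nr}_{project}_clean_{experiment}_{variable}_{years}.csv"
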