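"""Leaf functional trait derivation and validation.

Raw measurements arrive as one envelope row per leaf sample: bulk wet
mass, bulk dry mass, scanned leaf area, up to three thickness readings
and plant height, with leaf counts.  Derivation produces a long-format
table (one row per sample and trait):

* per-leaf averages — wet mass, dry mass and area divided by the number
  of leaves (dry mass by the possibly smaller leaf count at the drying
  station, when leaves were lost in between);
* the scanned area of the tightly folded graminoids (Festuca rubra /
  ovina / vivipara, Avenella flexuosa, Nardus stricta) doubled to the
  true one-sided area;
* leaf thickness as the mean of the readings;
* SLA = leaf area / dry mass (cm^2 g^-1) and LDMC = dry mass / wet mass
  (g g^-1), on per-leaf values;
* chemical ratios C:N and N:P.

Validation flags biologically implausible values (strict inequalities):
LDMC > 1 g/g, SLA outside (5, 500) cm^2/g, leaf nitrogen > 6.4 %.
Flagged values are removed from the *clean* view but kept, with their
flags, in the raw view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FOLDED_SPECIES, TraitThresholds

__all__ = [
    "MORPHOLOGICAL_TRAITS",
    "CHEMICAL_TRAITS",
    "derive_traits",
    "derive_chemical_ratios",
    "expand_pooled_chemistry",
    "validate_traits",
]

MORPHOLOGICAL_TRAITS = (
    "plant_height",
    "wet_mass_g",
    "dry_mass_g",
    "leaf_area_cm2",
    "leaf_thickness_mm",
    "SLA_cm2_g",
    "LDMC_g_g",
)
CHEMICAL_TRAITS = (
    "C_percent",
    "N_percent",
    "P_percent",
    "CN_ratio",
    "NP_ratio",
    "dC13_permil",
    "dN15_permil",
)

_META_COLS = (
    "species",
    "siteID",
    "blockID",
    "turfID",
    "warming",
    "individual_nr",
    "date",
)


def _trait_row(
    sample: pd.Series, trait: str, value: float | None, flag: str = ""
) -> dict:
    row = {"ID": sample["ID"], "trait": trait,
           "value": np.nan if value is None else value,
           "flag": flag, "problem": str(sample.get("problem", "") or ""),
           "comment": str(sample.get("comment", "") or ""),
           "merged": False, "ID_merged": ""}
    for col in _META_COLS:
        if col in sample.index:
            row[col] = sample[col]
    return row


def _get(sample: pd.Series, name: str) -> float | None:
    value = sample.get(name)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def derive_traits(
    samples: pd.DataFrame, folded_species: frozenset[str] | set[str] = FOLDED_SPECIES
) -> pd.DataFrame:
    """Derive long-format trait records from an envelope table.

    Missing or zero-denominator inputs yield rows with an absent value
    and a ``missing <field>`` flag rather than exceptions.
    """
    records: list[dict] = []
    for _, sample in samples.iterrows():
        n_leaves = int(sample.get("n_leaves", 1) or 1)
        n_at_dry = int(sample.get("n_leaves_at_dry", n_leaves) or n_leaves)
        wet = _get(sample, "wet_mass")
        dry = _get(sample, "dry_mass")
        scanned = _get(sample, "scanned_area")

        height = _get(sample, "plant_height")
        records.append(
            _trait_row(sample, "plant_height", height,
                       "" if height is not None else "missing plant_height")
        )

        area = None
        if scanned is not None:
            area = scanned * 2.0 if sample["species"] in folded_species else scanned

        wet_leaf = wet / n_leaves if wet is not None else None
        dry_leaf = dry / n_at_dry if dry is not None else None
        area_leaf = area / n_leaves if area is not None else None

        records.append(
            _trait_row(sample, "wet_mass_g", wet_leaf,
                       "" if wet_leaf is not None else "missing wet_mass")
        )
        records.append(
            _trait_row(sample, "dry_mass_g", dry_leaf,
                       "" if dry_leaf is not None else "missing dry_mass")
        )
        records.append(
            _trait_row(sample, "leaf_area_cm2", area_leaf,
                       "" if area_leaf is not None else "missing scanned_area")
        )

        readings = [
            _get(sample, c)
            for c in ("thickness_1", "thickness_2", "thickness_3")
            if _get(sample, c) is not None
        ]
        records.append(
            _trait_row(
                sample,
                "leaf_thickness_mm",
                float(np.mean(readings)) if readings else None,
                "" if readings else "missing thickness",
            )
        )

        if area_leaf is not None and dry_leaf is not None and dry_leaf > 0:
            records.append(_trait_row(sample, "SLA_cm2_g", area_leaf / dry_leaf))
        else:
            flag = "missing dry_mass" if dry_leaf in (None, 0) else "missing scanned_area"
            records.append(_trait_row(sample, "SLA_cm2_g", None, flag))

        if wet_leaf is not None and dry_leaf is not None and wet_leaf > 0:
            records.append(_trait_row(sample, "LDMC_g_g", dry_leaf / wet_leaf))
        else:
            flag = "missing wet_mass" if wet_leaf in (None, 0) else "missing dry_mass"
            records.append(_trait_row(sample, "LDMC_g_g", None, flag))

        for col, trait in (
            ("C_percent", "C_percent"),
            ("N_percent", "N_percent"),
            ("P_percent", "P_percent"),
            ("dC13", "dC13_permil"),
            ("dN15", "dN15_permil"),
        ):
            if col in sample.index:
                value = _get(sample, col)
                if value is not None:
                    records.append(_trait_row(sample, trait, value))
        c, n, p = (_get(sample, k) for k in ("C_percent", "N_percent", "P_percent"))
        cn, np_ratio = derive_chemical_ratios(c, n, p)
        if cn is not None:
            records.append(_trait_row(sample, "CN_ratio", cn))
        if np_ratio is not None:
            records.append(_trait_row(sample, "NP_ratio", np_ratio))
    return pd.DataFrame(records)


def derive_chemical_ratios(
    c_percent: float | None, n_percent: float | None, p_percent: float | None
) -> tuple[float | None, float | None]:
    """C:N and N:P mass ratios; absent on missing input or zero denominator."""
    cn = None
    if c_percent is not None and n_percent not in (None, 0):
        cn = c_percent / n_percent
    np_ratio = None
    if n_percent is not None and p_percent not in (None, 0):
        np_ratio = n_percent / p_percent
    return cn, np_ratio


def expand_pooled_chemistry(
    pooled: pd.DataFrame, members: dict[str, list[str]]
) -> pd.DataFrame:
    """Duplicate pooled chemistry rows onto each member leaf.

    ``pooled`` is a long-format trait table keyed by pool ID; ``members``
    maps pool ID to the individual leaf IDs it contains.  Each member
    receives a copy with ``merged=True`` (``False`` for singleton pools)
    and the underscore-joined member list in ``ID_merged``.
    """
    rows = []
    for _, row in pooled.iterrows():
        pool_members = members.get(row["ID"], [row["ID"]])
        merged = len(pool_members) > 1
        id_merged = "_".join(pool_members) if merged else ""
        for member in pool_members:
            new = row.copy()
            new["ID"] = member
            new["merged"] = merged
            new["ID_merged"] = id_merged
            rows.append(new)
    return pd.DataFrame(rows).reset_index(drop=True)


_REMOVAL_CHECKS = (
    # (trait, predicate name, flag text)
    ("LDMC_g_g", "ldmc", "unreliable LDMC above 1 g/g"),
    ("SLA_cm2_g", "sla_low", "unreliable SLA below 5 cm2/g"),
    ("SLA_cm2_g", "sla_high", "unreliable SLA above 500 cm2/g"),
    ("N_percent", "nitrogen", "unreliable leaf nitrogen above 6.4%"),
)


def validate_traits(
    records: pd.DataFrame, thresholds: TraitThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag implausible trait values and build the clean view.

    Returns ``(raw, clean)``.  ``raw`` keeps every row with machine
    flags appended to any pre-existing free-text flag; ``clean`` drops
    the flagged-removed values and duplicate (ID, trait) rows (first row
    kept).  Boundary-equal values are retained — the thresholds are
    strict inequalities.
    """
    thr = thresholds or TraitThresholds()
    raw = records.copy().reset_index(drop=True)
    value = raw["value"].astype(float)

    predicates = {
        "ldmc": (raw["trait"] == "LDMC_g_g") & (value > thr.ldmc_max),
        "sla_low": (raw["trait"] == "SLA_cm2_g") & (value < thr.sla_min),
        "sla_high": (raw["trait"] == "SLA_cm2_g") & (value > thr.sla_max),
        "nitrogen": (raw["trait"] == "N_percent") & (value > thr.nitrogen_max),
    }
    removed = pd.Series(False, index=raw.index)
    for trait, name, text in _REMOVAL_CHECKS:
        mask = predicates[name]
        removed |= mask
        if mask.any():
            existing = raw.loc[mask, "flag"].astype(str)
            raw.loc[mask, "flag"] = np.where(
                existing == "", text, existing + "; " + text
            )

    clean = raw.loc[~removed].drop_duplicates(subset=["ID", "trait"], keep="first")
    clean = clean.reset_index(drop=True)
    return raw, clean
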