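"""Trait derivation arithmetic, folded-leaf doubling, validation thresholds."""

import numpy as np
import pandas as pd
import pytest

from fieldflux.config import TraitThresholds
from fieldflux.synthetic import TraitScenario, generate_trait_table
from fieldflux.traits import (
    derive_chemical_ratios,
    derive_traits,
    expand_pooled_chemistry,
    validate_traits,
)


def sample_row(**kw):
    base = dict(
        ID="AAB0001", species="Achillea millefolium", n_leaves=1,
        n_leaves_at_dry=1, wet_mass=0.1, dry_mass=0.025, scanned_area=5.0,
        thickness_1=0.2, thickness_2=np.nan, thickness_3=np.nan,
        plant_height=12.0,
    )
    base.update(kw)
    return pd.DataFrame([base])


def trait_value(records, trait):
    rows = records[records["trait"] == trait]
    assert len(rows) == 1
    return rows["value"].iloc[0]


class TestDeriveTraits:
    def test_worked_example_two_leaf_sample(self):
        records = derive_traits(
            sample_row(n_leaves=2, n_leaves_at_dry=2,
                       wet_mass=0.2, dry_mass=0.05, scanned_area=10.0)
        )
        assert trait_value(records, "wet_mass_g") == pytest.approx(0.1)
        assert trait_value(records, "dry_mass_g") == pytest.approx(0.025)
        assert trait_value(records, "leaf_area_cm2") == pytest.approx(5.0)
        assert trait_value(records, "SLA_cm2_g") == pytest.approx(200.0)
        assert trait_value(records, "LDMC_g_g") == pytest.approx(0.25)

    def test_folded_graminoid_area_doubled(self):
        records = derive_traits(
            sample_row(species="Festuca rubra", scanned_area=3.10)
        )
        assert trait_value(records, "leaf_area_cm2") == pytest.approx(6.20)

    def test_unfolded_species_area_unchanged(self):
        records = derive_traits(sample_row(scanned_area=3.10))
        assert trait_value(records, "leaf_area_cm2") == pytest.approx(3.10)

    def test_thickness_is_mean_of_readings(self):
        records = derive_traits(
            sample_row(thickness_1=0.20, thickness_2=0.25, thickness_3=0.21)
        )
        assert trait_value(records, "leaf_thickness_mm") == pytest.approx(0.22)

    def test_leaf_loss_uses_count_at_drying(self):
        records = derive_traits(
            sample_row(n_leaves=3, n_leaves_at_dry=2,
                       wet_mass=0.3, dry_mass=0.05, scanned_area=9.0)
        )
        assert trait_value(records, "wet_mass_g") == pytest.approx(0.1)
        assert trait_value(records, "dry_mass_g") == pytest.approx(0.025)
        # per-leaf SLA/LDMC stay internally consistent
        assert trait_value(records, "SLA_cm2_g") == pytest.approx(3.0 / 0.025)
        assert trait_value(records, "LDMC_g_g") == pytest.approx(0.25)

    def test_missing_input_flags_instead_of_raising(self):
        records = derive_traits(sample_row(dry_mass=np.nan))
        sla = records[records["trait"] == "SLA_cm2_g"]
        assert np.isnan(sla["value"].iloc[0])
        assert sla["flag"].iloc[0] == "missing dry_mass"

    def test_sla_ldmc_product_identity(self):
        samples, _ = generate_trait_table(TraitScenario(n_samples=300, seed=6))
        records = derive_traits(samples)
        wide = records.pivot_table(index="ID", columns="trait", values="value")
        product = wide["SLA_cm2_g"] * wide["LDMC_g_g"]
        # the per-leaf dry mass cancels, leaving per-leaf area over wet mass
        expected = wide["leaf_area_cm2"] / wide["wet_mass_g"]
        assert np.allclose(product, expected, rtol=1e-9)

    def test_scale_invariance_when_no_leaf_loss(self):
        one = derive_traits(
            sample_row(n_leaves=1, n_leaves_at_dry=1,
                       wet_mass=0.1, dry_mass=0.025, scanned_area=5.0)
        )
        four = derive_traits(
            sample_row(n_leaves=4, n_leaves_at_dry=4,
                       wet_mass=0.4, dry_mass=0.1, scanned_area=20.0)
        )
        for trait in ("SLA_cm2_g", "LDMC_g_g"):
            assert trait_value(one, trait) == pytest.approx(trait_value(four, trait))


class TestChemicalRatios:
    def test_cn_ratio(self):
        assert derive_chemical_ratios(45.0, 2.25, 0.2)[0] == pytest.approx(20.0)

    def test_np_ratio(self):
        assert derive_chemical_ratios(45.0, 2.0, 0.2)[1] == pytest.approx(10.0)

    def test_missing_nitrogen_blanks_both(self):
        assert derive_chemical_ratios(45.0, None, 0.2) == (None, None)

    def test_zero_denominator_blanks(self):
        cn, np_ratio = derive_chemical_ratios(45.0, 2.0, 0.0)
        assert cn is not None and np_ratio is None


class TestPooledChemistry:
    pooled = pd.DataFrame(
        [
            {"ID": "POOL1", "trait": "N_percent", "value": 2.5,
             "flag": "", "problem": "", "comment": "", "merged": False,
             "ID_merged": ""},
        ]
    )

    def test_pool_of_three_expands_to_three_rows(self):
        out = expand_pooled_chemistry(self.pooled, {"POOL1": ["A", "B", "C"]})
        assert len(out) == 3
        assert set(out["ID"]) == {"A", "B", "C"}
        assert out["merged"].all()
        assert (out["ID_merged"] == "A_B_C").all()

    def test_singleton_pool_not_marked_merged(self):
        out = expand_pooled_chemistry(self.pooled, {"POOL1": ["A"]})
        assert len(out) == 1 and not out["merged"].iloc[0]

    def test_deduplication_drops_copies(self):
        out = expand_pooled_chemistry(self.pooled, {"POOL1": ["A", "B", "C"]})
        deduped = out.drop_duplicates(subset=["ID_merged", "trait"])
        assert len(out) - len(deduped) == 2


def long_row(trait, value, sample_id="X1"):
    return {"ID": sample_id, "trait": trait, "value": value, "flag": "",
            "problem": "", "comment": "", "merged": False, "ID_merged": ""}


class TestValidation:
    def test_ldmc_above_one_removed_from_clean_view(self):
        raw, clean = validate_traits(pd.DataFrame([long_row("LDMC_g_g", 1.05)]))
        assert "unreliable LDMC" in raw["flag"].iloc[0]
        assert clean.empty

    def test_sla_inside_interval_retained(self):
        _, clean = validate_traits(pd.DataFrame([long_row("SLA_cm2_g", 200.0)]))
        assert len(clean) == 1

    def test_nitrogen_above_cutoff_flagged(self):
        raw, clean = validate_traits(pd.DataFrame([long_row("N_percent", 7.0)]))
        assert "unreliable leaf nitrogen" in raw["flag"].iloc[0]
        assert clean.empty

    def test_boundaries_are_strict(self):
        records = pd.DataFrame(
            [long_row("SLA_cm2_g", 500.0), long_row("SLA_cm2_g", 5.0, "X2"),
             long_row("LDMC_g_g", 1.0, "X3"), long_row("N_percent", 6.4, "X4")]
        )
        raw, clean = validate_traits(records)
        assert (raw["flag"] == "").all()
        assert len(clean) == 4

    def test_duplicate_rows_dropped_keeping_first(self):
        records = pd.DataFrame(
            [long_row("SLA_cm2_g", 200.0), long_row("SLA_cm2_g", 210.0)]
        )
        _, clean = validate_traits(records)
        assert len(clean) == 1 and clean["value"].iloc[0] == 200.0

    def test_widening_thresholds_never_flags_more(self):
        samples, _ = generate_trait_table(
            TraitScenario(
                n_samples=400,
                violation_rates={"ldmc": 0.05, "sla_low": 0.05,
                                 "sla_high": 0.05, "nitrogen": 0.05},
                seed=3,
            )
        )
        records = derive_traits(samples)
        strict_raw, _ = validate_traits(records, TraitThresholds())
        wide_raw, _ = validate_traits(
            records,
            TraitThresholds(ldmc_max=2.0, sla_min=1.0, sla_max=700.0,
                            nitrogen_max=9.0),
        )
        n_strict = strict_raw["flag"].str.startswith("unreliable").sum()
        n_wide = wide_raw["flag"].str.startswith("unreliable").sum()
        assert n_wide <= n_strict

    def test_bookkeeping_clean_rows(self):
        records = pd.DataFrame(
            [long_row("SLA_cm2_g", 200.0), long_row("SLA_cm2_g", 200.0),
             long_row("LDMC_g_g", 1.2, "X2"), long_row("N_percent", 2.0, "X3")]
        )
        raw, clean = validate_traits(records)
        n_removed = raw["flag"].str.startswith("unreliable").sum()
        n_duplicates = 1
        assert len(clean) == len(raw) - n_removed - n_duplicates

    def test_flags_exactly_match_injected_violations(self):
        samples, truth = generate_trait_table(
            TraitScenario(
                n_samples=500,
                violation_rates={"ldmc": 0.04, "sla_low": 0.04,
                                 "sla_high": 0.04, "nitrogen": 0.04},
                seed=12,
            )
        )
        raw, _ = validate_traits(derive_traits(samples))
        flagged_ids = set(raw.loc[raw["flag"].str.startswith("unreliable"), "ID"])
        intended_ids = set(truth.loc[truth["intended_flag"] != "", "ID"])
        assert flagged_ids == intended_ids
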