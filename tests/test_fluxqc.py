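"""Flux QC decision tree, GPP partitioning, diurnal correction, bookkeeping."""

from collections import Counter
from datetime import datetime, timedelta

import numpy as np
import pytest

from fieldflux.chamber import ConcentrationSeries, ExponentialFit
from fieldflux.fluxqc import (
    FluxRecord,
    classify,
    compute_gpp,
    detect_missing_rounds,
    mark_weird,
    night_correct_gpp,
)


def make_fit(b=0.1, r=0.1, slope=1.0, converged=True):
    return ExponentialFit(
        Cm=450.0, a=0.02, b=b, tz=10.0, Cz=400.0, rmse=0.5,
        slope_at_tz=slope, pearson_r=r, converged=converged,
    )


def make_series(start=430.0, kind="NEE"):
    t = np.arange(160.0)
    return ConcentrationSeries("s1", kind, t, np.full(160, start))


class TestClassify:
    @pytest.mark.parametrize("start", [560.0, 300.0, 521.1, 320.9])
    def test_implausible_start_concentration(self, start):
        flag, value = classify(make_fit(), make_series(start=start))
        assert flag == "start_error" and value is None

    def test_boundary_start_concentrations_pass(self):
        for start in (321.0, 521.0):
            flag, _ = classify(make_fit(), make_series(start=start))
            assert flag == "okflux"

    def test_bad_b_with_trend_discarded(self):
        flag, value = classify(make_fit(b=1.2, r=0.8), make_series())
        assert flag == "discard" and value is None

    def test_bad_b_without_trend_zeroed(self):
        flag, value = classify(make_fit(b=1.2, r=0.3), make_series())
        assert flag == "zero" and value == 0.0

    def test_negative_b_is_bad_fit(self):
        flag, _ = classify(make_fit(b=-0.1, r=0.9), make_series())
        assert flag == "discard"

    def test_b_exactly_one_is_bad_fit(self):
        flag, _ = classify(make_fit(b=1.0, r=0.9), make_series())
        assert flag == "discard"

    def test_r_exactly_half_takes_zero_branch(self):
        flag, value = classify(make_fit(b=1.2, r=0.5), make_series())
        assert flag == "zero" and value == 0.0

    def test_er_with_negative_slope_discarded(self):
        flag, _ = classify(
            make_fit(slope=-0.4, r=-0.7), make_series(kind="ER")
        )
        assert flag == "discard"

    def test_nee_with_negative_slope_is_fine(self):
        flag, value = classify(make_fit(slope=-0.4, r=-0.9), make_series())
        assert flag == "okflux" and value < 0

    def test_nonconverged_fit_is_bad(self):
        flag, _ = classify(make_fit(converged=False, r=0.1), make_series())
        assert flag == "zero"

    def test_good_fit_passes_all_gates(self):
        flag, value = classify(make_fit(b=0.4, r=0.9), make_series(start=430.0))
        assert flag == "okflux" and value > 0

    def test_start_error_checked_before_fit_quality(self):
        flag, _ = classify(make_fit(b=1.2, r=0.9), make_series(start=560.0))
        assert flag == "start_error"


def rec(flux_id="1", type="NEE", value=1.0, flag="okflux", **kw):
    defaults = dict(turf_id="T1", dest_site_id="S1", round=0)
    defaults.update(kw)
    return FluxRecord(flux_id=flux_id, type=type, flux_value=value, flag=flag, **defaults)


class TestMarkWeird:
    def test_empty_list_is_noop(self):
        records = [rec()]
        assert mark_weird(records, []) == records

    def test_single_id_changes_exactly_one_record(self):
        records = [rec("1"), rec("2")]
        out = mark_weird(records, ["2"])
        assert [r.flag for r in out] == ["okflux", "weird_flux"]
        assert out[1].flux_value is None

    def test_unknown_id_warns_without_change(self):
        records = [rec("1")]
        with pytest.warns(UserWarning, match="nope"):
            out = mark_weird(records, ["nope"])
        assert out == records

    def test_missing_round_not_overridden(self):
        records = [rec("1", value=None, flag="missing_round")]
        out = mark_weird(records, ["1"])
        assert out[0].flag == "missing_round"


class TestComputeGpp:
    def test_arithmetic(self):
        gpp = compute_gpp(rec(value=-10.0), rec(type="ER", value=4.0))
        assert gpp.type == "GPP" and gpp.flux_value == -14.0
        assert gpp.flag == "okflux"

    def test_zero_er_propagates_as_zeroer(self):
        gpp = compute_gpp(rec(value=-10.0), rec(type="ER", value=0.0, flag="zero"))
        assert gpp.flag == "zeroER" and gpp.flux_value == -10.0

    def test_zero_nee_propagates_as_zeronee(self):
        gpp = compute_gpp(rec(value=0.0, flag="zero"), rec(type="ER", value=4.0))
        assert gpp.flag == "zeroNEE" and gpp.flux_value == -4.0

    def test_discarded_member_blocks_gpp(self):
        gpp = compute_gpp(rec(value=None, flag="discard"), rec(type="ER", value=4.0))
        assert gpp.flag == "discard" and gpp.flux_value is None

    def test_mismatched_pairing_keys_raise(self):
        with pytest.raises(ValueError, match="pairing mismatch"):
            compute_gpp(rec(), rec(type="ER", turf_id="other"))

    def test_wrong_types_raise(self):
        with pytest.raises(ValueError):
            compute_gpp(rec(type="ER"), rec(type="ER"))


def gpp_rec(value, ts, site="S1", flag="okflux", n=[0]):
    n[0] += 1
    return FluxRecord(
        flux_id=f"g{n[0]}", type="GPP", flux_value=value, flag=flag,
        dest_site_id=site, datetime=ts, turf_id="T1", round=0,
    )


class TestNightCorrection:
    T0 = datetime(2022, 7, 25, 12, 0)

    def test_group_rebaselined_to_zero(self):
        records = [gpp_rec(v, self.T0 + timedelta(hours=i))
                   for i, v in enumerate([-12.0, -4.5, 1.5])]
        out = night_correct_gpp(records)
        assert [r.flux_value for r in out] == [-13.5, -6.0, 0.0]
        assert all(r.gpp_offset == 1.5 for r in out)

    def test_all_negative_group(self):
        records = [gpp_rec(-5.0, self.T0), gpp_rec(-2.0, self.T0 + timedelta(hours=1))]
        assert [r.flux_value for r in night_correct_gpp(records)] == [-3.0, 0.0]

    def test_single_record_group(self):
        assert night_correct_gpp([gpp_rec(3.0, self.T0)])[0].flux_value == 0.0

    def test_sites_and_cycles_corrected_independently(self):
        records = [
            gpp_rec(-4.0, self.T0, site="A"),
            gpp_rec(2.0, self.T0, site="B"),
            gpp_rec(-1.0, self.T0 + timedelta(hours=30), site="A"),  # next cycle
        ]
        out = night_correct_gpp(records)
        by_id = {r.flux_id: r.flux_value for r in out}
        assert list(by_id.values()) == [0.0, 0.0, 0.0]

    def test_disabled_switch_leaves_values_bit_exact(self):
        records = [gpp_rec(v, self.T0 + timedelta(hours=i))
                   for i, v in enumerate([-12.0, -4.5, 1.5])]
        assert night_correct_gpp(records, enabled=False) == records

    def test_flags_unchanged_and_nee_er_untouched(self):
        nee = rec(value=5.0)
        records = [nee, gpp_rec(1.0, self.T0, flag="zeroER")]
        out = night_correct_gpp(records)
        assert out[0] == nee
        assert out[1].flag == "zeroER"


class TestDetectMissingRounds:
    schedule = [{"turfID": "T1", "round": r} for r in range(3)]

    def full_records(self):
        out = []
        for r in range(3):
            for ty in ("NEE", "ER", "GPP"):
                out.append(rec(f"{ty}{r}", type=ty, round=r))
        return out

    def test_full_campaign_adds_nothing(self):
        records = self.full_records()
        assert detect_missing_rounds(records, self.schedule) == records

    def test_one_absent_round_both_types(self):
        records = [r for r in self.full_records() if r.round != 1]
        out = detect_missing_rounds(records, self.schedule, types=("NEE", "ER"))
        added = [r for r in out if r.flag == "missing_round"]
        assert len(added) == 2
        assert {(r.type, r.round) for r in added} == {("NEE", 1), ("ER", 1)}

    def test_gpp_placeholders_mirror_gaps(self):
        records = [r for r in self.full_records() if r.round != 1]
        added = [r for r in detect_missing_rounds(records, self.schedule)
                 if r.flag == "missing_round"]
        assert {(r.type, r.round) for r in added} == {
            ("NEE", 1), ("ER", 1), ("GPP", 1)
        }


class TestCampaignPipeline:
    def test_flags_match_injected_failure_modes(self, processed_campaign):
        campaign, records = processed_campaign
        intended = dict(
            zip(campaign.truth["fluxID"], campaign.truth["intended_flag"])
        )
        measured = {r.flux_id: r.flag for r in records if r.flux_id in intended}
        assert measured == intended

    def test_flag_partition_is_exact(self, processed_campaign):
        campaign, records = processed_campaign
        counts = Counter(r.flag for r in records)
        assert sum(counts.values()) == len(records)
        assert len(records) == len(campaign.schedule) * 3  # NEE, ER, GPP per slot

    def test_each_slot_has_one_record_per_type(self, processed_campaign):
        _, records = processed_campaign
        slots = Counter((r.turf_id, r.round, r.type) for r in records)
        assert set(slots.values()) == {1}

    def test_night_corrected_gpp_max_is_zero(self, processed_campaign):
        _, records = processed_campaign
        gpp = [r.flux_value for r in records
               if r.type == "GPP" and r.flux_value is not None]
        assert max(gpp) == pytest.approx(0.0, abs=1e-12)
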