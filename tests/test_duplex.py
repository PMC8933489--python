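"""Duplex consensus, plasma calling filters, fragment sizes, fusions, phasing."""

import itertools

import numpy as np
import pandas as pd
import pytest

import retwatch as rw
from retwatch.duplex import LOD_AF, MIN_ALT_HOTSPOT, MIN_ALT_NON_HOTSPOT


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["umi_pair", "frag_start", "frag_end", "strand", "base"]
    )


class TestDuplexConsensus:
    def test_agreeing_family_emits_shared_base(self):
        rows = [("AAA+CCC", 100, 250, "top", "T")] * 3 + [
            ("AAA+CCC", 100, 250, "bottom", "T")
        ] * 2
        out = rw.build_duplex_consensus(_reads(rows))
        assert len(out) == 1
        assert out.iloc[0]["base"] == "T"
        assert out.iloc[0]["n_top"] == 3 and out.iloc[0]["n_bottom"] == 2

    def test_single_strand_family_emits_nothing(self):
        rows = [("AAA+CCC", 100, 250, "top", "T")] * 5
        assert len(rw.build_duplex_consensus(_reads(rows))) == 0

    def test_strand_disagreement_gives_n(self):
        rows = [("AAA+CCC", 100, 250, "top", "A"), ("AAA+CCC", 100, 250, "bottom", "G")]
        out = rw.build_duplex_consensus(_reads(rows))
        assert out.iloc[0]["base"] == "N"

    def test_simplex_agreement_threshold(self):
        # 8 of 10 top reads agree (80% < 90%) -> simplex N -> duplex N
        rows = [("AAA+CCC", 100, 250, "top", "T")] * 8 + [
            ("AAA+CCC", 100, 250, "top", "A")
        ] * 2 + [("AAA+CCC", 100, 250, "bottom", "T")]
        out = rw.build_duplex_consensus(_reads(rows))
        assert out.iloc[0]["base"] == "N"

    def test_umi_canonicalization_merges_orientations(self):
        # same duplex tagged CCC+AAA on the opposite strand
        rows = [("AAA+CCC", 100, 250, "top", "T"), ("CCC+AAA", 100, 250, "bottom", "T")]
        out = rw.build_duplex_consensus(_reads(rows))
        assert len(out) == 1 and out.iloc[0]["base"] == "T"

    def test_unknown_strand_label_errors(self):
        with pytest.raises(ValueError):
            rw.build_duplex_consensus(_reads([("A+C", 1, 2, "fwd", "T")]))

    def test_duplex_count_bounded_by_dual_strand_families(self):
        fams = rw.simulate_read_families(0.3, 300, 1.0, 0.0, seed=9)
        out = rw.build_duplex_consensus(fams)
        dual = (
            fams.groupby("family_id")["strand"].nunique().eq(2).sum()
        )
        assert len(out) <= dual


class TestErrorSuppression:
    def test_duplex_suppresses_raw_errors_tenfold(self):
        """At true AF 0 and raw error 1e-3, duplex alt fraction is >=10x lower."""
        fams = rw.simulate_read_families(0.0, 10_000, 3.0, 1e-3, seed=17)
        raw_alt = (fams["base"] == "T").mean()
        cons = rw.build_duplex_consensus(fams)
        dup_alt = (cons["base"] == "T").mean()
        assert raw_alt > 5e-4  # errors really are present in raw reads
        assert dup_alt <= raw_alt / 10


class TestCallingFilters:
    def test_hotspot_single_read_passes(self):
        pileup = pd.DataFrame(
            [{"variant_id": "v", "duplex_depth": 500, "duplex_alt": 1, "hotspot_flag": True}]
        )
        (call,) = rw.call_plasma_variants(pileup)
        assert call.passed and call.af == pytest.approx(0.002)

    def test_non_hotspot_needs_three_reads(self):
        pileup = pd.DataFrame(
            [{"variant_id": "v", "duplex_depth": 1000, "duplex_alt": 2, "hotspot_flag": False}]
        )
        (call,) = rw.call_plasma_variants(pileup)
        assert not call.passed

    def test_lod_filters_low_af(self):
        pileup = pd.DataFrame(
            [{"variant_id": "v", "duplex_depth": 10_000, "duplex_alt": 3, "hotspot_flag": False}]
        )
        (call,) = rw.call_plasma_variants(pileup)
        assert not call.passed  # af 0.03% below the 0.1% LOD

    def test_buffy_coat_observation_filters_ch(self):
        pileup = pd.DataFrame(
            [{"variant_id": "v", "duplex_depth": 1000, "duplex_alt": 50, "hotspot_flag": True}]
        )
        buffy = pd.DataFrame([{"variant_id": "v", "duplex_depth": 400, "duplex_alt": 2}])
        (call,) = rw.call_plasma_variants(pileup, buffy_pileup=buffy)
        assert call.ch_filtered and not call.passed

    def test_zero_depth_not_assessable(self):
        pileup = pd.DataFrame(
            [{"variant_id": "v", "duplex_depth": 0, "duplex_alt": 0, "hotspot_flag": True}]
        )
        (call,) = rw.call_plasma_variants(pileup)
        assert not call.assessable and not call.passed

    def test_exhaustive_grid_matches_brute_force_rules(self):
        """All (hotspot, alt, depth) in {0..5} x {500, 1000} vs direct rule check."""
        rows = []
        for hotspot, alt, depth in itertools.product(
            [True, False], range(6), [500, 1000]
        ):
            rows.append(
                {
                    "variant_id": f"v_{hotspot}_{alt}_{depth}",
                    "duplex_depth": depth,
                    "duplex_alt": alt,
                    "hotspot_flag": hotspot,
                }
            )
        pileup = pd.DataFrame(rows)
        calls = {c.variant_id: c.passed for c in rw.call_plasma_variants(pileup)}
        for row in rows:
            af = row["duplex_alt"] / row["duplex_depth"]
            min_alt = MIN_ALT_HOTSPOT if row["hotspot_flag"] else MIN_ALT_NON_HOTSPOT
            expect = af >= LOD_AF and row["duplex_alt"] >= min_alt
            assert calls[row["variant_id"]] == expect, row


class TestFragmentSizeTest:
    def test_identical_samples_null(self):
        rng = np.random.default_rng(2)
        x = rng.normal(160, 20, 200)
        res = rw.fragment_size_test(x, x)
        assert res.assessable
        assert res.median_difference == 0
        assert res.p_value == pytest.approx(0.5, abs=0.02)

    def test_shorter_tumor_fragments_detected(self):
        rng = np.random.default_rng(3)
        res = rw.fragment_size_test(rng.normal(145, 20, 200), rng.normal(167, 20, 200))
        assert res.p_value < 0.01
        assert res.median_difference < 0

    def test_too_few_fragments_not_assessable(self):
        res = rw.fragment_size_test([150] * 5, [160] * 200)
        assert not res.assessable

    def test_power_against_simulated_cfdna(self):
        """Tumor (145,20) vs WBC (167,20) at n=200: rejects at alpha=0.05
        in >=80% of replicates (simulation oracle)."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 50
        for _ in range(reps):
            cand = rng.normal(145, 20, 200)
            ref = rng.normal(167, 20, 200)
            if rw.fragment_size_test(cand, ref).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.8


class TestFusionAf:
    def test_stated_rule(self):
        assert rw.fusion_af(10, 990, 1010) == pytest.approx(0.01)

    def test_zero_spanning(self):
        assert rw.fusion_af(0, 500, 500) == 0.0

    def test_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert rw.fusion_af(100, 10, 10) == 1.0

    def test_zero_flanks_error(self):
        with pytest.raises(ValueError):
            rw.fusion_af(5, 0, 0)


def _frag_table(both, only_a, only_b, neither=0):
    rows = (
        [{"alt_a": True, "alt_b": True}] * both
        + [{"alt_a": True, "alt_b": False}] * only_a
        + [{"alt_a": False, "alt_b": True}] * only_b
        + [{"alt_a": False, "alt_b": False}] * neither
    )
    return pd.DataFrame(rows)


class TestPhasing:
    def test_all_cis_pattern(self):
        res = rw.phase_pair(_frag_table(20, 0, 0), "V804M", "Y806C")
        assert res.call == "cis"
        assert (res.both_alt, res.only_a, res.only_b) == (20, 0, 0)

    def test_exclusive_pattern_is_trans(self):
        assert rw.phase_pair(_frag_table(0, 15, 15)).call == "trans"

    def test_mixed_pattern_ambiguous(self):
        assert rw.phase_pair(_frag_table(5, 5, 5)).call == "ambiguous"

    def test_thresholds_exact(self):
        # 8/10 = 0.8 -> cis (inclusive); 2/10 = 0.2 -> trans (inclusive)
        assert rw.phase_pair(_frag_table(8, 1, 1)).call == "cis"
        assert rw.phase_pair(_frag_table(2, 4, 4)).call == "trans"
        assert rw.phase_pair(_frag_table(7, 2, 1)).call == "ambiguous"

    def test_too_few_informative_not_assessable(self):
        assert rw.phase_pair(_frag_table(1, 1, 0, neither=50)).call == "not_assessable"
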