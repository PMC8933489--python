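"""Knowledge-table annotation, mechanism rules, cohort metrics."""

import numpy as np
import pandas as pd
import pytest

import retwatch as rw
from conftest import resistance_trajectories


class TestAnnotation:
    @pytest.mark.parametrize(
        "gene,change,expected",
        [
            ("RET", "G810C", ["solvent_front"]),
            ("RET", "p.G810S", ["solvent_front"]),
            ("RET", "V804M", ["gatekeeper"]),
            ("RET", "Y806C", ["roof"]),
            ("RET", "T1078M", ["vus"]),
            ("RET", "M918T", ["oncogenic_activating"]),
            ("KRAS", "G12V", ["oncogenic_activating"]),  # residue-class match
            ("KRAS", "A59del", ["oncogenic_activating"]),
            ("NRAS", "Q61R", ["oncogenic_activating"]),
            ("BRAF", "D594N", ["oncogenic_activating"]),
            ("EGFR", "L858R", []),  # not in the table
            ("KRAS", "G11V", []),  # wrong residue
        ],
    )
    def test_lookup(self, knowledge, gene, change, expected):
        assert rw.annotate_variant(gene, change, knowledge) == expected

    def test_amplification_targets(self, knowledge):
        assert rw.annotate_variant("MET", None, knowledge, is_amplification=True) == [
            "amplification_target"
        ]
        assert rw.annotate_variant("KRAS", None, knowledge, is_amplification=True) == []

    def test_exact_match_beats_residue_class(self):
        frame = pd.DataFrame(
            {
                "gene": ["KRAS", "KRAS"],
                "allele": ["G12*", "G12C"],
                "category": ["oncogenic_activating", "special"],
            }
        )
        table = rw.KnowledgeTable(frame)
        assert table.lookup("KRAS", "G12C") == ["special"]
        assert table.lookup("KRAS", "G12V") == ["oncogenic_activating"]

    def test_malformed_protein_change_errors(self, knowledge):
        with pytest.raises(ValueError):
            rw.annotate_variant("RET", "not-a-change", knowledge)


def _traj(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "day", "af", "passed", "gene", "protein_change",
                 "is_amplification"],
    )


def _driver_rows(days=(0, 30, 60), afs=(0.10, 0.03, 0.005)):
    return [("RET_fusion", d, a, a >= 0.001, "RET", "", False) for d, a in zip(days, afs)]


class TestClassifyMechanisms:
    def test_emergent_solvent_front_is_on_target(self, knowledge):
        rows = _driver_rows() + [
            ("RET_G810S", 0, 0.0, False, "RET", "G810S", False),
            ("RET_G810S", 30, 0.0, False, "RET", "G810S", False),
            ("RET_G810S", 60, 0.02, True, "RET", "G810S", False),
        ]
        call = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        assert call.mechanisms == frozenset({"on_target_secondary"})

    def test_emergent_kras_is_bypass(self, knowledge):
        rows = _driver_rows() + [
            ("KRAS_G12V", 0, 0.0, False, "KRAS", "G12V", False),
            ("KRAS_G12V", 30, 0.0, False, "KRAS", "G12V", False),
            ("KRAS_G12V", 60, 0.02, True, "KRAS", "G12V", False),
        ]
        call = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        assert call.mechanisms == frozenset({"bypass_mutation"})

    def test_emergent_met_amplification_is_bypass_amp(self, knowledge):
        rows = _driver_rows() + [
            ("MET_amp", 0, 0.0, False, "MET", "", True),
            ("MET_amp", 30, 0.0, False, "MET", "", True),
            ("MET_amp", 60, 0.03, True, "MET", "", True),
        ]
        call = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        assert call.mechanisms == frozenset({"bypass_amplification"})

    def test_baseline_rising_kras_is_primary(self, knowledge):
        rows = _driver_rows() + [
            ("KRAS_G12D", 0, 0.004, True, "KRAS", "G12D", False),
            ("KRAS_G12D", 30, 0.01, True, "KRAS", "G12D", False),
            ("KRAS_G12D", 60, 0.03, True, "KRAS", "G12D", False),
        ]
        call = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        assert call.mechanisms == frozenset({"primary_ras"})

    def test_no_rule_fires_none_identified(self, knowledge):
        rows = _driver_rows() + [
            ("TP53_R175H", 0, 0.05, True, "TP53", "R175H", False),
            ("TP53_R175H", 30, 0.02, True, "TP53", "R175H", False),
            ("TP53_R175H", 60, 0.004, True, "TP53", "R175H", False),
        ]
        call = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        assert call.mechanisms == frozenset({"none_identified"})

    def test_polyclonal_on_target_plus_kras(self, knowledge):
        rows = _driver_rows() + [
            ("RET_G810C", 0, 0.0, False, "RET", "G810C", False),
            ("RET_G810C", 30, 0.005, True, "RET", "G810C", False),
            ("RET_G810C", 60, 0.02, True, "RET", "G810C", False),
            ("KRAS_G12A", 0, 0.0, False, "KRAS", "G12A", False),
            ("KRAS_G12A", 30, 0.0, False, "KRAS", "G12A", False),
            ("KRAS_G12A", 60, 0.015, True, "KRAS", "G12A", False),
        ]
        traj = _traj(rows)
        subclones = rw.assign_subclones(traj, driver="RET_fusion")
        call = rw.classify_mechanisms(
            traj, driver="RET_fusion", knowledge=knowledge, subclones=subclones
        )
        assert call.mechanisms == frozenset({"on_target_secondary", "bypass_mutation"})
        assert call.polyclonal

    def test_cis_gatekeeper_roof_compound(self, knowledge):
        # MTC-style: baseline V804M, acquired Y806C phased in cis
        rows = [
            ("RET_M918T", d, a, True, "RET", "M918T", False)
            for d, a in [(0, 0.10), (30, 0.06), (60, 0.09)]
        ]
        rows += [
            ("RET_V804M", d, a, True, "RET", "V804M", False)
            for d, a in [(0, 0.02), (30, 0.015), (60, 0.03)]
        ]
        rows += [
            ("RET_Y806C", 0, 0.0, False, "RET", "Y806C", False),
            ("RET_Y806C", 30, 0.0, False, "RET", "Y806C", False),
            ("RET_Y806C", 60, 0.02, True, "RET", "Y806C", False),
        ]
        frag = pd.DataFrame([{"alt_a": True, "alt_b": True}] * 20)
        phasing = [rw.phase_pair(frag, "V804M", "Y806C")]
        call = rw.classify_mechanisms(
            _traj(rows), driver="RET_M918T", knowledge=knowledge, phasing=phasing
        )
        assert "on_target_secondary" in call.mechanisms
        assert call.cis_compound == "V804M/Y806C"

    def test_rules_reproducible_and_order_independent(self, knowledge):
        rows = _driver_rows() + [
            ("KRAS_G12V", 0, 0.0, False, "KRAS", "G12V", False),
            ("KRAS_G12V", 30, 0.01, True, "KRAS", "G12V", False),
            ("KRAS_G12V", 60, 0.02, True, "KRAS", "G12V", False),
        ]
        a = rw.classify_mechanisms(_traj(rows), driver="RET_fusion", knowledge=knowledge)
        b = rw.classify_mechanisms(
            _traj(list(reversed(rows))), driver="RET_fusion", knowledge=knowledge
        )
        assert a.mechanisms == b.mechanisms


class TestPlantedMechanismRecovery:
    EXPECTED = {
        "on_target": {"on_target_secondary"},
        "bypass": {"bypass_mutation"},
        "both": {"on_target_secondary", "bypass_mutation"},
        "none": {"none_identified"},
    }

    def test_noisy_accuracy_at_depth_2000(self, knowledge):
        """>=90% of 50 sampled patients classified to exactly the planted set."""
        mechanisms = ["on_target", "bypass", "both", "none"]
        hits = 0
        n = 50
        for i in range(n):
            mech = mechanisms[i % 4]
            truth, meta = rw.simulate_resistance_patient(seed=900 + i, mechanism=mech)
            traj = resistance_trajectories(truth, meta)
            call = rw.classify_mechanisms(traj, driver="RET_fusion", knowledge=knowledge)
            hits += set(call.mechanisms) == self.EXPECTED[mech]
        assert hits / n >= 0.9


class TestOutcomes:
    @pytest.mark.parametrize(
        "resp,weeks,on_tx,expected",
        [
            ("PR", 30, False, True),
            ("SD", 24, False, True),
            ("SD", 23.9, False, False),
            ("SD", 10, True, True),  # ongoing treatment
            ("PD", 40, False, False),
            ("CR", 100, False, True),
        ],
    )
    def test_clinical_benefit_rule(self, resp, weeks, on_tx, expected):
        assert rw.PatientOutcome(resp, weeks, on_tx).clinical_benefit is expected

    def test_benefit_monotone_in_duration(self):
        for resp in ("SD", "PR", "CR"):
            flags = [rw.PatientOutcome(resp, w, False).clinical_benefit
                     for w in (0, 12, 24, 52)]
            assert flags == sorted(flags)


def _cohort(n_detected, n_total, ret_class):
    return pd.DataFrame(
        {
            "patient_id": [f"{ret_class}{i}" for i in range(n_total)],
            "ret_class": ret_class,
            "baseline_detected": [i < n_detected for i in range(n_total)],
            "best_response": "PR",
            "duration_weeks": 30.0,
            "on_treatment": False,
        }
    )


class TestCohortMetrics:
    def test_printed_detection_rates(self):
        cohort = pd.concat([_cohort(18, 19, "mutant"), _cohort(36, 49, "fusion")])
        rep = rw.cohort_metrics(cohort)
        assert rep["detection_rate"]["mutant"]["percent"] == 95
        assert rep["detection_rate"]["fusion"]["percent"] == 74

    def test_all_pd_zero_cbr(self):
        cohort = _cohort(3, 5, "fusion")
        cohort["best_response"] = "PD"
        assert rw.cohort_metrics(cohort)["clinical_benefit"]["percent"] == 0

    def test_median_reduction_and_tallies(self):
        cohort = _cohort(2, 3, "fusion")
        cohort["percent_reduction"] = [90.0, 82.5, 40.0]
        cohort["mechanisms"] = [["bypass_mutation"], ["on_target_secondary"],
                                ["on_target_secondary"]]
        rep = rw.cohort_metrics(cohort)
        assert rep["median_percent_reduction"] == pytest.approx(82.5)
        assert rep["mechanism_tally"] == {"bypass_mutation": 1, "on_target_secondary": 2}

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            rw.cohort_metrics(pd.DataFrame())
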