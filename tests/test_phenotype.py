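"""Oocyte stage pooling, cohort statistics and genotype-phenotype tables."""
import random

import numpy as np
import pandas as pd
import pytest

from patlas.phenotype import (STAGES, PatientOutcome, PhenotypeError,
                              cohort_stats, max_stage, pool_outcomes,
                              region_stage_association)


def patient(pid="p", gv=0, mi=0, pb1=0, empty=0, age=30.0, dur=5.0, cycles=1):
    return PatientOutcome(patient_id=pid, age=age, infertility_years=dur,
                          cycles=cycles,
                          oocytes={"gv": gv, "mi": mi, "pb1": pb1,
                                   "empty_atretic": empty})


class TestPooling:
    def test_fixture_cohort_reproduces_stage_spectrum(self, patients):
        s = pool_outcomes(patients)
        assert s.total_oocytes == 944
        assert s.counts == {"gv": 508, "mi": 87, "pb1": 139, "empty_atretic": 210}
        assert s.percents == {"gv": 53.81, "mi": 9.22, "pb1": 14.72,
                              "empty_atretic": 22.25}

    def test_percent_recomputable_from_counts(self, patients):
        s = pool_outcomes(patients)
        for stage in STAGES:
            assert s.percents[stage] == round(100 * s.counts[stage] /
                                              s.total_oocytes, 2)
        assert abs(sum(s.percents.values()) - 100.0) <= 0.02

    def test_single_patient_all_gv(self):
        s = pool_outcomes([patient(gv=5)])
        assert s.percents["gv"] == 100.0

    def test_order_invariance(self, patients):
        base = pool_outcomes(patients)
        shuffled = list(patients)
        random.Random(7).shuffle(shuffled)
        assert pool_outcomes(shuffled) == base

    def test_splitting_a_patient_across_rows_is_neutral(self):
        whole = [patient("a", gv=6, mi=2, pb1=1, empty=3)]
        split = [patient("a1", gv=4, mi=1), patient("a2", gv=2, mi=1, pb1=1,
                                                    empty=3)]
        assert pool_outcomes(whole).counts == pool_outcomes(split).counts

    def test_empty_cohort_and_zero_oocytes_raise(self):
        with pytest.raises(PhenotypeError):
            pool_outcomes([])
        with pytest.raises(PhenotypeError):
            pool_outcomes([patient()])


class TestCohortStats:
    def test_fixture_summary_statistics(self, patients):
        stats = cohort_stats(patients)
        assert stats.loc["oocytes_per_cycle", "mean"] == 11.24   # 944/84
        assert stats.loc["age", "mean"] == 31.41
        assert stats.loc["age", "sd"] == 4.34
        assert stats.loc["infertility_years", "mean"] == 7.00
        assert stats.loc["infertility_years", "sd"] == 3.04
        assert stats.loc["cycles", "mean"] == 2.47   # ratio 84/34, not 2.44

    def test_oocytes_per_cycle_is_ratio_of_totals(self):
        cohort = [patient("a", gv=10, cycles=1), patient("b", gv=1, cycles=3)]
        stats = cohort_stats(cohort)
        assert stats.loc["oocytes_per_cycle", "mean"] == round(11 / 4, 2)
        # mean of per-patient ratios would be (10 + 1/3)/2 = 5.17
        assert stats.loc["oocytes_per_cycle", "mean"] != round(
            np.mean([10 / 1, 1 / 3]), 2)

    def test_single_patient_sd_undefined(self):
        stats = cohort_stats([patient(gv=3)])
        assert stats.loc["age", "sd"] is None


class TestMaxStage:
    @pytest.mark.parametrize("counts,expected", [
        (dict(gv=5, mi=2, pb1=0, empty=3), "mi"),
        (dict(gv=0, mi=0, pb1=1, empty=0), "pb1"),
        (dict(gv=0, mi=0, pb1=0, empty=4), "empty_atretic"),
        (dict(gv=2, mi=0, pb1=0, empty=9), "gv"),
    ])
    def test_definition(self, counts, expected):
        assert max_stage(patient(**counts)) == expected

    def test_zero_oocytes_undefined(self):
        with pytest.raises(PhenotypeError):
            max_stage(patient())

    def test_order_is_configurable(self):
        p = patient(gv=1, empty=1)
        assert max_stage(p, order=("pb1", "mi", "gv", "empty_atretic")) == \
            "empty_atretic"


class TestRegionStageAssociation:
    def test_mid_region_patients_never_reach_pb1(self, patients, reported, model):
        """No patient whose variant falls in p.342-446 extrudes a first
        polar body."""
        out = region_stage_association(patients, reported, model)
        assert out["table"].loc["p342_446", "pb1"] == 0
        assert out["table"].loc["p342_446"].sum() > 0

    def test_pb1_patients_carry_n_terminal_variants(self, patients, reported,
                                                    model):
        out = region_stage_association(patients, reported, model)
        assert out["table"].loc["pre_p217", "pb1"] > 0

    def test_row_sums_match_crosstab_oracle(self, patients, reported, model):
        out = region_stage_association(patients, reported, model)
        # oracle: rebuild with pandas.crosstab over (patient, bucket) pairs
        from patlas.gene_model import assign_region
        from patlas.phenotype import REGION_BUCKETS
        rows = []
        links = {}
        for rec in reported:
            a = assign_region(rec, model)
            for pid in rec.patients:
                links.setdefault(pid, set()).update(
                    name for name, lo, hi in REGION_BUCKETS
                    if any(lo <= r <= hi for r in a.residues))
        by_id = {p.patient_id: p for p in patients}
        for pid, buckets in links.items():
            for b in buckets:
                rows.append({"bucket": b, "stage": max_stage(by_id[pid])})
        oracle = pd.crosstab(pd.DataFrame(rows).bucket, pd.DataFrame(rows).stage)
        for bucket in oracle.index:
            for stage in oracle.columns:
                assert out["table"].loc[bucket, stage] == oracle.loc[bucket, stage]

    def test_compound_het_double_counting_is_flagged(self, patients, reported,
                                                     model):
        out = region_stage_association(patients, reported, model)
        assert "P26" not in out["double_counted"]  # both variants pre-p217
        assert "P33" in out["double_counted"]      # p.P416H + p.A459E buckets

    def test_empty_cohort_gives_empty_table(self, reported, model):
        out = region_stage_association([], reported, model)
        assert out["table"].to_numpy().sum() == 0
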