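"""Allele-frequency aggregation, carrier models and 1-in-N formatting."""
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patlas.frequency import (FrequencyError, FrequencyRecord,
                              carrier_frequency, cumulative_af, format_one_in_n,
                              one_in_n, rank_by_af, read_frequency_table,
                              read_frequency_vcf, resolve_duplicates)
from .conftest import data_path


def rec(vid, af, ac=None, an=None, db="gnomAD"):
    return FrequencyRecord(variant_id=vid, allele_frequency=af,
                           allele_count=ac, allele_number=an, source_db=db)


class TestRecords:
    def test_af_computed_from_counts(self):
        records = read_frequency_table(data_path("frequencies_reported.tsv"))
        by = {(r.variant_id, r.source_db): r for r in records}
        exac = by[("c.478T>C", "ExAC")]
        assert exac.allele_frequency == pytest.approx(4 / 121412, abs=1e-15)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(FrequencyError):
            rec("v", 0.5, ac=1, an=100)

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(FrequencyError):
            rec("v", 1.5)


class TestCumulativeAf:
    def test_reported_fixture_sums_to_printed_cumulative(self, freq_reported):
        snp = [r for r in resolve_duplicates(freq_reported)
               if r.subset == "reported_snp"]
        assert len(snp) == 20
        assert cumulative_af(snp) * 1e5 == pytest.approx(48.09, abs=1e-9)

    def test_empty_is_zero(self):
        assert cumulative_af([]) == 0.0

    def test_additivity(self):
        assert cumulative_af([rec("a", 1e-5), rec("b", 2e-5)]) == pytest.approx(3e-5)

    def test_permutation_invariance(self):
        records = [rec(f"v{i}", (i + 1) * 1e-6) for i in range(10)]
        base = cumulative_af(records)
        for seed in (1, 2):
            shuffled = records[:]
            random.Random(seed).shuffle(shuffled)
            assert cumulative_af(shuffled) == pytest.approx(base, rel=1e-12)

    def test_unresolved_duplicate_raises(self):
        with pytest.raises(FrequencyError, match="dup"):
            cumulative_af([rec("dup", 1e-5), rec("dup", 2e-5, db="ExAC")])

    def test_duplicates_resolved_to_larger_allele_number(self):
        pair = [rec("v", 3.06e-5, an=250000),
                rec("v", 4 / 121412, ac=4, an=121412, db="ExAC")]
        kept = resolve_duplicates(pair)
        assert len(kept) == 1 and kept[0].allele_number == 250000

    def test_duplicates_without_an_cannot_resolve(self):
        with pytest.raises(FrequencyError):
            resolve_duplicates([rec("v", 1e-5), rec("v", 2e-5, db="ExAC")])


class TestOneInN:
    @pytest.mark.parametrize("freq,n", [
        (48.09e-5, 2080),     # plain rounding would give 2079
        (1.14e-3, 877),
        (0.5, 2),
        (0.25e-3, 4000),
    ])
    def test_three_significant_figures(self, freq, n):
        assert one_in_n(freq) == n

    def test_nonpositive_is_undefined(self):
        assert one_in_n(0.0) is None
        assert format_one_in_n(None) == "—"

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(1e-6, 0.5))
    def test_idempotent_at_three_sig_figs(self, freq):
        n = one_in_n(freq)
        assert one_in_n(1.0 / n) == n


class TestCarrierModels:
    def test_paper_convention_equates_carrier_and_cumulative(self):
        est = carrier_frequency(1.14e-3, "paper_convention")
        assert est.carrier_frequency == pytest.approx(1.14e-3)
        assert est.one_in_n == 877

    def test_hardy_weinberg_closed_form(self):
        est = carrier_frequency(1e-3, "hardy_weinberg")
        assert est.carrier_frequency == pytest.approx(2 * 0.001 * 0.999)

    def test_zero_cumulative(self):
        est = carrier_frequency(0.0)
        assert est.carrier_frequency == 0.0 and est.one_in_n is None

    def test_out_of_range_raises(self):
        with pytest.raises(FrequencyError):
            carrier_frequency(1.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-9, 1.0))
    def test_hw_carrier_below_twice_allele_frequency(self, p):
        est = carrier_frequency(p, "hardy_weinberg")
        assert est.carrier_frequency <= 2 * p


class TestRanking:
    def test_reported_top_three(self, freq_reported):
        snp = [r for r in resolve_duplicates(freq_reported)
               if r.subset == "reported_snp"]
        top = rank_by_af(snp).head(3)
        assert list(top.variant_id) == ["c.839G>A", "c.805C>A", "c.478T>C"]

    def test_single_record(self):
        df = rank_by_af([rec("only", 1e-5)])
        assert list(df.variant_id) == ["only"]

    def test_matches_sort_oracle_under_permutation(self):
        records = [rec(f"v{i}", af) for i, af in
                   enumerate([5e-5, 1e-5, 5e-5, 3e-5, 1e-6])]
        oracle = [r.variant_id for r in
                  sorted(records, key=lambda r: (-r.allele_frequency, r.variant_id))]
        for seed in (1, 2, 3):
            shuffled = records[:]
            random.Random(seed).shuffle(shuffled)
            assert list(rank_by_af(shuffled).variant_id) == oracle


class TestVcfIngestion:
    def test_vcf_agrees_with_tsv(self, freq_reported):
        vcf = {r.variant_id: r for r in
               read_frequency_vcf(data_path("frequencies_sample.vcf"))}
        assert len(vcf) == 10
        tsv = {r.variant_id: r for r in freq_reported if r.source_db == "gnomAD"}
        for vid in ("c.805C>A", "c.778G>A", "c.920G>A", "c.1133T>C"):
            assert vcf[vid].allele_count == tsv[vid].allele_count
            assert vcf[vid].allele_frequency == pytest.approx(
                tsv[vid].allele_frequency, rel=1e-6)
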