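import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainvar.model import VARIANT_COLUMNS, VariantSite
from strainvar.simulate import plant_indels, synthesize_reference
from strainvar.varstats import (
    annotation_tallies,
    divergence_time,
    indel_repeat_context,
    pairwise_snv_distance,
)


def _frame(keys, annotation=None):
    rows = [(c, p, "A", a, 30, 30, annotation) for c, p, a in keys]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


class TestPairwiseDistance:
    def test_identical_sets_distance_zero(self):
        keys = [("chrI", 100, "G"), ("chrII", 5, "T")]
        assert pairwise_snv_distance(_frame(keys), _frame(keys)) == 0

    def test_disjoint_sets_sum(self):
        a = _frame([("chrI", i, "G") for i in range(1, 4)])
        b = _frame([("chrII", i, "T") for i in range(1, 5)])
        assert pairwise_snv_distance(a, b) == 7

    def test_shared_position_different_allele_counts_twice(self):
        a = _frame([("chrI", 100, "G")])
        b = _frame([("chrI", 100, "T")])
        assert pairwise_snv_distance(a, b) == 2

    def test_indels_excluded(self):
        a = _frame([("chrI", 100, "G")])
        indel = pd.DataFrame([("chrI", 200, "AT", "A", 30, 30, None)],
                             columns=VARIANT_COLUMNS)
        assert pairwise_snv_distance(pd.concat([a, indel]), a) == 0

    @given(st.sets(st.tuples(st.sampled_from(["chrI", "chrII"]),
                             st.integers(1, 50), st.sampled_from(["G", "T"])),
                   max_size=20),
           st.sets(st.tuples(st.sampled_from(["chrI", "chrII"]),
                             st.integers(1, 50), st.sampled_from(["G", "T"])),
                   max_size=20))
    def test_equals_brute_force_symmetric_difference(self, set_a, set_b):
        got = pairwise_snv_distance(_frame(sorted(set_a)), _frame(sorted(set_b)))
        assert got == len(set_a ^ set_b)

    @given(st.sets(st.tuples(st.just("chrI"), st.integers(1, 30), st.just("G")),
                   max_size=10),
           st.sets(st.tuples(st.just("chrI"), st.integers(1, 30), st.just("G")),
                   max_size=10),
           st.sets(st.tuples(st.just("chrI"), st.integers(1, 30), st.just("G")),
                   max_size=10))
    def test_triangle_inequality(self, sa, sb, sc):
        fa, fb, fc = _frame(sorted(sa)), _frame(sorted(sb)), _frame(sorted(sc))
        assert (pairwise_snv_distance(fa, fc)
                <= pairwise_snv_distance(fa, fb) + pairwise_snv_distance(fb, fc))


class TestDivergenceTime:
    def test_closest_pair_estimate(self):
        assert round(divergence_time(3671, 0.005, 2.0)) == 168

    def test_furthest_pair_estimate(self):
        assert round(divergence_time(86949, 0.005, 2.0)) == 3970

    def test_zero_difference_zero_years(self):
        assert divergence_time(0, 0.005, 2.0) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-1, 0.005, 2.0)

    @given(st.integers(0, 10**6), st.integers(1, 10))
    def test_linear_in_count_and_generation_time(self, count, factor):
        base = divergence_time(count, 0.005, 2.0)
        assert divergence_time(count * factor, 0.005, 2.0) == pytest.approx(base * factor)
        assert divergence_time(count, 0.005, 2.0 * factor) == pytest.approx(base * factor)
        assert divergence_time(count, 0.005 * factor, 2.0) == pytest.approx(base / factor)


class TestAnnotationTallies:
    def test_coding_fraction_and_ratio(self):
        rows = ([("chrI", i, "A", "G", 30, 30, "synonymous") for i in range(1, 51)]
                + [("chrI", i, "A", "G", 30, 30, "missense") for i in range(51, 81)]
                + [("chrI", i, "A", "G", 30, 30, "noncoding") for i in range(81, 101)])
        tally = annotation_tallies(pd.DataFrame(rows, columns=VARIANT_COLUMNS))
        assert tally.n_snvs == 100
        assert tally.coding_fraction == pytest.approx(0.80)
        assert tally.syn_missense_ratio == pytest.approx(50 / 30)

    def test_frameshift_from_indel_length(self):
        rows = [("chrI", 1, "AT", "A", 30, 30, "missense"),     # 1 bp coding: frameshift
                ("chrI", 10, "ACTG", "A", 30, 30, "missense"),  # 3 bp coding: in-frame
                ("chrI", 20, "AT", "A", 30, 30, "noncoding")]   # non-coding: not counted
        tally = annotation_tallies(pd.DataFrame(rows, columns=VARIANT_COLUMNS))
        assert tally.frameshift_indels == 1

    def test_missing_annotation_counts_as_other(self, caplog):
        rows = [("chrI", 1, "A", "G", 30, 30, None)]
        with caplog.at_level("INFO"):
            tally = annotation_tallies(pd.DataFrame(rows, columns=VARIANT_COLUMNS))
        assert tally.coding_fraction == 0.0
        assert any("without annotation" in r.message for r in caplog.records)

    def test_ratio_undefined_without_missense(self):
        rows = [("chrI", 1, "A", "G", 30, 30, "synonymous")]
        tally = annotation_tallies(pd.DataFrame(rows, columns=VARIANT_COLUMNS))
        assert np.isnan(tally.syn_missense_ratio)


class TestIndelRepeatContext:
    def _indel(self, ref, alt):
        return VariantSite("chrI", 100, ref, alt, 10, 70)

    def test_insertion_in_mononucleotide_run(self):
        window = "CGTCGTCGTT" + "A" + "AAAAGCGTCG"  # anchor A followed by AAAA
        site = self._indel("A", "AA")
        assert indel_repeat_context(site, window, center=10) == "mononucleotide_repeat"

    def test_deletion_in_microsatellite(self):
        window = "CGTCGGTCGC" + "A" + "TATATATGCG"  # (AT)x4 from the anchor
        site = self._indel("CAT", "C")
        assert indel_repeat_context(site, window, center=9) == "microsatellite"

    def test_deletion_in_plain_sequence(self):
        window = "CGTCAGTCGA" + "C" + "TGACTTGCAG"
        site = self._indel("CT", "C")
        assert indel_repeat_context(site, window, center=10) == "non_repeat"

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="21"):
            indel_repeat_context(self._indel("CT", "C"), "ACTGCAT")

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError, match="InDel"):
            indel_repeat_context(VariantSite("chrI", 1, "A", "G", 5, 5), "A" * 21)

    @pytest.mark.parametrize("fraction", [0.0, 0.5, 0.82, 1.0])
    def test_recovery_on_planted_indels(self, fraction, layout):
        reference = synthesize_reference(layout, np.random.default_rng(31))
        rng = np.random.default_rng(int(fraction * 100) + 7)
        rows, truth = plant_indels(reference, 100, fraction, rng)
        correct = 0
        for row, (chrom, pos, context) in zip(rows.itertuples(index=False), truth):
            site = VariantSite(row.chrom, row.pos, row.ref, row.alt,
                               row.ref_depth, row.alt_depth)
            window = reference[chrom][pos - 11: pos + 10]
            correct += indel_repeat_context(site, window) == context
        assert correct >= 98
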