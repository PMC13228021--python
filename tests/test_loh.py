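import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainvar.loh import (
    LohSegmenter,
    classify_loh_segments,
    classify_zygosity,
    homozygosity_fraction,
    loh_pattern_statistic,
    segment_homozygous_runs,
    zygosity_table,
)
from strainvar.model import LohSegment, VariantSite
from strainvar.simulate import StrainSpec, simulate_strain

from .oracles import tolerant_runs_brute


def _site(ref_depth, alt_depth):
    return VariantSite("chrI", 100, "A", "G", ref_depth, alt_depth)


def _calls(hom_flags, chrom="chrI", spacing=300):
    pos = np.arange(1, len(hom_flags) + 1) * spacing
    support = np.where(hom_flags, 0.99, 0.5)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "support": support,
                         "homozygous": np.asarray(hom_flags, dtype=bool)})


class TestZygosity:
    def test_high_support_homozygous(self):
        assert classify_zygosity(_site(5, 95)).state == "homozygous"

    def test_exact_threshold_inclusive(self):
        assert classify_zygosity(_site(10, 90)).state == "homozygous"

    def test_balanced_site_heterozygous(self):
        assert classify_zygosity(_site(50, 50)).state == "heterozygous"

    def test_mirrored_rule_for_reference_homozygous(self):
        assert classify_zygosity(_site(95, 5)).state == "homozygous"

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="zero depth"):
            classify_zygosity(_site(0, 0))

    @given(st.integers(0, 200), st.integers(0, 200))
    def test_symmetric_under_support_reflection(self, a, b):
        if a + b == 0:
            return
        assert (classify_zygosity(_site(a, b)).state
                == classify_zygosity(_site(b, a)).state)


class TestSegmentation:
    def test_uninterrupted_run_is_one_segment(self):
        segs = segment_homozygous_runs(_calls([True] * 100))
        assert len(segs) == 1 and segs[0].n_sites == 100

    def test_short_run_below_min_sites_dropped(self):
        assert segment_homozygous_runs(_calls([True] * 9)) == []

    def test_isolated_het_interrupt_tolerated(self):
        flags = [True] * 50 + [False] + [True] * 50
        segs = segment_homozygous_runs(_calls(flags))
        assert len(segs) == 1 and segs[0].n_sites == 101

    def test_adjacent_het_interrupts_split_run(self):
        flags = [True] * 50 + [False, False] + [True] * 50
        segs = segment_homozygous_runs(_calls(flags))
        assert len(segs) == 2

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_enumerator(self, trial):
        rng = np.random.default_rng(1000 + trial)
        flags = (rng.random(rng.integers(10, 80)) < 0.7).tolist()
        calls = _calls(flags)
        segs = segment_homozygous_runs(calls, min_sites=1)
        expected = tolerant_runs_brute(flags, 0.02)
        got = [(int(np.flatnonzero(calls["pos"].to_numpy() == s.start + 1)[0]),
                int(np.flatnonzero(calls["pos"].to_numpy() == s.end)[0]))
               for s in segs]
        assert got == expected


class TestClassification:
    def test_whole_chromosome_run_is_upd(self, layout):
        calls = _calls([True] * 60, chrom="chrIX")
        segs = classify_loh_segments(segment_homozygous_runs(calls), calls, layout)
        assert [s.kind for s in segs] == ["upd"]

    def test_run_reaching_last_site_is_terminal(self, layout):
        flags = [False] * 40 + [True] * 20
        calls = _calls(flags, chrom="chrIV")
        segs = classify_loh_segments(segment_homozygous_runs(calls), calls, layout)
        assert [s.kind for s in segs] == ["terminal"]

    def test_internal_run_is_interstitial(self, layout):
        flags = [False] * 20 + [True] * 20 + [False] * 20
        calls = _calls(flags, chrom="chrIV")
        segs = classify_loh_segments(segment_homozygous_runs(calls), calls, layout)
        assert [s.kind for s in segs] == ["interstitial"]

    def test_unknown_chromosome_rejected(self, layout):
        seg = LohSegment("chrZZ", 0, 100, None, 10, 0.99)
        with pytest.raises(ValueError, match="chrZZ"):
            classify_loh_segments([seg], _calls([True] * 10), layout)


class TestHomozygosityFraction:
    def test_fully_homozygous_is_one(self):
        calls = _calls([True] * 50)
        segs = segment_homozygous_runs(calls)
        assert homozygosity_fraction(segs, calls) == 1.0

    def test_no_segments_is_zero(self):
        assert homozygosity_fraction([], _calls([False] * 50)) == 0.0

    def test_half_covered_span(self):
        calls = _calls([False] * 20, chrom="chrI")
        # synthetic segment covering half of the 6 kb assessed span
        span = int(calls["pos"].max()) - (int(calls["pos"].min()) - 1)
        seg = LohSegment("chrI", 300, 300 + span // 2, None, 10, 0.99)
        assert homozygosity_fraction([seg], calls) == pytest.approx(0.5, abs=0.01)

    def test_no_assessed_sites_is_nan(self):
        empty = _calls([])
        assert np.isnan(homozygosity_fraction([], empty))

    def test_monotone_in_planted_tract_length(self, sim_config, layout):
        fractions = []
        for length in (10000, 30000, 60000):
            spec = StrainSpec(name="m", loh_tracts=(("chrIV", 40000, 40000 + length,
                                                     "interstitial"),))
            sim = simulate_strain(sim_config, spec, seed=55)
            seg = LohSegmenter().fit(sim.variants, layout=layout)
            fractions.append(seg.homozygosity_)
        assert fractions == sorted(fractions)


class TestPatternStatistic:
    def _segments_at(self, layout, positions):
        segs = []
        for chrom, start, length in positions:
            segs.append(LohSegment(chrom, start, start + length, "terminal", 20, 0.99))
        return segs

    def test_telomere_packed_segments_are_mitotic(self, layout):
        segs = []
        for chrom in ("chrII", "chrIV", "chrVII", "chrX", "chrXIII"):
            length = layout[chrom].length
            segs.append(LohSegment(chrom, 0, 3000, "terminal", 10, 0.99))
            segs.append(LohSegment(chrom, length - 3000, length, "terminal", 10, 0.99))
        report = loh_pattern_statistic(segs, layout, n_permutations=500, seed=1)
        assert report.pattern == "mitotic-dominated"
        assert report.p_value < 0.05

    def test_evenly_spread_segments_are_meiotic(self, layout):
        # segments at 10/30/50/70/90 % of each chromosome: an even spread
        # whose terminal overlap matches the uniform null
        segs = []
        for chrom in ("chrII", "chrIV", "chrVII", "chrX", "chrXII", "chrXV"):
            length = layout[chrom].length
            for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
                start = min(int(frac * length), length - 3000)
                segs.append(LohSegment(chrom, start, start + 3000, None, 15, 0.99))
        report = loh_pattern_statistic(segs, layout, n_permutations=500, seed=2)
        assert report.pattern == "meiotic-dominated"

    def test_fully_homozygous_short_circuits(self, layout):
        report = loh_pattern_statistic([], layout, homozygosity=1.0)
        assert report.pattern == "fully-homozygous"

    def test_too_few_segments_undetermined(self, layout):
        segs = [LohSegment("chrI", 0, 2000, None, 10, 0.99)]
        report = loh_pattern_statistic(segs, layout, n_permutations=100)
        assert report.pattern == "undetermined"

    def test_false_positive_rate_on_uniform_placement(self, layout):
        """Uniformly re-placed segments should rarely be called mitotic."""
        rng = np.random.default_rng(99)
        chroms = ["chrII", "chrIV", "chrVII", "chrX", "chrXII", "chrXV", "chrXIII"]
        false_positives = 0
        n_reps = 200
        for rep in range(n_reps):
            segs = []
            for chrom in chroms:
                length = layout[chrom].length
                seg_len = int(rng.integers(3000, 8000))
                start = int(rng.integers(0, length - seg_len))
                segs.append(LohSegment(chrom, start, start + seg_len, None, 10, 0.99))
            report = loh_pattern_statistic(segs, layout, n_permutations=300,
                                           seed=int(rng.integers(2**31)))
            false_positives += report.pattern == "mitotic-dominated"
        assert false_positives / n_reps <= 0.07


class TestLohSegmenterEndToEnd:
    def test_planted_tracts_recovered_with_class(self, diploid_sim, layout):
        seg = LohSegmenter().fit(diploid_sim.variants, layout=layout, strain="dip")
        by_kind = {}
        for s in seg.segments_:
            by_kind.setdefault(s.kind, []).append(s)
        truth = {kind: (chrom, start, end)
                 for chrom, start, end, kind in diploid_sim.truth.loh_tracts}
        for kind, (chrom, start, end) in truth.items():
            matches = [s for s in by_kind.get(kind, [])
                       if s.chrom == chrom and min(s.end, end) - max(s.start, start) > 0]
            assert matches, f"planted {kind} tract on {chrom} not recovered"

    def test_zygosity_table_filters_depth(self, diploid_sim):
        table = zygosity_table(diploid_sim.variants, min_depth=10)
        assert (table["support"] >= 0).all()
        assert set(table.columns) == {"chrom", "pos", "support", "homozygous"}
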