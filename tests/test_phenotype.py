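import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainvar.phenotype import (
    ConditionClusterer,
    cluster_conditions,
    conversion_efficiency,
    fermentation_period,
    fermentation_rate,
    relative_biomass,
    tolerance_fermentation_correlation,
)
from strainvar.simulate import simulate_fermentation_series, simulate_phenotype_matrix


class TestRelativeBiomass:
    def test_ratio(self):
        assert relative_biomass(0.6, 1.2) == 0.5

    def test_identity(self):
        assert relative_biomass(1.2, 1.2) == 1.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            relative_biomass(0.5, 0.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.1, 100))
    def test_scale_invariance(self, stress, control, k):
        assert relative_biomass(stress * k, control * k) == pytest.approx(
            relative_biomass(stress, control))


class TestClusterConditions:
    def test_identical_columns_merge_at_zero(self, rng):
        base = rng.random(10)
        matrix = pd.DataFrame({"a": base, "b": base, "c": rng.random(10)})
        Z, order, labels = cluster_conditions(matrix)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert labels["a"] == labels["b"]

    def test_single_condition_trivial_tree(self):
        matrix = pd.DataFrame({"only": [1.0, 2.0, 3.0]})
        Z, order, labels = cluster_conditions(matrix)
        assert order == ["only"] and labels == {"only": 1}

    def test_constant_column_rejected_by_name(self):
        matrix = pd.DataFrame({"flat": [1.0] * 5, "ok": [1, 2, 3, 4, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            cluster_conditions(matrix)

    def test_planted_blocks_recovered(self):
        hits = 0
        for seed in range(20):
            matrix, truth = simulate_phenotype_matrix(
                np.random.default_rng(seed), n_strains=41, blocks=(8, 8))
            clusterer = ConditionClusterer(cut_height=0.8).fit(
                matrix.drop(columns="control"))
            labels = clusterer.labels_
            conds = [c for c in matrix.columns if c != "control"]
            block_labels = {}
            consistent = True
            for cond, block in zip(conds, truth):
                block_labels.setdefault(block, labels[cond])
                consistent &= block_labels[block] == labels[cond]
            consistent &= len(set(block_labels.values())) == len(block_labels)
            hits += consistent
        assert hits >= 19  # >= 95% of replicates


class TestFermentation:
    def test_midpoint_interpolation(self):
        series = pd.DataFrame({"time_h": [0.0, 96.0], "ethanol": [0.0, 100.0],
                               "co2_loss": [0.0, 10.0]})
        assert fermentation_rate(series, duration=96.0) == 50.0

    def test_exact_sample_at_midpoint_returned(self):
        series = pd.DataFrame({"time_h": [0.0, 48.0, 96.0],
                               "ethanol": [0.0, 70.0, 100.0],
                               "co2_loss": [0.0, 7.0, 10.0]})
        assert fermentation_rate(series, duration=96.0) == 70.0

    def test_single_time_point_rejected(self):
        series = pd.DataFrame({"time_h": [0.0], "ethanol": [0.0], "co2_loss": [0.0]})
        with pytest.raises(ValueError, match="two"):
            fermentation_rate(series, duration=96.0)

    def test_period_detected_at_plateau(self, rng):
        series = simulate_fermentation_series(rng, midpoint_hours=20.0, rate=0.3)
        period = fermentation_period(series)
        assert 24.0 <= period < 96.0  # plateau well before the end of sampling

    def test_midpoint_outside_range_rejected(self):
        series = pd.DataFrame({"time_h": [40.0, 96.0], "ethanol": [50.0, 100.0],
                               "co2_loss": [5.0, 10.0]})
        with pytest.raises(ValueError, match="midpoint"):
            fermentation_rate(series, duration=40.0)


class TestConversionEfficiency:
    @pytest.mark.parametrize("product,sugar,expected",
                             [(96.0, 200.0, 0.48), (84.0, 200.0, 0.42), (0.0, 200.0, 0.0)])
    def test_ratios(self, product, sugar, expected):
        assert conversion_efficiency(product, sugar) == pytest.approx(expected)

    def test_zero_consumption_rejected(self):
        with pytest.raises(ValueError):
            conversion_efficiency(10.0, 0.0)


class TestToleranceCorrelation:
    def _matrix(self, rng, n=20):
        return pd.DataFrame({"condA": rng.random(n), "condB": rng.random(n)},
                            index=[f"S{i}" for i in range(n)])

    def test_self_correlation_is_one(self, rng):
        matrix = self._matrix(rng)
        out = tolerance_fermentation_correlation(matrix, matrix["condA"])
        assert out.set_index("condition").loc["condA", "r"] == pytest.approx(1.0)

    def test_negated_metric_is_minus_one(self, rng):
        matrix = self._matrix(rng)
        out = tolerance_fermentation_correlation(matrix, -matrix["condA"])
        assert out.set_index("condition").loc["condA", "r"] == pytest.approx(-1.0)

    def test_zero_variance_metric_reported_nan(self, rng):
        matrix = self._matrix(rng)
        metric = pd.Series(1.0, index=matrix.index)
        out = tolerance_fermentation_correlation(matrix, metric)
        assert out["r"].isna().all()

    def test_affine_invariance_and_sign_flip(self, rng):
        matrix = self._matrix(rng)
        metric = pd.Series(rng.random(len(matrix)), index=matrix.index)
        base = tolerance_fermentation_correlation(matrix, metric)["r"]
        scaled = tolerance_fermentation_correlation(matrix, 3.0 * metric + 7.0)["r"]
        flipped = tolerance_fermentation_correlation(matrix, -metric)["r"]
        assert np.allclose(base, scaled)
        assert np.allclose(base, -flipped)

    def test_planted_correlation_recovered(self):
        """r = 0.4 planted in bivariate-normal data with n = 41 strains is
        estimated within sampling error (+-0.25)."""
        reps = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cov = np.array([[1.0, 0.4], [0.4, 1.0]])
            data = rng.multivariate_normal([0, 0], cov, size=41)
            matrix = pd.DataFrame({"cond": data[:, 0]},
                                  index=[f"S{i}" for i in range(41)])
            metric = pd.Series(data[:, 1], index=matrix.index)
            out = tolerance_fermentation_correlation(matrix, metric)
            reps.append(out["r"].iloc[0])
        reps = np.array(reps)
        assert np.mean(np.abs(reps - 0.4) <= 0.25) >= 0.9
        assert abs(reps.mean() - 0.4) < 0.1

    def test_permutation_p_value_small_for_strong_signal(self, rng):
        matrix = self._matrix(rng)
        out = tolerance_fermentation_correlation(matrix, matrix["condA"],
                                                 n_permutations=200, seed=1)
        assert out.set_index("condition").loc["condA", "p_permutation"] < 0.05
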