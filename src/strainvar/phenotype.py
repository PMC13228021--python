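"""Stress-tolerance and fermentation-performance analysis.

Tolerance to a stressor is the *relative biomass*: optical density under
stress divided by optical density in plain medium.  Condition profiles
across strains are clustered hierarchically (correlation distance,
average linkage by default) to reveal stressors with shared physiology.
Fermentation performance is summarized by the ethanol titer at the
midpoint of the fermentation period (the "fermentation rate" proxy),
conversion efficiencies (g product per g sugar consumed), and Pearson
correlations between tolerance and fermentation metrics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "relative_biomass",
    "cluster_conditions",
    "fermentation_period",
    "fermentation_rate",
    "conversion_efficiency",
    "tolerance_fermentation_correlation",
    "ConditionClusterer",
]


def relative_biomass(stress_od: float, control_od: float) -> float:
    """Biomass under stress divided by biomass under the control condition."""
    if control_od <= 0:
        raise ValueError("control biomass must be positive")
    if stress_od < 0:
        raise ValueError("stress biomass must be non-negative")
    return stress_od / control_od


def cluster_conditions(
    matrix: pd.DataFrame,
    linkage: str = "average",
    distance: str = "correlation",
    cut_height: float = 0.5,
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Hierarchically cluster condition columns of a strains x conditions
    relative-biomass matrix.

    Returns the linkage matrix, conditions in dendrogram leaf order, and
    flat cluster labels at ``cut_height``.  Correlation distance rejects
    constant columns (their correlation is undefined).
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one condition column")
    if matrix.shape[1] == 1:
        only = str(matrix.columns[0])
        return np.empty((0, 4)), [only], {only: 1}
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if distance == "correlation":
        stds = matrix.std(axis=0, ddof=0)
        constant = stds[stds == 0].index.tolist()
        if constant:
            raise ValueError(f"constant condition column(s) under correlation "
                             f"distance: {constant}")
    elif distance != "euclidean":
        raise ValueError(f"unsupported distance {distance!r}")
    dists = pdist(matrix.to_numpy().T, metric=distance)
    Z = hierarchy.linkage(dists, method=linkage)
    order = [str(matrix.columns[i]) for i in hierarchy.leaves_list(Z)]
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = {str(col): int(lbl) for col, lbl in zip(matrix.columns, flat)}
    return Z, order, labels


def fermentation_period(series: pd.DataFrame, epsilon: float = 0.05) -> float:
    """Duration of active fermentation: the first time point at which the
    CO2-loss increment over the preceding interval falls below
    ``epsilon`` g/100 mL (plateau), falling back to the full sampled
    range."""
    times = series["time_h"].to_numpy(dtype=float)
    co2 = series["co2_loss"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(co2) < -1e-9):
        raise ValueError("CO2 loss must be non-decreasing")
    increments = np.diff(co2)
    below = np.flatnonzero(increments < epsilon)
    # ignore a lag phase: plateau means a *return* below epsilon after activity
    started = np.flatnonzero(increments >= epsilon)
    if len(started) and len(below):
        below = below[below > started[0]]
    if len(below):
        return float(times[below[0] + 1])
    return float(times[-1])


def fermentation_rate(series: pd.DataFrame, duration: float | None = None) -> float:
    """Ethanol titer (g/L) at the midpoint of the fermentation period,
    linearly interpolated between sampled time points."""
    times = series["time_h"].to_numpy(dtype=float)
    ethanol = series["ethanol"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two ethanol time points")
    if duration is None:
        duration = fermentation_period(series)
    midpoint = duration / 2.0
    if midpoint < times.min() or midpoint > times.max():
        raise ValueError(f"midpoint {midpoint} h outside sampled range "
                         f"[{times.min()}, {times.max()}]")
    return float(np.interp(midpoint, times, ethanol))


def conversion_efficiency(product_g_per_l: float, sugar_consumed_g_per_l: float) -> float:
    """Grams of product per gram of sugar consumed (ethanol or glycerol)."""
    if sugar_consumed_g_per_l <= 0:
        raise ValueError("sugar consumed must be positive")
    if product_g_per_l < 0:
        raise ValueError("product titer must be non-negative")
    return product_g_per_l / sugar_consumed_g_per_l


def tolerance_fermentation_correlation(
    matrix: pd.DataFrame,
    metric: pd.Series,
    n_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation between each condition column and a per-strain
    fermentation metric.

    Strains missing either value are pairwise-dropped (counts logged);
    zero-variance vectors yield an undefined (NaN) r.  With
    ``n_permutations`` > 0 a permutation p-value is added (seeded).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in matrix.columns:
        joined = pd.concat([matrix[cond], metric], axis=1, join="inner").dropna()
        n = len(joined)
        dropped = len(matrix) - n
        if dropped:
            logger.info("%s: %d strains dropped (missing values)", cond, dropped)
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append((str(cond), float("nan"), n, float("nan")))
            continue
        r, _ = pearsonr(x, y)
        p_perm = float("nan")
        if n_permutations > 0:
            perm_r = np.empty(n_permutations)
            for b in range(n_permutations):
                perm_r[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
            p_perm = float((np.sum(np.abs(perm_r) >= abs(r)) + 1) / (n_permutations + 1))
        rows.append((str(cond), float(r), n, p_perm))
    return pd.DataFrame(rows, columns=["condition", "r", "n", "p_permutation"])


class ConditionClusterer(BaseEstimator):
    """Hierarchical clustering of stress conditions (scikit-learn style).

    Attributes (after ``fit``)
    --------------------------
    linkage_ : scipy linkage matrix.
    leaf_order_ : conditions in dendrogram order.
    labels_ : condition -> flat cluster id at ``cut_height``.
    """

    def __init__(self, linkage: str = "average", distance: str = "correlation",
                 cut_height: float = 0.5):
        self.linkage = linkage
        self.distance = distance
        self.cut_height = cut_height

    def fit(self, X: pd.DataFrame, y=None) -> "ConditionClusterer":
        self.linkage_, self.leaf_order_, self.labels_ = cluster_conditions(
            X, linkage=self.linkage, distance=self.distance,
            cut_height=self.cut_height)
        return self
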