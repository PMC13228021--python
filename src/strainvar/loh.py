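"""Loss-of-heterozygosity detection and positional classification.

Zygosity follows the 90 % read-support rule: a site whose alternate-read
fraction is at or above the threshold — or at or below its mirror
(reference-homozygous sites sit near 0 % alternate support) — is
homozygous; everything in between is heterozygous.  Runs of homozygous
calls become LOH segments, classified by position into

* ``interstitial`` — internal tracts (gene conversion / double crossover),
* ``terminal`` — tracts reaching a chromosome end (single crossover),
* ``upd`` — whole-chromosome homozygosity (uniparental disomy from a
  chromosome-segregation error).

A permutation statistic on the fraction of LOH length in the terminal
20 % of chromosome arms separates mitotic-dominated (telomere-biased)
from meiotic-dominated (uniform) genome-wide patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import GenomeLayout, LohSegment, VariantSite

__all__ = [
    "ZygosityCall",
    "LohPatternReport",
    "classify_zygosity",
    "zygosity_table",
    "segment_homozygous_runs",
    "classify_loh_segments",
    "homozygosity_fraction",
    "loh_pattern_statistic",
    "LohSegmenter",
]


@dataclass(frozen=True)
class ZygosityCall:
    """Per-site zygosity under the read-support rule."""

    chrom: str
    pos: int
    support: float
    state: str  # homozygous | heterozygous


@dataclass(frozen=True)
class LohPatternReport:
    """Genome-wide LOH positional pattern for one strain."""

    strain: str
    homozygosity_fraction: float
    terminal_length_fraction: float
    pattern: str  # mitotic-dominated | meiotic-dominated | fully-homozygous | undetermined
    p_value: float


def classify_zygosity(site: VariantSite, threshold: float = 0.90) -> ZygosityCall:
    """Classify one site: homozygous iff support >= threshold or
    support <= 1 - threshold (the rule is applied two-sidedly because a
    reference-homozygous site has near-zero alternate support)."""
    if site.total_depth == 0:
        raise ValueError(f"{site.chrom}:{site.pos} has zero depth; filter before calling")
    support = site.support
    # the mirror comparison uses (1 - support) >= threshold rather than
    # support <= 1 - threshold so the rule is exactly symmetric in floats
    hom = support >= threshold or (1.0 - support) >= threshold
    return ZygosityCall(site.chrom, site.pos, support,
                        "homozygous" if hom else "heterozygous")


def zygosity_table(
    sites: pd.DataFrame,
    threshold: float = 0.90,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Vectorized zygosity over a variant table (SNVs only, depth-filtered).

    Returns a sorted DataFrame with ``chrom``, ``pos``, ``support`` and
    ``homozygous`` columns.
    """
    snv = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)
    depth = sites["ref_depth"] + sites["alt_depth"]
    out = sites.loc[snv & (depth >= min_depth), ["chrom", "pos"]].copy()
    depth = depth[out.index]
    support = sites.loc[out.index, "alt_depth"] / depth
    out["support"] = support
    out["homozygous"] = (support >= threshold) | ((1.0 - support) >= threshold)
    return out.reset_index(drop=True)


def segment_homozygous_runs(
    calls: pd.DataFrame,
    min_sites: int = 10,
    het_interrupt_rate: float = 0.02,
) -> list[LohSegment]:
    """Greedy left-to-right maximal tolerant runs of homozygous calls.

    A window of consecutive calls is a valid run when it starts and ends
    homozygous, contains no two adjacent heterozygous calls, and its
    heterozygous count does not exceed ``floor(rate * window size)``
    (default one interruption per 50 sites).  Scanning left to right,
    each run is extended to the furthest valid endpoint and the scan
    resumes after it; runs shorter than ``min_sites`` are dropped.
    Segment span is first to last member site (0-based half-open).
    """
    segments: list[LohSegment] = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        hom = grp["homozygous"].to_numpy(dtype=bool)
        support = grp["support"].to_numpy()
        n = len(pos)
        i = 0
        while i < n:
            if not hom[i]:
                i += 1
                continue
            valid_j = i
            n_het = 0
            prev_het = False
            j = i
            while j < n:
                if hom[j]:
                    prev_het = False
                    length = j - i + 1
                    if n_het <= math.floor(het_interrupt_rate * length):
                        valid_j = j
                else:
                    if prev_het:
                        break  # adjacent heterozygous calls end the run
                    n_het += 1
                    prev_het = True
                j += 1
            n_members = valid_j - i + 1
            if n_members >= min_sites:
                member_support = support[i:valid_j + 1]
                major = np.maximum(member_support, 1.0 - member_support)
                segments.append(LohSegment(
                    chrom=chrom, start=int(pos[i]) - 1, end=int(pos[valid_j]),
                    kind=None, n_sites=n_members, mean_support=float(major.mean())))
            i = valid_j + 1
    return segments


def classify_loh_segments(
    segments: list[LohSegment],
    calls: pd.DataFrame,
    layout: GenomeLayout,
    terminal_margin_sites: int = 3,
    upd_fraction: float = 0.95,
) -> list[LohSegment]:
    """Assign positional classes using the assessed sites per chromosome.

    ``upd`` when the segment contains >= ``upd_fraction`` of the
    chromosome's assessed sites; ``terminal`` when it reaches within
    ``terminal_margin_sites`` assessed sites of either outermost assessed
    site; else ``interstitial``.
    """
    assessed = {chrom: grp["pos"].sort_values().to_numpy()
                for chrom, grp in calls.groupby("chrom", sort=False)}
    out: list[LohSegment] = []
    for seg in segments:
        if seg.chrom not in layout:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        pos = assessed.get(seg.chrom)
        if pos is None or len(pos) == 0:
            raise ValueError(f"no assessed sites on {seg.chrom}")
        inside = (pos - 1 >= seg.start) & (pos - 1 < seg.end)
        n_inside = int(inside.sum())
        if n_inside >= upd_fraction * len(pos):
            out.append(seg.with_kind("upd"))
            continue
        idx = np.flatnonzero(inside)
        first, last = int(idx[0]), int(idx[-1])
        reaches_left = first < terminal_margin_sites
        reaches_right = (len(pos) - 1 - last) < terminal_margin_sites
        if reaches_left or reaches_right:
            out.append(seg.with_kind("terminal"))
        else:
            out.append(seg.with_kind("interstitial"))
    return out


def homozygosity_fraction(
    segments: list[LohSegment],
    calls: pd.DataFrame,
) -> float:
    """Length-weighted homozygosity: total LOH segment length divided by
    the total assessed span (first-to-last assessed site per chromosome).

    NaN when no sites were assessed.
    """
    span_total = 0
    for _, grp in calls.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        span_total += int(pos.max()) - (int(pos.min()) - 1)
    if span_total == 0:
        return float("nan")
    seg_total = sum(seg.length for seg in segments)
    return min(1.0, seg_total / span_total)


def _terminal_regions(layout: GenomeLayout, chrom: str,
                      arm_fraction: float) -> list[tuple[int, int]]:
    rec = layout[chrom]
    left_len = int(round(arm_fraction * rec.centromere))
    right_len = int(round(arm_fraction * (rec.length - rec.centromere)))
    return [(0, left_len), (rec.length - right_len, rec.length)]


def _terminal_overlap(starts: np.ndarray, length: int,
                      regions: list[tuple[int, int]]) -> np.ndarray:
    total = np.zeros(len(starts))
    ends = starts + length
    for r_start, r_end in regions:
        total += np.clip(np.minimum(ends, r_end) - np.maximum(starts, r_start), 0, None)
    return total


def loh_pattern_statistic(
    segments: list[LohSegment],
    layout: GenomeLayout,
    n_permutations: int = 1000,
    seed: int = 0,
    terminal_arm_fraction: float = 0.20,
    homozygosity: float | None = None,
    min_segments: int = 3,
    strain: str = "strain",
) -> LohPatternReport:
    """Score the telomere bias of the genome-wide LOH pattern.

    Statistic: fraction of total LOH length inside the terminal
    ``terminal_arm_fraction`` of each chromosome arm (arms split at the
    centromere).  The null re-places each segment uniformly along its
    chromosome, preserving lengths.  ``mitotic-dominated`` when the
    statistic exceeds the null's 95th percentile, ``meiotic-dominated``
    inside the central 90 %, ``fully-homozygous`` when the genome-wide
    homozygosity is >= 0.99, otherwise ``undetermined``.
    """
    rng = np.random.default_rng(seed)
    hom_frac = homozygosity if homozygosity is not None else float("nan")
    if homozygosity is not None and homozygosity >= 0.99:
        return LohPatternReport(strain, hom_frac, float("nan"), "fully-homozygous",
                                float("nan"))
    total_len = sum(seg.length for seg in segments)
    if len(segments) < min_segments or total_len == 0:
        return LohPatternReport(strain, hom_frac, float("nan"), "undetermined",
                                float("nan"))
    observed_terminal = 0.0
    null_terminal = np.zeros(n_permutations)
    for seg in segments:
        regions = _terminal_regions(layout, seg.chrom, terminal_arm_fraction)
        observed_terminal += float(_terminal_overlap(np.array([seg.start]), seg.length,
                                                     regions)[0])
        chrom_len = layout[seg.chrom].length
        max_start = max(1, chrom_len - seg.length)
        starts = rng.integers(0, max_start, size=n_permutations)
        null_terminal += _terminal_overlap(starts, seg.length, regions)
    statistic = observed_terminal / total_len
    null = null_terminal / total_len
    p_value = float((np.sum(null >= statistic) + 1) / (n_permutations + 1))
    q5, q95 = np.percentile(null, [5, 95])
    if statistic > q95:
        pattern = "mitotic-dominated"
    elif statistic >= q5:
        pattern = "meiotic-dominated"
    else:
        pattern = "undetermined"
    return LohPatternReport(strain, hom_frac, statistic, pattern, p_value)


class LohSegmenter(BaseEstimator):
    """Full LOH analysis for one strain (scikit-learn style).

    ``fit`` runs zygosity calling, run segmentation, positional
    classification, the homozygosity fraction and the mitotic/meiotic
    pattern statistic.

    Attributes (after ``fit``)
    --------------------------
    calls_ : per-site zygosity DataFrame.
    segments_ : classified :class:`LohSegment` list.
    homozygosity_ : length-weighted homozygous fraction of the assessed span.
    report_ : :class:`LohPatternReport`.
    """

    def __init__(self, threshold: float = 0.90, min_depth: int = 10,
                 min_sites: int = 10, het_interrupt_rate: float = 0.02,
                 terminal_margin_sites: int = 3, upd_fraction: float = 0.95,
                 terminal_arm_fraction: float = 0.20,
                 n_permutations: int = 1000, seed: int = 0):
        self.threshold = threshold
        self.min_depth = min_depth
        self.min_sites = min_sites
        self.het_interrupt_rate = het_interrupt_rate
        self.terminal_margin_sites = terminal_margin_sites
        self.upd_fraction = upd_fraction
        self.terminal_arm_fraction = terminal_arm_fraction
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None, *, layout: GenomeLayout,
            strain: str = "strain") -> "LohSegmenter":
        self.calls_ = zygosity_table(X, threshold=self.threshold, min_depth=self.min_depth)
        raw = segment_homozygous_runs(self.calls_, min_sites=self.min_sites,
                                      het_interrupt_rate=self.het_interrupt_rate)
        self.segments_ = classify_loh_segments(
            raw, self.calls_, layout,
            terminal_margin_sites=self.terminal_margin_sites,
            upd_fraction=self.upd_fraction)
        self.homozygosity_ = homozygosity_fraction(self.segments_, self.calls_)
        self.report_ = loh_pattern_statistic(
            self.segments_, layout, n_permutations=self.n_permutations,
            seed=self.seed, terminal_arm_fraction=self.terminal_arm_fraction,
            homozygosity=self.homozygosity_, strain=strain)
        return self
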