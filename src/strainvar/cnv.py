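"""Aneuploidy and segmental CNV calling from normalized window coverage.

Whole-chromosome copy number is the per-chromosome median of
``norm_ratio`` (depth / genome-wide median depth) scaled by the baseline
ploidy and rounded; an aneuploidy is only called when a clear majority
of windows agree, so segmental events or noisy chromosomes fall back to
a euploid call with a low support fraction.  Segmental events are
maximal runs of windows deviating consistently from the chromosome's
called level, classified as interstitial or terminal by their distance
to the chromosome ends — the classes under which subtelomeric
duplications/deletions and internal rearrangements are tallied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import ChromosomeCopyCall, CnvSegment, GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "call_chromosome_copies",
    "detect_segmental_cnv",
    "classify_segment_position",
    "annotate_breakpoint_repeats",
    "CnvCaller",
]


def _round_half_up(x: np.ndarray | float) -> np.ndarray | int:
    """Round with ties going up (0.5 -> 1), unlike banker's rounding."""
    return np.floor(np.asarray(x) + 0.5).astype(int)


def call_chromosome_copies(
    windows: pd.DataFrame,
    baseline_ploidy: int,
    support_fraction: float = 0.8,
    min_windows: int = 3,
    deny_chroms: frozenset[str] | set[str] = frozenset(),
) -> list[ChromosomeCopyCall]:
    """Call a whole-chromosome copy number per chromosome.

    copy = round(median(norm_ratio) * baseline_ploidy); the call is
    aneuploid (gain/loss) only when >= ``support_fraction`` of windows
    individually round to that same non-baseline copy number, otherwise
    the chromosome is reported euploid.  Chromosomes with fewer than
    ``min_windows`` windows are skipped with a warning.
    """
    if baseline_ploidy not in (2, 3, 4):
        raise ValueError(f"baseline ploidy must be 2, 3 or 4, got {baseline_ploidy}")
    calls: list[ChromosomeCopyCall] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        if chrom in deny_chroms:
            continue
        n = len(grp)
        if n < min_windows:
            logger.warning("%s: only %d windows; copy call skipped", chrom, n)
            continue
        ratios = grp["norm_ratio"].to_numpy()
        copy = int(_round_half_up(float(np.median(ratios)) * baseline_ploidy))
        window_copies = _round_half_up(ratios * baseline_ploidy)
        support = float(np.mean(window_copies == copy))
        if copy != baseline_ploidy and support >= support_fraction:
            state = "gain" if copy > baseline_ploidy else "loss"
            calls.append(ChromosomeCopyCall(chrom, copy, state, support, n))
        else:
            baseline_support = float(np.mean(window_copies == baseline_ploidy))
            calls.append(ChromosomeCopyCall(chrom, baseline_ploidy, "euploid",
                                            baseline_support, n))
    return calls


def classify_segment_position(
    segment: CnvSegment,
    layout: GenomeLayout,
    terminal_margin: int,
    chrom_copy_number: int,
) -> str:
    """Combine position (terminal/interstitial) with direction
    (duplication/deletion) relative to the chromosome's called copies."""
    chrom = layout[segment.chrom]
    if segment.start < 0 or segment.end > chrom.length:
        raise ValueError(f"segment {segment.chrom}:{segment.start}-{segment.end} "
                         f"outside chromosome bounds (0-{chrom.length})")
    terminal = segment.start < terminal_margin or segment.end > chrom.length - terminal_margin
    position = "terminal" if terminal else "interstitial"
    if segment.copy_number == chrom_copy_number:
        raise ValueError("segment copy number equals the chromosome level; not a CNV")
    direction = "duplication" if segment.copy_number > chrom_copy_number else "deletion"
    return f"{position}_{direction}"


def detect_segmental_cnv(
    windows: pd.DataFrame,
    chromosome_calls: list[ChromosomeCopyCall],
    baseline_ploidy: int,
    min_windows: int = 3,
    ratio_margin: float = 0.3,
    layout: GenomeLayout | None = None,
    terminal_margin: int | None = None,
) -> list[CnvSegment]:
    """Find maximal runs of windows deviating from the chromosome level.

    A window deviates when |norm_ratio - called level| >=
    ``ratio_margin / baseline_ploidy`` (0.3 of one copy by default); runs
    of >= ``min_windows`` consecutive windows deviating in one direction
    become segments with copy number round(run median * baseline).
    With a layout, each segment is classified positionally
    (``terminal_margin`` defaults to two window widths).
    """
    if min_windows < 2:
        raise ValueError("min_windows must be >= 2")
    level_by_chrom = {c.chrom: c.copy_number for c in chromosome_calls}
    segments: list[CnvSegment] = []
    threshold = ratio_margin / baseline_ploidy
    for chrom, grp in windows.groupby("chrom", sort=False):
        if chrom not in level_by_chrom:
            continue
        level_ratio = level_by_chrom[chrom] / baseline_ploidy
        grp = grp.sort_values("start")
        ratios = grp["norm_ratio"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if terminal_margin is None:
            width = int(np.median(ends - starts))
            margin = 2 * width
        else:
            margin = terminal_margin
        dev = ratios - level_ratio
        direction = np.where(dev >= threshold, 1, np.where(dev <= -threshold, -1, 0))
        i = 0
        n = len(direction)
        while i < n:
            if direction[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and direction[j + 1] == direction[i]:
                j += 1
            if j - i + 1 >= min_windows:
                run_copy = int(_round_half_up(float(np.median(ratios[i:j + 1])) * baseline_ploidy))
                if run_copy != level_by_chrom[chrom]:
                    seg = CnvSegment(chrom=chrom, start=int(starts[i]), end=int(ends[j]),
                                     copy_number=run_copy, kind=None, n_windows=j - i + 1)
                    if layout is not None:
                        kind = classify_segment_position(seg, layout, margin,
                                                         level_by_chrom[chrom])
                        seg = seg.with_kind(kind)
                    segments.append(seg)
            i = j + 1
    return segments


def annotate_breakpoint_repeats(
    segments: list[CnvSegment],
    repeats: pd.DataFrame,
    flank: int = 1000,
) -> tuple[list[CnvSegment], float]:
    """Label each segment boundary with any repeat feature (LTR, Ty,
    mating locus, ...) lying within ``flank`` bp; returns the annotated
    segments and the fraction of breakpoints that are repeat-associated."""
    annotated: list[CnvSegment] = []
    hits = 0
    total = 0
    for seg in segments:
        feats = repeats[repeats["chrom"] == seg.chrom]
        labels = []
        for boundary in (seg.start, seg.end):
            total += 1
            near = feats[(feats["end"] >= boundary - flank) & (feats["start"] <= boundary + flank)]
            if len(near):
                # closest feature wins
                dist = np.minimum(np.abs(near["start"] - boundary), np.abs(near["end"] - boundary))
                labels.append(str(near.loc[dist.idxmin(), "kind"]))
                hits += 1
            else:
                labels.append("none")
        annotated.append(CnvSegment(seg.chrom, seg.start, seg.end, seg.copy_number,
                                    seg.kind, seg.n_windows, (labels[0], labels[1])))
    fraction = hits / total if total else float("nan")
    return annotated, fraction


class CnvCaller(BaseEstimator):
    """Whole-chromosome and segmental CNV caller (scikit-learn style).

    Parameters mirror :func:`call_chromosome_copies` /
    :func:`detect_segmental_cnv`; ``deny_chroms`` excludes depth-artifact
    contigs (rDNA, mitochondrial) from calling.

    Attributes (after ``fit``)
    --------------------------
    chromosome_calls_ : list of :class:`ChromosomeCopyCall`.
    segments_ : list of :class:`CnvSegment`.
    aneuploid_chroms_ : set of chromosomes called gain/loss.
    """

    def __init__(self, baseline_ploidy: int = 2, support_fraction: float = 0.8,
                 min_windows: int = 3, ratio_margin: float = 0.3,
                 terminal_margin: int | None = None,
                 deny_chroms: tuple[str, ...] = ()):
        self.baseline_ploidy = baseline_ploidy
        self.support_fraction = support_fraction
        self.min_windows = min_windows
        self.ratio_margin = ratio_margin
        self.terminal_margin = terminal_margin
        self.deny_chroms = deny_chroms

    def fit(self, X: pd.DataFrame, y=None, *, layout: GenomeLayout | None = None,
            repeats: pd.DataFrame | None = None) -> "CnvCaller":
        """Fit on a normalized coverage DataFrame."""
        self.chromosome_calls_ = call_chromosome_copies(
            X, self.baseline_ploidy, support_fraction=self.support_fraction,
            deny_chroms=set(self.deny_chroms))
        self.segments_ = detect_segmental_cnv(
            X, self.chromosome_calls_, self.baseline_ploidy,
            min_windows=self.min_windows, ratio_margin=self.ratio_margin,
            layout=layout, terminal_margin=self.terminal_margin)
        if repeats is not None:
            self.segments_, self.repeat_fraction_ = annotate_breakpoint_repeats(
                self.segments_, repeats)
        self.aneuploid_chroms_ = {c.chrom for c in self.chromosome_calls_
                                  if c.state != "euploid"}
        return self
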