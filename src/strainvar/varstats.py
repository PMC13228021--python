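"""Strain-pair SNV distances, divergence times, and variant annotation
tallies.

Divergence time between two strains follows the molecular-clock
arithmetic: ``years = snv_difference / mu * generation_hours / 8760``
with a default accumulation rate mu of 5e-3 SNVs per genome per cell
division and a 2 h generation time.  The count is used as-is (no
division over the two lineages), matching how the endpoint estimates
are conventionally quoted for these rates.

InDel repeat context captures the replication-slippage signature: most
small InDels arise inside mononucleotide runs or microsatellites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceEstimate",
    "AnnotationTally",
    "pairwise_snv_distance",
    "divergence_time",
    "annotation_tallies",
    "indel_repeat_context",
]

HOURS_PER_YEAR = 8760.0  # 365 days

CODING_LABELS = frozenset({"synonymous", "missense", "frameshift", "start_stop_gain_loss"})


@dataclass(frozen=True)
class DivergenceEstimate:
    strain_a: str
    strain_b: str
    snv_difference: int
    mu: float  # SNVs per genome per cell division
    generation_hours: float
    years: float


@dataclass(frozen=True)
class AnnotationTally:
    """Per-strain annotation summary."""

    strain: str
    n_snvs: int
    coding_fraction: float
    synonymous: int
    missense: int
    syn_missense_ratio: float  # NaN when missense == 0
    frameshift_indels: int
    start_stop_gain_loss: int
    repeat_context_indel_fraction: float


def _snv_keys(sites: pd.DataFrame) -> set[tuple[str, int, str]]:
    snv = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)
    sub = sites.loc[snv]
    return set(zip(sub["chrom"], sub["pos"], sub["alt"]))


def pairwise_snv_distance(sites_a: pd.DataFrame, sites_b: pd.DataFrame) -> int:
    """Number of SNVs private to either strain: the size of the symmetric
    difference over (chrom, pos, alt) records.  InDels are excluded; a
    shared position with different alternate alleles counts twice."""
    return len(_snv_keys(sites_a) ^ _snv_keys(sites_b))


def divergence_time(
    snv_difference: int,
    mu: float = 0.005,
    generation_hours: float = 2.0,
) -> float:
    """Molecular-clock divergence estimate in years.

    ``snv_difference / mu`` cell divisions, ``generation_hours`` each,
    converted with 8,760 hours per year.
    """
    if snv_difference < 0:
        raise ValueError("SNV difference must be non-negative")
    if mu <= 0 or generation_hours <= 0:
        raise ValueError("mu and generation_hours must be positive")
    return snv_difference / mu * generation_hours / HOURS_PER_YEAR


def annotation_tallies(
    sites: pd.DataFrame,
    strain: str = "strain",
    indel_contexts: dict[tuple[str, int], str] | None = None,
) -> AnnotationTally:
    """Tally annotation labels over a variant table.

    SNV labels are consumed as supplied (codon-level effect calling is an
    upstream annotator's job); frameshift status of coding InDels is
    computed natively from lengths (|len(alt) - len(ref)| mod 3 != 0).
    Sites lacking an annotation count as ``other`` (logged).
    ``indel_contexts`` maps (chrom, pos) to a repeat-context label for
    the repeat-context fraction.
    """
    ann = sites["annotation"].where(sites["annotation"].notna(), None)
    n_missing = int((ann.isna() | (ann == None)).sum())  # noqa: E711
    if n_missing:
        logger.info("%s: %d sites without annotation counted as 'other'", strain, n_missing)
    labels = ann.fillna("other")
    is_snv = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)

    snv_labels = labels[is_snv]
    n_snvs = int(is_snv.sum())
    coding = int(snv_labels.isin(CODING_LABELS).sum())
    synonymous = int((snv_labels == "synonymous").sum())
    missense = int((snv_labels == "missense").sum())
    start_stop = int((snv_labels == "start_stop_gain_loss").sum())

    indels = sites.loc[~is_snv]
    delta = (indels["alt"].str.len() - indels["ref"].str.len()).abs()
    coding_indel = labels[~is_snv].isin(CODING_LABELS)
    frameshift = int(((delta % 3 != 0) & coding_indel).sum())

    if indel_contexts and len(indels):
        ctx = [indel_contexts.get((c, p)) for c, p in zip(indels["chrom"], indels["pos"])]
        known = [c for c in ctx if c is not None]
        repeat_fraction = (sum(c != "non_repeat" for c in known) / len(known)
                           if known else float("nan"))
    else:
        repeat_fraction = float("nan")

    return AnnotationTally(
        strain=strain,
        n_snvs=n_snvs,
        coding_fraction=coding / n_snvs if n_snvs else float("nan"),
        synonymous=synonymous,
        missense=missense,
        syn_missense_ratio=synonymous / missense if missense else float("nan"),
        frameshift_indels=frameshift,
        start_stop_gain_loss=start_stop,
        repeat_context_indel_fraction=repeat_fraction,
    )


# ---------------------------------------------------------------------------
# repeat context

def _max_run_through(seq: str, lo: int, hi: int, base: str) -> int:
    """Length of the maximal single-base run of ``base`` containing
    positions [lo, hi) of ``seq`` (assumes seq[lo:hi] is all ``base``)."""
    left = lo
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = hi
    while right < len(seq) and seq[right] == base:
        right += 1
    return right - left


def _tandem_overlaps(seq: str, lo: int, hi: int,
                     min_units: int = 3, motif_sizes: range = range(2, 7)) -> bool:
    """True if any tandem repeat (motif of 2-6 bp, >= min_units copies)
    in ``seq`` overlaps positions [lo, hi)."""
    n = len(seq)
    for k in motif_sizes:
        for s in range(0, n - min_units * k + 1):
            unit = seq[s:s + k]
            t = 1
            while seq[s + t * k: s + (t + 1) * k] == unit:
                t += 1
            if t >= min_units:
                span_end = s + t * k
                if s < hi and span_end > lo:
                    return True
    return False


def indel_repeat_context(site: VariantSite, window: str, center: int | None = None) -> str:
    """Classify the repeat context of an InDel.

    ``window`` is the reference sequence around the InDel (>= 21 bp) and
    ``center`` the window index of the InDel's anchor base (defaults to
    the middle).  The event's own bases count toward run lengths:
    ``mononucleotide_repeat`` for a single-base run of >= 4 bp,
    ``microsatellite`` for >= 3 tandem units of a 2-6 bp motif, else
    ``non_repeat``; mononucleotide takes precedence.
    """
    if len(window) < 21:
        raise ValueError(f"reference window must be >= 21 bp, got {len(window)}")
    if not site.is_indel:
        raise ValueError("site is not an InDel")
    if center is None:
        center = len(window) // 2
    window = window.upper()

    if len(site.ref) > len(site.alt):  # deletion: event bases are in the reference
        event = site.ref[len(site.alt):]
        seq = window
        lo, hi = center + 1, center + 1 + len(event)
    else:  # insertion: analyse the post-insertion sequence
        event = site.alt[len(site.ref):]
        seq = window[:center + 1] + event + window[center + 1:]
        lo, hi = center + 1, center + 1 + len(event)
    if hi > len(seq):
        raise ValueError("window too short to contain the InDel event")

    if len(set(event)) == 1 and _max_run_through(seq, lo, hi, event[0]) >= 4:
        return "mononucleotide_repeat"
    if _tandem_overlaps(seq, lo, hi):
        return "microsatellite"
    return "non_repeat"
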