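"""Detection of additional (horizontally acquired) genes.

A predicted ORF is *additional* when its best global-alignment identity
to the reference ORF set is at or below 85 % (or it has no credible
match at all).  Identity is computed over global-alignment columns
(Needleman-Wunsch, match +1 / mismatch -1 / gap -2, end gaps penalized;
gap columns count toward the denominator), which is stricter and more
deterministic than a local-alignment identity.  An exact-k-mer
pre-filter keeps the all-vs-all comparison tractable.

Contig-level evidence is also assessed: tandem telomere-motif repeats at
a contig end place the insertion at a chromosome end, and a run of
additional genes flanked on both sides by copies of the same native gene
marks an integration that duplicated its target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .model import TELOMERE_MOTIF

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMatch",
    "ContigReport",
    "percent_identity",
    "align_global",
    "flag_additional_genes",
    "detect_telomeric_end",
    "detect_flanking_duplication",
    "AdditionalGeneClassifier",
]

GAP = -2
MATCH = 1
MISMATCH = -1


@dataclass(frozen=True)
class GeneMatch:
    """Best reference match for one query ORF."""

    query_id: str
    ref_id: str | None
    identity: float  # percent, 0-100
    additional: bool
    contig: str | None = None


@dataclass(frozen=True)
class ContigReport:
    contig: str
    length: int
    telomeric_end: str  # left | right | both | none
    genes: tuple[GeneMatch, ...]
    flanking_duplication: bool
    flanking_gene: str | None


# ---------------------------------------------------------------------------
# global alignment

def _score_matrix(a: str, b: str) -> np.ndarray:
    """Needleman-Wunsch score matrix with linear gaps, end gaps penalized.

    Row recurrence: the within-row left-gap dependency is a running
    maximum, solved with an accumulate over candidates + 2j.
    """
    n, m = len(a), len(b)
    a_idx = np.frombuffer(a.encode(), dtype=np.uint8)
    b_idx = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(a_idx[:, None] == b_idx[None, :], MATCH, MISMATCH).astype(np.int32)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0] = GAP * np.arange(m + 1)
    offsets = -GAP * np.arange(m + 1)  # +2j
    for i in range(1, n + 1):
        prev = H[i - 1]
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = GAP * i
        np.maximum(prev[:-1] + sub[i - 1], prev[1:] + GAP, out=cand[1:])
        H[i] = np.maximum.accumulate(cand + offsets) - offsets
    return H


def align_global(a: str, b: str) -> tuple[int, int, int]:
    """Optimal global alignment of two sequences.

    Returns (score, matches, columns).  Traceback ties break diagonal
    first, then gap-in-``b``, then gap-in-``a``, so the reported identity
    is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    H = _score_matrix(a, b)
    i, j = len(a), len(b)
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + GAP:
            i -= 1
            continue
        j -= 1
    return int(H[len(a), len(b)]), matches, columns


def percent_identity(query: str, reference: str) -> float:
    """Global-alignment percent identity: matches / alignment columns x 100."""
    _, matches, columns = align_global(query.upper(), reference.upper())
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# additional-gene screening

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def flag_additional_genes(
    query_orfs: list[tuple[str, str]],
    reference_orfs: list[tuple[str, str]],
    threshold: float = 85.0,
    k: int = 15,
    min_shared_kmers: int = 5,
    contig: str | None = None,
) -> list[GeneMatch]:
    """Match each query ORF to its best-identity reference ORF and flag
    the additional ones (identity <= ``threshold``, boundary inclusive,
    or no candidate sharing >= ``min_shared_kmers`` exact k-mers).

    Ties on identity go to the lexicographically smallest reference id.
    """
    if not reference_orfs:
        logger.warning("empty reference ORF set: every query is additional")
        return [GeneMatch(qid, None, 0.0, True, contig) for qid, _ in query_orfs]
    ref_kmers = [(rid, rseq, _kmers(rseq.upper(), k)) for rid, rseq in reference_orfs]
    matches: list[GeneMatch] = []
    for qid, qseq in query_orfs:
        qk = _kmers(qseq.upper(), k)
        candidates = [(rid, rseq) for rid, rseq, rk in ref_kmers
                      if len(qk & rk) >= min_shared_kmers]
        best_id: str | None = None
        best_identity = 0.0
        for rid, rseq in sorted(candidates):
            identity = percent_identity(qseq, rseq)
            if identity > best_identity:
                best_identity, best_id = identity, rid
        matches.append(GeneMatch(qid, best_id, best_identity,
                                 best_id is None or best_identity <= threshold, contig))
    return matches


# ---------------------------------------------------------------------------
# contig evidence

def _motif_tandem_copies(region: str, motif: str, min_conservation: float = 0.9) -> int:
    """Maximum number of consecutive motif copies anywhere in ``region``,
    each copy conserved at >= ``min_conservation``."""
    L = len(motif)
    best = 0
    motif_arr = np.frombuffer(motif.encode(), dtype=np.uint8)
    region_arr = np.frombuffer(region.encode(), dtype=np.uint8)
    for start in range(len(region) - L + 1):
        t = 0
        pos = start
        while pos + L <= len(region):
            window = region_arr[pos:pos + L]
            if np.mean(window == motif_arr) >= min_conservation:
                t += 1
                pos += L
            else:
                break
        best = max(best, t)
        if best >= len(region) // L:
            break
    return best


def detect_telomeric_end(
    contig_seq: str,
    motif: str = TELOMERE_MOTIF,
    min_copies: int = 8,
    window: int = 500,
) -> str:
    """Which contig end carries >= ``min_copies`` tandem telomere-motif
    repeats (each copy >= 90 % conserved) within the terminal ``window``:
    ``left``, ``right``, ``both`` or ``none``.  Contigs shorter than the
    window are scanned whole."""
    if not motif:
        raise ValueError("telomere motif must be non-empty")
    seq = contig_seq.upper()
    motif = motif.upper()
    w = min(window, len(seq))
    left = _motif_tandem_copies(seq[:w], motif) >= min_copies
    right = _motif_tandem_copies(seq[-w:], motif) >= min_copies
    if left and right:
        return "both"
    if left:
        return "left"
    if right:
        return "right"
    return "none"


def detect_flanking_duplication(
    gene_order: list[GeneMatch],
) -> tuple[bool, str | None]:
    """Detect a run of additional genes bounded on both sides by matches
    to the same native reference gene (the signature of an integration
    that duplicated its target locus).  ``gene_order`` follows the gene
    order along the contig."""
    for i, left in enumerate(gene_order):
        if left.additional or left.ref_id is None:
            continue
        j = i + 1
        saw_additional = False
        while j < len(gene_order) and gene_order[j].additional:
            saw_additional = True
            j += 1
        if saw_additional and j < len(gene_order) and gene_order[j].ref_id == left.ref_id:
            return True, left.ref_id
    return False, None


class AdditionalGeneClassifier(BaseEstimator):
    """Additional-gene screen (scikit-learn style).

    ``fit`` indexes the reference ORF set; ``predict`` flags query ORFs.

    Attributes (after ``fit``)
    --------------------------
    reference_ : the indexed reference ORF list.
    """

    def __init__(self, threshold: float = 85.0, k: int = 15,
                 min_shared_kmers: int = 5,
                 telomere_motif: str = TELOMERE_MOTIF,
                 telomere_min_copies: int = 8, telomere_window: int = 500):
        self.threshold = threshold
        self.k = k
        self.min_shared_kmers = min_shared_kmers
        self.telomere_motif = telomere_motif
        self.telomere_min_copies = telomere_min_copies
        self.telomere_window = telomere_window

    def fit(self, X: list[tuple[str, str]], y=None) -> "AdditionalGeneClassifier":
        """``X`` is the reference ORF set as (id, sequence) pairs."""
        self.reference_ = list(X)
        return self

    def predict(self, X: list[tuple[str, str]],
                contig: str | None = None) -> list[GeneMatch]:
        """Flag additional genes among query ORFs (id, sequence pairs)."""
        return flag_additional_genes(X, self.reference_, threshold=self.threshold,
                                     k=self.k, min_shared_kmers=self.min_shared_kmers,
                                     contig=contig)

    def contig_report(self, contig_id: str, contig_seq: str,
                      genes: list[tuple[str, str]]) -> ContigReport:
        """Full per-contig report: gene matches in contig order, telomeric
        ends, and flanking-duplication evidence."""
        matches = self.predict(genes, contig=contig_id)
        telo = detect_telomeric_end(contig_seq, self.telomere_motif,
                                    self.telomere_min_copies, self.telomere_window)
        flagged, flank_gene = detect_flanking_duplication(matches)
        return ContigReport(contig_id, len(contig_seq), telo, tuple(matches),
                            flagged, flank_gene)
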