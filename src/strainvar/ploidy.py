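"""Ploidy inference from heterozygous-site allele fractions.

A diploid heterozygous site shows ~50 % alternate-read support; triploid
heterozygous sites cluster around 33 % / 66 %, tetraploid around
25 % / 50 % / 75 %.  Each candidate ploidy ``c`` therefore predicts a
uniform-weight mixture of Binomial(depth, a/c) alt counts for
``a = 1..c-1``; the candidate maximizing a complexity-penalized
log-likelihood is returned.  This is the sequencing-based analog of
flow-cytometry ploidy determination.

Note the tetraploid mixture contains the a=2 (50 %) component that
overlaps the diploid model; discrimination rests on the 25 %/75 %
components, which is why per-candidate scores are always reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .model import PloidyCall

__all__ = ["collect_het_fractions", "fit_ploidy", "PloidyEstimator"]

CANDIDATE_PLOIDIES = (2, 3, 4)


def collect_het_fractions(
    sites: pd.DataFrame,
    min_depth: int = 10,
    band: tuple[float, float] = (0.10, 0.90),
) -> pd.DataFrame:
    """Filter sites to usable heterozygous candidates and attach ``support``.

    Keeps sites with total depth >= ``min_depth`` whose alternate-read
    fraction lies inside ``band`` (the band mirrors the homozygosity rule:
    fractions at or beyond its edges belong to homozygous sites).
    SNVs only; InDel records are excluded.
    """
    low, high = band
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"invalid band {band}")
    snv = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1)
    depth = sites["ref_depth"] + sites["alt_depth"]
    out = sites.loc[snv & (depth >= min_depth)].copy()
    depth = out["ref_depth"] + out["alt_depth"]
    out["depth"] = depth
    out["support"] = out["alt_depth"] / depth
    out = out[(out["support"] > low) & (out["support"] < high)]
    return out.reset_index(drop=True)


def _mixture_loglik(alt: np.ndarray, depth: np.ndarray, ploidy: int) -> float:
    """Log-likelihood of alt counts under the uniform Binomial mixture for
    one candidate ploidy."""
    comps = np.stack([
        binom.logpmf(alt, depth, a / ploidy) for a in range(1, ploidy)
    ])
    return float(np.sum(logsumexp(comps, axis=0) - np.log(ploidy - 1)))


def fit_ploidy(
    fractions: np.ndarray,
    depths: np.ndarray,
    min_sites: int = 200,
    candidates: tuple[int, ...] = CANDIDATE_PLOIDIES,
    strain: str = "strain",
) -> PloidyCall:
    """Score each candidate ploidy and return the best-supported one.

    Score(c) = log-likelihood(c) - (c - 1) * log(n): the penalty counts
    mixture components, so richer mixtures must earn their keep.  Ties go
    to the smaller ploidy; fewer than ``min_sites`` usable sites yields an
    undetermined call.
    """
    fractions = np.asarray(fractions, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if fractions.shape != depths.shape:
        raise ValueError("fractions and depths must be aligned")
    n = len(fractions)
    if n == 0:
        return PloidyCall(strain=strain, ploidy=None, scores={}, n_sites=0)
    alt = np.rint(fractions * depths)
    scores = {
        c: _mixture_loglik(alt, depths, c) - (c - 1) * np.log(n)
        for c in candidates
    }
    if n < min_sites:
        return PloidyCall(strain=strain, ploidy=None, scores=scores, n_sites=n)
    best = None
    for c in sorted(candidates):
        if best is None or scores[c] > scores[best]:
            best = c
    return PloidyCall(strain=strain, ploidy=best, scores=scores, n_sites=n)


class PloidyEstimator(BaseEstimator):
    """Infer strain ploidy from a variant table (scikit-learn style).

    Parameters
    ----------
    min_depth : minimum total depth for a usable site.
    band : (low, high) alternate-fraction window defining heterozygosity.
    min_sites : fewer usable sites than this gives an undetermined call.
    candidates : ploidies scored (the study's range is 2-4).

    Attributes (after ``fit``)
    --------------------------
    ploidy_ : inferred ploidy or ``None`` if undetermined.
    scores_ : per-candidate penalized log-likelihood.
    n_sites_ : number of heterozygous sites used.
    call_ : the full :class:`~strainvar.model.PloidyCall`.
    """

    def __init__(self, min_depth: int = 10, band: tuple[float, float] = (0.10, 0.90),
                 min_sites: int = 200, candidates: tuple[int, ...] = CANDIDATE_PLOIDIES):
        self.min_depth = min_depth
        self.band = band
        self.min_sites = min_sites
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y=None, *, strain: str = "strain",
            exclude_chroms: set[str] | None = None) -> "PloidyEstimator":
        """Fit on a variant DataFrame.  ``exclude_chroms`` drops chromosomes
        already known to be aneuploid (their shifted allele fractions would
        otherwise distort the genome-wide mixture)."""
        sites = X
        if exclude_chroms:
            sites = sites[~sites["chrom"].isin(exclude_chroms)]
        usable = collect_het_fractions(sites, min_depth=self.min_depth, band=self.band)
        self.call_ = fit_ploidy(
            usable["support"].to_numpy(), usable["depth"].to_numpy(),
            min_sites=self.min_sites, candidates=self.candidates, strain=strain)
        self.ploidy_ = self.call_.ploidy
        self.scores_ = self.call_.scores
        self.n_sites_ = self.call_.n_sites
        return self
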