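"""Shared domain types for the strain-comparison pipeline.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  VCF-style I/O is 1-based
inclusive and BED I/O is 0-based half-open; conversion happens at the I/O
boundary only (:mod:`strainvar.io`).

Site and window collections are carried as :class:`pandas.DataFrame` objects
(columns :data:`VARIANT_COLUMNS` / :data:`COVERAGE_COLUMNS`); the dataclasses
here describe single records and results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "VARIANT_COLUMNS",
    "COVERAGE_COLUMNS",
    "VariantSite",
    "CoverageWindow",
    "Chromosome",
    "GenomeLayout",
    "LohSegment",
    "CnvSegment",
    "ChromosomeCopyCall",
    "PloidyCall",
]

#: Column order for per-site variant tables.
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "annotation"]

#: Column order for windowed coverage tables.
COVERAGE_COLUMNS = ["chrom", "start", "end", "depth", "norm_ratio"]

_NUCLEOTIDES = set("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant site with per-allele read depths.

    ``pos`` is 1-based, matching variant-table conventions.  ``annotation``
    is an optional effect label (``synonymous``, ``missense``, ``frameshift``,
    ``start_stop_gain_loss``, ``noncoding``, ``other``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be non-negative")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _NUCLEOTIDES:
                raise ValueError(f"allele {allele!r} is not a non-empty ACGT string")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def support(self) -> float:
        """Alternate-allele read-support fraction (VAF)."""
        depth = self.total_depth
        if depth == 0:
            raise ZeroDivisionError("site has zero total depth")
        return self.alt_depth / depth

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class CoverageWindow:
    """Fixed-width coverage window (0-based half-open) with depth and
    the ratio of depth to the genome-wide median depth."""

    chrom: str
    start: int
    end: int
    depth: float
    norm_ratio: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must exceed start {self.start}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0 < self.centromere < self.length:
            raise ValueError(f"{self.name}: centromere must lie strictly inside the chromosome")


# sacCer3 chromosome lengths and centromere midpoints, downscaled 10x so a
# whole-genome simulation stays around 1.2 Mb while preserving the relative
# sizes (chromosome I remains the shortest, IV the longest).
_SCALED_CHROMOSOMES = [
    ("chrI", 23022, 15147),
    ("chrII", 81318, 23821),
    ("chrIII", 31662, 11439),
    ("chrIV", 153193, 44971),
    ("chrV", 57687, 15199),
    ("chrVI", 27016, 14851),
    ("chrVII", 109094, 49692),
    ("chrVIII", 56264, 10559),
    ("chrIX", 43989, 35563),
    ("chrX", 74575, 43631),
    ("chrXI", 66682, 44013),
    ("chrXII", 107818, 15083),
    ("chrXIII", 92443, 26803),
    ("chrXIV", 78433, 62876),
    ("chrXV", 109129, 32658),
    ("chrXVI", 94807, 55596),
]

#: Budding-yeast telomeric repeat consensus (TG1-3 family) used by the
#: simulator and the telomeric-end detector.
TELOMERE_MOTIF = "TGTGGGTGTGGTG"


@dataclass
class GenomeLayout:
    """Chromosome names, lengths and centromere positions plus the telomere
    repeat motif — the positional scaffold every caller shares."""

    chromosomes: list[Chromosome] = field(default_factory=list)
    telomere_motif: str = TELOMERE_MOTIF

    def __post_init__(self) -> None:
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names in layout")

    @classmethod
    def yeast_scaled(cls) -> "GenomeLayout":
        """Default 16-chromosome layout, ~1.2 Mb total (1/10 genome scale)."""
        return cls([Chromosome(n, l, c) for n, l, c in _SCALED_CHROMOSOMES])

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in layout") from None

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class LohSegment:
    """Contiguous run of homozygous sites.

    ``kind`` is one of ``interstitial``, ``terminal``, ``upd`` (or ``None``
    before positional classification).  ``start``/``end`` span the first to
    last member site, 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    kind: str | None
    n_sites: int
    mean_support: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_kind(self, kind: str) -> "LohSegment":
        return replace(self, kind=kind)


@dataclass(frozen=True)
class CnvSegment:
    """Segmental copy-number change called from window coverage.

    ``kind`` combines position and direction: ``interstitial_deletion``,
    ``interstitial_duplication``, ``terminal_deletion``,
    ``terminal_duplication``.
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    kind: str | None
    n_windows: int
    breakpoint_repeats: tuple[str, str] = ("none", "none")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_kind(self, kind: str) -> "CnvSegment":
        return replace(self, kind=kind)


@dataclass(frozen=True)
class ChromosomeCopyCall:
    """Whole-chromosome copy state relative to the baseline ploidy."""

    chrom: str
    copy_number: int
    state: str  # euploid | gain | loss
    support: float  # fraction of windows rounding to the called copy number
    n_windows: int


@dataclass(frozen=True)
class PloidyCall:
    """Result of allele-fraction ploidy inference for one strain."""

    strain: str
    ploidy: int | None  # None == undetermined
    scores: dict[int, float]
    n_sites: int
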