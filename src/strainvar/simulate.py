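"""Synthetic strain generator with known ground truth.

Generates yeast-like strains on a 1/10-scale 16-chromosome genome
(~1.2 Mb) with configurable ploidy, whole-chromosome aneuploidies,
LOH tracts of the three positional classes (interstitial / terminal /
uniparental disomy), segmental CNVs, InDels with controlled repeat
context, and horizontally acquired gene contigs at controlled sequence
identity.  Output matches the formats the callers consume (variant
table, coverage table, contig FASTA) plus a ground-truth record for
parameter-recovery tests.

Sampling model
--------------
* site depth ~ Poisson(mean_depth x local_copy_number / baseline_ploidy)
* at a heterozygous site carrying ``a`` alternate copies out of ``c``
  total copies, alt_depth ~ Binomial(depth, a/c)
* homozygous sites keep a residual error rate: the alternate fraction is
  sampled at p = 0.995 (alt-homozygous) or p = 0.005 (ref-homozygous),
  never exactly 1, so the 90 %% read-support rule is exercised
  non-trivially
* window depth is the Poisson read count expected for the window scaled
  by local copy number, converted back to mean depth (150 bp reads)

No read-level data are simulated: the downstream analyses consume only
allele depths and window depths.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import TELOMERE_MOTIF, VARIANT_COLUMNS, GenomeLayout

__all__ = [
    "SimulationConfig",
    "StrainSpec",
    "StrainTruth",
    "SimulatedStrain",
    "simulate_strain",
    "simulate_het_site_supports",
    "synthesize_reference",
    "synthesize_orfs",
    "plant_hgt_contig",
    "plant_indels",
    "make_loh_tract",
    "random_strain_spec",
    "simulate_phenotype_matrix",
    "simulate_fermentation_series",
]

_BASES = np.array(list("ACGT"))

VALID_PLOIDIES = (2, 3, 4)
LOH_KINDS = ("interstitial", "terminal", "upd")


# ---------------------------------------------------------------------------
# configuration and truth containers

@dataclass
class SimulationConfig:
    """Study-condition defaults for the simulator.

    het_density:
        heterozygous SNVs per bp (default one per 300 bp, giving a few
        thousand assessable sites genome-wide at 1/10 scale).
    mean_depth:
        genome-average sequencing depth at baseline copy number.
    hom_support:
        alternate-allele fraction sampled at homozygous sites (residual
        sequencing error keeps it below 1).
    indel_repeat_fraction:
        fraction of planted InDels placed in mononucleotide runs or
        microsatellites (replication-slippage contexts).
    """

    layout: GenomeLayout = field(default_factory=GenomeLayout.yeast_scaled)
    het_density: float = 1.0 / 300.0
    mean_depth: float = 80.0
    hom_support: float = 0.995
    window: int = 1000
    read_length: int = 150
    indel_repeat_fraction: float = 0.82

    def __post_init__(self) -> None:
        if self.het_density <= 0 or self.mean_depth <= 0:
            raise ValueError("densities and depths must be positive")
        if not 0.5 < self.hom_support < 1.0:
            raise ValueError("hom_support must be in (0.5, 1)")
        if not 0.0 <= self.indel_repeat_fraction <= 1.0:
            raise ValueError("indel_repeat_fraction must be in [0, 1]")


@dataclass
class StrainSpec:
    """Event plan for one simulated strain."""

    name: str = "sim"
    ploidy: int = 2
    aneuploidies: tuple[tuple[str, int], ...] = ()  # (chrom, copy delta)
    loh_tracts: tuple[tuple[str, int, int, str], ...] = ()  # (chrom, start, end, kind)
    cnvs: tuple[tuple[str, int, int, int], ...] = ()  # (chrom, start, end, copy delta)
    n_hgt_genes: int = 0
    hgt_identity: float = 0.80
    hgt_telomeric: bool = True
    n_native_orfs: int = 5
    n_indels: int = 0


@dataclass
class StrainTruth:
    """Ground truth emitted alongside each simulated strain."""

    strain: str
    ploidy: int
    chromosome_copies: dict[str, int]
    loh_tracts: list[tuple[str, int, int, str]]
    cnv_segments: list[tuple[str, int, int, int, str]]  # (..., copy delta, kind)
    hgt_genes: list[dict]
    het_sites: list[tuple[str, int, int, int]]  # (chrom, pos, alt copies, total copies)
    indel_contexts: list[tuple[str, int, str]]  # (chrom, pos, context)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StrainTruth":
        raw = json.loads(Path(path).read_text())
        raw["loh_tracts"] = [tuple(t) for t in raw["loh_tracts"]]
        raw["cnv_segments"] = [tuple(t) for t in raw["cnv_segments"]]
        raw["het_sites"] = [tuple(t) for t in raw["het_sites"]]
        raw["indel_contexts"] = [tuple(t) for t in raw["indel_contexts"]]
        return cls(**raw)


@dataclass
class SimulatedStrain:
    """Bundle of everything :func:`simulate_strain` emits."""

    variants: pd.DataFrame
    coverage: pd.DataFrame
    contigs: list[tuple[str, str]]  # (contig id, sequence)
    orfs: list[tuple[str, str]]  # predicted query ORFs (id, sequence)
    truth: StrainTruth


# ---------------------------------------------------------------------------
# low-level samplers

def simulate_het_site_supports(
    n_sites: int,
    depth: int,
    alt_copies: int,
    total_copies: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alt-allele support fractions at heterozygous sites with a fixed
    sequencing depth: alt_depth ~ Binomial(depth, alt_copies/total_copies)."""
    if not 0 < alt_copies < total_copies:
        raise ValueError("need 0 < alt_copies < total_copies for a heterozygous site")
    alt = rng.binomial(depth, alt_copies / total_copies, size=n_sites)
    return alt / depth


def _random_alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


# ---------------------------------------------------------------------------
# event placement helpers

def make_loh_tract(
    layout: GenomeLayout,
    chrom: str,
    kind: str,
    length: int,
    rng: np.random.Generator,
) -> tuple[str, int, int, str]:
    """Place an LOH tract of the requested positional class on a chromosome.

    interstitial tracts are internal (not touching either end), terminal
    tracts abut one chromosome end, and UPD covers the whole chromosome.
    """
    chrom_len = layout[chrom].length
    if kind not in LOH_KINDS:
        raise ValueError(f"unknown LOH kind {kind!r}")
    if kind == "upd":
        return (chrom, 0, chrom_len, "upd")
    if length >= chrom_len:
        raise ValueError(f"tract length {length} exceeds {chrom} ({chrom_len} bp)")
    if kind == "terminal":
        if rng.random() < 0.5:
            return (chrom, 0, length, "terminal")
        return (chrom, chrom_len - length, chrom_len, "terminal")
    # interstitial: keep a clear gap to both ends so the class is unambiguous
    gap = max(1000, chrom_len // 20)
    lo, hi = gap, chrom_len - gap - length
    if hi <= lo:
        raise ValueError(f"chromosome {chrom} too short for an interstitial tract of {length} bp")
    start = int(rng.integers(lo, hi))
    return (chrom, start, start + length, "interstitial")


def _validate_spec(config: SimulationConfig, spec: StrainSpec) -> None:
    layout = config.layout
    if spec.ploidy not in VALID_PLOIDIES:
        raise ValueError(f"ploidy must be one of {VALID_PLOIDIES}, got {spec.ploidy}")
    for chrom, _ in spec.aneuploidies:
        if chrom not in layout:
            raise ValueError(f"aneuploidy on unknown chromosome {chrom!r}")
    for chrom, start, end, kind in spec.loh_tracts:
        if chrom not in layout:
            raise ValueError(f"LOH tract on unknown chromosome {chrom!r}")
        if kind not in LOH_KINDS:
            raise ValueError(f"unknown LOH kind {kind!r}")
        if not (0 <= start < end <= layout[chrom].length):
            raise ValueError(f"LOH tract {chrom}:{start}-{end} outside chromosome")
    for chrom, start, end, _ in spec.cnvs:
        if chrom not in layout or not (0 <= start < end <= layout[chrom].length):
            raise ValueError(f"CNV {chrom}:{start}-{end} outside chromosome")


def _cnv_kind(chrom_len: int, start: int, end: int, delta: int, margin: int) -> str:
    position = "terminal" if (start < margin or end > chrom_len - margin) else "interstitial"
    direction = "duplication" if delta > 0 else "deletion"
    return f"{position}_{direction}"


def _local_copy(pos: np.ndarray, base_cn: int,
                cnvs: Sequence[tuple[int, int, int]]) -> np.ndarray:
    cn = np.full(pos.shape, base_cn, dtype=int)
    for start, end, delta in cnvs:
        cn[(pos >= start) & (pos < end)] += delta
    return np.maximum(cn, 0)


# ---------------------------------------------------------------------------
# main simulator

def simulate_strain(
    config: SimulationConfig,
    spec: StrainSpec,
    seed: int | np.random.Generator = 0,
) -> SimulatedStrain:
    """Simulate one strain: variant sites, window coverage, contigs, truth.

    Bit-reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _validate_spec(config, spec)
    layout = config.layout
    ploidy = spec.ploidy

    aneuploidy = {}
    for chrom, delta in spec.aneuploidies:
        aneuploidy[chrom] = aneuploidy.get(chrom, 0) + delta
    chrom_copies = {c.name: ploidy + aneuploidy.get(c.name, 0) for c in layout}
    if any(cn < 1 for cn in chrom_copies.values()):
        raise ValueError("aneuploidy would reduce a chromosome below one copy")

    tracts_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, kind in spec.loh_tracts:
        tracts_by_chrom.setdefault(chrom, []).append((start, end, kind))
    cnvs_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, delta in spec.cnvs:
        cnvs_by_chrom.setdefault(chrom, []).append((start, end, delta))

    rows: list[tuple] = []
    het_truth: list[tuple[str, int, int, int]] = []
    for chrom_rec in layout:
        chrom = chrom_rec.name
        base_cn = chrom_copies[chrom]
        n_sites = max(1, int(round(chrom_rec.length * config.het_density)))
        pos0 = np.sort(rng.choice(chrom_rec.length, size=n_sites, replace=False))
        # guarantee every planted tract overlaps at least one site
        for start, end, _ in tracts_by_chrom.get(chrom, []):
            if not np.any((pos0 >= start) & (pos0 < end)):
                pos0 = np.sort(np.append(pos0, (start + end) // 2))
        cn = _local_copy(pos0, base_cn, cnvs_by_chrom.get(chrom, ()))
        keep = cn > 0  # homozygously deleted regions yield no observable sites
        pos0, cn = pos0[keep], cn[keep]
        n = len(pos0)

        in_tract = np.zeros(n, dtype=bool)
        for start, end, _ in tracts_by_chrom.get(chrom, []):
            in_tract |= (pos0 >= start) & (pos0 < end)

        hom = in_tract | (cn < 2)
        alt_copies = np.zeros(n, dtype=int)
        het = ~hom
        if het.any():
            alt_copies[het] = rng.integers(1, cn[het])
        p_het = np.zeros(n)
        if het.any():
            p_het[het] = alt_copies[het] / cn[het]
        hom_p = np.where(rng.random(n) < 0.5, config.hom_support, 1 - config.hom_support)
        p = np.where(hom, hom_p, p_het)
        depth = rng.poisson(config.mean_depth * cn / ploidy)
        depth = np.maximum(depth, 1)
        alt_depth = rng.binomial(depth, p)
        ref_depth = depth - alt_depth
        ref_allele, alt_allele = _random_alleles(n, rng)
        pos1 = pos0 + 1  # variant tables are 1-based
        for i in range(n):
            rows.append((chrom, int(pos1[i]), ref_allele[i], alt_allele[i],
                         int(ref_depth[i]), int(alt_depth[i]), None))
            if het[i]:
                het_truth.append((chrom, int(pos1[i]), int(alt_copies[i]), int(cn[i])))

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)

    coverage = _simulate_coverage(config, chrom_copies, cnvs_by_chrom, ploidy, rng)

    # contigs and query ORFs
    contigs: list[tuple[str, str]] = []
    orfs: list[tuple[str, str]] = []
    hgt_truth: list[dict] = []
    ref_orfs = synthesize_orfs(rng, n=max(20, spec.n_native_orfs + spec.n_hgt_genes + 5))
    for ref_id, seq in ref_orfs[: spec.n_native_orfs]:
        orfs.append((f"{spec.name}_{ref_id}", seq))
    if spec.n_hgt_genes > 0:
        contig_id, contig_seq, genes = plant_hgt_contig(
            ref_orfs[spec.n_native_orfs:],
            identity=spec.hgt_identity,
            n_genes=spec.n_hgt_genes,
            telomeric_end=spec.hgt_telomeric,
            rng=rng,
            motif=layout.telomere_motif,
            contig_id=f"{spec.name}_NODE_1",
        )
        contigs.append((contig_id, contig_seq))
        for gene in genes:
            orfs.append((gene["query_id"], gene["sequence"]))
            hgt_truth.append({k: v for k, v in gene.items() if k != "sequence"})

    indel_truth: list[tuple[str, int, str]] = []
    if spec.n_indels > 0:
        reference = synthesize_reference(layout, np.random.default_rng(rng.integers(2**31)))
        indel_rows, indel_truth = plant_indels(
            reference, spec.n_indels, config.indel_repeat_fraction, rng,
            mean_depth=config.mean_depth, hom_support=config.hom_support)
        variants = pd.concat([variants, indel_rows], ignore_index=True)

    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].map({n: i for i, n in enumerate(layout.names)}).to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)

    margin = 2 * config.window
    truth = StrainTruth(
        strain=spec.name,
        ploidy=ploidy,
        chromosome_copies=chrom_copies,
        loh_tracts=list(spec.loh_tracts),
        cnv_segments=[(c, s, e, d, _cnv_kind(layout[c].length, s, e, d, margin))
                      for c, s, e, d in spec.cnvs],
        hgt_genes=hgt_truth,
        het_sites=het_truth,
        indel_contexts=indel_truth,
    )
    return SimulatedStrain(variants=variants, coverage=coverage,
                           contigs=contigs, orfs=orfs, truth=truth)


def _simulate_coverage(
    config: SimulationConfig,
    chrom_copies: dict[str, int],
    cnvs_by_chrom: dict[str, list[tuple[int, int, int]]],
    ploidy: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for chrom_rec in config.layout:
        chrom = chrom_rec.name
        starts = np.arange(0, chrom_rec.length, config.window)
        ends = np.minimum(starts + config.window, chrom_rec.length)
        mids = (starts + ends) // 2
        cn = _local_copy(mids, chrom_copies[chrom], cnvs_by_chrom.get(chrom, ()))
        widths = ends - starts
        expected_reads = config.mean_depth * cn / ploidy * widths / config.read_length
        reads = rng.poisson(expected_reads)
        depth = reads * config.read_length / widths
        for i in range(len(starts)):
            rows.append((chrom, int(starts[i]), int(ends[i]), float(depth[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    median = float(np.median(df["depth"]))
    return df.assign(norm_ratio=df["depth"] / median)


# ---------------------------------------------------------------------------
# sequence-level generators

def synthesize_reference(layout: GenomeLayout, rng: np.random.Generator) -> dict[str, str]:
    """Random reference sequence for every chromosome in the layout."""
    return {c.name: "".join(rng.choice(_BASES, size=c.length)) for c in layout}


def synthesize_orfs(
    rng: np.random.Generator,
    n: int = 60,
    min_len: int = 300,
    max_len: int = 1500,
) -> list[tuple[str, str]]:
    """Random reference ORF set; lengths are multiples of 3, ATG-initiated."""
    orfs = []
    for i in range(n):
        length = int(rng.integers(min_len // 3, max_len // 3 + 1)) * 3
        seq = "ATG" + "".join(rng.choice(_BASES, size=length - 3))
        orfs.append((f"ORF{i + 1:04d}", seq))
    return orfs


def plant_hgt_contig(
    ref_orfs: Sequence[tuple[str, str]],
    identity: float,
    n_genes: int,
    telomeric_end: bool,
    rng: np.random.Generator,
    motif: str = TELOMERE_MOTIF,
    contig_id: str = "NODE_1",
    n_motif_copies: int = 10,
) -> tuple[str, str, list[dict]]:
    """Build a contig carrying mutated copies of reference ORFs.

    Each gene receives ``round((1 - identity) * length)`` substitutions at
    uniformly chosen distinct positions (no indels), so the realized
    substitution identity matches the request exactly within rounding
    (well inside +-1 percentage point).  With ``telomeric_end`` the contig
    carries >= 8 tandem telomere-motif copies at its right end.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    if n_genes > len(ref_orfs):
        raise ValueError(f"requested {n_genes} genes but only {len(ref_orfs)} reference ORFs")
    chosen = [ref_orfs[i] for i in rng.choice(len(ref_orfs), size=n_genes, replace=False)]
    parts: list[str] = ["".join(rng.choice(_BASES, size=int(rng.integers(200, 400))))]
    genes: list[dict] = []
    offset = len(parts[0])
    for ref_id, ref_seq in chosen:
        n_sub = int(round((1.0 - identity) * len(ref_seq)))
        if identity < 1.0 and n_sub < 1:
            raise ValueError(f"identity {identity} leaves no substitutable site in {ref_id} "
                             f"({len(ref_seq)} bp)")
        seq = np.array(list(ref_seq))
        if n_sub:
            sub_pos = rng.choice(len(seq), size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub)
            idx = np.searchsorted(_BASES, seq[sub_pos])
            seq[sub_pos] = _BASES[(idx + shift) % 4]
        mutated = "".join(seq)
        realized = (len(ref_seq) - n_sub) / len(ref_seq)
        genes.append({
            "query_id": f"{contig_id}_{ref_id}",
            "ref_id": ref_id,
            "identity": realized,
            "start": offset,
            "end": offset + len(mutated),
            "sequence": mutated,
        })
        parts.append(mutated)
        spacer = "".join(rng.choice(_BASES, size=int(rng.integers(150, 300))))
        parts.append(spacer)
        offset += len(mutated) + len(spacer)
    if telomeric_end:
        parts.append(motif * n_motif_copies)
    return contig_id, "".join(parts), genes


# -- InDel planting ---------------------------------------------------------

_MONO_RE = re.compile(r"A{4,}|C{4,}|G{4,}|T{4,}")
_DI_RE = re.compile(r"(AC|AG|AT|CA|CG|CT|GA|GC|GT|TA|TC|TG)\1{2,}")
_TANDEM_RE = re.compile(r"([ACGT]{2,6})\1{2,}")  # any 2-6 bp motif, >= 3 units


def _has_repeat_context(window: str) -> bool:
    return bool(_MONO_RE.search(window) or _TANDEM_RE.search(window))


def plant_indels(
    reference: dict[str, str],
    n: int,
    repeat_fraction: float,
    rng: np.random.Generator,
    mean_depth: float = 80.0,
    hom_support: float = 0.995,
) -> tuple[pd.DataFrame, list[tuple[str, int, str]]]:
    """Plant homozygous InDels; ``round(repeat_fraction * n)`` of them fall
    in replication-slippage contexts (mononucleotide runs >= 4 bp or
    dinucleotide microsatellites >= 3 units), the rest in repeat-free
    context.  Returns variant rows plus (chrom, pos, context) truth."""
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ValueError("repeat_fraction must be in [0, 1]")
    n_repeat = int(round(repeat_fraction * n))

    mono_loci: list[tuple[str, int, int]] = []
    micro_loci: list[tuple[str, int, int]] = []
    for chrom, seq in reference.items():
        for m in _MONO_RE.finditer(seq):
            if m.start() > 0:
                mono_loci.append((chrom, m.start(), m.end()))
        for m in _DI_RE.finditer(seq):
            if m.start() > 0:
                micro_loci.append((chrom, m.start(), m.end()))
    if n_repeat and not (mono_loci or micro_loci):
        raise ValueError("reference contains no repeat loci; use a larger genome")

    rows: list[tuple] = []
    truth: list[tuple[str, int, str]] = []
    used: set[tuple[str, int]] = set()

    loci = mono_loci + micro_loci
    order = rng.permutation(len(loci))
    taken = 0
    for idx in order:
        if taken >= n_repeat:
            break
        chrom, start, end = loci[idx]
        is_mono = idx < len(mono_loci)
        anchor = start - 1
        if (chrom, anchor + 1) in used:
            continue
        seq = reference[chrom]
        if is_mono:
            base = seq[start]
            if rng.random() < 0.5:  # 1-bp deletion of one run base
                ref_allele, alt_allele = seq[anchor] + base, seq[anchor]
            else:  # 1-bp insertion extending the run
                ref_allele, alt_allele = seq[anchor], seq[anchor] + base
            context = "mononucleotide_repeat"
        else:
            unit = seq[start:start + 2]
            if rng.random() < 0.5:  # delete one unit
                ref_allele, alt_allele = seq[anchor] + unit, seq[anchor]
            else:  # insert one unit
                ref_allele, alt_allele = seq[anchor], seq[anchor] + unit
            context = "microsatellite"
        rows.append((chrom, anchor + 1, ref_allele, alt_allele))
        truth.append((chrom, anchor + 1, context))
        used.add((chrom, anchor + 1))
        taken += 1
    if taken < n_repeat:
        raise ValueError("reference contains too few repeat loci; use a larger genome")

    chroms = list(reference)
    attempts = 0
    while len(rows) < n and attempts < 100 * n:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = reference[chrom]
        pos0 = int(rng.integers(11, len(seq) - 12))
        if (chrom, pos0 + 1) in used:
            continue
        window = seq[pos0 - 10: pos0 + 11]
        if _has_repeat_context(window):
            continue
        anchor_base = seq[pos0]
        if rng.random() < 0.5:  # 1-bp deletion
            ref_allele, alt_allele = anchor_base + seq[pos0 + 1], anchor_base
        else:  # 1-bp insertion of a base differing from both neighbours
            options = [b for b in "ACGT" if b != anchor_base and b != seq[pos0 + 1]]
            ref_allele, alt_allele = anchor_base, anchor_base + options[int(rng.integers(len(options)))]
        rows.append((chrom, pos0 + 1, ref_allele, alt_allele))
        truth.append((chrom, pos0 + 1, "non_repeat"))
        used.add((chrom, pos0 + 1))
    if len(rows) < n:
        raise ValueError("could not place the requested number of repeat-free InDels")

    depth = np.maximum(rng.poisson(mean_depth, size=len(rows)), 1)
    alt_depth = rng.binomial(depth, hom_support)
    df = pd.DataFrame(
        [(c, p, r, a, int(depth[i] - alt_depth[i]), int(alt_depth[i]), None)
         for i, (c, p, r, a) in enumerate(rows)],
        columns=VARIANT_COLUMNS,
    )
    return df, truth


# ---------------------------------------------------------------------------
# cohort helper

def random_strain_spec(
    layout: GenomeLayout,
    rng: np.random.Generator,
    name: str = "sim",
    ploidy: int | None = None,
    n_aneuploidies: int = 0,
    n_loh_tracts: int = 0,
    n_cnvs: int = 0,
    **kwargs,
) -> StrainSpec:
    """Draw a random event plan: aneuploidies on distinct chromosomes,
    LOH tracts of random class on distinct chromosomes, window-aligned
    segmental CNVs on otherwise untouched chromosomes."""
    names = layout.names
    if ploidy is None:
        ploidy = int(rng.choice(VALID_PLOIDIES))
    chosen = rng.choice(len(names), size=min(n_aneuploidies + n_loh_tracts + n_cnvs, len(names)),
                        replace=False)
    pool = [names[i] for i in chosen]
    aneuploidies = []
    for _ in range(n_aneuploidies):
        chrom = pool.pop()
        delta = int(rng.choice([-1, 1])) if ploidy > 2 else int(rng.choice([-1, 1, 1]))
        aneuploidies.append((chrom, delta))
    tracts = []
    for _ in range(n_loh_tracts):
        chrom = pool.pop()
        kind = str(rng.choice(LOH_KINDS))
        length = int(rng.integers(4000, max(6000, layout[chrom].length // 3)))
        tracts.append(make_loh_tract(layout, chrom, kind, length, rng))
    cnvs = []
    for _ in range(n_cnvs):
        chrom = pool.pop()
        chrom_len = layout[chrom].length
        n_windows = int(rng.integers(5, 13))
        span = n_windows * 1000
        if rng.random() < 0.5:  # terminal
            start = 0 if rng.random() < 0.5 else chrom_len - span
        else:
            start = int(rng.integers(5, max(6, chrom_len // 1000 - n_windows - 5))) * 1000
        delta = int(rng.choice([-1, 1]))
        cnvs.append((chrom, max(0, start), min(chrom_len, max(0, start) + span), delta))
    return StrainSpec(name=name, ploidy=ploidy, aneuploidies=tuple(aneuploidies),
                      loh_tracts=tuple(tracts), cnvs=tuple(cnvs), **kwargs)


# ---------------------------------------------------------------------------
# phenotype / fermentation simulators

def simulate_phenotype_matrix(
    rng: np.random.Generator,
    n_strains: int = 41,
    blocks: Sequence[int] = (12, 12),
    within_r: float = 0.9,
    baseline: float = 0.6,
    scale: float = 0.15,
) -> tuple[pd.DataFrame, list[int]]:
    """Strains x conditions relative-biomass matrix with planted condition
    blocks: conditions within a block share a latent factor at correlation
    ``within_r``; across blocks correlation is ~0.

    Returns the matrix (control column first, all 1.0) and the true block
    label per non-control condition.
    """
    strains = [f"S{i + 1:02d}" for i in range(n_strains)]
    cols: dict[str, np.ndarray] = {"control": np.ones(n_strains)}
    labels: list[int] = []
    cond = 0
    for b, size in enumerate(blocks):
        factor = rng.standard_normal(n_strains)
        for _ in range(size):
            noise = rng.standard_normal(n_strains)
            z = np.sqrt(within_r) * factor + np.sqrt(1 - within_r) * noise
            cols[f"cond{cond + 1:02d}"] = np.clip(baseline + scale * z, 0.01, None)
            labels.append(b)
            cond += 1
    return pd.DataFrame(cols, index=strains), labels


def simulate_fermentation_series(
    rng: np.random.Generator,
    strain: str = "sim",
    duration: float = 96.0,
    step: float = 8.0,
    final_ethanol: float = 100.0,
    midpoint_hours: float = 24.0,
    rate: float = 0.15,
    sugars: float = 245.0,
) -> pd.DataFrame:
    """Logistic CO2-loss and ethanol accumulation curve sampled every 8 h,
    mimicking a 96-h starchy-substrate fermentation."""
    times = np.arange(0.0, duration + step / 2, step)
    progress = 1.0 / (1.0 + np.exp(-rate * (times - midpoint_hours)))
    progress = (progress - progress[0]) / (1.0 - progress[0])
    co2 = 10.0 * progress
    ethanol = final_ethanol * progress
    return pd.DataFrame({"strain": strain, "time_h": times,
                         "co2_loss": co2, "ethanol": ethanol,
                         "sugars_supplied": sugars})
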