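"""Readers and writers for the external formats the pipeline touches.

Variant tables come either as a headerless/``#``-commented TSV
(``chrom pos ref alt ref_depth alt_depth [annotation]``, 1-based positions)
or as a VCF subset (``CHROM POS REF ALT`` plus per-allele ``AD`` depths,
read through :mod:`pysam`).  Coverage tables are BED-like TSVs
(``chrom start end depth``, 0-based half-open).  Segment collections are
written as BED with the segment class in column 4.

Every filter logs how many records it dropped; conversions between the
1-based variant convention and internal/BED 0-based half-open coordinates
happen here and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (
    COVERAGE_COLUMNS,
    VARIANT_COLUMNS,
    Chromosome,
    CnvSegment,
    GenomeLayout,
    LohSegment,
    VariantSite,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "write_variant_vcf",
    "read_coverage_table",
    "write_coverage_table",
    "write_segments_bed",
    "read_loh_segments_bed",
    "read_cnv_segments_bed",
    "read_layout_tsv",
    "write_layout_tsv",
    "read_config",
    "sort_variants",
    "sort_windows",
]

# ---------------------------------------------------------------------------
# configuration

#: Default values for every tunable threshold, overridable from a flat
#: ``key = value`` config file (see :func:`read_config`).
CONFIG_DEFAULTS: dict[str, float | int | str] = {
    "min_depth": 10,
    "het_band_low": 0.10,
    "het_band_high": 0.90,
    "hom_threshold": 0.90,
    "min_het_sites": 200,
    "loh_min_sites": 10,
    "loh_het_interrupt_rate": 0.02,  # one heterozygous interruption per 50 sites
    "loh_terminal_margin_sites": 3,
    "loh_terminal_arm_fraction": 0.20,
    "loh_permutations": 1000,
    "cnv_support_fraction": 0.8,
    "cnv_min_windows": 3,
    "cnv_ratio_margin": 0.3,
    "hgt_identity_threshold": 85.0,
    "hgt_kmer_size": 15,
    "hgt_min_shared_kmers": 5,
    "telomere_min_copies": 8,
    "telomere_window": 500,
    "mu_snv_per_division": 0.005,
    "generation_hours": 2.0,
}


def read_config(path: str | Path) -> dict[str, float | int | str]:
    """Read a flat ``key = value`` text config, merged over the defaults.

    Lines starting with ``#`` and blank lines are ignored; values are
    coerced to int/float where possible.
    """
    values = dict(CONFIG_DEFAULTS)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        values[key] = value
    return values


# ---------------------------------------------------------------------------
# sorting helpers

def _chrom_sort_key(chroms: pd.Series, layout: GenomeLayout | None) -> pd.Series:
    if layout is None:
        return chroms
    order = {name: i for i, name in enumerate(layout.names)}
    unknown = set(chroms.unique()) - set(order)
    if unknown:
        raise ValueError(f"chromosomes not in layout: {sorted(unknown)}")
    return chroms.map(order)


def sort_variants(sites: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Sort a variant table by (chromosome, position); idempotent."""
    key = _chrom_sort_key(sites["chrom"], layout)
    order = np.lexsort((sites["pos"].to_numpy(), key.to_numpy()))
    return sites.iloc[order].reset_index(drop=True)


def sort_windows(windows: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Sort a coverage table by (chromosome, start); idempotent."""
    key = _chrom_sort_key(windows["chrom"], layout)
    order = np.lexsort((windows["start"].to_numpy(), key.to_numpy()))
    return windows.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# variant tables

def _finalize_variants(df: pd.DataFrame, layout: GenomeLayout | None, source: str) -> pd.DataFrame:
    if layout is not None:
        unknown = set(df["chrom"].unique()) - set(layout.names)
        if unknown:
            raise ValueError(f"{source}: chromosomes not in layout: {sorted(unknown)}")
    zero = (df["ref_depth"] + df["alt_depth"]) <= 0
    if zero.any():
        logger.info("%s: dropped %d sites with zero total depth", source, int(zero.sum()))
        df = df[~zero]
    return sort_variants(df.reset_index(drop=True), layout)


def _read_variant_tsv(path: Path, layout: GenomeLayout | None) -> pd.DataFrame:
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (6, 7):
            raise ValueError(f"{path}:{lineno}: expected 6 or 7 tab-separated fields, got {len(fields)}")
        try:
            site = VariantSite(
                chrom=fields[0],
                pos=int(fields[1]),
                ref=fields[2].upper(),
                alt=fields[3].upper(),
                ref_depth=int(fields[4]),
                alt_depth=int(fields[5]),
                annotation=(fields[6] or None) if len(fields) == 7 else None,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed variant row: {exc}") from exc
        rows.append((site.chrom, site.pos, site.ref, site.alt,
                     site.ref_depth, site.alt_depth, site.annotation))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _read_variant_vcf(path: Path, layout: GenomeLayout | None) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), None)
        for rec in vcf:
            if rec.alts is None:
                continue
            if sample is not None:
                ad = rec.samples[sample].get("AD")
            else:
                ad = rec.info.get("AD")
            if ad is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD per-allele depths")
            # split multiallelic rows: one biallelic record per alternate allele
            for i, alt in enumerate(rec.alts):
                rows.append((rec.chrom, rec.pos, rec.ref.upper(), alt.upper(),
                             int(ad[0]), int(ad[i + 1]), None))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Read a per-site variant table into a sorted biallelic DataFrame.

    Parameters
    ----------
    dialect:
        ``"tsv"`` for the plain table or ``"vcf"`` for the VCF subset
        (requires per-allele AD depths).  Multiallelic VCF rows are split
        into one biallelic record per alternate allele.

    Sites with zero total depth are dropped (count logged).
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_variant_tsv(path, layout)
    elif dialect == "vcf":
        df = _read_variant_vcf(path, layout)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")
    return _finalize_variants(df, layout, str(path))


def write_variant_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as the 7-column TSV (header as a ``#`` comment)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(VARIANT_COLUMNS) + "\n")
        for row in sites.itertuples(index=False):
            ann = row.annotation if isinstance(row.annotation, str) else ""
            fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t"
                     f"{row.ref_depth}\t{row.alt_depth}\t{ann}\n")


def write_variant_vcf(sites: pd.DataFrame, path: str | Path,
                      layout: GenomeLayout, sample: str = "strain") -> None:
    """Write sites as a minimal single-sample VCF with FORMAT/AD depths."""
    header = pysam.VariantHeader()
    for chrom in layout:
        header.contigs.add(chrom.name, length=chrom.length)
    header.formats.add("AD", "R", "Integer", "Per-allele read depths")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sort_variants(sites, layout).itertuples(index=False):
            rec = vcf.new_record(contig=row.chrom, start=row.pos - 1,
                                 alleles=(row.ref, row.alt))
            rec.samples[sample]["AD"] = (int(row.ref_depth), int(row.alt_depth))
            vcf.write(rec)


# ---------------------------------------------------------------------------
# coverage tables

def read_coverage_table(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a BED-like coverage TSV and fill ``norm_ratio`` as
    depth / genome-wide median depth.

    Raises on overlapping windows within one chromosome.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 fields (chrom start end depth)")
        try:
            chrom, start, end, depth = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coverage row: {exc}") from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: window end {end} <= start {start}")
        if depth < 0:
            raise ValueError(f"{path}:{lineno}: negative depth")
        rows.append((chrom, start, end, depth))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    df = sort_windows(df.assign(norm_ratio=np.nan), layout)
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping windows on {chrom}")
    return normalize_coverage(df)


def normalize_coverage(windows: pd.DataFrame) -> pd.DataFrame:
    """Recompute ``norm_ratio`` = depth / genome-wide median depth."""
    median = float(np.median(windows["depth"])) if len(windows) else float("nan")
    if median == 0:
        raise ValueError("genome-wide median depth is zero; cannot normalize")
    return windows.assign(norm_ratio=windows["depth"] / median)


def write_coverage_table(windows: pd.DataFrame, path: str | Path) -> None:
    """Write windows as BED-like TSV (chrom, start, end, depth)."""
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tdepth\n")
        for row in windows.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.depth:.6g}\n")


# ---------------------------------------------------------------------------
# segment BED

def write_segments_bed(segments: Sequence[LohSegment | CnvSegment], path: str | Path) -> None:
    """Write LOH or CNV segments as BED, class label in column 4.

    Extra columns keep the remaining fields so the matching reader
    round-trips losslessly.
    """
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tclass\tscore\textra\n")
        for seg in segments:
            kind = seg.kind if seg.kind is not None else "."
            if isinstance(seg, LohSegment):
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{kind}\t"
                         f"{seg.n_sites}\t{seg.mean_support:.6f}\n")
            else:
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{kind}\t"
                         f"{seg.copy_number}\t{seg.n_windows}\n")


def _read_bed_rows(path: str | Path) -> list[list[str]]:
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 BED fields")
        rows.append(fields)
    return rows


def read_loh_segments_bed(path: str | Path) -> list[LohSegment]:
    return [
        LohSegment(chrom=f[0], start=int(f[1]), end=int(f[2]),
                   kind=None if f[3] == "." else f[3],
                   n_sites=int(f[4]), mean_support=float(f[5]))
        for f in _read_bed_rows(path)
    ]


def read_cnv_segments_bed(path: str | Path) -> list[CnvSegment]:
    return [
        CnvSegment(chrom=f[0], start=int(f[1]), end=int(f[2]),
                   kind=None if f[3] == "." else f[3],
                   copy_number=int(f[4]), n_windows=int(f[5]))
        for f in _read_bed_rows(path)
    ]


def read_repeat_bed(path: str | Path) -> pd.DataFrame:
    """Read a repeat/feature annotation BED (class in column 4:
    LTR | Ty | mating_locus | other)."""
    rows = [(f[0], int(f[1]), int(f[2]), f[3]) for f in _read_bed_rows(path)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"])


# ---------------------------------------------------------------------------
# genome layout

def read_layout_tsv(path: str | Path) -> GenomeLayout:
    """Read a genome layout TSV (chrom, length, centromere); the telomere
    motif may be given on a ``#telomere_motif=`` comment line."""
    motif = None
    chroms = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#telomere_motif="):
                motif = line.split("=", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected chrom/length/centromere")
        chroms.append(Chromosome(fields[0], int(fields[1]), int(fields[2])))
    layout = GenomeLayout(chroms)
    if motif:
        layout.telomere_motif = motif
    return layout


def write_layout_tsv(layout: GenomeLayout, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"#telomere_motif={layout.telomere_motif}\n")
        fh.write("#chrom\tlength\tcentromere\n")
        for chrom in layout:
            fh.write(f"{chrom.name}\t{chrom.length}\t{chrom.centromere}\n")
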