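"""Readers and writers for BED, FASTA, phased VCF and the pipeline's TSV tables.

BED is handled by a small dedicated layer so that malformed input fails with
the offending line number and inverted coordinates are rejected at the
boundary. VCF goes through pysam; FASTA through pyfaidx; tables through
pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .intervals import GenomicInterval, GenomeLayout

logger = logging.getLogger(__name__)


class BedParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name[, score]]).

    Raises :class:`BedParseError` naming the line number on malformed lines;
    intervals with end <= start are rejected.
    """
    chroms, starts, ends, names, scores = [], [], [], [], []
    max_extra = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval "
                    f"[{start}, {end})"
                )
            if not fields[0]:
                raise BedParseError(f"{path}: line {lineno}: empty chrom")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else None)
            scores.append(fields[4] if len(fields) > 4 else None)
            max_extra = max(max_extra, len(fields) - 3)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if max_extra >= 1:
        df["name"] = names
    if max_extra >= 2:
        df["score"] = scores
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    for optional in ("name", "score"):
        if optional in df.columns:
            cols.append(optional)
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path) -> Fasta:
    """Open a FASTA with a position index (built on first access)."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def layout_from_fasta(path) -> GenomeLayout:
    fasta = open_fasta(path)
    return GenomeLayout({name: len(fasta[name]) for name in fasta.keys()})


# ---------------------------------------------------------------------------
# Phased VCF -> haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased biallelic allele matrix: one row per haplotype, one column per
    variant, entries in {0, 1}. Positions are 1-based (VCF convention) and
    strictly increasing along one chromosome."""

    chrom: str
    positions: np.ndarray  # int64, 1-based, strictly increasing
    alleles: np.ndarray  # (n_haplotypes, n_variants) int8 in {0,1}
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.n_variants:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if not np.isin(self.alleles, (0, 1)).all():
                raise ValueError("alleles must be 0/1")
        if self.alleles.shape[0] < 2:
            raise ValueError("panel needs >=2 haplotypes")
        if not self.ids:
            self.ids = [f"var{i}" for i in range(self.n_variants)]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.positions)


class EmptyPanelError(ValueError):
    """No qualifying phased biallelic SNPs in the requested region."""


def read_phased_vcf(
    path,
    region: GenomicInterval | None = None,
    keep_filters: tuple[str, ...] = ("PASS", "."),
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a haplotype panel.

    Multiallelic, unphased, missing-genotype, non-SNP and filtered records are
    dropped (counts logged). Each sample contributes two haplotype rows.
    ``region`` is 0-based half-open and converted to VCF positions here.
    ``keep_filters`` is the FILTER policy; the default keeps PASS and
    unfiltered records.
    """
    dropped = {"multiallelic": 0, "not_snp": 0, "filtered": 0, "unphased": 0}
    positions, ids, columns = [], [], []
    n_samples = None
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if region is not None:
                if rec.chrom != region.chrom:
                    continue
                pos0 = rec.pos - 1
                if not (region.start <= pos0 < region.end):
                    continue
            if len(rec.alts or ()) != 1:
                dropped["multiallelic"] += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                dropped["not_snp"] += 1
                continue
            filters = list(rec.filter.keys()) or ["."]
            if any(f not in keep_filters for f in filters):
                dropped["filtered"] += 1
                continue
            col = []
            ok = True
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if (
                    gt is None
                    or len(gt) != 2
                    or None in gt
                    or not sample.phased
                ):
                    ok = False
                    break
                col.extend(gt)
            if not ok:
                dropped["unphased"] += 1
                continue
            if n_samples is None:
                n_samples = len(rec.samples)
            positions.append(rec.pos)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            columns.append(col)
            chrom = rec.chrom
    total_dropped = sum(dropped.values())
    if total_dropped:
        logger.info("read_phased_vcf: dropped records %s", dropped)
    if not positions:
        raise EmptyPanelError(
            f"no phased biallelic SNPs in {path}"
            + (f" within {region}" if region else "")
        )
    alleles = np.array(columns, dtype=np.int8).T  # haplotypes x variants
    return HaplotypePanel(chrom=chrom, positions=np.array(positions), alleles=alleles, ids=ids)


def write_phased_vcf(panel: HaplotypePanel, path, contig_length: int | None = None) -> None:
    """Write a haplotype panel as a minimal phased VCFv4.2 text file."""
    n_samples = panel.n_haplotypes // 2
    if panel.n_haplotypes % 2:
        raise ValueError("haplotype count must be even to form diploid samples")
    samples = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = contig_length or int(panel.positions[-1]) + 1
        fh.write(f"##contig=<ID={panel.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(panel.n_variants):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phased_vcf_multi(
    panels: dict[str, HaplotypePanel], path, contig_lengths: dict[str, int] | None = None
) -> None:
    """Write several per-chromosome panels into one phased VCF."""
    panels = dict(panels)
    n_hap = {p.n_haplotypes for p in panels.values()}
    if len(n_hap) != 1:
        raise ValueError("all panels must share the haplotype count")
    n_samples = n_hap.pop() // 2
    samples = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, panel in panels.items():
            length = (contig_lengths or {}).get(chrom, int(panel.positions[-1]) + 1)
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, panel in panels.items():
            for j in range(panel.n_variants):
                col = panel.alleles[:, j]
                gts = "\t".join(
                    f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
                )
                fh.write(
                    f"{chrom}\t{panel.positions[j]}\t{panel.ids[j]}"
                    f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )


def read_phased_vcf_all(path, **kwargs) -> dict[str, HaplotypePanel]:
    """Load a (possibly multi-chromosome) phased VCF, one panel per chromosome."""
    with pysam.VariantFile(str(path)) as vcf:
        chroms = list(vcf.header.contigs)
    panels = {}
    for chrom in chroms:
        try:
            panels[chrom] = read_phased_vcf(
                path,
                region=GenomicInterval(chrom, 0, 2**62),
                **kwargs,
            )
        except EmptyPanelError:
            continue
    return panels


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["chrom", "pos", "id", "p_value", "group"]


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS association: 1-based position, p-value and population group."""

    chrom: str
    pos: int
    id: str
    p_value: float
    group: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


def read_snp_table(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "group": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP table columns {sorted(missing)}")
    return [
        SnpRecord(r.chrom, int(r.pos), r.id, float(r.p_value), r.group)
        for r in df.itertuples()
    ]


def write_snp_table(snps: list[SnpRecord], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.id, s.p_value, s.group) for s in snps],
        columns=SNP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
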