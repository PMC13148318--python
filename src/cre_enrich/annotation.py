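"""Genome tiling, GC content, genomic annotation classes and sampling strata.

Each interval receives exactly one annotation class by any-overlap with a
fixed priority (promoter > utr5 > utr3 > exon > intron > intergenic) and a
GC fraction over unambiguous bases; the pair (GC bin, annotation) is the
stratum used for matched background sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, intervals_to_frame, overlaps_any

ANNOTATION_PRIORITY = ["promoter", "utr5", "utr3", "exon", "intron", "intergenic"]


@dataclass
class GeneModel:
    """One gene: strand, transcript span, exons and coding span, all 0-based
    half-open on one chromosome. UTRs are derived as the exonic sequence
    outside the coding span; the TSS is the strand-aware transcript start."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Load gene models from GFF3 (coordinates converted to 0-based half-open)."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for child in db.children(gene, featuretype="exon"):
            exons.append((child.start - 1, child.end))
        for child in db.children(gene, featuretype="CDS"):
            cds.append((child.start - 1, child.end))
        exons.sort()
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons or [(gene.start - 1, gene.end)],
                cds_start=min(c[0] for c in cds) if cds else None,
                cds_end=max(c[1] for c in cds) if cds else None,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={tid};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t."
                    f"\tID={tid}.e{k};Parent={tid}\n"
                )
                if g.cds_start is not None:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if ce > cs:
                        fh.write(
                            f"{g.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0"
                            f"\tID={tid}.c{k};Parent={tid}\n"
                        )


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_genome(layout: GenomeLayout, tile_width: int = 500) -> pd.DataFrame:
    """Consecutive non-overlapping half-open tiles covering each chromosome.

    The terminal partial tile is kept, so tiles partition the genome exactly.
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    chroms, starts, ends = [], [], []
    for chrom in layout:
        length = layout[chrom]
        s = np.arange(0, length, tile_width)
        e = np.minimum(s + tile_width, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else [],
            "end": np.concatenate(ends) if ends else [],
        }
    )


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(interval: GenomicInterval, fasta) -> float:
    """GC fraction over unambiguous bases; NaN when all bases are ambiguous."""
    seq = str(fasta[interval.chrom][interval.start : interval.end]).upper()
    if len(seq) != interval.length:
        raise IndexError(f"{interval} outside sequence bounds")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else float("nan")


def gc_content_bulk(regions: pd.DataFrame, fasta) -> np.ndarray:
    """Vectorised GC for many intervals: one cumulative-sum pass per chromosome."""
    out = np.full(len(regions), np.nan)
    for chrom, grp in regions.groupby("chrom", sort=False):
        seq = np.frombuffer(
            str(fasta[chrom][:]).upper().encode("ascii"), dtype=np.uint8
        )
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        is_acgt = is_gc | (seq == ord("A")) | (seq == ord("T"))
        cgc = np.concatenate([[0], np.cumsum(is_gc)])
        cac = np.concatenate([[0], np.cumsum(is_acgt)])
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if s.min() < 0 or e.max() > len(seq):
            raise IndexError(f"interval outside {chrom} bounds")
        gc = cgc[e] - cgc[s]
        acgt = cac[e] - cac[s]
        vals = np.full(len(grp), np.nan)
        nz = acgt > 0
        vals[nz] = gc[nz] / acgt[nz]
        out[regions.index.get_indexer(grp.index)] = vals
    return out


# ---------------------------------------------------------------------------
# Annotation classes
# ---------------------------------------------------------------------------

def feature_intervals(
    genes: list[GeneModel], promoter_up: int = 2000, promoter_down: int = 200
) -> dict[str, pd.DataFrame]:
    """Per-class feature intervals derived from gene models.

    promoter: strand-aware [TSS - up, TSS + down); utr5/utr3: exonic sequence
    outside the coding span on the 5'/3' side; intron: transcript minus exons.
    """
    feats: dict[str, list[tuple[str, int, int]]] = {
        k: [] for k in ("promoter", "utr5", "utr3", "exon", "intron")
    }
    for g in genes:
        if g.strand == "+":
            p0, p1 = g.tss - promoter_up, g.tss + promoter_down
        else:
            p0, p1 = g.tss - promoter_down + 1, g.tss + promoter_up + 1
        feats["promoter"].append((g.chrom, max(p0, 0), max(p1, 1)))
        prev_end = g.start
        for s, e in g.exons:
            feats["exon"].append((g.chrom, s, e))
            if s > prev_end:
                feats["intron"].append((g.chrom, prev_end, s))
            prev_end = e
            if g.cds_start is not None:
                left = (s, min(e, g.cds_start))
                right = (max(s, g.cds_end), e)
                for lo, hi in (left, right):
                    if hi > lo:
                        five = (hi <= g.cds_start) == (g.strand == "+")
                        feats["utr5" if five else "utr3"].append((g.chrom, lo, hi))
    return {
        k: pd.DataFrame(v, columns=["chrom", "start", "end"])
        for k, v in feats.items()
    }


def annotate_regions(
    regions,
    genes: list[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> pd.Series:
    """Annotation class per region: any-overlap with fixed priority."""
    df = intervals_to_frame(regions).reset_index(drop=True)
    feats = feature_intervals(genes, promoter_up, promoter_down)
    labels = pd.Series("intergenic", index=df.index, dtype=object)
    unassigned = np.ones(len(df), dtype=bool)
    for cls in ANNOTATION_PRIORITY[:-1]:
        fdf = feats[cls]
        if fdf.empty or not unassigned.any():
            continue
        hit = overlaps_any(df, fdf)
        take = hit & unassigned
        labels[take] = cls
        unassigned &= ~hit
    return labels


def annotate(
    interval: GenomicInterval,
    genes: list[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> str:
    return annotate_regions([interval], genes, promoter_up, promoter_down).iloc[0]


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------

EXCLUDED_STRATUM = "excluded"


def assign_stratum(gc: float, annotation: str, gc_bins: int = 10) -> str:
    """Composite stratum id '<gc bin>|<annotation>'; gc=1.0 goes to the top
    bin; undefined gc yields the excluded sentinel stratum."""
    if annotation not in ANNOTATION_PRIORITY:
        raise ValueError(f"unknown annotation class {annotation!r}")
    if gc is None or (isinstance(gc, float) and np.isnan(gc)):
        return EXCLUDED_STRATUM
    if not 0 <= gc <= 1:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    b = min(int(gc * gc_bins), gc_bins - 1)
    return f"{b}|{annotation}"


def stratify_regions(
    regions: pd.DataFrame,
    fasta,
    genes: list[GeneModel],
    gc_bins: int = 10,
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> pd.DataFrame:
    """Annotated region table: chrom, start, end, gc, annotation, stratum."""
    df = intervals_to_frame(regions).reset_index(drop=True).copy()
    df["gc"] = gc_content_bulk(df, fasta)
    df["annotation"] = annotate_regions(df, genes, promoter_up, promoter_down)
    df["stratum"] = [
        assign_stratum(g, a, gc_bins) for g, a in zip(df["gc"], df["annotation"])
    ]
    return df
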