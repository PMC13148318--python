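"""Synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis consumes, at
desk scale and with planted ground truth:

* a genome with isochore-like GC heterogeneity (per-1-kb GC drawn from a
  Beta distribution) and non-overlapping genes providing every annotation
  class;
* a phased haplotype panel with block-structured LD: each chromosome is
  partitioned into latent segments, and within a segment each haplotype
  either carries a shared founder haplotype (probability rho) or is an
  independent recombinant, giving expected within-segment r2 ~ rho^2 and
  ~0 across segment boundaries;
* a GWAS SNP table whose significant hits cluster inside designated trait
  segments;
* peak sets with a planted enrichment factor lambda inside the trait blocks;
* DAR sets in two species plus projection-score tables drawn from stated
  class-proportion mixtures.

Every generator is a pure function of (config, seed); all randomness flows
from a master seed through numbered substreams, and planted truths are
returned alongside (and written to a sidecar TSV) for test assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .intervals import GenomeLayout, GenomicInterval, merge_intervals, total_length
from .io import HaplotypePanel, SnpRecord

# substream ids: all randomness is default_rng([master_seed, STREAM_x])
STREAM_GENOME, STREAM_PANEL, STREAM_GWAS, STREAM_PEAKS, STREAM_PROJ = 1, 2, 3, 4, 5

POPULATION_GROUPS = ["EUR", "AFR", "EAS", "SAS", "AMR"]


@dataclass
class GenomeConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    gc_alpha: float = 41.0  # per-1kb GC ~ Beta(alpha, beta): mean 0.41, sd ~0.05
    gc_beta: float = 59.0
    gc_window: int = 1000
    genes_per_mb: float = 10.0
    gene_length_range: tuple[int, int] = (3000, 10000)
    exons_per_gene: tuple[int, int] = (3, 6)


@dataclass
class PanelConfig:
    n_haplotypes: int = 200
    snp_spacing: int = 1000  # mean bp between panel SNPs
    segment_mean: int = 50_000  # mean latent LD-segment length
    rho: float = 0.95  # founder-copying probability per haplotype per segment


@dataclass
class GwasConfig:
    n_hits: int = 2400
    n_significant: int = 1687
    n_trait_loci: int = 8  # latent segments holding the significant hits
    groups: list[str] = field(default_factory=lambda: list(POPULATION_GROUPS))


@dataclass
class PeakConfig:
    n_peaks: int = 2000
    width: int = 501  # fixed-width peaks, scATAC convention
    enrichment: float = 5.0  # lambda: in-block density / out-of-block density


@dataclass
class ProjectionConfig:
    # class proportions (direct, indirect, nonconserved)
    proportions: tuple[float, float, float] = (0.143, 0.411, 0.444)
    direct_min: float = 0.98
    indirect_min: float = 0.84
    n_dars: int = 2000
    dar_width: int = 500
    ectoderm_fraction: float = 0.4
    n_populations_ectoderm: int = 3
    n_populations_mesenchyme: int = 5
    # P(conserved projection lands on a target DAR), per tissue
    hit_prob: dict[str, float] = field(
        default_factory=lambda: {"ectoderm": 0.29, "mesenchyme": 0.066}
    )
    identity_prob: float = 0.8  # P(matched target DAR shares the tissue)
    n_target_dars: int = 4000


@dataclass
class SimConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    projections: ProjectionConfig = field(default_factory=ProjectionConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(
    cfg: SimConfig,
) -> tuple[GenomeLayout, dict[str, str], list[GeneModel]]:
    """Random genome with heterogeneous GC and non-overlapping gene models."""
    g = cfg.genome
    rng = np.random.default_rng([cfg.seed, STREAM_GENOME])
    layout = GenomeLayout(dict(g.chrom_lengths))
    sequences: dict[str, str] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in g.chrom_lengths.items():
        n_win = int(np.ceil(length / g.gc_window))
        gc = rng.beta(g.gc_alpha, g.gc_beta, size=n_win)
        seq = np.empty(length, dtype=np.uint8)
        for w in range(n_win):
            lo, hi = w * g.gc_window, min((w + 1) * g.gc_window, length)
            p = np.array(
                [(1 - gc[w]) / 2, gc[w] / 2, gc[w] / 2, (1 - gc[w]) / 2]
            )
            seq[lo:hi] = rng.choice(bases, size=hi - lo, p=p)
        sequences[chrom] = seq.tobytes().decode("ascii")
    genes = _place_genes(cfg, layout, rng)
    return layout, sequences, genes


def _place_genes(cfg: SimConfig, layout: GenomeLayout, rng) -> list[GeneModel]:
    g = cfg.genome
    genes: list[GeneModel] = []
    idx = 0
    for chrom in layout:
        length = layout[chrom]
        n_genes = int(round(g.genes_per_mb * length / 1e6))
        if n_genes == 0:
            continue
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while len([o for o in occupied]) < n_genes:
            attempts += 1
            if attempts > n_genes * 200:
                raise ValueError(
                    f"cannot place {n_genes} genes on {chrom}: genome too small"
                )
            glen = int(rng.integers(*g.gene_length_range))
            if glen >= length:
                raise ValueError("gene length exceeds chromosome length")
            start = int(rng.integers(0, length - glen))
            end = start + glen
            if any(start < oe and os_ < end for os_, oe in occupied):
                continue
            occupied.append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(g.exons_per_gene[0], g.exons_per_gene[1] + 1))
            # split the gene span into alternating exons/introns
            cuts = np.sort(rng.choice(np.arange(1, glen), 2 * n_ex - 2, replace=False))
            edges = np.concatenate([[0], cuts, [glen]])
            exons = [
                (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                for k in range(n_ex)
            ]
            # coding span: inside the first/last exon so both UTRs exist
            e0s, e0e = exons[0]
            els, ele = exons[-1]
            cds_start = e0s + max(1, (e0e - e0s) // 3)
            cds_end = ele - max(1, (ele - els) // 3)
            if cds_end <= cds_start:
                cds_start, cds_end = e0s, ele
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            idx += 1
    return genes


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class PanelSim:
    panels: dict[str, HaplotypePanel]
    segments: dict[str, np.ndarray]  # latent breakpoints per chrom (0-based)


def simulate_panel(cfg: SimConfig, layout: GenomeLayout) -> PanelSim:
    """Founder-copying haplotype panel with block-structured LD.

    Within each latent segment every haplotype carries the segment's founder
    haplotype with probability rho and is an independent Bernoulli(1/2)
    recombinant otherwise; segments are independent of each other, so r2
    decays to ~0 at segment boundaries.
    """
    p = cfg.panel
    rng = np.random.default_rng([cfg.seed, STREAM_PANEL])
    panels, segments = {}, {}
    for chrom in layout:
        length = layout[chrom]
        n_snp = max(2, length // p.snp_spacing)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snp, replace=False))
        bounds = [0]
        while bounds[-1] < length:
            bounds.append(bounds[-1] + int(rng.exponential(p.segment_mean)) + 1)
        bounds = np.asarray(bounds, dtype=np.int64)
        bounds[-1] = length
        seg_of = np.searchsorted(bounds, pos - 1, side="right") - 1
        X = np.empty((p.n_haplotypes, n_snp), dtype=np.int8)
        for s in range(len(bounds) - 1):
            cols = np.where(seg_of == s)[0]
            if not len(cols):
                continue
            founder = rng.integers(0, 2, p.n_haplotypes, dtype=np.int8)
            is_copy = rng.random(p.n_haplotypes) < p.rho
            noise = rng.integers(0, 2, (p.n_haplotypes, len(cols)), dtype=np.int8)
            X[:, cols] = np.where(is_copy[:, None], founder[:, None], noise)
        ids = [f"{chrom}:{q}" for q in pos]
        panels[chrom] = HaplotypePanel(chrom=chrom, positions=pos, alleles=X, ids=ids)
        segments[chrom] = bounds
    return PanelSim(panels=panels, segments=segments)


# ---------------------------------------------------------------------------
# GWAS table
# ---------------------------------------------------------------------------

@dataclass
class GwasSim:
    snps: list[SnpRecord]
    trait_blocks: pd.DataFrame  # latent segments holding the significant hits


def simulate_gwas(cfg: SimConfig, panel_sim: PanelSim) -> GwasSim:
    """GWAS hits at panel positions; significant hits cluster in trait loci.

    Exactly n_significant records get p < 5e-8 (drawn log-uniform below the
    threshold) and the rest get p >= 5e-8; groups rotate round-robin over the
    configured populations.
    """
    gw = cfg.gwas
    rng = np.random.default_rng([cfg.seed, STREAM_GWAS])
    if gw.n_significant > gw.n_hits:
        raise ValueError("n_significant cannot exceed n_hits")
    # trait loci: the largest latent segments, spread over chromosomes
    candidates = []
    for chrom, bounds in panel_sim.segments.items():
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s >= 20_000:
                candidates.append((chrom, int(s), int(e)))
    if len(candidates) < gw.n_trait_loci:
        raise ValueError("not enough latent segments for the trait loci")
    pick = rng.choice(len(candidates), size=gw.n_trait_loci, replace=False)
    trait = pd.DataFrame(
        [candidates[i] for i in sorted(pick)], columns=["chrom", "start", "end"]
    )

    # GWAS positions need not coincide with panel variants (hence proxies):
    # significant hits fall uniformly inside trait loci, the rest anywhere
    sizes = (trait["end"] - trait["start"]).to_numpy()
    if sizes.sum() < gw.n_significant:
        raise ValueError("trait loci too small for the significant hits")
    cum = np.concatenate([[0], np.cumsum(sizes)])
    offsets = rng.choice(cum[-1], size=gw.n_significant, replace=False)
    which = np.searchsorted(cum, offsets, side="right") - 1
    sig_sites = [
        (trait["chrom"].iat[w], int(trait["start"].iat[w] + offsets[i] - cum[w]) + 1)
        for i, w in enumerate(which)
    ]

    chroms = list(panel_sim.panels)
    ns_sites = []
    for _ in range(gw.n_hits - gw.n_significant):
        chrom = chroms[int(rng.integers(len(chroms)))]
        panel = panel_sim.panels[chrom]
        ns_sites.append((chrom, int(rng.integers(1, panel.positions[-1] + 1))))

    thr = 5e-8
    snps = []
    for k, (chrom, pos) in enumerate(sig_sites):
        p = thr * 10 ** float(-rng.uniform(0.05, 12.0))
        snps.append(SnpRecord(chrom, pos, f"rs_sig{k}", p, gw.groups[k % len(gw.groups)]))
    for k, (chrom, pos) in enumerate(ns_sites):
        p = float(rng.uniform(thr * 1.001, 1.0))
        snps.append(SnpRecord(chrom, pos, f"rs_ns{k}", p, gw.groups[k % len(gw.groups)]))
    order = rng.permutation(len(snps))
    return GwasSim(snps=[snps[i] for i in order], trait_blocks=trait)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    cfg: SimConfig, layout: GenomeLayout, trait_blocks: pd.DataFrame
) -> pd.DataFrame:
    """Fixed-width peaks with density lambda-fold higher inside trait blocks.

    Each peak is in-block with probability lambda*f / (lambda*f + 1 - f)
    where f is the block fraction of the genome, then placed uniformly within
    the chosen compartment; the planted flag is returned in column
    'planted_in_block'.
    """
    pk = cfg.peaks
    rng = np.random.default_rng([cfg.seed, STREAM_PEAKS])
    blocks = merge_intervals(trait_blocks)
    genome_bp = layout.total_length
    block_bp = total_length(blocks)
    f = block_bp / genome_bp
    lam = pk.enrichment
    p_in = lam * f / (lam * f + (1 - f)) if block_bp else 0.0
    in_block = rng.random(pk.n_peaks) < p_in

    # cumulative base coordinates over block / non-block compartments
    def draw_positions(intervals: pd.DataFrame, n: int) -> pd.DataFrame:
        sizes = (intervals["end"] - intervals["start"]).to_numpy()
        cum = np.concatenate([[0], np.cumsum(sizes)])
        u = rng.integers(0, cum[-1], size=n)
        which = np.searchsorted(cum, u, side="right") - 1
        offs = u - cum[which]
        return pd.DataFrame(
            {
                "chrom": intervals["chrom"].to_numpy()[which],
                "pos": intervals["start"].to_numpy()[which] + offs,
            }
        )

    complement = []
    for chrom in layout:
        prev = 0
        for _, b in blocks[blocks["chrom"] == chrom].iterrows():
            if b["start"] > prev:
                complement.append((chrom, prev, b["start"]))
            prev = b["end"]
        if prev < layout[chrom]:
            complement.append((chrom, prev, layout[chrom]))
    comp_df = pd.DataFrame(complement, columns=["chrom", "start", "end"])

    n_in = int(in_block.sum())
    pos_in = draw_positions(blocks, n_in) if n_in else pd.DataFrame(columns=["chrom", "pos"])
    pos_out = draw_positions(comp_df, pk.n_peaks - n_in)
    chroms = np.empty(pk.n_peaks, dtype=object)
    centers = np.empty(pk.n_peaks, dtype=np.int64)
    chroms[in_block] = pos_in["chrom"].to_numpy()
    centers[in_block] = pos_in["pos"].to_numpy()
    chroms[~in_block] = pos_out["chrom"].to_numpy()
    centers[~in_block] = pos_out["pos"].to_numpy()
    half = pk.width // 2
    starts = centers - half
    ends = starts + pk.width
    for i, chrom in enumerate(chroms):  # clip to chromosome ends
        starts[i] = max(0, min(int(starts[i]), layout[chrom] - pk.width))
        ends[i] = starts[i] + pk.width
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "name": [f"peak{i}" for i in range(pk.n_peaks)],
            "planted_in_block": in_block,
        }
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# DARs and projections
# ---------------------------------------------------------------------------

@dataclass
class ProjectionSim:
    dars_source: list  # DarRecord list (source species)
    dar_ids: list[str]
    projections: dict  # region id -> ProjectionRecord
    dars_target: list  # DarRecord list (target species)
    truth: pd.DataFrame


def simulate_projections(
    cfg: SimConfig,
    layout: GenomeLayout,
    direction: str = "mouse_to_chicken",
    hit_scale: float = 1.0,
) -> ProjectionSim:
    """DAR sets in two species plus a projection-score table.

    Scores come from three uniform components on (direct_min, 1],
    (indirect_min, direct_min] and [0, indirect_min] with the configured
    proportions. Conserved DARs receive target coordinates that overlap a
    target-species DAR with the per-tissue hit probability (scaled by
    ``hit_scale`` for the reverse direction); misses are placed in
    DAR-free gaps of the target genome, so the planted truth is exact.
    """
    from .conservation import DarRecord, ProjectionRecord

    pj = cfg.projections
    total = sum(pj.proportions)
    # printed percentages may carry rounding (e.g. 14.3+41.1+44.4 = 99.8)
    if abs(total - 1.0) > 5e-3:
        raise ValueError(f"class proportions must sum to 1, got {total}")
    proportions = [p / total for p in pj.proportions]
    import zlib

    rng = np.random.default_rng(
        [cfg.seed, STREAM_PROJ, zlib.crc32(direction.encode()) % (2**31)]
    )
    source_species, target_species = direction.split("_to_")

    # target genome: DARs on a regular grid with guaranteed empty gaps
    grid = 2000
    target_chrom = "chrT"
    target_dars = []
    for i in range(pj.n_target_dars):
        s = 1000 + i * grid
        tissue = "ectoderm" if i % 2 == 0 else "mesenchyme"
        target_dars.append(
            DarRecord(
                interval=GenomicInterval(target_chrom, s, s + pj.dar_width),
                population=f"{target_species}_{tissue}",
                tissue=tissue,
                species=target_species,
            )
        )
    ect_idx = np.arange(0, pj.n_target_dars, 2)
    mes_idx = np.arange(1, pj.n_target_dars, 2)

    chroms = list(layout)
    pops_e = [f"ecto_{i}" for i in range(pj.n_populations_ectoderm)]
    pops_m = [f"mes_{i}" for i in range(pj.n_populations_mesenchyme)]
    source_dars, dar_ids, projections, rows = [], [], {}, []
    for i in range(pj.n_dars):
        rid = f"{source_species}_dar{i}"
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(0, layout[chrom] - pj.dar_width))
        src_iv = GenomicInterval(chrom, start, start + pj.dar_width)
        is_ect = rng.random() < pj.ectoderm_fraction
        tissue = "ectoderm" if is_ect else "mesenchyme"
        pop = (pops_e if is_ect else pops_m)[
            int(rng.integers(0, len(pops_e if is_ect else pops_m)))
        ]
        source_dars.append(
            DarRecord(interval=src_iv, population=pop, tissue=tissue, species=source_species)
        )
        dar_ids.append(rid)

        cls = ["direct", "indirect", "nonconserved"][
            int(rng.choice(3, p=proportions))
        ]
        if cls == "direct":
            score = float(rng.uniform(pj.direct_min + 1e-9, 1.0))
        elif cls == "indirect":
            score = float(rng.uniform(pj.indirect_min + 1e-9, pj.direct_min))
        else:
            score = float(rng.uniform(0.0, pj.indirect_min))
        hit = cls != "nonconserved" and rng.random() < pj.hit_prob[tissue] * hit_scale
        same_tissue = None
        if hit:
            same_tissue = bool(rng.random() < pj.identity_prob)
            want = tissue if same_tissue else ("mesenchyme" if is_ect else "ectoderm")
            pool = ect_idx if want == "ectoderm" else mes_idx
            j = int(pool[rng.integers(0, len(pool))])
            t = target_dars[j].interval
            jitter = int(rng.integers(-pj.dar_width // 2, pj.dar_width // 2))
            target = GenomicInterval(
                target_chrom, max(0, t.start + jitter), max(1, t.start + jitter) + pj.dar_width
            )
        else:
            # guaranteed DAR-free gap: grid cell [1500+2000k, 3000+2000k)
            k = int(rng.integers(0, pj.n_target_dars))
            s = 1700 + k * grid
            target = GenomicInterval(target_chrom, s, s + pj.dar_width)
        projections[rid] = ProjectionRecord(
            region_id=rid, source=src_iv, score=score, target=target, bridge="human"
        )
        rows.append(
            {
                "region_id": rid,
                "planted_class": cls,
                "planted_conserved": hit,
                "planted_same_tissue": same_tissue,
                "tissue": tissue,
            }
        )
    return ProjectionSim(
        dars_source=source_dars,
        dar_ids=dar_ids,
        projections=projections,
        dars_target=target_dars,
        truth=pd.DataFrame(rows),
    )


def projection_table(sim: ProjectionSim) -> pd.DataFrame:
    rows = []
    for rid in sim.dar_ids:
        p = sim.projections[rid]
        rows.append(
            {
                "region_id": rid,
                "chrom": p.source.chrom,
                "start": p.source.start,
                "end": p.source.end,
                "score": p.score,
                "target_chrom": p.target.chrom if p.target else "",
                "target_start": p.target.start if p.target else "",
                "target_end": p.target.end if p.target else "",
                "bridge": p.bridge or "",
            }
        )
    return pd.DataFrame(rows)


def dars_to_frame(dars) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in dars],
            "start": [d.interval.start for d in dars],
            "end": [d.interval.end for d in dars],
            "name": [d.population for d in dars],
        }
    )
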