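"""End-to-end orchestration: simulate -> LD blocks -> tile/annotate ->
matched background -> enrichment -> conservation, with a run manifest.

Every stage reads its inputs from files and writes its outputs back, so each
stage is runnable standalone and a full run is reproducible file-by-file. A
single master seed drives the simulation and the background sampler through
separate substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, background, conservation, enrichment, io, ld, simulate
from .intervals import GenomeLayout, GenomicInterval

STREAM_SAMPLER = 10


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    sim: simulate.SimConfig = None  # filled from seed when absent
    ld: ld.LdParams = field(default_factory=ld.LdParams)
    tile_width: int = 500
    gc_bins: int = 10
    promoter_up: int = 2000
    promoter_down: int = 200
    n_sets: int = 200
    exclude_overlapping: bool = False
    write_background_sets: bool = False

    def __post_init__(self):
        if self.sim is None:
            self.sim = simulate.SimConfig(seed=self.seed)
        if self.n_sets < 1:
            raise ConfigError("n_sets must be >= 1")
        if self.tile_width < 1:
            raise ConfigError("tile_width must be >= 1")
        if self.gc_bins < 1:
            raise ConfigError("gc_bins must be >= 1")


_LD_KEYS = {"p_threshold", "window", "r2_min"}
_TOP_KEYS = {
    "seed",
    "out_dir",
    "tile_width",
    "gc_bins",
    "promoter_up",
    "promoter_down",
    "n_sets",
    "exclude_overlapping",
    "write_background_sets",
    "ld",
    "sim",
}


def config_from_toml(path) -> PipelineConfig:
    """Parse and validate a TOML config; unknown keys are config errors."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    ld_raw = raw.pop("ld", {})
    bad = set(ld_raw) - _LD_KEYS
    if bad:
        raise ConfigError(f"unknown [ld] keys: {sorted(bad)}")
    sim_raw = raw.pop("sim", {})
    seed = raw.get("seed", 0)
    sim_cfg = simulate.SimConfig(seed=seed)
    for section, value in sim_raw.items():
        if not hasattr(sim_cfg, section):
            raise ConfigError(f"unknown [sim] section: {section}")
        sub = getattr(sim_cfg, section)
        for k, v in value.items():
            if not hasattr(sub, k):
                raise ConfigError(f"unknown key sim.{section}.{k}")
            setattr(sub, k, v)
    try:
        params = ld.LdParams(**ld_raw)
        return PipelineConfig(sim=sim_cfg, ld=params, **raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    layout, sequences, genes = simulate.simulate_genome(sim)
    io.write_fasta(sequences, out / "genome.fa")
    annotation.write_gff3(genes, out / "genes.gff3")
    panel_sim = simulate.simulate_panel(sim, layout)
    io.write_phased_vcf_multi(
        panel_sim.panels, out / "panel.vcf", contig_lengths=layout.lengths
    )
    gwas_sim = simulate.simulate_gwas(sim, panel_sim)
    io.write_snp_table(gwas_sim.snps, out / "gwas.tsv")
    io.write_bed(gwas_sim.trait_blocks, out / "trait_blocks.bed")
    peaks = simulate.simulate_peaks(sim, layout, gwas_sim.trait_blocks)
    io.write_bed(peaks[["chrom", "start", "end", "name"]], out / "peaks.bed")
    truth_frames = {
        "peaks": peaks[["name", "planted_in_block"]].rename(
            columns={"name": "region_id", "planted_in_block": "value"}
        )
    }
    directions = {"mouse_to_chicken": 1.0, "chicken_to_mouse": 2 / 9}
    for direction, scale in directions.items():
        psim = simulate.simulate_projections(sim, layout, direction, hit_scale=scale)
        src = simulate.dars_to_frame(psim.dars_source)
        src["score"] = [d.tissue for d in psim.dars_source]
        src["name"] = psim.dar_ids
        io.write_bed(src, out / f"dars_source_{direction}.bed")
        tgt = simulate.dars_to_frame(psim.dars_target)
        tgt["score"] = [d.tissue for d in psim.dars_target]
        io.write_bed(tgt, out / f"dars_target_{direction}.bed")
        io.write_tsv(
            simulate.projection_table(psim), out / f"projections_{direction}.tsv"
        )
        io.write_tsv(psim.truth, out / f"truth_projections_{direction}.tsv")
    io.write_tsv(
        truth_frames["peaks"].assign(kind="peak_in_block"), out / "truth_peaks.tsv"
    )
    return {"layout": layout}


def stage_ld_blocks(
    snps_path, vcf_path, params: ld.LdParams, out_bed, out_provenance=None
) -> list[ld.LdBlock]:
    """GWAS filter -> per-SNP blocks -> pooled merge, from files to BED."""
    snps = io.read_snp_table(snps_path)
    significant = ld.filter_gwas(snps, params.p_threshold)
    panels = io.read_phased_vcf_all(vcf_path)
    blocks = []
    for chrom, panel in panels.items():
        chrom_snps = [s for s in significant if s.chrom == chrom]
        blocks.extend(ld.build_blocks(chrom_snps, panel, params))
    merged = ld.merge_blocks(blocks)
    io.write_bed(ld.blocks_to_frame(merged), out_bed)
    if out_provenance:
        prov = pd.DataFrame(
            {
                "chrom": [b.interval.chrom for b in merged],
                "start": [b.interval.start for b in merged],
                "end": [b.interval.end for b in merged],
                "n_source_snps": [len(b.source_snps) for b in merged],
                "source_snps": [";".join(b.source_snps) for b in merged],
                "group": [b.group or "pooled" for b in merged],
            }
        )
        io.write_tsv(prov, out_provenance)
    return merged


def stage_annotate(
    fasta_path, gff3_path, cfg: PipelineConfig, out: Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fasta = io.open_fasta(fasta_path)
    layout = io.layout_from_fasta(fasta_path)
    genes = annotation.read_gene_models(gff3_path)
    tiles = annotation.tile_genome(layout, cfg.tile_width)
    kw = dict(
        gc_bins=cfg.gc_bins,
        promoter_up=cfg.promoter_up,
        promoter_down=cfg.promoter_down,
    )
    tiles = annotation.stratify_regions(tiles, fasta, genes, **kw)
    io.write_tsv(tiles, out / "annotated_tiles.tsv")
    peaks = io.read_bed(out / "peaks.bed")
    peaks_annot = annotation.stratify_regions(
        peaks[["chrom", "start", "end"]], fasta, genes, **kw
    )
    peaks_annot["name"] = peaks["name"].to_numpy()
    io.write_tsv(peaks_annot, out / "annotated_peaks.tsv")
    return tiles, peaks_annot


def stage_background(
    tiles: pd.DataFrame, peaks_annot: pd.DataFrame, cfg: PipelineConfig, out: Path
) -> list[background.BackgroundSet]:
    pool = background.build_pool(
        tiles, peaks_annot, exclude_overlapping=cfg.exclude_overlapping
    )
    sampler_seed = int(
        np.random.SeedSequence([cfg.seed, STREAM_SAMPLER]).generate_state(1)[0]
        % (2**31)
    )
    plan = background.plan_from_foreground(
        peaks_annot, pool, n_sets=cfg.n_sets, seed=sampler_seed
    )
    sets = background.sample_sets(plan)
    manifest = pd.DataFrame(
        {
            "set_index": [s.index for s in sets],
            "seed": [s.seed for s in sets],
            "n_regions": [len(s.regions) for s in sets],
            "n_fallbacks": [sum(n for _, _, n in s.fallbacks) for s in sets],
        }
    )
    io.write_tsv(manifest, out / "background_manifest.tsv")
    if cfg.write_background_sets:
        bg_dir = io.ensure_dir(out / "background_sets")
        for s in sets:
            io.write_bed(s.regions[["chrom", "start", "end"]], bg_dir / f"set_{s.index:04d}.bed")
    return sets


def stage_enrich(peaks_annot, blocks_bed, sets, out: Path) -> pd.DataFrame:
    blocks = io.read_bed(blocks_bed)
    overlap_res, density_res = enrichment.run_enrichment(
        peaks_annot[["chrom", "start", "end"]], blocks, sets
    )
    table = enrichment.results_table([overlap_res, density_res])
    io.write_tsv(table, out / "enrichment.tsv")
    return table


def stage_conserve(out: Path, directions=("mouse_to_chicken", "chicken_to_mouse")) -> pd.DataFrame:
    rows = []
    for direction in directions:
        src_bed = io.read_bed(out / f"dars_source_{direction}.bed")
        tgt_bed = io.read_bed(out / f"dars_target_{direction}.bed")
        src_species = direction.split("_to_")[0]
        tgt_species = direction.split("_to_")[1]
        dars_source = [
            conservation.DarRecord(
                interval=GenomicInterval(r.chrom, r.start, r.end),
                population=r.name,
                tissue=r.score,
                species=src_species,
            )
            for r in src_bed.itertuples()
        ]
        dars_target = [
            conservation.DarRecord(
                interval=GenomicInterval(r.chrom, r.start, r.end),
                population=r.name,
                tissue=r.score,
                species=tgt_species,
            )
            for r in tgt_bed.itertuples()
        ]
        projections = conservation.read_projection_table(
            out / f"projections_{direction}.tsv"
        )
        calls = conservation.functional_conservation(
            dars_source, projections, dars_target, dar_ids=src_bed["name"].tolist()
        )
        io.write_tsv(calls, out / f"conservation_calls_{direction}.tsv")
        ratio, p, _table = conservation.tissue_rate_ratio(calls)
        class_counts = calls["conservation_class"].value_counts(normalize=True)
        rows.append(
            {
                "direction": direction,
                "n_dars": len(calls),
                "pct_direct": 100 * class_counts.get("direct", 0.0),
                "pct_indirect": 100 * class_counts.get("indirect", 0.0),
                "pct_nonconserved": 100 * class_counts.get("nonconserved", 0.0),
                "pct_functionally_conserved": 100 * calls["functionally_conserved"].mean(),
                "identity_retention": conservation.identity_retention(calls),
                "ectoderm_mesenchyme_ratio": ratio,
                "tissue_p": p,
            }
        )
    summary = pd.DataFrame(rows)
    io.write_tsv(summary, out / "conservation_summary.tsv")
    return summary


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    digests: dict[str, str]
    version: str
    started: float
    finished: float
    failed_stage: str | None = None


def run_all(cfg: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute all stages in dependency order; fail fast naming the stage.

    Returns the manifest plus a dict of in-memory results (blocks, background
    sets, enrichment table, conservation summary).
    """
    from . import __version__

    out = io.ensure_dir(cfg.out_dir)
    started = time.time()
    results: dict = {}
    stage = "simulate"
    try:
        stage_simulate(cfg, out)
        stage = "ld_blocks"
        results["blocks"] = stage_ld_blocks(
            out / "gwas.tsv",
            out / "panel.vcf",
            cfg.ld,
            out / "blocks.bed",
            out / "blocks_provenance.tsv",
        )
        stage = "annotate"
        tiles, peaks_annot = stage_annotate(
            out / "genome.fa", out / "genes.gff3", cfg, out
        )
        stage = "sample_background"
        sets = stage_background(tiles, peaks_annot, cfg, out)
        results["background_sets"] = sets
        stage = "enrich"
        results["enrichment"] = stage_enrich(peaks_annot, out / "blocks.bed", sets, out)
        stage = "conserve"
        results["conservation"] = stage_conserve(out)
    except Exception as exc:
        manifest = RunManifest(
            config=_config_dict(cfg),
            seed=cfg.seed,
            digests=_collect_digests(out),
            version=__version__,
            started=started,
            finished=time.time(),
            failed_stage=stage,
        )
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    manifest = RunManifest(
        config=_config_dict(cfg),
        seed=cfg.seed,
        digests=_collect_digests(out),
        version=__version__,
        started=started,
        finished=time.time(),
    )
    _write_manifest(manifest, out)
    return manifest, results


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _collect_digests(out: Path) -> dict[str, str]:
    return {
        p.name: _digest(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.suffix in {".bed", ".tsv", ".fa", ".gff3", ".vcf"}
    }


def _write_manifest(manifest: RunManifest, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
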