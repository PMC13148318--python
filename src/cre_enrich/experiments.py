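"""Replicate-level simulation experiments over the pipeline.

These drivers fix one synthetic genome (tiling, annotation, strata) and
re-simulate the stochastic layer (peak sets, panels, DAR labels) across
replicates, which is both how the real study is structured — one genome,
one background pool, one observed peak set — and what keeps the experiments
desk-sized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation, background, conservation, enrichment, simulate
from .intervals import GenomeLayout
from .ld import LdParams, build_block
from .io import SnpRecord


@dataclass
class _FixedGenome:
    layout: GenomeLayout
    sequences: dict[str, str]
    tiles: pd.DataFrame  # stratified
    genes: list


def _make_genome(length: int, seed: int, tile_width: int = 500, gc_bins: int = 10) -> _FixedGenome:
    cfg = simulate.SimConfig(seed=seed)
    cfg.genome.chrom_lengths = {"chr1": length}
    layout, sequences, genes = simulate.simulate_genome(cfg)
    tiles = annotation.tile_genome(layout, tile_width)
    tiles = annotation.stratify_regions(tiles, sequences, genes, gc_bins=gc_bins)
    return _FixedGenome(layout=layout, sequences=sequences, tiles=tiles, genes=genes)


def _spaced_blocks(length: int, n_blocks: int, block_fraction: float) -> pd.DataFrame:
    """Equally spaced blocks jointly covering block_fraction of the genome.

    Starts are offset off the 500-bp tile grid: grid-aligned blocks would
    deny background tiles the partial edge overlaps that peaks at arbitrary
    offsets get, biasing observed counts high relative to the null.
    """
    width = int(length * block_fraction / n_blocks)
    gap = length // (n_blocks + 1)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [gap * (i + 1) + 173 for i in range(n_blocks)],
            "end": [gap * (i + 1) + 173 + width for i in range(n_blocks)],
        }
    )


def enrichment_replicates(
    lam: float,
    n_reps: int,
    n_sets: int,
    n_peaks: int,
    block_fraction: float = 0.05,
    genome_length: int = 4_000_000,
    n_blocks: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p-values and folds over replicate peak simulations.

    One genome and block set are fixed; each replicate draws a fresh peak set
    with in-block enrichment ``lam``, builds matched backgrounds, and runs
    both statistics. Returns one row per replicate.
    """
    genome = _make_genome(genome_length, seed=seed)
    blocks = _spaced_blocks(genome_length, n_blocks, block_fraction)
    rows = []
    for rep in range(n_reps):
        cfg = simulate.SimConfig(seed=int(np.random.default_rng([seed, 100, rep]).integers(2**31)))
        cfg.peaks.n_peaks = n_peaks
        cfg.peaks.enrichment = lam
        peaks = simulate.simulate_peaks(cfg, genome.layout, blocks)
        peaks = annotation.stratify_regions(
            peaks[["chrom", "start", "end"]], genome.sequences, genome.genes
        )
        pool = background.build_pool(genome.tiles, peaks)
        plan = background.plan_from_foreground(
            peaks, pool, n_sets=n_sets, seed=int(np.random.default_rng([seed, 200, rep]).integers(2**31))
        )
        sets = background.sample_sets(plan)
        overlap_res, density_res = enrichment.run_enrichment(peaks, blocks, sets)
        rows.append(
            {
                "rep": rep,
                "overlap_observed": overlap_res.observed,
                "overlap_p": overlap_res.empirical_p,
                "overlap_fold": overlap_res.fold,
                "density_p": density_res.empirical_p,
                "density_fold": density_res.fold,
            }
        )
    return pd.DataFrame(rows)


def expected_fold(lam: float, block_fraction: float) -> float:
    """Closed-form fold for peaks planted at rate lam inside blocks covering
    fraction f of the genome: (lam f/(lam f + 1 - f)) / f-under-the-null."""
    f = block_fraction
    return lam / (lam * f + (1 - f))


def block_recovery_trials(
    n_trials: int = 100,
    rho: float = 0.95,
    n_haplotypes: int = 200,
    chrom_length: int = 500_000,
    snp_spacing: int = 1000,
    segment_mean: int = 50_000,
    params: LdParams = LdParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Recover latent LD-segment boundaries with the block builder.

    Each trial simulates a founder-copying panel, queries a SNP at the centre
    of a latent segment holding >=5 panel variants, and compares the block
    edges to the outermost panel SNPs inside that segment (the best boundary
    any r2-based method can recover). Errors are in bp; ``within_one_spacing``
    flags trials where both edges land within one mean SNP spacing.
    """
    rows = []
    for trial in range(n_trials):
        cfg = simulate.SimConfig(seed=int(np.random.default_rng([seed, 300, trial]).integers(2**31)))
        cfg.genome.chrom_lengths = {"chr1": chrom_length}
        cfg.panel.n_haplotypes = n_haplotypes
        cfg.panel.rho = rho
        cfg.panel.snp_spacing = snp_spacing
        cfg.panel.segment_mean = segment_mean
        layout = GenomeLayout(cfg.genome.chrom_lengths)
        psim = simulate.simulate_panel(cfg, layout)
        panel = psim.panels["chr1"]
        bounds = psim.segments["chr1"]
        rng = np.random.default_rng([seed, 301, trial])
        # segments with enough variants, away from chromosome ends
        viable = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            inside = panel.positions[(panel.positions > s) & (panel.positions <= e)]
            if len(inside) >= 5:
                viable.append((int(s), int(e), inside))
        if not viable:
            continue
        s, e, inside = viable[int(rng.integers(len(viable)))]
        snp = SnpRecord("chr1", int((s + e) // 2), f"query{trial}", 1e-9, "EUR")
        block = build_block(snp, panel, params)
        start_err = abs((block.interval.start + 1) - int(inside.min()))
        end_err = abs(block.interval.end - int(inside.max()))
        rows.append(
            {
                "trial": trial,
                "start_err": start_err,
                "end_err": end_err,
                "within_one_spacing": start_err <= snp_spacing and end_err <= snp_spacing,
            }
        )
    return pd.DataFrame(rows)


def conservation_ratio_replicates(
    rate_ectoderm: float = 0.44,
    rate_mesenchyme: float = 0.10,
    n_per_tissue: int = 500,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Recover a planted tissue-level conservation-rate contrast.

    Each replicate draws Bernoulli conservation flags at the planted rates
    and re-estimates the ratio and Fisher p through the summary machinery.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 400, rep])
        calls = pd.DataFrame(
            {
                "tissue": ["ectoderm"] * n_per_tissue + ["mesenchyme"] * n_per_tissue,
                "functionally_conserved": np.concatenate(
                    [
                        rng.random(n_per_tissue) < rate_ectoderm,
                        rng.random(n_per_tissue) < rate_mesenchyme,
                    ]
                ),
            }
        )
        ratio, p, _ = conservation.tissue_rate_ratio(calls)
        rows.append({"rep": rep, "ratio": ratio, "p": p})
    return pd.DataFrame(rows)
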