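import numpy as np
import pandas as pd
import pytest

from cre_enrich import simulate
from cre_enrich.conservation import classify
from cre_enrich.intervals import GenomeLayout
from cre_enrich.ld import filter_gwas, r2


def cfg_with(seed=0, **genome):
    cfg = simulate.SimConfig(seed=seed)
    for k, v in genome.items():
        setattr(cfg.genome, k, v)
    return cfg


class TestGenome:
    def test_determinism_and_seed_sensitivity(self):
        cfg = cfg_with(seed=3, chrom_lengths={"chr1": 50_000})
        _, seq_a, genes_a = simulate.simulate_genome(cfg)
        _, seq_b, genes_b = simulate.simulate_genome(cfg_with(seed=3, chrom_lengths={"chr1": 50_000}))
        assert seq_a == seq_b
        assert [g.gene_id for g in genes_a] == [g.gene_id for g in genes_b]
        _, seq_c, _ = simulate.simulate_genome(cfg_with(seed=4, chrom_lengths={"chr1": 50_000}))
        assert seq_a != seq_c

    def test_balanced_beta_gives_half_gc(self):
        cfg = cfg_with(seed=1, chrom_lengths={"chr1": 1_000_000}, gc_alpha=50.0, gc_beta=50.0)
        _, seqs, _ = simulate.simulate_genome(cfg)
        s = seqs["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.5, abs=0.02)

    def test_zero_genes_everything_intergenic(self):
        from cre_enrich.annotation import annotate
        from cre_enrich.intervals import GenomicInterval

        cfg = cfg_with(seed=2, chrom_lengths={"chr1": 20_000}, genes_per_mb=0.0)
        _, _, genes = simulate.simulate_genome(cfg)
        assert genes == []
        assert annotate(GenomicInterval("chr1", 0, 500), genes) == "intergenic"

    def test_genes_do_not_overlap(self, small_genome):
        _, _, genes = small_genome
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestPanel:
    def test_rho_one_gives_perfect_within_segment_ld(self):
        cfg = simulate.SimConfig(seed=5)
        cfg.panel.rho = 1.0
        cfg.panel.n_haplotypes = 50
        layout = GenomeLayout({"chr1": 100_000})
        sim = simulate.simulate_panel(cfg, layout)
        panel, bounds = sim.panels["chr1"], sim.segments["chr1"]
        seg_of = np.searchsorted(bounds, panel.positions - 1, side="right") - 1
        for s in np.unique(seg_of):
            cols = np.where(seg_of == s)[0]
            polymorphic = [
                j for j in cols if 0 < panel.alleles[:, j].mean() < 1
            ]
            for a, b in zip(polymorphic, polymorphic[1:]):
                assert r2(panel.alleles[:, a], panel.alleles[:, b]) == pytest.approx(1.0)

    def test_rho_zero_matches_independence_baseline(self):
        cfg = simulate.SimConfig(seed=6)
        cfg.panel.rho = 0.0
        cfg.panel.n_haplotypes = 100
        layout = GenomeLayout({"chr1": 200_000})
        sim = simulate.simulate_panel(cfg, layout)
        panel, bounds = sim.panels["chr1"], sim.segments["chr1"]
        seg_of = np.searchsorted(bounds, panel.positions - 1, side="right") - 1
        rng = np.random.default_rng(0)
        within, across = [], []
        for _ in range(400):
            i, j = rng.integers(0, panel.n_variants, 2)
            if i == j:
                continue
            v = r2(panel.alleles[:, i], panel.alleles[:, j])
            if np.isnan(v):
                continue
            (within if seg_of[i] == seg_of[j] else across).append(v)
        # both means near the finite-sample floor 1/n_haplotypes
        assert np.mean(within) == pytest.approx(1 / 100, abs=0.01)
        assert np.mean(across) == pytest.approx(1 / 100, abs=0.01)

    def test_high_rho_gives_strong_within_segment_ld(self, small_panel):
        panel = small_panel.panels["chr1"]
        bounds = small_panel.segments["chr1"]
        seg_of = np.searchsorted(bounds, panel.positions - 1, side="right") - 1
        vals = []
        for s in np.unique(seg_of):
            cols = np.where(seg_of == s)[0]
            if len(cols) < 2:
                continue
            v = r2(panel.alleles[:, cols[0]], panel.alleles[:, cols[-1]])
            if not np.isnan(v):
                vals.append(v)
        assert np.median(vals) > 0.8


class TestGwas:
    def test_planted_significance_counts(self, small_sim_config, small_panel):
        sim = simulate.simulate_gwas(small_sim_config, small_panel)
        assert len(sim.snps) == 120
        assert len(filter_gwas(sim.snps, 5e-8)) == 80

    def test_zero_significant_fraction(self, small_panel, small_sim_config):
        import copy

        cfg = copy.deepcopy(small_sim_config)
        cfg.gwas.n_significant = 0
        sim = simulate.simulate_gwas(cfg, small_panel)
        assert filter_gwas(sim.snps, 5e-8) == []

    def test_significant_snps_inside_trait_blocks(self, small_sim_config, small_panel):
        sim = simulate.simulate_gwas(small_sim_config, small_panel)
        trait = sim.trait_blocks
        for s in filter_gwas(sim.snps, 5e-8):
            hit = trait[
                (trait["chrom"] == s.chrom)
                & (trait["start"] < s.pos)
                & (s.pos <= trait["end"])
            ]
            assert len(hit) == 1

    def test_determinism(self, small_sim_config, small_panel):
        a = simulate.simulate_gwas(small_sim_config, small_panel)
        b = simulate.simulate_gwas(small_sim_config, small_panel)
        assert a.snps == b.snps


class TestPeaks:
    def closed_form(self, lam, f):
        return lam * f / (lam * f + 1 - f)

    @pytest.mark.parametrize("lam", [1.0, 5.0])
    def test_in_block_fraction_matches_closed_form(self, lam):
        cfg = simulate.SimConfig(seed=8)
        cfg.peaks.n_peaks = 2000
        cfg.peaks.enrichment = lam
        layout = GenomeLayout({"chr1": 4_000_000})
        blocks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [500_000, 2_000_000], "end": [540_000, 2_040_000]}
        )
        peaks = simulate.simulate_peaks(cfg, layout, blocks)
        f = 80_000 / 4_000_000
        expect = self.closed_form(lam, f)
        frac = peaks["planted_in_block"].mean()
        sd = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(frac - expect) <= 3 * sd

    def test_peaks_fit_inside_genome_and_fixed_width(self):
        cfg = simulate.SimConfig(seed=9)
        cfg.peaks.n_peaks = 500
        layout = GenomeLayout({"chr1": 100_000})
        blocks = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [20_000]})
        peaks = simulate.simulate_peaks(cfg, layout, blocks)
        assert (peaks["start"] >= 0).all()
        assert (peaks["end"] <= 100_000).all()
        assert ((peaks["end"] - peaks["start"]) == cfg.peaks.width).all()

    def test_determinism(self):
        cfg = simulate.SimConfig(seed=10)
        layout = GenomeLayout({"chr1": 500_000})
        blocks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        a = simulate.simulate_peaks(cfg, layout, blocks)
        b = simulate.simulate_peaks(cfg, layout, blocks)
        pd.testing.assert_frame_equal(a, b)


class TestProjections:
    def test_classify_recovers_planted_labels_exactly(self, small_sim_config):
        layout = GenomeLayout(small_sim_config.genome.chrom_lengths)
        sim = simulate.simulate_projections(small_sim_config, layout)
        for rid, planted in zip(sim.truth["region_id"], sim.truth["planted_class"]):
            assert classify(sim.projections[rid].score) == planted

    def test_all_direct_when_proportions_degenerate(self):
        cfg = simulate.SimConfig(seed=12)
        cfg.projections.proportions = (1.0, 0.0, 0.0)
        cfg.projections.n_dars = 100
        layout = GenomeLayout(cfg.genome.chrom_lengths)
        sim = simulate.simulate_projections(cfg, layout)
        assert (sim.truth["planted_class"] == "direct").all()

    def test_bad_proportions_rejected(self):
        cfg = simulate.SimConfig(seed=12)
        cfg.projections.proportions = (0.5, 0.1, 0.1)
        layout = GenomeLayout(cfg.genome.chrom_lengths)
        with pytest.raises(ValueError):
            simulate.simulate_projections(cfg, layout)

    def test_determinism(self, small_sim_config):
        layout = GenomeLayout(small_sim_config.genome.chrom_lengths)
        a = simulate.simulate_projections(small_sim_config, layout)
        b = simulate.simulate_projections(small_sim_config, layout)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.projections == b.projections
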