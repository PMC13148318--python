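import numpy as np
import pytest

from cre_enrich.intervals import GenomicInterval
from cre_enrich.io import HaplotypePanel, SnpRecord
from cre_enrich.ld import (
    LdBlock,
    LdParams,
    NoProxyError,
    build_block,
    filter_gwas,
    merge_blocks,
    r2,
    select_proxies,
)


def r2_table_oracle(x, y):
    """r2 from the explicit 2x2 haplotype-count table."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    n11 = np.sum((x == 1) & (y == 1))
    p1, q1 = np.sum(x == 1) / n, np.sum(y == 1) / n
    if p1 in (0, 1) or q1 in (0, 1):
        return float("nan")
    d = n11 / n - p1 * q1
    return d * d / (p1 * (1 - p1) * q1 * (1 - q1))


def snp(pos, chrom="chr1"):
    return SnpRecord(chrom, pos, f"rs{pos}", 1e-9, "EUR")


class TestFilterGwas:
    def test_strict_threshold_boundary(self):
        snps = [
            SnpRecord("chr1", 1, "a", 1e-9, "EUR"),
            SnpRecord("chr1", 2, "b", 5e-8, "EUR"),
            SnpRecord("chr1", 3, "c", 4.9e-8, "EUR"),
        ]
        kept = filter_gwas(snps, 5e-8)
        assert [s.id for s in kept] == ["a", "c"]

    def test_empty_input(self):
        assert filter_gwas([], 5e-8) == []


class TestR2:
    def test_perfect_ld(self):
        assert r2([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_coding_flip_invariance(self):
        assert r2([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_against_table_oracle_example(self):
        x = [0, 0, 1, 1, 0, 1, 0, 1]
        y = [0, 1, 1, 1, 0, 0, 0, 1]
        assert r2(x, y) == pytest.approx(r2_table_oracle(x, y), abs=1e-12)

    def test_monomorphic_is_nan(self):
        assert np.isnan(r2([0, 0, 0, 0], [0, 1, 0, 1]))

    def test_symmetry_and_range_random(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 64))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            v = r2(x, y)
            if np.isnan(v):
                continue
            assert 0 <= v <= 1 + 1e-12
            assert v == pytest.approx(r2(y, x))
            assert v == pytest.approx(r2(1 - x, y))


def make_panel(positions, alleles, chrom="chr1"):
    return HaplotypePanel(
        chrom=chrom, positions=np.array(positions), alleles=np.array(alleles)
    )


class TestSelectProxies:
    def test_snp_in_panel(self):
        panel = make_panel([900, 1000, 1100], np.random.default_rng(0).integers(0, 2, (4, 3)))
        down, up = select_proxies(snp(1000), panel)
        assert down == up == 1

    def test_flanking(self):
        panel = make_panel([800, 1200], np.random.default_rng(0).integers(0, 2, (4, 2)))
        assert select_proxies(snp(1000), panel) == (0, 1)

    def test_one_sided(self):
        panel = make_panel([700, 800], np.random.default_rng(0).integers(0, 2, (4, 2)))
        assert select_proxies(snp(1000), panel) == (1, 1)

    def test_no_proxy_in_window(self):
        panel = make_panel([900_000], np.random.default_rng(0).integers(0, 2, (4, 1)))
        with pytest.raises(NoProxyError):
            select_proxies(snp(1000), panel)


class TestBuildBlock:
    def test_degenerate_block_spans_proxies(self):
        # independent variants: nothing linked except the proxies themselves
        rng = np.random.default_rng(1)
        positions = [500, 950, 1050, 1500]
        alleles = rng.integers(0, 2, (400, 4))
        block = build_block(snp(1000), make_panel(positions, alleles))
        assert block.interval == GenomicInterval("chr1", 949, 1050)

    def test_monotone_in_r2_min(self, small_panel):
        panel = small_panel.panels["chr1"]
        query = snp(int(panel.positions[len(panel.positions) // 2]))
        loose = build_block(query, panel, LdParams(r2_min=0.8))
        tight = build_block(query, panel, LdParams(r2_min=0.95))
        assert loose.interval.start <= tight.interval.start
        assert tight.interval.end <= loose.interval.end

    def test_block_contains_source_snp(self, small_panel):
        panel = small_panel.panels["chr1"]
        query = snp(int(panel.positions[10]) + 1)
        block = build_block(query, panel)
        assert block.interval.start <= query.pos - 1 < block.interval.end

    def test_matches_exhaustive_scan(self):
        """Block edges equal an exhaustive all-variant r2 scan vs the proxies."""
        rng = np.random.default_rng(99)
        params = LdParams()
        for _ in range(20):
            positions = np.sort(rng.choice(20_000, 20, replace=False)) + 1
            # two founder groups create designed correlation structure
            founder = rng.integers(0, 2, 60)
            alleles = np.where(
                rng.random((60, 20)) < 0.8, founder[:, None], rng.integers(0, 2, (60, 20))
            )
            panel = make_panel(positions, alleles)
            query = snp(int(positions[10]))
            down, up = select_proxies(query, panel, params.window)
            linked_pos = []
            for j in range(20):
                vals = [
                    r2_table_oracle(alleles[:, j], alleles[:, down]),
                    r2_table_oracle(alleles[:, j], alleles[:, up]),
                ]
                if j in (down, up) or any(not np.isnan(v) and v >= 0.8 for v in vals):
                    linked_pos.append(positions[j])
            block = build_block(query, panel, params)
            assert block.interval.start == min(linked_pos) - 1
            assert block.interval.end == max(linked_pos)


class TestMergeBlocks:
    def b(self, chrom, start, end, ids=("x",)):
        return LdBlock(GenomicInterval(chrom, start, end), list(ids))

    def test_overlapping_merged_with_provenance_union(self):
        merged = merge_blocks(
            [self.b("chr1", 0, 100, ["a"]), self.b("chr1", 50, 200, ["b"])]
        )
        assert len(merged) == 1
        assert merged[0].interval == GenomicInterval("chr1", 0, 200)
        assert merged[0].source_snps == ["a", "b"]

    def test_abutting_not_merged(self):
        merged = merge_blocks([self.b("chr1", 0, 100), self.b("chr1", 100, 200)])
        assert len(merged) == 2

    def test_idempotent_nonoverlapping_coverage_conserved(self):
        rng = np.random.default_rng(11)
        blocks = [
            self.b("chr%d" % rng.integers(1, 3), s, s + int(rng.integers(1, 400)), [f"s{i}"])
            for i, s in enumerate(rng.integers(0, 5000, 500))
        ]
        merged = merge_blocks(blocks)
        again = merge_blocks(merged)
        assert [b.interval for b in merged] == [b.interval for b in again]
        for a, c in zip(merged, merged[1:]):
            if a.interval.chrom == c.interval.chrom:
                assert a.interval.end <= c.interval.start
        # coverage conservation via footprint
        def footprint(bs):
            foot = {}
            for blk in bs:
                arr = foot.setdefault(blk.interval.chrom, np.zeros(6000, dtype=bool))
                arr[blk.interval.start : blk.interval.end] = True
            return {k: v.sum() for k, v in foot.items()}

        assert footprint(blocks) == footprint(merged)
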