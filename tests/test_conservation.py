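import numpy as np
import pandas as pd
import pytest

from cre_enrich.conservation import (
    DarRecord,
    ProjectionRecord,
    classify,
    conservation_summary,
    functional_conservation,
    identity_retention,
    read_projection_table,
    tissue_rate_ratio,
)
from cre_enrich.intervals import GenomicInterval


def dar(start, end, tissue="ectoderm", pop=None, chrom="chrT", species="chicken"):
    return DarRecord(
        interval=GenomicInterval(chrom, start, end),
        population=pop or tissue,
        tissue=tissue,
        species=species,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.99, "direct"),
            (0.981, "direct"),
            (0.98, "indirect"),  # boundary falls in the lower class
            (0.9, "indirect"),
            (0.84, "nonconserved"),
            (0.5, "nonconserved"),
            (0.0, "nonconserved"),
            (1.0, "direct"),
        ],
    )
    def test_thresholds(self, score, expected):
        assert classify(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2)

    def test_monotone_in_score(self):
        order = {"nonconserved": 0, "indirect": 1, "direct": 2}
        grid = np.linspace(0, 1, 501)
        ranks = [order[classify(s)] for s in grid]
        assert ranks == sorted(ranks)


def proj(rid, score, target=None):
    return ProjectionRecord(
        region_id=rid,
        source=GenomicInterval("chr1", 0, 500),
        score=score,
        target=target,
    )


class TestFunctionalConservation:
    def test_conserved_projection_into_desert_not_conserved(self):
        src = [dar(0, 500, species="mouse")]
        projections = {"d0": proj("d0", 0.99, GenomicInterval("chrT", 10_000, 10_500))}
        calls = functional_conservation(src, projections, [dar(0, 500)], ["d0"])
        assert not calls["functionally_conserved"].iloc[0]

    def test_nonconserved_projection_on_dar_not_conserved(self):
        # conservation gate applies before the overlap check
        src = [dar(0, 500, species="mouse")]
        projections = {"d0": proj("d0", 0.5, GenomicInterval("chrT", 100, 600))}
        calls = functional_conservation(src, projections, [dar(0, 500)], ["d0"])
        assert not calls["functionally_conserved"].iloc[0]

    def test_missing_target_interval_not_conserved(self):
        src = [dar(0, 500, species="mouse")]
        calls = functional_conservation(src, {"d0": proj("d0", 0.99)}, [dar(0, 500)], ["d0"])
        assert not calls["functionally_conserved"].iloc[0]

    def test_missing_projection_record_counts_nonconserved(self):
        src = [dar(0, 500, species="mouse")]
        calls = functional_conservation(src, {}, [dar(0, 500)], ["d0"])
        assert calls["conservation_class"].iloc[0] == "nonconserved"
        assert not calls["functionally_conserved"].iloc[0]

    def test_planted_conserved_count_recovered(self):
        rng = np.random.default_rng(17)
        targets = [dar(i * 2000, i * 2000 + 500) for i in range(50)]
        src, projections, ids, planted = [], {}, [], 0
        for i in range(200):
            rid = f"d{i}"
            conserved = rng.random() < 0.3
            score = 0.99 if conserved else 0.5
            if conserved:
                t = targets[int(rng.integers(50))].interval
                target = GenomicInterval("chrT", t.start + 100, t.start + 600)
                planted += 1
            else:
                k = int(rng.integers(50))  # gap between DARs k and k+1
                target = GenomicInterval("chrT", k * 2000 + 700, k * 2000 + 1200)
            src.append(dar(i * 1000, i * 1000 + 500, species="mouse", chrom="chr1"))
            projections[rid] = proj(rid, score, target)
            ids.append(rid)
        calls = functional_conservation(src, projections, targets, ids)
        assert int(calls["functionally_conserved"].sum()) == planted

    def test_best_overlap_tie_broken_leftmost(self):
        src = [dar(0, 500, tissue="ectoderm", species="mouse")]
        # two target DARs overlap the projection by the same amount
        targets = [
            dar(200, 400, tissue="mesenchyme"),
            dar(400, 600, tissue="ectoderm"),
        ]
        projections = {"d0": proj("d0", 0.99, GenomicInterval("chrT", 200, 600))}
        calls = functional_conservation(src, projections, targets, ["d0"])
        assert calls["target_tissue"].iloc[0] == "mesenchyme"  # leftmost wins the tie


class TestIdentityRetention:
    def test_all_same_tissue(self):
        calls = pd.DataFrame(
            {"functionally_conserved": [True, True], "identity_retained": [True, True]}
        )
        assert identity_retention(calls) == 1.0

    def test_no_conserved_dars_undefined(self):
        calls = pd.DataFrame({"functionally_conserved": [False], "identity_retained": [None]})
        assert np.isnan(identity_retention(calls))


class TestTissueRateRatio:
    def make_calls(self, ect_conserved, ect_total, mes_conserved, mes_total):
        return pd.DataFrame(
            {
                "tissue": ["ectoderm"] * ect_total + ["mesenchyme"] * mes_total,
                "functionally_conserved": (
                    [True] * ect_conserved + [False] * (ect_total - ect_conserved)
                    + [True] * mes_conserved + [False] * (mes_total - mes_conserved)
                ),
            }
        )

    def test_planted_fold(self):
        ratio, p, table = tissue_rate_ratio(self.make_calls(44, 100, 10, 100))
        assert ratio == pytest.approx(4.4)
        assert p < 0.001

    def test_identical_rates(self):
        ratio, p, _ = tissue_rate_ratio(self.make_calls(20, 100, 20, 100))
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_mesenchyme_rate_is_infinite(self):
        ratio, _, table = tissue_rate_ratio(self.make_calls(10, 50, 0, 50))
        assert np.isinf(ratio)
        assert table.loc[table["tissue"] == "mesenchyme", "n_conserved"].iloc[0] == 0

    def test_missing_tissue_rejected(self):
        calls = pd.DataFrame({"tissue": ["ectoderm"], "functionally_conserved": [True]})
        with pytest.raises(ValueError):
            tissue_rate_ratio(calls)


def test_projection_table_roundtrip(tmp_path):
    df = pd.DataFrame(
        {
            "region_id": ["a", "b"],
            "chrom": ["chr1", "chr1"],
            "start": [0, 1000],
            "end": [500, 1500],
            "score": [0.99, 0.5],
            "target_chrom": ["chrT", ""],
            "target_start": [100, ""],
            "target_end": [600, ""],
            "bridge": ["human", ""],
        }
    )
    p = tmp_path / "proj.tsv"
    df.to_csv(p, sep="\t", index=False)
    records = read_projection_table(p)
    assert records["a"].target == GenomicInterval("chrT", 100, 600)
    assert records["b"].target is None
    assert records["b"].score == 0.5


def test_summary_counts_by_population():
    calls = pd.DataFrame(
        {
            "population": ["a", "a", "b"],
            "functionally_conserved": [True, False, True],
        }
    )
    out = conservation_summary(calls).set_index("population")
    assert out.loc["a", "rate"] == 0.5
    assert out.loc["b", "n_conserved"] == 1
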