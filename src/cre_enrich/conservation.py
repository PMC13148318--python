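"""Cross-species conservation of regulatory regions from projection scores.

Regions are classified by their synteny-projection score: directly conserved
(score > 0.98), indirectly conserved (score > 0.84) or nonconserved
(score <= 0.84); a higher score means the position lies closer to conserved
synteny anchors. A differentially accessible region (DAR) counts as
functionally conserved when its projection is conserved AND the projected
coordinates overlap a DAR in the other species, irrespective of cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

CLASSES = ["direct", "indirect", "nonconserved"]
CONSERVED = ("direct", "indirect")


@dataclass(frozen=True)
class ProjectionRecord:
    region_id: str
    source: GenomicInterval
    score: float
    target: GenomicInterval | None = None  # absent when projection failed
    bridge: str | None = None

    def __post_init__(self):
        if not 0 <= self.score <= 1:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class DarRecord:
    interval: GenomicInterval
    population: str
    tissue: str  # 'ectoderm' or 'mesenchyme'
    species: str


def classify(score: float, direct_min: float = 0.98, indirect_min: float = 0.84) -> str:
    """Conservation class from a projection score.

    Strict thresholds: scores exactly at a boundary fall in the lower class,
    so the three classes partition [0, 1].
    """
    if not 0 <= score <= 1:
        raise ValueError(f"score must be in [0, 1], got {score}")
    if score > direct_min:
        return "direct"
    if score > indirect_min:
        return "indirect"
    return "nonconserved"


def _best_overlap(target: GenomicInterval, dars: list[DarRecord]) -> DarRecord | None:
    """Target DAR with the largest overlap; ties broken by leftmost target."""
    best, best_key = None, None
    for d in dars:
        if d.interval.chrom != target.chrom:
            continue
        ov = min(target.end, d.interval.end) - max(target.start, d.interval.start)
        if ov <= 0:
            continue
        key = (-ov, d.interval.start, d.interval.end)
        if best_key is None or key < best_key:
            best, best_key = d, key
    return best


def functional_conservation(
    dars_source: list[DarRecord],
    projections: dict[str, ProjectionRecord],
    dars_target: list[DarRecord],
    dar_ids: list[str] | None = None,
    direct_min: float = 0.98,
    indirect_min: float = 0.84,
) -> pd.DataFrame:
    """Per-source-DAR functional-conservation calls.

    A source DAR is functionally conserved iff its projection score is in a
    conserved class, the projection produced target coordinates, and those
    coordinates overlap >=1 bp of >=1 target-species DAR. DARs without a
    projection record are counted nonconserved (logged). Returns one row per
    source DAR with its class, call, and best-overlapping target DAR.
    """
    if dar_ids is None:
        dar_ids = [f"dar{i}" for i in range(len(dars_source))]
    rows = []
    n_missing = 0
    for dar, rid in zip(dars_source, dar_ids):
        proj = projections.get(rid)
        if proj is None:
            n_missing += 1
            cls, conserved, match = "nonconserved", False, None
        else:
            cls = classify(proj.score, direct_min, indirect_min)
            match = None
            conserved = False
            if cls in CONSERVED and proj.target is not None:
                match = _best_overlap(proj.target, dars_target)
                conserved = match is not None
        rows.append(
            {
                "region_id": rid,
                "population": dar.population,
                "tissue": dar.tissue,
                "conservation_class": cls,
                "functionally_conserved": conserved,
                "target_tissue": match.tissue if match else None,
                "identity_retained": (match.tissue == dar.tissue) if match else None,
            }
        )
    if n_missing:
        logger.warning(
            "%d source DARs lacked projection records; counted nonconserved",
            n_missing,
        )
    return pd.DataFrame(rows)


def conservation_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-population conserved counts and rates."""
    g = calls.groupby("population")["functionally_conserved"]
    out = g.agg(n_total="size", n_conserved="sum").reset_index()
    out["rate"] = out["n_conserved"] / out["n_total"]
    return out


def identity_retention(calls: pd.DataFrame) -> float:
    """Fraction of functionally conserved DARs whose best-overlapping target
    DAR shares the source tissue class; NaN when nothing is conserved."""
    conserved = calls[calls["functionally_conserved"]]
    if conserved.empty:
        return float("nan")
    return float(conserved["identity_retained"].mean())


def tissue_rate_ratio(calls: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Ectoderm vs mesenchyme functional-conservation rate ratio.

    Returns (ratio, p, 2x2 table); p is from a two-sided Fisher exact test on
    conserved x tissue. The ratio is inf when the mesenchyme rate is zero.
    """
    table = (
        calls.groupby("tissue")["functionally_conserved"]
        .agg(n_conserved="sum", n_total="size")
        .reindex(["ectoderm", "mesenchyme"])
    )
    if table["n_total"].isna().any() or (table["n_total"] == 0).any():
        raise ValueError("both tissue classes must be represented")
    rate = table["n_conserved"] / table["n_total"]
    ratio = (
        float(rate["ectoderm"] / rate["mesenchyme"])
        if rate["mesenchyme"] > 0
        else float("inf")
    )
    contingency = np.array(
        [
            [table.loc["ectoderm", "n_conserved"], table.loc["ectoderm", "n_total"] - table.loc["ectoderm", "n_conserved"]],
            [table.loc["mesenchyme", "n_conserved"], table.loc["mesenchyme", "n_total"] - table.loc["mesenchyme", "n_conserved"]],
        ]
    )
    _, p = fisher_exact(contingency, alternative="two-sided")
    return ratio, float(p), table.reset_index()


def read_projection_table(path_or_df) -> dict[str, ProjectionRecord]:
    """Projection TSV -> records keyed by region id.

    Columns: region_id, chrom, start, end, score, target_chrom, target_start,
    target_end, bridge; target columns may be empty when projection failed.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    out = {}
    for r in df.itertuples():
        target = None
        if pd.notna(r.target_chrom) and str(r.target_chrom):
            target = GenomicInterval(str(r.target_chrom), int(r.target_start), int(r.target_end))
        out[str(r.region_id)] = ProjectionRecord(
            region_id=str(r.region_id),
            source=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            score=float(r.score),
            target=target,
            bridge=getattr(r, "bridge", None),
        )
    return out
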