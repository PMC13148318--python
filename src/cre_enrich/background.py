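"""Matched background sampling: N region sets drawn from the tiled genome so
each set reproduces the foreground's joint (GC bin x annotation) histogram,
by stratified sampling without replacement within each set.

Each set gets its own generator seeded from (master seed, set index), so any
single set can be reproduced independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ANNOTATION_PRIORITY, EXCLUDED_STRATUM
from .intervals import overlaps_any

__all__ = ["SamplingPlan", "BackgroundSet", "build_pool", "sample_sets"]


class PoolExhaustedError(RuntimeError):
    """The global pool is smaller than the foreground."""


def _parse_stratum(stratum: str) -> tuple[int, str]:
    b, a = stratum.split("|")
    return int(b), a


def build_pool(
    tiles: pd.DataFrame,
    foreground: pd.DataFrame | None = None,
    exclude_overlapping: bool = False,
) -> pd.DataFrame:
    """Candidate background tiles grouped by stratum.

    Tiles in the excluded (undefined-GC) stratum are dropped. Optionally,
    tiles overlapping any foreground peak can be removed; this is off by
    default because tying the pool to the observed peak configuration makes
    the null anti-conservative (wherever the observed peaks happen to sit,
    the matching tiles vanish from the pool, deflating the null statistic).
    """
    pool = tiles[tiles["stratum"] != EXCLUDED_STRATUM].reset_index(drop=True)
    if exclude_overlapping and foreground is not None and len(foreground):
        hit = overlaps_any(pool, foreground)
        pool = pool[~hit].reset_index(drop=True)
    return pool


@dataclass
class SamplingPlan:
    required: dict[str, int]  # per-stratum demand, from the foreground
    pool: pd.DataFrame  # stratified candidate tiles
    n_sets: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        demand = sum(self.required.values())
        if demand > len(self.pool):
            raise PoolExhaustedError(
                f"foreground needs {demand} regions but pool holds "
                f"{len(self.pool)} tiles"
            )


@dataclass
class BackgroundSet:
    index: int
    regions: pd.DataFrame
    achieved: dict[str, int]
    seed: int
    fallbacks: list[tuple[str, str, int]] = field(default_factory=list)


def plan_from_foreground(
    foreground: pd.DataFrame, pool: pd.DataFrame, n_sets: int = 1000, seed: int = 0
) -> SamplingPlan:
    required = foreground["stratum"].value_counts().to_dict()
    required.pop(EXCLUDED_STRATUM, None)
    return SamplingPlan(required=required, pool=pool, n_sets=n_sets, seed=seed)


def _fallback_order(stratum: str, all_strata: list[str]) -> list[str]:
    """Substitution preference when a stratum is exhausted: nearest GC bin
    with the same annotation first, then same GC bin with priority-adjacent
    annotation, then everything else by joint distance."""
    b, a = _parse_stratum(stratum)
    pri = {cls: i for i, cls in enumerate(ANNOTATION_PRIORITY)}

    def key(other: str):
        ob, oa = _parse_stratum(other)
        same_annot = oa == a
        same_bin = ob == b
        if same_annot:
            tier = 0
        elif same_bin:
            tier = 1
        else:
            tier = 2
        return (tier, abs(ob - b), abs(pri[oa] - pri[a]), ob, pri[oa])

    return sorted((s for s in all_strata if s != stratum), key=key)


def sample_sets(plan: SamplingPlan) -> list[BackgroundSet]:
    """Draw the N background sets.

    Within a set, each stratum is sampled uniformly without replacement to
    the foreground's count; exhaustion triggers the logged fallback. The set
    size always equals the foreground size. Sets are independent (regions may
    recur across sets) and individually reproducible.
    """
    pool = plan.pool.reset_index(drop=True)
    strata = sorted(plan.required)
    by_stratum = {
        s: grp.index.to_numpy() for s, grp in pool.groupby("stratum", sort=True)
    }
    all_strata = sorted(by_stratum)
    sets = []
    for set_idx in range(plan.n_sets):
        rng = np.random.default_rng([plan.seed, set_idx])
        taken = np.zeros(len(pool), dtype=bool)
        chosen: list[np.ndarray] = []
        achieved: dict[str, int] = {}
        fallbacks: list[tuple[str, str, int]] = []
        for stratum in strata:
            need = plan.required[stratum]
            avail = by_stratum.get(stratum, np.empty(0, dtype=int))
            avail = avail[~taken[avail]]
            take_n = min(need, len(avail))
            if take_n:
                picked = rng.choice(avail, size=take_n, replace=False)
                taken[picked] = True
                chosen.append(picked)
            short = need - take_n
            if short:
                for other in _fallback_order(stratum, all_strata):
                    o_avail = by_stratum[other]
                    o_avail = o_avail[~taken[o_avail]]
                    if not len(o_avail):
                        continue
                    n_borrow = min(short, len(o_avail))
                    picked = rng.choice(o_avail, size=n_borrow, replace=False)
                    taken[picked] = True
                    chosen.append(picked)
                    fallbacks.append((stratum, other, n_borrow))
                    short -= n_borrow
                    if not short:
                        break
                if short:
                    raise PoolExhaustedError(
                        f"set {set_idx}: stratum {stratum} short by {short} "
                        "after exhausting all fallbacks"
                    )
            achieved[stratum] = take_n  # own-stratum draws; borrows are logged
        idx = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)
        regions = pool.loc[idx].reset_index(drop=True)
        sets.append(
            BackgroundSet(
                index=set_idx,
                regions=regions,
                achieved=achieved,
                seed=plan.seed,
                fallbacks=fallbacks,
            )
        )
    return sets
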