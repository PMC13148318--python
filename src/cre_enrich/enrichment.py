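"""Enrichment of peaks within LD blocks against matched background sets.

Two one-sided statistics: overlap frequency (number of peaks touching any
block) and peak density (overlapping peaks per Mb of merged block length).
Significance is the empirical p-value: the proportion of background sets
whose statistic is equal to or greater than the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import count_overlapping, merge_intervals, total_length


@dataclass
class EnrichmentResult:
    statistic: str  # 'overlap_frequency' or 'peak_density'
    observed: float
    null: np.ndarray
    empirical_p: float
    fold: float  # observed / mean(null); NaN when mean(null) == 0

    @property
    def n_sets(self) -> int:
        return len(self.null)

    @property
    def p_bound(self) -> str | None:
        """Resolution bound printed when no background set reaches the
        observed value (p = 0 -> '< 1/N')."""
        if self.empirical_p == 0:
            return f"< {1 / self.n_sets:g}"
        return None


def overlap_frequency(peaks, blocks) -> int:
    """Peaks overlapping >=1 bp of >=1 block, each peak counted once."""
    return count_overlapping(peaks, blocks)


def peak_density(peaks, blocks) -> float:
    """Overlapping peaks per megabase of merged block length."""
    merged = merge_intervals(blocks)
    length_mb = total_length(merged) / 1e6
    if length_mb == 0:
        raise ValueError("blocks have zero total length")
    return overlap_frequency(peaks, merged) / length_mb


def empirical_p(observed: float, null_values) -> float:
    """Proportion of background sets with a statistic equal to or greater
    than the observed value. No add-one correction; p = 0 means 'below the
    resolution 1/N' and is reported with that bound."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values must be non-empty")
    return float(np.mean(null_values >= observed))


def _result(name: str, observed: float, null: np.ndarray) -> EnrichmentResult:
    mean_null = float(np.mean(null))
    return EnrichmentResult(
        statistic=name,
        observed=float(observed),
        null=null,
        empirical_p=empirical_p(observed, null),
        fold=float(observed / mean_null) if mean_null > 0 else float("nan"),
    )


def run_enrichment(
    peaks, blocks, background_sets
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Both statistics on the observed peaks, with null values from the same
    statistic applied to each background set against the same blocks."""
    if not len(background_sets):
        raise ValueError("need >=1 background set")
    merged = merge_intervals(blocks)
    length_mb = total_length(merged) / 1e6
    if length_mb == 0:
        raise ValueError("blocks have zero total length")
    obs_count = overlap_frequency(peaks, merged)
    null_counts = np.array(
        [
            overlap_frequency(bg.regions if hasattr(bg, "regions") else bg, merged)
            for bg in background_sets
        ],
        dtype=float,
    )
    overlap_res = _result("overlap_frequency", obs_count, null_counts)
    density_res = _result(
        "peak_density", obs_count / length_mb, null_counts / length_mb
    )
    return overlap_res, density_res


def results_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "statistic": r.statistic,
                "observed": r.observed,
                "null_mean": float(np.mean(r.null)),
                "null_sd": float(np.std(r.null, ddof=1)) if r.n_sets > 1 else 0.0,
                "fold": r.fold,
                "empirical_p": r.empirical_p,
                "p_bound": r.p_bound or "",
                "n_sets": r.n_sets,
            }
        )
    return pd.DataFrame(rows)
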