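"""Core genomic-interval types and interval algebra.

All coordinates inside the package are 0-based, half-open (BED convention).
1-based formats (VCF, GFF3) are converted at the reader boundary, so overlap
and merge logic never has to reason about conventions.

Bulk interval sets are carried as pandas DataFrames with at least the columns
``chrom``, ``start``, ``end``; single intervals as :class:`GenomicInterval`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span on a named chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeLayout:
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, lengths: dict[str, int]):
        if len(set(lengths)) != len(lengths):
            raise ValueError("duplicate chromosome names")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has length {length} <= 0")
        self.lengths = dict(lengths)

    def __iter__(self):
        return iter(self.lengths)

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self.lengths == other.lengths

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.lengths), "length": list(self.lengths.values())}
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Abutting intervals ([0,10) vs [10,20)) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def intervals_to_frame(intervals) -> pd.DataFrame:
    """Normalise a list of GenomicInterval or a DataFrame to a DataFrame."""
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals],
        columns=INTERVAL_COLUMNS,
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def merge_intervals(intervals) -> pd.DataFrame:
    """Merge overlapping intervals; abutting half-open intervals stay separate.

    Returns a DataFrame sorted by (chrom, start) whose intervals are pairwise
    non-overlapping and cover exactly the same bases as the input.
    """
    df = intervals_to_frame(intervals)
    if df.empty:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    out_chrom, out_start, out_end = [], [], []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # strict: abutting intervals do not merge
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def total_length(intervals) -> int:
    """Total bases covered by the (possibly overlapping) interval set."""
    merged = merge_intervals(intervals)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())


def overlaps_any(query, subject) -> np.ndarray:
    """Boolean vector: does each query interval overlap >=1 subject interval?

    Subjects are merged first, then each query is checked against the sorted
    non-overlapping subject list with a binary search, so the cost is
    O((n+m) log m) rather than the naive n*m.
    """
    qdf = intervals_to_frame(query)
    merged = merge_intervals(subject)
    result = np.zeros(len(qdf), dtype=bool)
    if qdf.empty or merged.empty:
        return result
    for chrom, sub in merged.groupby("chrom", sort=False):
        mask = (qdf["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        q_start = qdf.loc[mask, "start"].to_numpy()
        q_end = qdf.loc[mask, "end"].to_numpy()
        # candidate: rightmost subject with start < q_end
        idx = np.searchsorted(starts, q_end, side="left") - 1
        hit = (idx >= 0) & (ends[np.clip(idx, 0, None)] > q_start)
        result[mask] = hit
    return result


def count_overlapping(query, subject) -> int:
    """Number of query intervals overlapping at least one subject interval."""
    return int(overlaps_any(query, subject).sum())
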