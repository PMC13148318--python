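"""Haplotype r-squared and LD-block construction around GWAS hits.

The procedure: keep genome-wide-significant SNPs (P < 5e-8), pick the nearest
panel variants up- and downstream of each hit as proxies, and span the block
from the most upstream to the most downstream panel variant, within a window
around the hit, whose r2 with either proxy reaches the threshold (default
0.8). Overlapping blocks are merged, pooling blocks across population groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals
from .io import HaplotypePanel, SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdParams:
    """Thresholds of the block-building procedure.

    window is the total width of the search window centred on the SNP
    (i.e. the scan covers pos +/- window/2).
    """

    p_threshold: float = 5e-8
    window: int = 500_000
    r2_min: float = 0.8

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")


@dataclass
class LdBlock:
    interval: GenomicInterval
    source_snps: list[str]
    proxy_ids: tuple[str, str] | None = None
    group: str | None = None

    def __post_init__(self):
        if not self.source_snps:
            raise ValueError("LdBlock needs >=1 source SNP")


class NoProxyError(ValueError):
    """No panel variant within the search window on either side of the SNP."""


def filter_gwas(snps: list[SnpRecord], p_threshold: float = 5e-8) -> list[SnpRecord]:
    """Keep SNPs strictly below the genome-wide significance threshold."""
    return [s for s in snps if s.p_value < p_threshold]


def r2(x, y) -> float:
    """Squared haplotype correlation between two biallelic variants.

    With allele frequencies p = mean(x), q = mean(y) and haplotype frequency
    p_xy = mean(x*y), D = p_xy - p*q and r2 = D^2 / (p(1-p) q(1-q)).
    Returns NaN for a monomorphic variant (no LD information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("r2 needs two equal-length vectors of length >= 2")
    p, q = x.mean(), y.mean()
    den = p * (1 - p) * q * (1 - q)
    if den == 0:
        return float("nan")
    d = (x * y).mean() - p * q
    return float(d * d / den)


def _r2_profile(panel: HaplotypePanel, cols: np.ndarray, anchor: int) -> np.ndarray:
    """r2 of the anchor variant against each variant in ``cols`` (vectorised).

    Monomorphic variants yield NaN.
    """
    X = panel.alleles[:, cols].astype(float)
    y = panel.alleles[:, anchor].astype(float)
    p = X.mean(axis=0)
    q = y.mean()
    d = (X * y[:, None]).mean(axis=0) - p * q
    den = p * (1 - p) * q * (1 - q)
    out = np.full(len(cols), np.nan)
    ok = den > 0
    out[ok] = d[ok] ** 2 / den[ok]
    return out


def select_proxies(snp: SnpRecord, panel: HaplotypePanel, window: int = 500_000) -> tuple[int, int]:
    """Indices of the nearest panel variants downstream (pos <= snp) and
    upstream (pos >= snp) of the GWAS SNP, within +/- window/2.

    If the SNP itself is in the panel both proxies are that variant; if only
    one side has a variant in the window, it serves as both proxies.
    """
    half = window // 2
    pos = panel.positions
    i = int(np.searchsorted(pos, snp.pos, side="left"))
    down = None
    if i < len(pos) and pos[i] == snp.pos:
        return i, i
    if i > 0 and snp.pos - pos[i - 1] <= half:
        down = i - 1
    up = i if i < len(pos) and pos[i] - snp.pos <= half else None
    if down is None and up is None:
        raise NoProxyError(
            f"no panel variant within +/-{half} bp of {snp.id} at "
            f"{snp.chrom}:{snp.pos}"
        )
    if down is None:
        down = up
    if up is None:
        up = down
    return down, up


def build_block(snp: SnpRecord, panel: HaplotypePanel, params: LdParams = LdParams()) -> LdBlock:
    """LD block around one significant SNP.

    Panel variants within +/- window/2 of the SNP are marked linked when their
    r2 with either proxy reaches r2_min; the block spans the outermost linked
    variants (the proxies are always linked to themselves). Coordinates are
    returned 0-based half-open.
    """
    down, up = select_proxies(snp, panel, params.window)
    half = params.window // 2
    pos = panel.positions
    lo = int(np.searchsorted(pos, snp.pos - half, side="left"))
    hi = int(np.searchsorted(pos, snp.pos + half, side="right"))
    cols = np.arange(lo, hi)
    prof = np.fmax(_r2_profile(panel, cols, down), _r2_profile(panel, cols, up))
    linked = np.zeros(len(cols), dtype=bool)
    finite = ~np.isnan(prof)
    linked[finite] = prof[finite] >= params.r2_min
    linked[np.searchsorted(cols, [down, up])] = True  # self-linkage
    span = pos[cols[linked]]
    start, end = int(span.min()) - 1, int(span.max())
    if end <= start:  # single linked variant -> 1-bp block
        end = start + 1
    return LdBlock(
        interval=GenomicInterval(panel.chrom, start, end),
        source_snps=[snp.id],
        proxy_ids=(panel.ids[down], panel.ids[up]),
        group=snp.group,
    )


def build_blocks(
    snps: list[SnpRecord],
    panels: dict[str, HaplotypePanel] | HaplotypePanel,
    params: LdParams = LdParams(),
    on_no_proxy: str = "degenerate",
) -> list[LdBlock]:
    """Blocks for a list of significant SNPs.

    ``panels`` maps population group to its haplotype panel (or a single
    panel shared by all groups). A SNP without any proxy yields a 1-bp
    degenerate block with a warning, or is dropped when
    ``on_no_proxy='drop'``.
    """
    blocks = []
    for snp in snps:
        panel = panels if isinstance(panels, HaplotypePanel) else panels[snp.group]
        if panel.chrom != snp.chrom:
            continue
        try:
            blocks.append(build_block(snp, panel, params))
        except NoProxyError:
            if on_no_proxy == "drop":
                logger.warning("dropping %s: no proxy in window", snp.id)
                continue
            logger.warning("no proxy for %s: emitting 1-bp block", snp.id)
            blocks.append(
                LdBlock(
                    interval=GenomicInterval(snp.chrom, snp.pos - 1, snp.pos),
                    source_snps=[snp.id],
                    group=snp.group,
                )
            )
    return blocks


def merge_blocks(blocks: list[LdBlock]) -> list[LdBlock]:
    """Merge overlapping blocks (pooled across groups), unioning provenance.

    Output is sorted by (chrom, start); abutting half-open blocks are kept
    separate; covered bases are conserved.
    """
    if not blocks:
        return []
    order = sorted(
        range(len(blocks)),
        key=lambda i: (blocks[i].interval.chrom, blocks[i].interval.start, blocks[i].interval.end),
    )
    merged: list[LdBlock] = []
    for i in order:
        b = blocks[i]
        if merged:
            last = merged[-1]
            if (
                last.interval.chrom == b.interval.chrom
                and b.interval.start < last.interval.end
            ):
                merged[-1] = LdBlock(
                    interval=GenomicInterval(
                        last.interval.chrom,
                        last.interval.start,
                        max(last.interval.end, b.interval.end),
                    ),
                    source_snps=sorted(set(last.source_snps) | set(b.source_snps)),
                    group=last.group if last.group == b.group else None,
                )
                continue
        merged.append(
            LdBlock(
                interval=b.interval,
                source_snps=list(b.source_snps),
                proxy_ids=b.proxy_ids,
                group=b.group,
            )
        )
    return merged


def blocks_to_frame(blocks: list[LdBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.interval.chrom for b in blocks],
            "start": [b.interval.start for b in blocks],
            "end": [b.interval.end for b in blocks],
            "name": [";".join(b.source_snps) for b in blocks],
        }
    )
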