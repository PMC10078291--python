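"""Nascent-transcription metrics: pause summits, pause indices, composites.

The promoter-proximal pause summit is the point of maximum sense-strand
signal within 1 kb downstream of the TSS (ties broken toward the TSS); the
pause region is the 50-bp window around it and the gene body starts 250 bp
downstream of the summit.  The pause index (PI) is the ratio of pause-region
density to gene-body density (signal per bp).  Differential transcription on
gene-body counts reuses the negative-binomial Wald machinery of
:mod:`kineticnet.accessibility`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .accessibility import differential_test
from .io import Gene, SignalTrack

__all__ = [
    "PAUSE_SEARCH_BP",
    "PAUSE_REGION_BP",
    "BODY_OFFSET_BP",
    "PauseMetrics",
    "pause_metrics",
    "differential_transcription",
    "composite_profile",
    "call_divergent_peaks",
    "expression_matrix",
]

PAUSE_SEARCH_BP = 1000
PAUSE_REGION_BP = 50
BODY_OFFSET_BP = 250  # body starts this far downstream of the pause summit


@dataclass(frozen=True)
class PauseMetrics:
    """Pause summit/region and densities for one gene at one time point.

    ``pause_index`` is NaN (and ``ok`` False) when the gene is flagged:
    zero signal in the summit search window or zero body density.
    """

    gene: str
    summit: int | None
    pause_start: int | None
    pause_end: int | None
    pause_density: float
    body_density: float
    pause_index: float

    @property
    def ok(self) -> bool:
        return self.summit is not None and np.isfinite(self.pause_index)


def _sense_window(gene: Gene) -> tuple[int, int]:
    """[start, end) of the 1-kb summit search window, strand-aware."""
    if gene.strand == "+":
        return gene.tss, gene.tss + PAUSE_SEARCH_BP
    return gene.tss - PAUSE_SEARCH_BP + 1, gene.tss + 1


def pause_metrics(gene: Gene, signal: SignalTrack) -> PauseMetrics:
    """Summit, 50-bp pause region, body density and PI for one gene.

    Requires the gene to extend at least 500 bp past the pause region.
    """
    if len(gene) < PAUSE_SEARCH_BP:
        raise ValueError(f"gene {gene.name} shorter than the pause search window")
    w0, w1 = _sense_window(gene)
    vals = signal.values(gene.chrom, w0, w1, gene.strand)
    if vals.sum() <= 0:
        return PauseMetrics(gene.name, None, None, None, 0.0, 0.0, float("nan"))
    if gene.strand == "+":
        summit = w0 + int(np.argmax(vals))  # leftmost max = toward the TSS
        p0, p1 = summit - 25, summit + 25
        b0, b1 = summit + BODY_OFFSET_BP, gene.end
    else:
        rev = vals[::-1]
        summit = w1 - 1 - int(np.argmax(rev))  # rightmost max = toward the TSS
        p0, p1 = summit - 24, summit + 26  # mirror image of the + convention
        b0, b1 = gene.start, summit - BODY_OFFSET_BP + 1
    if b1 - b0 < 500:
        raise ValueError(f"gene {gene.name}: body region shorter than 500 bp")
    pause_density = signal.sum(gene.chrom, p0, p1, gene.strand) / PAUSE_REGION_BP
    body_density = signal.sum(gene.chrom, b0, b1, gene.strand) / (b1 - b0)
    pi = pause_density / body_density if body_density > 0 else float("nan")
    return PauseMetrics(gene.name, summit, p0, p1, pause_density, body_density, pi)


def differential_transcription(body_counts: pd.DataFrame, design: pd.DataFrame,
                               time_a: int, time_b: int,
                               q_threshold: float = 0.05,
                               **kwargs) -> pd.DataFrame:
    """Differential gene-body transcription; adds an activated/repressed label.

    Genes with zero counts in both groups are excluded from the output
    rather than called.
    """
    calls = differential_test(body_counts, design, time_a, time_b, q_threshold,
                              **kwargs)
    calls = calls[(calls["mean_a"] > 0) | (calls["mean_b"] > 0)].copy()
    calls["gene_class"] = calls["direction"].map(
        {"up": "activated", "down": "repressed", "none": "unchanged"})
    return calls


def composite_profile(anchors: Sequence[tuple[str, int, str]], signal: SignalTrack,
                      half_window: int = 500) -> pd.DataFrame:
    """Mean sense/antisense signal around anchors, in transcription direction.

    Anchors are (chrom, position, strand); minus-strand anchors are mirrored
    so offset +d always points downstream of the anchor.  Anchors whose
    windows run off the chromosome start are clipped with per-offset
    denominators.  Columns: offset, sense, antisense, n.
    """
    if len(anchors) == 0:
        raise ValueError("need at least one anchor")
    offsets = np.arange(-half_window, half_window + 1)
    width = len(offsets)
    sense_sum = np.zeros(width)
    anti_sum = np.zeros(width)
    denom = np.zeros(width)
    for chrom, pos, strand in anchors:
        lo, hi = pos - half_window, pos + half_window + 1
        clip_lo = max(lo, 0)
        plus = signal.values(chrom, clip_lo, hi, "+")
        minus = signal.values(chrom, clip_lo, hi, "-")
        pad = clip_lo - lo
        window = slice(pad, width)
        if strand == "+":
            sense_sum[window] += plus
            anti_sum[window] += minus
            denom[window] += 1
        else:
            # mirror: genomic left = downstream; sense = minus strand
            window = slice(0, width - pad)
            sense_sum[window] += minus[::-1]
            anti_sum[window] += plus[::-1]
            denom[window] += 1
    denom = np.maximum(denom, 1)
    return pd.DataFrame({"offset": offsets, "sense": sense_sum / denom,
                         "antisense": anti_sum / denom, "n": denom.astype(int)})


def expression_matrix(body_density: pd.DataFrame,
                      floor_quantile: float = 0.25) -> pd.DataFrame:
    """Boolean genes x time-points matrix of "expressed" status.

    A gene counts as expressed at a time point when its body density exceeds
    the ``floor_quantile`` quantile of the nonzero body densities at that
    time point.
    """
    out = {}
    for t in body_density.columns:
        col = body_density[t]
        nonzero = col[col > 0]
        floor = float(np.quantile(nonzero, floor_quantile)) if len(nonzero) else 0.0
        out[t] = col > floor
    return pd.DataFrame(out)


def call_divergent_peaks(signal: SignalTrack, chrom: str, start: int, end: int,
                         threshold: float, max_separation: int = 300,
                         ) -> list[tuple[str, int, int, int]]:
    """Simple divergent-transcription caller (a stand-in heuristic).

    Reports (chrom, center, minus_pos, plus_pos) wherever a plus-strand local
    maximum above ``threshold`` has a minus-strand maximum above threshold
    within ``max_separation`` bp upstream of it.  This is a deliberately
    simple rule-based substitute for learned bidirectional-peak detection and
    is not equivalent to it.
    """
    plus = signal.values(chrom, start, end, "+")
    minus = signal.values(chrom, start, end, "-")

    def local_maxima(arr):
        above = arr >= threshold
        idx = np.flatnonzero(above)
        peaks = []
        for i in idx:
            left = arr[i - 1] if i > 0 else -np.inf
            right = arr[i + 1] if i < len(arr) - 1 else -np.inf
            if arr[i] >= left and arr[i] > right:
                peaks.append(i)
        return np.array(peaks, dtype=int)

    plus_peaks = local_maxima(plus)
    minus_peaks = local_maxima(minus)
    out = []
    for p in plus_peaks:
        upstream = minus_peaks[(minus_peaks < p) & (minus_peaks >= p - max_separation)]
        if len(upstream):
            m = int(upstream[np.argmax(minus[upstream])])
            out.append((chrom, start + (m + p) // 2, start + m, start + int(p)))
    return out
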