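"""PWM scanning, motif-density composites, and direction-of-effect assignment.

Scoring is log-odds in bits against a background model (uniform by default).
Score p-values are exact: per-position scores are discretized onto an integer
lattice (1000 bins across the motif's total score range) and the full null
score distribution is obtained by dynamic programming (convolution over
positions under the background).  Both the reported p-values and the hit
threshold live on this lattice, so they agree exactly with brute-force
enumeration over all sequences scored with the same lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotifModel",
    "MotifHit",
    "consensus",
    "scan_pwm",
    "scan_peaks",
    "motif_density",
    "assign_direction",
    "INCREASE_CLASSES",
    "DECREASE_CLASSES",
]

_BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.int8)  # everything else (incl. N) -> 4
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

INCREASE_CLASSES = frozenset(
    {"immediate_increase", "transient_increase", "gradual_increase"})
DECREASE_CLASSES = frozenset({"transient_decrease", "gradual_decrease"})

DEFAULT_PVALUE_THRESHOLD = 1e-4
SCORE_LATTICE_BINS = 1000


def _encode(sequence: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifModel:
    """A TF-family position weight matrix with its direction of effect.

    ``function`` records whether binding of the family opens ("opener") or
    closes ("closer") local chromatin; it is assigned from single-motif
    dynamic peaks by :func:`assign_direction` and drives the direction rule
    of trans-edge inference.
    """

    name: str
    pwm: np.ndarray  # (w, 4) probabilities, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD
    function: str = "unassigned"  # opener | closer | unassigned

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("PWM must be (w, 4)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if not 0 < self.pvalue_threshold < 1:
            raise ValueError("pvalue threshold must lie in (0, 1)")
        self._lattice_cache = None

    def __len__(self):
        return self.pwm.shape[0]

    @property
    def bit_scores(self) -> np.ndarray:
        """(w, 5) log2-odds matrix; column 4 is the N score (0 bits)."""
        with np.errstate(divide="ignore"):
            s = np.log2(np.maximum(self.pwm, 1e-300) / self.background)
        return np.hstack([s, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.bit_scores[:, :4].max(axis=1).sum())

    # -- exact score distribution on the integer lattice ------------------
    def _lattice(self):
        if self._lattice_cache is None:
            s = self.bit_scores  # (w, 5)
            row_min = s[:, :4].min(axis=1)
            span = float((s[:, :4].max(axis=1) - row_min).sum())
            scale = (SCORE_LATTICE_BINS - 1) / span if span > 0 else 1.0
            ints = np.rint((s - row_min[:, None]) * scale).astype(np.int64)
            max_total = int(ints[:, :4].max(axis=1).sum())
            pmf = np.zeros(max_total + 1)
            pmf[0] = 1.0
            for i in range(len(self)):
                row = np.zeros(int(ints[i, :4].max()) + 1)
                for j in range(4):
                    row[ints[i, j]] += self.background[j]
                pmf = np.convolve(pmf, row)
            # survival[t] = P(lattice score >= t) under the background
            survival = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
            self._lattice_cache = (ints, scale, row_min, pmf, survival)
        return self._lattice_cache

    def lattice_scores(self) -> np.ndarray:
        """(w, 5) integer lattice score matrix (column 4 = N)."""
        return self._lattice()[0]

    def lattice_pvalue(self, lattice_total: int) -> float:
        """Exact P(score >= lattice_total) under the background model."""
        _ints, _scale, _row_min, _pmf, survival = self._lattice()
        t = int(np.clip(lattice_total, 0, len(survival) - 1))
        return float(survival[t])

    def threshold_lattice_score(self, pvalue: float | None = None) -> int | None:
        """Smallest lattice score whose exact p-value is <= ``pvalue``.

        Returns None when even the maximal score is less extreme than the
        requested p-value (possible for short matrices).
        """
        if pvalue is None:
            pvalue = self.pvalue_threshold
        *_rest, survival = self._lattice()
        ok = np.nonzero(survival[:-1] <= pvalue)[0]
        return int(ok[0]) if len(ok) else None

    def reverse_complement(self) -> "MotifModel":
        m = MotifModel(self.name, self.pwm[::-1, ::-1].copy(), self.background.copy(),
                       self.pvalue_threshold, self.function)
        return m


def consensus(motif: MotifModel) -> str:
    return "".join(_BASES[j] for j in motif.pwm.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence inside a scanned sequence."""

    offset: int  # leftmost position of the match on the forward strand
    strand: str
    score: float  # log2 odds, bits
    score_fraction: float  # score / max achievable score
    pvalue: float


def _window_lattice_totals(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    w = ints.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    totals = np.zeros(n, dtype=np.int64)
    for i in range(w):
        totals += ints[i, codes[i:i + n]]
    return totals


def _window_bit_scores(codes: np.ndarray, bits: np.ndarray) -> np.ndarray:
    w = bits.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for i in range(w):
        scores += bits[i, codes[i:i + n]]
    return scores


def scan_pwm(sequence: str, motif: MotifModel,
             pvalue_threshold: float | None = None) -> list[MotifHit]:
    """Scan both strands of ``sequence``; return hits at the exact-p threshold.

    A window is a hit when its lattice score reaches the smallest lattice
    score with exact p-value <= the threshold (default 1e-4).  Windows
    containing N score those positions as background (0-bit contribution).
    A PWM longer than the sequence yields an empty result.
    """
    hits: list[MotifHit] = []
    if len(motif) > len(sequence):
        return hits
    codes = _encode(sequence)
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        # share the forward lattice for '-' so both strands use one threshold
        ints = m.lattice_scores() if strand == "+" else motif.lattice_scores()[::-1, :][:, [3, 2, 1, 0, 4]]
        bits = m.bit_scores
        thresh = motif.threshold_lattice_score(pvalue_threshold)
        if thresh is None:
            continue
        totals = _window_lattice_totals(codes, ints)
        scores = _window_bit_scores(codes, bits)
        for idx in np.nonzero(totals >= thresh)[0]:
            hits.append(MotifHit(
                offset=int(idx), strand=strand, score=float(scores[idx]),
                score_fraction=float(scores[idx] / motif.max_score),
                pvalue=motif.lattice_pvalue(int(totals[idx])),
            ))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_peaks(peaks, genome: Mapping[str, str], motifs: Sequence[MotifModel],
               pvalue_threshold: float | None = None) -> pd.DataFrame:
    """Scan every peak sequence with every motif; tidy hit table out."""
    rows = []
    for peak in peaks:
        seq = genome[peak.chrom][peak.start:peak.end]
        for motif in motifs:
            for h in scan_pwm(seq, motif, pvalue_threshold):
                rows.append((peak.name, motif.name, h.offset, h.strand, h.score,
                             h.score_fraction, h.pvalue))
    return pd.DataFrame(rows, columns=["peak", "family", "offset", "strand",
                                       "score", "score_fraction", "pvalue"])


def motif_density(peaks, hits: pd.DataFrame, family: str,
                  peak_classes: Mapping[str, str], half_window: int = 200,
                  motif_width: int | None = None) -> pd.DataFrame:
    """Score-fraction-weighted motif density around peak summits, per class.

    Classes are collapsed to increased / decreased / nondynamic.  The trace
    value at offset d is the summed hit weight at summit+d divided by the
    number of peaks in the class.
    """
    groups = {"increased": [], "decreased": [], "nondynamic": []}
    for p in peaks:
        cls = peak_classes.get(p.name, "nondynamic")
        if cls in INCREASE_CLASSES:
            groups["increased"].append(p)
        elif cls in DECREASE_CLASSES:
            groups["decreased"].append(p)
        else:
            groups["nondynamic"].append(p)
    for label, members in groups.items():
        if not members:
            raise ValueError(f"empty peak class {label!r}")

    fam_hits = hits[hits["family"] == family]
    by_peak = {k: v for k, v in fam_hits.groupby("peak")}
    offsets = np.arange(-half_window, half_window + 1)
    out = {"offset": offsets}
    for label, members in groups.items():
        trace = np.zeros_like(offsets, dtype=float)
        for p in members:
            sub = by_peak.get(p.name)
            if sub is None:
                continue
            w = motif_width if motif_width is not None else 0
            centers = p.start + sub["offset"].to_numpy() + w // 2 - p.summit
            weights = sub["score_fraction"].to_numpy()
            sel = (centers >= -half_window) & (centers <= half_window)
            np.add.at(trace, centers[sel] + half_window, weights[sel])
        out[label] = trace / len(members)
    return pd.DataFrame(out)


def assign_direction(hits: pd.DataFrame, peak_classes: Mapping[str, str],
                     motifs: Sequence[MotifModel] | None = None,
                     ) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Assign opener/closer function per family from single-motif dynamic peaks.

    A dynamic peak counts for a family only when that family's motif is the
    sole family motif it contains.  A family is an opener when >50% of its
    single-motif dynamic peaks fall in increase classes, a closer when >50%
    fall in decrease classes, and unassigned on an exact tie (or with no
    single-motif dynamic peaks).  When ``motifs`` is given, the assigned
    functions are written back onto the models.
    """
    dynamic = {p for p, c in peak_classes.items()
               if c in INCREASE_CLASSES or c in DECREASE_CLASSES}
    fams_per_peak = hits.groupby("peak")["family"].agg(lambda s: frozenset(s))
    single = {peak: next(iter(fams)) for peak, fams in fams_per_peak.items()
              if len(fams) == 1 and peak in dynamic}

    families = sorted(hits["family"].unique())
    functions: dict[str, str] = {}
    isolated: dict[str, list[str]] = {f: [] for f in families}
    for peak, fam in single.items():
        isolated[fam].append(peak)
    for fam in families:
        peaks = isolated[fam]
        n_up = sum(peak_classes[p] in INCREASE_CLASSES for p in peaks)
        n_down = sum(peak_classes[p] in DECREASE_CLASSES for p in peaks)
        total = len(peaks)
        if total and n_up * 2 > total:
            functions[fam] = "opener"
        elif total and n_down * 2 > total:
            functions[fam] = "closer"
        else:
            functions[fam] = "unassigned"
    if motifs is not None:
        for m in motifs:
            if m.name in functions:
                m.function = functions[m.name]
    return functions, isolated
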