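"""Readers and writers for the plain-text genomics formats the pipeline touches.

All coordinates are 0-based, half-open (BED native) everywhere in the package.
Supported formats: BED6 / BED6+1 peak files (7th column = summit offset from
``start``), 6-column gene tables, 4-column bedGraph signal (one file per
strand), MEME minimal position weight matrices, and network edge lists
(TSV + GraphML via :mod:`networkx`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "Gene",
    "SignalTrack",
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_signal_pair",
    "write_signal_pair",
    "read_pwm",
    "write_pwm",
    "write_network",
    "read_network_tsv",
    "load_config",
    "save_config",
]


class ParseError(ValueError):
    """Malformed input line; carries the offending file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals; 0 if they overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(self.start, other.start) - min(self.end, other.end) if (
            self.end <= other.start or other.end <= self.start
        ) else 0


@dataclass(frozen=True)
class Peak:
    """An accessibility peak; summit stored as an offset from ``start``."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    summit_offset: int = -1  # -1 => midpoint

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"peak {self.name}: end <= start")
        off = self.summit_offset
        if off == -1:
            object.__setattr__(self, "summit_offset", (self.end - self.start) // 2)
        elif not 0 <= off < self.end - self.start:
            raise ValueError(
                f"peak {self.name}: summit offset {off} outside [0, {self.end - self.start})"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position."""
        return self.start + self.summit_offset

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class PeakSet:
    """An ordered collection of :class:`Peak`, sorted by (chrom, start)."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate peak names")
        self._by_name = {p.name: p for p in self.peaks}

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, name: str) -> Peak:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "score": [p.score for p in self.peaks],
                "strand": [p.strand for p in self.peaks],
                "summit_offset": [p.summit_offset for p in self.peaks],
            }
        )


@dataclass(frozen=True)
class Gene:
    """Gene coordinates with an explicit TSS (strand-aware)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    tss: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end <= start")
        if self.tss is None:
            object.__setattr__(self, "tss", self.start if self.strand == "+" else self.end - 1)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def __len__(self):
        return self.end - self.start


class SignalTrack:
    """Strand-resolved base-pair signal stored as non-overlapping runs.

    Minus-strand values are stored as magnitudes; the strand is carried
    separately.  Point queries return 0 outside covered intervals
    (half-open convention).
    """

    def __init__(self):
        # (chrom, strand) -> dict of sorted arrays starts/ends/values
        self._runs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        self._pending: dict[tuple[str, str], list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, value: float, strand: str = "+"):
        if end <= start or start < 0:
            raise ValueError(f"bad interval [{start}, {end})")
        if not np.isfinite(value):
            raise ValueError("signal value must be finite")
        self._pending.setdefault((chrom, strand), []).append((start, end, abs(float(value))))
        self._runs.pop((chrom, strand), None)

    def _compiled(self, key) -> dict[str, np.ndarray]:
        if key not in self._runs:
            rows = sorted(self._pending.get(key, []))
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            if len(rows) > 1 and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping intervals on {key}: [{starts[i]},{ends[i]}) and "
                    f"[{starts[i + 1]},{ends[i + 1]})"
                )
            self._runs[key] = {"starts": starts, "ends": ends, "values": vals}
        return self._runs[key]

    def chroms(self) -> set[str]:
        return {c for (c, _s) in set(self._pending) | set(self._runs)}

    def query(self, chrom: str, pos: int, strand: str = "+") -> float:
        arr = self.values(chrom, pos, pos + 1, strand)
        return float(arr[0])

    def values(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Per-base signal over [start, end); zero where uncovered."""
        out = np.zeros(end - start, dtype=float)
        key = (chrom, strand)
        if key not in self._pending and key not in self._runs:
            return out
        runs = self._compiled(key)
        starts, ends, vals = runs["starts"], runs["ends"], runs["values"]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(start, int(starts[i])) - start
            b = min(end, int(ends[i])) - start
            if b > a:
                out[a:b] = vals[i]
        return out

    def sum(self, chrom: str, start: int, end: int, strand: str = "+") -> float:
        return float(self.values(chrom, start, end, strand).sum())

    def iter_runs(self, strand: str):
        for (chrom, s) in sorted(set(self._pending) | set(self._runs)):
            if s != strand:
                continue
            runs = self._compiled((chrom, s))
            for a, b, v in zip(runs["starts"], runs["ends"], runs["values"]):
                yield chrom, int(a), int(b), float(v)


# ---------------------------------------------------------------------------
# BED peaks


def read_peaks(path) -> PeakSet:
    """Read BED6 or BED6+1 peaks (column 7 = summit offset from start)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
                score = float(fields[4]) if len(fields) > 4 else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                summit = int(fields[6]) if len(fields) > 6 else -1
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            try:
                peaks.append(Peak(chrom, start, end, name, score, strand, summit))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return PeakSet(peaks)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}"
                f"\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# Gene tables (6-column TSV: chrom start end name strand tss)


def read_genes(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(path, lineno, "expected >=5 columns")
            try:
                tss = int(f[5]) if len(f) > 5 else None
                genes.append(Gene(f[0], int(f[1]), int(f[2]), f[3], f[4], tss))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_genes(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t{g.strand}\t{g.tss}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, track: SignalTrack | None = None, strand: str = "+") -> SignalTrack:
    """Read one 4-column bedGraph into ``track`` under the given strand.

    Values on the minus strand may be negative in the file; magnitudes are
    stored and the sign is dropped (the strand label carries orientation).
    """
    if track is None:
        track = SignalTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(f)}")
            try:
                track.add(f[0], int(f[1]), int(f[2]), float(f[3]), strand)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    # force overlap validation now so errors carry the file name
    try:
        for chrom in track.chroms():
            track._compiled((chrom, strand))
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from exc
    return track


def read_signal_pair(plus_path, minus_path) -> SignalTrack:
    """Read a (plus, minus) bedGraph pair into one strand-resolved track."""
    track = read_bedgraph(plus_path, strand="+")
    return read_bedgraph(minus_path, track=track, strand="-")


def write_bedgraph(track: SignalTrack, path, strand: str = "+", signed: bool = False) -> None:
    sign = -1.0 if (signed and strand == "-") else 1.0
    with open(path, "w") as fh:
        for chrom, a, b, v in track.iter_runs(strand):
            fh.write(f"{chrom}\t{a}\t{b}\t{sign * v:g}\n")


def write_signal_pair(track: SignalTrack, plus_path, minus_path, signed: bool = True) -> None:
    write_bedgraph(track, plus_path, "+")
    write_bedgraph(track, minus_path, "-", signed=signed)


# ---------------------------------------------------------------------------
# MEME minimal PWMs


def read_pwm(path) -> list:
    """Parse MEME minimal format into a list of :class:`~kineticnet.motifs.MotifModel`.

    Probability rows must sum to 1 within 1e-3 (then renormalized exactly).
    """
    from .motifs import MotifModel  # deferred: avoid import cycle

    text = Path(path).read_text()
    motifs = []
    lines = text.splitlines()
    i = 0
    background = np.full(4, 0.25)
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i >= len(lines):
                raise ParseError(path, i, f"MOTIF {name}: missing letter-probability matrix")
            rows = []
            i += 1
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    raise ParseError(path, i + 1, f"expected 4 probabilities, got {len(vals)}")
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise ParseError(
                        path, i + 1, f"probability row sums to {sum(vals):.6f}, not 1"
                    )
                rows.append(vals)
                i += 1
            mat = np.asarray(rows, dtype=float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(MotifModel(name=name, pwm=mat, background=background.copy()))
            continue
        i += 1
    return motifs


def write_pwm(motifs, path) -> None:
    """Write motifs in MEME minimal format."""
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)) + "\n\n")
    for m in motifs:
        buf.write(f"MOTIF {m.name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {m.pwm.shape[0]}\n")
        for row in m.pwm:
            buf.write(" ".join(f"{x:.9f}" for x in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Network export

NETWORK_TSV_COLUMNS = [
    "src",
    "dst",
    "edge_kind",
    "interval_start_min",
    "interval_end_min",
    "attribute",
]


def write_network(net, tsv_path, graphml_path=None) -> None:
    """Export a network as an edge-list TSV and (optionally) GraphML."""
    frame = net.to_frame()
    frame.to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), graphml_path)


def read_network_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in NETWORK_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(path, 0, f"missing network columns: {missing}")
    return frame


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
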