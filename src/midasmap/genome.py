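"""Coordinate model, genome layout and plain-text interval/track I/O.

Everything downstream works in 0-based half-open coordinates (BED convention)
and on fixed-width bins anchored at coordinate 0 of each chromosome. The final
partial bin of a chromosome is kept.

Formats handled here are the plain-text staples of the field: BED3/BED6 for
interval sets, bedGraph for per-bin tracks. Inputs using bare chromosome names
("1") are mapped onto the "chr" dialect through an alias map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import BoundsError, ParseError, ValidationError

INTERVAL_KINDS = {
    "gene", "origin", "rloop", "g4", "rt_domain", "cfs_gene", "control", "site",
}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the bin width used for all signal math.

    The default 10 kb bin is the resolution at which nascent-DNA read counts
    are aggregated before sigma normalization and peak calling.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 10_000

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int], bin_size: int = 10_000) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(sizes.values()), bin_size)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.length(chrom):
            raise BoundsError(f"position {pos} outside {chrom} (length {self.length(chrom)})")
        return pos // self.bin_size

    def bin_start(self, bin_idx: int) -> int:
        return bin_idx * self.bin_size

    def bin_mid(self, chrom: str, bin_idx: int) -> int:
        """bp midpoint of a bin; the trailing partial bin uses its true extent."""
        start = bin_idx * self.bin_size
        end = min(start + self.bin_size, self.length(chrom))
        return (start + end) // 2

    def is_partial_bin(self, chrom: str, bin_idx: int) -> bool:
        return (bin_idx + 1) * self.bin_size > self.length(chrom)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def from_tsv(cls, path, bin_size: int = 10_000) -> "GenomeLayout":
        names, lengths = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(path, lineno, "expected 'chrom<TAB>length'")
                names.append(parts[0])
                try:
                    lengths.append(int(parts[1]))
                except ValueError:
                    raise ParseError(path, lineno, f"bad length {parts[1]!r}") from None
        return cls(tuple(names), tuple(lengths), bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, label and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    score: float | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A labeled, per-chromosome-sorted collection of genomic intervals.

    Provides vectorized per-chromosome start/end arrays for window queries.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], kind: str = "site"):
        if kind not in INTERVAL_KINDS:
            raise ValidationError(f"unknown interval kind {kind!r}")
        self.kind = kind
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalSet)
            and self.kind == other.kind
            and self.intervals == other.intervals
        )

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, indices-into-self.intervals) for one chromosome."""
        if self._index is None:
            index: dict[str, list[list[int]]] = {}
            for i, iv in enumerate(self.intervals):
                index.setdefault(iv.chrom, [[], [], []])
                index[iv.chrom][0].append(iv.start)
                index[iv.chrom][1].append(iv.end)
                index[iv.chrom][2].append(i)
            self._index = {
                c: (np.asarray(v[0]), np.asarray(v[1]), np.asarray(v[2]))
                for c, v in index.items()
            }
        empty = (np.empty(0, int), np.empty(0, int), np.empty(0, int))
        return self._index.get(chrom, empty)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals intersecting the half-open window [start, end)."""
        starts, ends, idx = self.by_chrom(chrom)
        if len(idx) == 0:
            return []
        hit = (starts < end) & (ends > start)
        return [self.intervals[i] for i in idx[hit]]

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        starts, ends, _ = self.by_chrom(chrom)
        if len(starts) == 0:
            return 0
        return int(np.count_nonzero((starts < end) & (ends > start)))


def _normalize_chrom(name: str, layout: GenomeLayout | None, aliases: Mapping[str, str] | None) -> str:
    if aliases and name in aliases:
        return aliases[name]
    if layout is not None and name not in layout and f"chr{name}" in layout:
        return f"chr{name}"
    return name


def read_intervals(
    path,
    kind: str = "site",
    layout: GenomeLayout | None = None,
    aliases: Mapping[str, str] | None = None,
) -> IntervalSet:
    """Read a BED3/BED6 file into an IntervalSet.

    Blank lines and lines starting with ``#``, ``track`` or ``browser`` are
    skipped. Strand defaults to "." when the file is BED3. When a layout is
    supplied, chromosome names are checked (after alias mapping) and
    coordinates must fall within the chromosome.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, f"expected >= 3 tab-separated columns, got {len(parts)}")
            chrom = _normalize_chrom(parts[0], layout, aliases)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {parts[1]!r}/{parts[2]!r}") from None
            if end <= start or start < 0:
                raise ParseError(path, lineno, f"invalid coordinates start={start} end={end}")
            label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score: float | None = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {parts[4]!r}") from None
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            if layout is not None:
                if chrom not in layout:
                    raise ParseError(path, lineno, f"unknown chromosome {parts[0]!r}")
                if end > layout.length(chrom):
                    raise ParseError(path, lineno, f"end {end} exceeds {chrom} length {layout.length(chrom)}")
            intervals.append(GenomicInterval(chrom, start, end, strand, label, score))
    return IntervalSet(intervals, kind)


def write_intervals(intervals: IntervalSet | Sequence[GenomicInterval], path, header: bool = False) -> None:
    """Write BED6; round-trips through :func:`read_intervals` field-for-field."""
    with open(path, "w") as fh:
        if header:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            label = iv.label if iv.label else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t{score}\t{iv.strand}\n")


@dataclass
class BinTrack:
    """Per-chromosome fixed-width bin values; the unit of all signal math."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    kind: str = "raw_count"

    def __post_init__(self):
        for chrom, vec in self.values.items():
            expect = self.layout.n_bins(chrom)
            if len(vec) != expect:
                raise ValidationError(
                    f"{chrom}: {len(vec)} bins, layout expects {expect}"
                )
        if self.kind == "raw_count":
            for chrom, vec in self.values.items():
                if np.any(vec < 0):
                    raise ValidationError(f"{chrom}: negative raw counts")

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.chrom_names if c in self.values])

    def copy_with(self, values: dict[str, np.ndarray], kind: str) -> "BinTrack":
        return BinTrack(self.layout, values, kind)


def load_bin_track(source, layout: GenomeLayout, aliases: Mapping[str, str] | None = None) -> BinTrack:
    """Build a raw-count BinTrack from read positions or a bedGraph file.

    ``source`` is either an iterable of ``(chrom, position)`` pairs (each read
    represented by its alignment start; the read increments bin
    ``floor(pos / bin_size)``) or a path to a bedGraph whose record mass is
    split across overlapped bins proportionally to overlap length.
    """
    values = {c: np.zeros(layout.n_bins(c)) for c in layout.chrom_names}
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(source, lineno, "bedGraph needs 4 columns")
                chrom = _normalize_chrom(parts[0], layout, aliases)
                if chrom not in layout:
                    raise ParseError(source, lineno, f"unknown chromosome {parts[0]!r}")
                try:
                    start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError:
                    raise ParseError(source, lineno, "bad bedGraph record") from None
                if end <= start or start < 0 or end > layout.length(chrom):
                    raise ParseError(source, lineno, f"bad record bounds {start}-{end}")
                b0 = start // layout.bin_size
                b1 = (end - 1) // layout.bin_size
                for b in range(b0, b1 + 1):
                    lo = max(start, b * layout.bin_size)
                    hi = min(end, (b + 1) * layout.bin_size)
                    values[chrom][b] += value * (hi - lo) / (end - start)
    else:
        for chrom, pos in source:
            chrom = _normalize_chrom(chrom, layout, aliases)
            if chrom not in layout:
                raise ValidationError(f"unknown chromosome {chrom!r}")
            values[chrom][layout.bin_index(chrom, int(pos))] += 1
    # integral non-negative mass (read positions, bin-resolution count bedGraphs)
    # stays raw_count; anything else (RFD, normalized signal) is generic signal
    integral = all(
        np.allclose(v, np.round(v), atol=1e-9) and np.all(v >= 0) for v in values.values()
    )
    if integral:
        values = {c: np.round(v).astype(np.int64) for c, v in values.items()}
        return BinTrack(layout, values, "raw_count")
    return BinTrack(layout, values, "signal")


def write_bedgraph(track: BinTrack, path, precision: int = 6) -> None:
    """Write one bedGraph line per bin (zero bins included, keeps parsing exact)."""
    with open(path, "w") as fh:
        for chrom in track.layout.chrom_names:
            if chrom not in track.values:
                continue
            vec = track.values[chrom]
            length = track.layout.length(chrom)
            bs = track.layout.bin_size
            for b, v in enumerate(vec):
                if isinstance(v, (np.floating, float)) and np.isnan(v):
                    continue  # missing bins are omitted, not zero-filled
                start = b * bs
                end = min(start + bs, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{format(float(v), f'.{precision}g')}\n")
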