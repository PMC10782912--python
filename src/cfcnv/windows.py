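"""Genomic window generation, masking, and per-window track annotation.

Windows are fixed-width, non-overlapping intervals tiling each chromosome in
0-based half-open (BED) coordinates.  The terminal window of a chromosome may
be shorter than the nominal width (ceiling convention), so every base of the
genome belongs to exactly one window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChromSizes",
    "GenomicWindow",
    "WindowSet",
    "load_chrom_sizes",
    "make_windows",
    "mask_windows",
    "window_track_values",
    "read_bed3",
    "read_bedgraph",
]


class ChromSizesError(ValueError):
    """Raised on malformed chromosome-size input."""


@dataclass(frozen=True)
class GenomicWindow:
    """One genomic window in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    index: int
    masked: bool = False

    def __len__(self) -> int:
        return self.end - self.start


class ChromSizes:
    """Ordered chromosome name -> length mapping.

    Order is preserved from the input; names must be unique and lengths
    strictly positive.
    """

    def __init__(self, items: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ChromSizesError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ChromSizesError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            self._names.append(name)
            self._lengths[name] = length
        if not self._names:
            raise ChromSizesError("no chromosomes")

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def items(self) -> Iterator[tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())


def load_chrom_sizes(path) -> ChromSizes:
    """Parse a UCSC-style chrom.sizes file (name, length per line)."""
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ChromSizesError(f"{path}:{lineno}: expected two columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ChromSizesError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
            if length <= 0:
                raise ChromSizesError(f"{path}:{lineno}: non-positive length {length}")
            items.append((fields[0], length))
    if not items:
        raise ChromSizesError(f"{path}: empty chrom.sizes file")
    return ChromSizes(items)


class WindowSet:
    """Ordered, genome-tiling windows with optional per-window tracks.

    Backed by parallel numpy arrays for efficiency at genome scale; the
    :meth:`windows` iterator materialises :class:`GenomicWindow` objects on
    demand.  Track arrays (``gc``, ``mappability``) cover *all* windows
    (masked included) and use NaN for windows without track coverage.
    """

    def __init__(
        self,
        window_size: int,
        chroms: Sequence[str],
        starts: np.ndarray,
        ends: np.ndarray,
        chrom_sizes: ChromSizes,
        masked: np.ndarray | None = None,
    ):
        self.window_size = int(window_size)
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.chrom_sizes = chrom_sizes
        n = len(self.starts)
        self.masked = (
            np.zeros(n, dtype=bool) if masked is None else np.asarray(masked, dtype=bool)
        )
        self.gc: np.ndarray | None = None
        self.mappability: np.ndarray | None = None
        self.track_covered_fraction: dict[str, np.ndarray] = {}
        # first window index per chromosome, for O(1) interval->window lookup
        self._chrom_offset: dict[str, int] = {}
        for i, c in enumerate(self.chroms):
            if c not in self._chrom_offset:
                self._chrom_offset[c] = i

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def unmasked_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.masked)

    def windows(self) -> Iterator[GenomicWindow]:
        for i in range(len(self)):
            yield GenomicWindow(
                chrom=str(self.chroms[i]),
                start=int(self.starts[i]),
                end=int(self.ends[i]),
                index=i,
                masked=bool(self.masked[i]),
            )

    def window_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Indices [lo, hi) of windows overlapping interval (chrom, start, end).

        Relies on the regular tiling: window ``j`` of a chromosome covers
        ``[j*w, min((j+1)*w, L))``.
        """
        if chrom not in self._chrom_offset:
            raise KeyError(chrom)
        offset = self._chrom_offset[chrom]
        chrom_len = self.chrom_sizes[chrom]
        start = max(0, int(start))
        end = min(int(end), chrom_len)
        if end <= start:
            return offset, offset
        lo = offset + start // self.window_size
        hi = offset + (end - 1) // self.window_size + 1
        return lo, hi

    def set_track(self, name: str, values: np.ndarray, covered_fraction: np.ndarray):
        values = np.asarray(values, dtype=float)
        if len(values) != len(self):
            raise ValueError(f"track {name!r}: length {len(values)} != {len(self)} windows")
        setattr(self, name, values)
        self.track_covered_fraction[name] = np.asarray(covered_fraction, dtype=float)

    # ------------------------------------------------------------------ I/O
    def to_bed(self, path) -> None:
        """Write windows as BED4 with the window index as the name column."""
        with open(path, "w") as fh:
            for w in self.windows():
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.index}\n")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "index": np.arange(len(self)),
                "masked": self.masked,
            }
        )
        if self.gc is not None:
            df["gc"] = self.gc
        if self.mappability is not None:
            df["mappability"] = self.mappability
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_windows(chrom_sizes: ChromSizes, window_size: int) -> WindowSet:
    """Tile every chromosome with non-overlapping windows of ``window_size``.

    Each chromosome yields ``ceil(length / window_size)`` windows; the last
    one is truncated at the chromosome end.  Indices run 0..N-1 in genome
    (input) order.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in chrom_sizes.items():
        n = -(-length // window_size)  # ceil division
        for j in range(n):
            chroms.append(name)
            starts.append(j * window_size)
            ends.append(min((j + 1) * window_size, length))
    return WindowSet(window_size, chroms, np.array(starts), np.array(ends), chrom_sizes)


def mask_windows(
    ws: WindowSet,
    exclusion: Iterable[tuple[str, int, int]],
    min_overlap_fraction: float = 0.5,
) -> WindowSet:
    """Mask windows overlapping exclusion intervals.

    A window is masked iff it is touched by at least one excluded base and
    its overlapped fraction (overlap bp / window length) is >=
    ``min_overlap_fraction``.  Overlap is accumulated across intervals.
    Intervals on unknown chromosomes are skipped with a warning.
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    overlap = np.zeros(len(ws), dtype=np.int64)
    for chrom, start, end in exclusion:
        if chrom not in ws.chrom_sizes:
            warnings.warn(f"exclusion interval on unknown chromosome {chrom!r} skipped")
            continue
        lo, hi = ws.window_range(chrom, start, end)
        for i in range(lo, hi):
            overlap[i] += min(end, ws.ends[i]) - max(start, ws.starts[i])
    frac = overlap / ws.lengths
    masked = (overlap > 0) & (frac >= min_overlap_fraction)
    out = WindowSet(
        ws.window_size, ws.chroms, ws.starts, ws.ends, ws.chrom_sizes,
        masked=ws.masked | masked,
    )
    if ws.gc is not None:
        out.set_track("gc", ws.gc, ws.track_covered_fraction["gc"])
    if ws.mappability is not None:
        out.set_track("mappability", ws.mappability,
                      ws.track_covered_fraction["mappability"])
    n = int(out.masked.sum())
    logger.info("masked %d of %d windows", n, len(ws))
    return out


def accumulate_track(
    ws: WindowSet, records: Iterable[tuple[str, int, int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate (value * overlap bp, overlap bp) per window from interval records.

    Records must be non-overlapping within a chromosome.  Returns the pair of
    per-window arrays (weighted sums, covered bp).
    """
    wsum = np.zeros(len(ws), dtype=float)
    wbp = np.zeros(len(ws), dtype=np.int64)
    for chrom, start, end, value in records:
        if chrom not in ws.chrom_sizes:
            warnings.warn(f"track record on unknown chromosome {chrom!r} skipped")
            continue
        if end <= start:
            continue
        lo, hi = ws.window_range(chrom, start, end)
        for i in range(lo, hi):
            bp = min(end, ws.ends[i]) - max(start, ws.starts[i])
            wsum[i] += value * bp
            wbp[i] += bp
    return wsum, wbp


def window_track_values(
    ws: WindowSet,
    track: Iterable[tuple[str, int, int, float]],
    name: str | None = None,
    value_range: tuple[float, float] | None = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window length-weighted mean of a bedGraph-like track.

    Only covered bases contribute to the mean; the covered fraction of each
    window is returned alongside.  Windows with no track coverage get NaN.
    When ``name`` is given, the result is attached to ``ws`` as a track.
    """
    track = list(track)
    if value_range is not None:
        lo, hi = value_range
        for chrom, start, end, value in track:
            if not (lo <= value <= hi):
                raise ValueError(
                    f"track value {value} at {chrom}:{start}-{end} outside "
                    f"declared range [{lo}, {hi}]"
                )
    wsum, wbp = accumulate_track(ws, track)
    values = np.full(len(ws), np.nan)
    covered = wbp > 0
    values[covered] = wsum[covered] / wbp[covered]
    covered_fraction = wbp / ws.lengths
    if name is not None:
        ws.set_track(name, values, covered_fraction)
    return values, covered_fraction


def read_bed3(path) -> list[tuple[str, int, int]]:
    """Read a BED3 file; malformed lines raise with their line number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph (chrom, start, end, value) file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out
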