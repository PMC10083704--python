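"""Coverage tracks and reference-point signal matrices.

A :class:`CoverageTrack` is a genome-wide step function given by sorted,
non-overlapping intervals with float values (0 elsewhere) — the bedGraph
model. :func:`compute_matrix` summarizes a track into a regions x bins
matrix of length-weighted mean signal in fixed-width bins centered on each
region (deepTools computeMatrix reference-point semantics), and
:func:`sort_by_lead_sample` reproduces the heatmap convention of sorting
all samples by the first sample's descending per-region mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "CoverageTrack",
    "SignalMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "mean_signal",
    "compute_matrix",
    "sort_by_lead_sample",
    "aggregate_profile",
]


class BedGraphParseError(ValueError):
    pass


class CoverageTrack:
    """Step-function coverage: per chrom, sorted non-overlapping intervals
    with finite float values; implicitly 0 everywhere else."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: empty or inverted interval")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping intervals")
            if not np.isfinite(values).all():
                raise ValueError(f"{chrom}: non-finite values")
            self._data[chrom] = (starts, ends, values)
            # cumulative integral of value over covered bases, for O(log n)
            # window sums
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(values * (ends - starts))]
            )

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        per: dict[str, tuple[list, list, list]] = {}
        for chrom, start, end, value in intervals:
            s, e, v = per.setdefault(chrom, ([], [], []))
            s.append(start)
            e.append(end)
            v.append(value)
        return cls({c: tuple(map(np.asarray, t)) for c, t in per.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, chrom: str):
        return self._data.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))

    def value_at(self, chrom: str, pos: int) -> float:
        starts, ends, values = self.intervals(chrom)
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """F(pos) = integral of the track over (-inf, pos)."""
        starts, ends, values = self.intervals(chrom)
        if len(starts) == 0:
            return np.zeros_like(np.asarray(pos, dtype=float))
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(starts, pos, side="right")
        cum = self._cum[chrom]
        full = cum[i]
        # subtract the part of interval i-1 at or beyond pos
        prev = i - 1
        valid = prev >= 0
        correction = np.zeros(pos.shape, dtype=float)
        p = np.clip(prev, 0, None)
        overhang = np.clip(ends[p] - pos, 0, ends[p] - starts[p])
        correction[valid] = (values[p] * overhang)[valid]
        return full - correction

    def window_sum(self, chrom: str, start: int | np.ndarray, end: int | np.ndarray):
        """Integral of the track over [start, end); vectorized."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        return self._integral(chrom, end) - self._integral(chrom, start)


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Parse a 4-column bedGraph. Overlapping intervals or non-numeric
    values raise :class:`BedGraphParseError` naming the line."""
    path = Path(path)
    per: dict[str, tuple[list, list, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise BedGraphParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise BedGraphParseError(f"{path}:{lineno}: {exc}") from exc
            s, e, v = per.setdefault(f[0], ([], [], []))
            s.append(start)
            e.append(end)
            v.append(value)
    try:
        return CoverageTrack(
            {c: tuple(map(np.asarray, t)) for c, t in per.items()}
        )
    except ValueError as exc:
        raise BedGraphParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def mean_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of the track over the interval, counting
    uncovered bases as 0."""
    total = float(track.window_sum(interval.chrom, interval.start, interval.end))
    return total / len(interval)


@dataclass
class SignalMatrix:
    """Regions x bins mean-signal matrix centered on region centers."""

    region_ids: list[str]
    values: np.ndarray
    flank: int
    bin_width: int

    def __post_init__(self) -> None:
        n_bins = 2 * self.flank // self.bin_width
        if self.values.shape != (len(self.region_ids), n_bins):
            raise ValueError("values shape inconsistent with regions/bins")

    @property
    def bin_offsets(self) -> np.ndarray:
        """Bin center offsets in bp relative to the region center."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_width)
        return (edges[:-1] + edges[1:]) / 2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=self.region_ids,
            columns=[f"{int(o):+d}" for o in self.bin_offsets],
        )


def compute_matrix(
    track: CoverageTrack,
    regions: PeakSet,
    flank: int = 2000,
    bin_width: int = 50,
) -> SignalMatrix:
    """Reference-point matrix: per region, mean signal in ``bin_width``-bp
    bins across ``[center - flank, center + flank)``.

    Bins reaching before position 0 or past chromosome ends contribute 0
    over the out-of-range bases (missing data is 0, not NaN).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    ids: list[str] = []
    rows = np.zeros((len(regions), n_bins))
    offsets = np.arange(-flank, flank, bin_width)
    for r, iv in enumerate(regions):
        c = iv.center
        bin_starts = np.maximum(c + offsets, 0)
        bin_ends = np.maximum(c + offsets + bin_width, 0)
        sums = track.window_sum(iv.chrom, bin_starts, bin_ends)
        rows[r] = sums / bin_width
        ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}:{r}")
    return SignalMatrix(ids, rows, flank, bin_width)


def sort_by_lead_sample(matrices: Sequence[SignalMatrix]) -> list[int]:
    """Row order by descending per-region mean of the FIRST matrix.

    All matrices must share the region list; the same permutation applies
    to every sample so heatmaps stay row-aligned. Ties break by region id
    ascending. Returns the permutation as a list of row indices.
    """
    if not matrices:
        raise ValueError("no matrices given")
    first = matrices[0]
    for m in matrices[1:]:
        if m.region_ids != first.region_ids:
            raise ValueError("matrices have mismatched region lists")
    means = first.values.mean(axis=1)
    return sorted(
        range(len(first.region_ids)),
        key=lambda i: (-means[i], first.region_ids[i]),
    )


def aggregate_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin mean over regions (the summary profile above a heatmap)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix has no regions")
    return matrix.values.mean(axis=0)
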