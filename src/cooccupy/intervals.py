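"""Genomic interval algebra for ChIP-seq peak co-occupancy analysis.

Peaks are half-open, 0-based intervals (BED convention). Two intervals
overlap iff they share at least one base, so ``[0, 100)`` and ``[100, 200)``
do not overlap (the bedtools default). Strand is carried through I/O but
ignored for overlap and distance computations, since ChIP peaks are
unstranded.

The central operation is :func:`classify_cooccupancy`: peak sets from
several factors (e.g. Opa and Oc at one embryonic stage) are merged into
combined regions, and each combined region is labelled with the subset of
factors whose peaks intersect it — "Opa-Oc overlap", "Opa-only", "Oc-only"
classes and their multi-factor generalisations.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CooccupancyRegion",
    "TSSTable",
    "PeakGeneAssignment",
    "OverlapTest",
    "read_bed",
    "write_bed",
    "read_genome_sizes",
    "read_tss_table",
    "merge_intervals",
    "classify_cooccupancy",
    "venn_region_counts",
    "fraction_overlapping",
    "cooccupancy_chi2",
    "annotate_nearest_tss",
    "PROMOTER_CUTOFF",
]

#: Maximum peak-center-to-TSS distance (bp) for a "promoter" call; larger
#: distances are "distal".
PROMOTER_CUTOFF = 3000


class BedParseError(ValueError):
    """Raised for malformed BED / TSV records, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """A labelled collection of peaks for one factor/stage (e.g. "Opa_St5E").

    ``normalize()`` sorts by (chrom, start) and merges overlapping or
    touching peaks within the set; most consumers require normalized input
    and normalize defensively.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        self.intervals: list[GenomicInterval] = list(intervals)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def normalize(self) -> "PeakSet":
        """Return a new PeakSet with sorted, non-overlapping intervals."""
        return PeakSet(self.label, merge_intervals(self.intervals, gap=0))

    def _interval_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chrom (starts, ends) arrays of the *merged* intervals."""
        if self._index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for iv in merge_intervals(self.intervals, gap=0):
                s, e = idx.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._index

    def intersects(self, iv: GenomicInterval) -> bool:
        """True iff any peak in this set shares >= 1 base with ``iv``."""
        idx = self._interval_index()
        if iv.chrom not in idx:
            return False
        starts, ends = idx[iv.chrom]
        # first merged interval ending after iv.start; it overlaps iff it
        # also starts before iv.end
        i = int(np.searchsorted(ends, iv.start, side="right"))
        return i < len(starts) and starts[i] < iv.end

    def covered_bases(self) -> int:
        """Total bases covered by the merged union of the set."""
        return sum(int(e - s) for s, e in
                   ((iv.start, iv.end) for iv in merge_intervals(self.intervals)))


@dataclass(frozen=True)
class CooccupancyRegion:
    """One merged region and the labels of the peak sets intersecting it."""

    region: GenomicInterval
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("co-occupancy region with empty membership")


@dataclass(frozen=True)
class TSSEntry:
    gene: str
    chrom: str
    pos: int
    strand: str = "."


class TSSTable:
    """Transcription start sites, unique per gene id."""

    def __init__(self, entries: Iterable[TSSEntry]):
        self.entries = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.gene in seen:
                raise ValueError(f"duplicate gene id {e.gene!r} in TSS table")
            seen.add(e.gene)
        # per chrom: positions sorted, genes sorted by (pos, gene) so that
        # equidistant ties resolve to the lexicographically smallest gene id
        self._by_chrom: dict[str, tuple[list[int], list[str]]] = {}
        per: dict[str, list[tuple[int, str]]] = {}
        for e in self.entries:
            per.setdefault(e.chrom, []).append((e.pos, e.gene))
        for chrom, items in per.items():
            items.sort()
            self._by_chrom[chrom] = ([p for p, _ in items], [g for _, g in items])

    def __len__(self) -> int:
        return len(self.entries)

    def nearest(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene, distance) of the nearest TSS, or None if chrom unknown.

        Ties (two equidistant TSSs) resolve to the smallest gene id.
        """
        if chrom not in self._by_chrom:
            return None
        positions, genes = self._by_chrom[chrom]
        i = bisect_left(positions, pos)
        best: tuple[int, str] | None = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                cand = (abs(positions[j] - pos), genes[j])
                if best is None or cand < best:
                    best = cand
        # equal positions are adjacent after the (pos, gene) sort; scan the
        # neighbourhood for same-distance entries with smaller gene ids
        lo, hi = max(0, i - 2), min(len(positions), i + 2)
        for j in range(lo, hi):
            cand = (abs(positions[j] - pos), genes[j])
            if cand < best:
                best = cand
        assert best is not None
        return best[1], best[0]


@dataclass(frozen=True)
class PeakGeneAssignment:
    """Nearest-TSS annotation of one peak.

    ``category`` is "promoter" iff center-to-TSS distance <= 3 kb,
    "distal" otherwise, and "unannotated" when the peak's chromosome has no
    TSS entry (gene and distance are then None).
    """

    peak: GenomicInterval
    gene: str | None
    distance: int | None
    category: str

    def __post_init__(self) -> None:
        if self.category not in {"promoter", "distal", "unannotated"}:
            raise ValueError(f"bad category {self.category!r}")
        if self.category != "unannotated":
            assert self.distance is not None
            expected = "promoter" if self.distance <= PROMOTER_CUTOFF else "distal"
            if self.category != expected:
                raise ValueError("category inconsistent with distance")


@dataclass(frozen=True)
class OverlapTest:
    """Chi-squared test of observed vs expected peak-overlap counts."""

    observed_overlapping: int
    observed_non_overlapping: int
    expected_overlapping: float
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if self.observed_overlapping < 0 or self.observed_non_overlapping < 0:
            raise ValueError("negative counts")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3–BED6 file into a PeakSet.

    Raises :class:`BedParseError` naming the line number for non-integer
    coordinates or start >= end. Track/browser/comment lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label or path.stem, intervals)


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` TSV -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def read_tss_table(path: str | Path, fmt: str = "auto") -> TSSTable:
    """Read TSS entries from a 4-column TSV (gene, chrom, pos, strand) or
    BED6 (TSS = start for '+', end-1 for '-').
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "bed" if path.suffix.lower() == ".bed" else "tsv"
    entries: list[TSSEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if fmt == "bed":
                    if len(f) < 6:
                        raise ValueError("BED TSS table needs 6 columns")
                    pos = int(f[1]) if f[5] != "-" else int(f[2]) - 1
                    entries.append(TSSEntry(f[3], f[0], pos, f[5]))
                else:
                    if len(f) < 3:
                        raise ValueError("TSS TSV needs gene, chrom, pos")
                    entries.append(
                        TSSEntry(f[0], f[1], int(f[2]), f[3] if len(f) > 3 else ".")
                    )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return TSSTable(entries)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation is <= ``gap`` bp.

    With the default ``gap=0``, overlapping or touching intervals merge.
    Output is sorted by (chrom, start) and pairwise non-overlapping.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def classify_cooccupancy(peak_sets: Sequence[PeakSet]) -> list[CooccupancyRegion]:
    """Merge the union of all peaks and label each combined region with the
    peak sets it intersects.

    Single-member regions are the "X-only" classes; multi-member regions
    are the co-occupied ("overlap") classes. The output regions are
    disjoint and cover exactly the union of the input peaks.
    """
    if not peak_sets:
        raise ValueError("at least one PeakSet required")
    labels = [ps.label for ps in peak_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate PeakSet labels: {labels}")
    normalized = [ps.normalize() for ps in peak_sets]
    union = merge_intervals(
        [iv for ps in normalized for iv in ps.intervals], gap=0
    )
    regions: list[CooccupancyRegion] = []
    for region in union:
        members = frozenset(
            ps.label for ps in normalized if ps.intersects(region)
        )
        regions.append(CooccupancyRegion(region, members))
    return regions


def venn_region_counts(
    regions: Sequence[CooccupancyRegion],
    labels: Sequence[str] | None = None,
) -> dict[frozenset[str], int]:
    """Region counts per non-empty label subset (region-level Venn).

    All non-empty subsets of ``labels`` (default: union of observed
    memberships) appear as keys, zero-count subsets included; the values
    sum to ``len(regions)``.
    """
    if labels is None:
        observed: set[str] = set()
        for r in regions:
            observed |= r.members
        labels = sorted(observed)
    counts: dict[frozenset[str], int] = {}
    n = len(labels)
    for mask in range(1, 2 ** n):
        subset = frozenset(l for i, l in enumerate(labels) if mask >> i & 1)
        counts[subset] = 0
    for r in regions:
        if r.members not in counts:
            raise ValueError(f"region members {set(r.members)} outside labels")
        counts[r.members] += 1
    return counts


def fraction_overlapping(query: PeakSet, subject: PeakSet) -> float:
    """Fraction of query peaks sharing >= 1 base with any subject peak.

    This is the peak-level statistic behind "85% of Oc peaks ... coinciding
    with Opa peaks"; it is invariant under normalization of the query and
    merging of the subject.
    """
    if len(query) == 0:
        raise ValueError("fraction undefined for an empty query set")
    qn = query.normalize()
    hits = sum(1 for iv in qn if subject.intersects(iv))
    return hits / len(qn)


def cooccupancy_chi2(
    query: PeakSet,
    subject: PeakSet,
    genome: Mapping[str, int],
) -> OverlapTest:
    """Chi-squared test of query-peak overlap counts against random placement.

    Under random placement of a query peak of length L on a genome of total
    length G, the probability of intersecting the subject set is
    approximated by ``min(1, (covered_bases(subject) + n_subject * L) / G)``
    (each of the n_subject merged subject intervals extends the collision
    region by ~L). The test compares (overlapping, non-overlapping) counts
    to their expectations with a 1-df chi-squared statistic,
    ``sum((O - E)^2 / E)`` over both cells.
    """
    qn = query.normalize()
    sn = subject.normalize()
    for iv in list(qn) + list(sn):
        if iv.chrom not in genome:
            raise ValueError(f"chromosome {iv.chrom!r} missing from genome sizes")
    G = float(sum(genome.values()))
    covered = sn.covered_bases()
    n_subject = len(sn)
    n = len(qn)
    if n == 0:
        raise ValueError("empty query set")
    expected = 0.0
    observed = 0
    for iv in qn:
        p = min(1.0, (covered + n_subject * len(iv)) / G)
        expected += p
        if sn.intersects(iv):
            observed += 1
    if expected <= 0 or expected >= n:
        raise ValueError(
            "degenerate test: expected overlap count is 0 or equals n "
            f"(expected={expected:.3g}, n={n})"
        )
    stat = (observed - expected) ** 2 / expected + (
        (n - observed) - (n - expected)
    ) ** 2 / (n - expected)
    p_value = float(stats.chi2.sf(stat, df=1))
    return OverlapTest(observed, n - observed, expected, float(stat), p_value)


def shuffle_null_pvalues(
    query: PeakSet,
    subject: PeakSet,
    genome: Mapping[str, int],
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Empirical null: observed overlap counts under random re-placement of
    query peaks (lengths preserved, uniform placement per chromosome drawn
    proportional to length). Returns the vector of shuffled overlap counts;
    a cross-check for :func:`cooccupancy_chi2`, not a replacement.
    """
    rng = np.random.default_rng(seed)
    qn = query.normalize()
    sn = subject.normalize()
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    counts = np.zeros(n_shuffles, dtype=int)
    peak_lens = [len(iv) for iv in qn]
    for k in range(n_shuffles):
        c_idx = rng.choice(len(chroms), size=len(peak_lens), p=probs)
        hits = 0
        for L, ci in zip(peak_lens, c_idx):
            chrom = chroms[ci]
            limit = genome[chrom] - L
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if sn.intersects(GenomicInterval(chrom, start, start + L)):
                hits += 1
        counts[k] = hits
    return counts


def annotate_nearest_tss(
    peaks: PeakSet,
    tss: TSSTable,
    promoter_cutoff: int = PROMOTER_CUTOFF,
) -> list[PeakGeneAssignment]:
    """Assign each peak to the nearest TSS by peak-center distance.

    Distance is ``|center - TSS|`` with center = floor((start + end) / 2);
    category is "promoter" iff distance <= ``promoter_cutoff`` (3 kb by
    default), "distal" otherwise. Peaks on chromosomes absent from the TSS
    table are flagged "unannotated". Equidistant ties resolve to the
    lexicographically smallest gene id.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    out: list[PeakGeneAssignment] = []
    for iv in peaks:
        hit = tss.nearest(iv.chrom, iv.center)
        if hit is None:
            out.append(PeakGeneAssignment(iv, None, None, "unannotated"))
        else:
            gene, dist = hit
            cat = "promoter" if dist <= promoter_cutoff else "distal"
            out.append(PeakGeneAssignment(iv, gene, dist, cat))
    return out
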