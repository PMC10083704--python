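"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator is deterministic per (seed, parameters) and returns a
:class:`GroundTruth` record of exactly what was planted. Wherever the
downstream statistic is a count or a fraction, the generator plants an
exact count (not a probabilistic expectation), so recovery tests are
equality tests: a peak set generated with ``overlap_fraction=0.85`` and
``n_a=2000`` yields ``fraction_overlapping == 1700/2000`` exactly.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .coexpression import CellRecord
from .embryo import EmbryoImage
from .intervals import GenomicInterval, PeakSet
from .signal import CoverageTrack

__all__ = [
    "GroundTruth",
    "SimGenome",
    "gen_genome",
    "gen_peak_sets",
    "random_sequences",
    "plant_motifs",
    "gen_coverage",
    "gaussian_curve",
    "gen_scrna",
    "gen_embryo_image",
    "gen_gene_sets",
]


@dataclass
class GroundTruth:
    """What a generator planted: name, seed, parameters, exact quantities."""

    generator: str
    seed: int
    parameters: dict
    planted: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "parameters": self.parameters,
                "planted": self.planted,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(d["generator"], d["seed"], d["parameters"], d["planted"])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class SimGenome:
    """Chromosome lengths and base composition of a simulated genome."""

    chrom_lengths: dict[str, int]
    gc: float
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"non-positive length for {c!r}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def gen_genome(
    seed: int,
    chrom_lengths: Mapping[str, int],
    gc: float = 0.42,
    masked_fraction: float = 0.0,
) -> tuple[dict[str, str], SimGenome]:
    """I.i.d. random genome at a stated GC content.

    ``masked_fraction`` lowercases that fraction of each chromosome in
    random 100-bp blocks, emulating repeat masking.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, str] = {}
    for chrom, length in chrom_lengths.items():
        codes = rng.choice(4, size=length, p=probs)
        arr = bases[codes]
        if masked_fraction > 0:
            n_blocks = int(round(masked_fraction * length / 100))
            lower = arr.copy()
            for _ in range(n_blocks):
                s = int(rng.integers(0, max(1, length - 100)))
                lower[s : s + 100] |= 0x20  # ASCII lowercase
            arr = lower
        genome[chrom] = arr.tobytes().decode("ascii")
    sim = SimGenome(dict(chrom_lengths), gc, masked_fraction)
    return genome, sim


class _Occupancy:
    """Per-chrom sorted interval list supporting disjoint placement with a
    1-bp guard so normalization never merges separately planted peaks."""

    def __init__(self) -> None:
        self._per: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int, guard: int = 1) -> bool:
        ivs = self._per.get(chrom, [])
        i = bisect_left(ivs, (start, start))
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if start - guard < e and s < end + guard:
                    return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._per.setdefault(chrom, []), (start, end))


def _draw_chrom(rng, chroms: list[str], lengths: np.ndarray) -> str:
    return chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]


def gen_peak_sets(
    seed: int,
    genome: SimGenome | Mapping[str, int],
    n_a: int,
    n_b: int,
    overlap_fraction: float,
    peak_len: int = 200,
    labels: tuple[str, str] = ("A", "B"),
    max_tries: int = 10_000,
) -> tuple[PeakSet, PeakSet, GroundTruth]:
    """Paired peak sets with an exact planted overlap fraction.

    Exactly ``round(overlap_fraction * n_a)`` A-peaks are placed to share
    >= 1 bp with a B-peak; the remaining A-peaks are rejection-sampled to
    avoid B entirely. All peaks within each set are pairwise separated by
    >= 1 bp so normalization preserves counts.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    lengths_map = (
        genome.chrom_lengths if isinstance(genome, SimGenome) else dict(genome)
    )
    chroms = sorted(lengths_map)
    lengths = np.array([lengths_map[c] for c in chroms], dtype=float)
    total = lengths.sum()
    needed = (n_a + n_b) * (peak_len + 2)
    if needed > 0.5 * total:
        raise ValueError(
            f"infeasible density: {n_a + n_b} peaks of {peak_len} bp on a "
            f"{int(total)} bp genome"
        )
    rng = np.random.default_rng(seed)
    occ_b = _Occupancy()
    b_peaks: list[GenomicInterval] = []
    for i in range(n_b):
        for _ in range(max_tries):
            chrom = _draw_chrom(rng, chroms, lengths)
            limit = lengths_map[chrom] - peak_len
            if limit <= 0:
                continue
            s = int(rng.integers(0, limit))
            if not occ_b.conflicts(chrom, s, s + peak_len):
                occ_b.add(chrom, s, s + peak_len)
                b_peaks.append(
                    GenomicInterval(chrom, s, s + peak_len, name=f"{labels[1]}_{i}")
                )
                break
        else:
            raise RuntimeError("could not place B peaks without collisions")

    n_overlap = int(round(overlap_fraction * n_a))
    occ_a = _Occupancy()
    a_peaks: list[GenomicInterval] = []
    overlapping_ids: list[str] = []
    # planted overlappers: offset against a random B peak with guaranteed
    # >= 1 bp intersection
    for i in range(n_overlap):
        for _ in range(max_tries):
            b = b_peaks[int(rng.integers(0, len(b_peaks)))]
            lo = max(0, b.start - peak_len + 1)
            hi = min(lengths_map[b.chrom] - peak_len, b.end - 1)
            if hi < lo:
                continue
            s = int(rng.integers(lo, hi + 1))
            if not occ_a.conflicts(b.chrom, s, s + peak_len):
                name = f"{labels[0]}_{i}"
                occ_a.add(b.chrom, s, s + peak_len)
                a_peaks.append(GenomicInterval(b.chrom, s, s + peak_len, name=name))
                overlapping_ids.append(name)
                break
        else:
            raise RuntimeError("could not place overlapping A peaks")
    # non-overlappers: avoid every B peak (and other A peaks)
    for i in range(n_overlap, n_a):
        for _ in range(max_tries):
            chrom = _draw_chrom(rng, chroms, lengths)
            limit = lengths_map[chrom] - peak_len
            if limit <= 0:
                continue
            s = int(rng.integers(0, limit))
            if occ_b.conflicts(chrom, s, s + peak_len, guard=0):
                continue
            if occ_a.conflicts(chrom, s, s + peak_len):
                continue
            name = f"{labels[0]}_{i}"
            occ_a.add(chrom, s, s + peak_len)
            a_peaks.append(GenomicInterval(chrom, s, s + peak_len, name=name))
            break
        else:
            raise RuntimeError("could not place non-overlapping A peaks")

    gt = GroundTruth(
        "gen_peak_sets",
        seed,
        {
            "n_a": n_a,
            "n_b": n_b,
            "overlap_fraction": overlap_fraction,
            "peak_len": peak_len,
            "chrom_lengths": {c: int(lengths_map[c]) for c in chroms},
        },
        {
            "n_overlapping": n_overlap,
            "overlap_fraction_exact": n_overlap / n_a if n_a else 0.0,
            "overlapping_ids": overlapping_ids,
        },
    )
    return PeakSet(labels[0], a_peaks), PeakSet(labels[1], b_peaks), gt


def random_sequences(
    seed: int, n: int, length: int, alphabet: str = "ACGT"
) -> list[str]:
    """N random sequences over the given alphabet (a single-letter alphabet
    gives a spurious-match-free background for disjoint-alphabet motifs)."""
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return [
        rng.choice(letters, size=length).tobytes().decode("ascii") for _ in range(n)
    ]


def plant_motifs(
    seed: int,
    sequences: Sequence[str],
    consensus: str,
    offset_sd: float = 0.0,
    fraction_of_sequences: float = 1.0,
    max_tries: int = 1000,
) -> tuple[list[str], GroundTruth]:
    """Plant a consensus motif into exactly round(fraction * n) sequences.

    Offsets are drawn from N(0, offset_sd) around the sequence center
    (offset_sd = 0 plants exactly at the center) and recorded per planted
    sequence; draws that would run off the sequence are resampled, with an
    error after ``max_tries`` failures.
    """
    if not 0.0 <= fraction_of_sequences <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(sequences)
    k = int(round(fraction_of_sequences * n))
    chosen = sorted(rng.choice(n, size=k, replace=False).tolist())
    L = len(consensus)
    out = list(sequences)
    offsets: dict[int, int] = {}
    for idx in chosen:
        seq = out[idx]
        center = len(seq) // 2
        for _ in range(max_tries):
            off = int(round(rng.normal(0.0, offset_sd))) if offset_sd > 0 else 0
            start = center + off - L // 2
            if 0 <= start <= len(seq) - L:
                out[idx] = seq[:start] + consensus + seq[start + L :]
                offsets[idx] = off
                break
        else:
            raise RuntimeError(
                f"could not place motif within sequence after {max_tries} draws"
            )
    gt = GroundTruth(
        "plant_motifs",
        seed,
        {
            "consensus": consensus,
            "offset_sd": offset_sd,
            "fraction_of_sequences": fraction_of_sequences,
            "n_sequences": n,
        },
        {
            "n_planted": k,
            "fraction_exact": k / n if n else 0.0,
            "offsets": {str(i): o for i, o in offsets.items()},
        },
    )
    return out, gt


def gen_coverage(
    seed: int,
    genome: SimGenome | Mapping[str, int],
    bump_centers: Sequence[tuple[str, int]],
    amplitude: float = 10.0,
    width: int = 500,
    noise_sd: float = 0.0,
    step: int = 10,
) -> tuple[CoverageTrack, GroundTruth]:
    """Coverage track of triangular bumps plus truncated Gaussian noise,
    discretized into ``step``-bp constant intervals.

    Each bump contributes ``amplitude * max(0, 1 - |x - center| / width)``
    evaluated at step midpoints; noise is N(0, noise_sd) per step,
    truncated at zero after summation.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    lengths_map = (
        genome.chrom_lengths if isinstance(genome, SimGenome) else dict(genome)
    )
    rng = np.random.default_rng(seed)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, c in bump_centers:
        if chrom not in lengths_map:
            raise ValueError(f"bump on unknown chromosome {chrom!r}")
        centers_by_chrom.setdefault(chrom, []).append(int(c))
    for chrom, length in lengths_map.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + step, length)
        mids = (starts + ends) / 2.0
        values = np.zeros(len(starts))
        for c in centers_by_chrom.get(chrom, []):
            values += amplitude * np.clip(1.0 - np.abs(mids - c) / width, 0.0, None)
        if noise_sd > 0:
            values += rng.normal(0.0, noise_sd, size=len(values))
        values = np.clip(values, 0.0, None)
        nz = values != 0
        per_chrom[chrom] = (starts[nz], ends[nz], values[nz])
    track = CoverageTrack(per_chrom)
    gt = GroundTruth(
        "gen_coverage",
        seed,
        {
            "amplitude": amplitude,
            "width": width,
            "noise_sd": noise_sd,
            "step": step,
            "chrom_lengths": {c: int(L) for c, L in lengths_map.items()},
        },
        {"bump_centers": [[c, int(p)] for c, p in bump_centers]},
    )
    return track, gt


def gaussian_curve(
    peak_age: float, amplitude: float, sd: float, baseline: float = 0.05
) -> Callable[[np.ndarray], np.ndarray]:
    """Mean-count curve over age: baseline + amplitude * exp Gaussian."""

    def curve(age):
        age = np.asarray(age, dtype=float)
        return baseline + amplitude * np.exp(-0.5 * ((age - peak_age) / sd) ** 2)

    return curve


def gen_scrna(
    seed: int,
    n_cells: int,
    age_range: tuple[float, float],
    gene_mean_curves: Mapping[str, Callable],
    nb_dispersion: float = 1.0,
    planted_double_positive: tuple[str, str, tuple[float, float], int] | None = None,
) -> tuple[list[CellRecord], GroundTruth]:
    """Negative-binomial single-cell counts over a developmental-age score.

    Ages are uniform on ``age_range``; each gene's counts are NB with mean
    from its curve evaluated at the cell's age and dispersion (size)
    ``nb_dispersion``. If ``planted_double_positive = (gA, gB, (lo, hi),
    count)`` is given, exactly ``count`` cells with age in [lo, hi) are
    forced to >= 1 count for both genes and every other in-window cell is
    forced to 0 in at least one of the two, so the planted count is exact.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    lo_age, hi_age = age_range
    ages = rng.uniform(lo_age, hi_age, size=n_cells)
    genes = list(gene_mean_curves)
    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    for j, g in enumerate(genes):
        mu = np.clip(np.asarray(gene_mean_curves[g](ages), dtype=float), 1e-9, None)
        p = nb_dispersion / (nb_dispersion + mu)
        counts[:, j] = rng.negative_binomial(nb_dispersion, p)

    planted_ids: list[str] = []
    if planted_double_positive is not None:
        ga, gb, (wlo, whi), n_plant = planted_double_positive
        for g in (ga, gb):
            if g not in gene_mean_curves:
                raise ValueError(f"planted gene {g!r} has no mean curve")
        ja, jb = genes.index(ga), genes.index(gb)
        in_window = np.flatnonzero((ages >= wlo) & (ages < whi))
        if n_plant > len(in_window):
            raise ValueError(
                f"cannot plant {n_plant} double-positives: only "
                f"{len(in_window)} cells in the age window"
            )
        pick = rng.choice(in_window, size=n_plant, replace=False)
        pick_set = set(pick.tolist())
        counts[pick, ja] = np.maximum(counts[pick, ja], 1)
        counts[pick, jb] = np.maximum(counts[pick, jb], 1)
        for i in in_window:
            if int(i) not in pick_set and counts[i, ja] >= 1 and counts[i, jb] >= 1:
                # knock out one gene, alternating deterministically by index
                counts[i, jb if i % 2 == 0 else ja] = 0
        planted_ids = [f"cell{int(i):06d}" for i in sorted(pick_set)]

    cells = [
        CellRecord(
            f"cell{i:06d}",
            float(ages[i]),
            {g: int(counts[i, j]) for j, g in enumerate(genes)},
        )
        for i in range(n_cells)
    ]
    gt = GroundTruth(
        "gen_scrna",
        seed,
        {
            "n_cells": n_cells,
            "age_range": list(age_range),
            "genes": genes,
            "nb_dispersion": nb_dispersion,
        },
        {
            "planted_double_positive": (
                None
                if planted_double_positive is None
                else {
                    "gene_a": planted_double_positive[0],
                    "gene_b": planted_double_positive[1],
                    "window": list(planted_double_positive[2]),
                    "count": planted_double_positive[3],
                    "cell_ids": planted_ids,
                }
            )
        },
    )
    return cells, gt


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def gen_embryo_image(
    seed: int,
    shape: tuple[int, int],
    domain_a: tuple[float, float],
    domain_b: tuple[float, float],
    edge_softness: float = 0.0,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    channel_names: tuple[str, str] = ("chA", "chB"),
) -> tuple[EmbryoImage, GroundTruth]:
    """Two-channel embryo image with logistic-edge AP expression domains.

    The mask is an inscribed ellipse; percent egg length for a column x is
    measured over the masked span (anterior-most masked column = 0%).
    Each channel is ``amplitude * rise(p - anterior) * fall(posterior - p)``
    with logistic edges of scale ``edge_softness`` (% egg length; 0 gives
    hard steps), plus Gaussian noise clipped at zero.
    """
    for ant, post in (domain_a, domain_b):
        if not 0.0 <= ant < post <= 100.0:
            raise ValueError("domain boundaries must satisfy 0 <= ant < post <= 100")
    h, w = shape
    if h < 8 or w < 20:
        raise ValueError("image too small for an embryo mask")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    cols = np.flatnonzero(mask.any(axis=0))
    first, last = int(cols[0]), int(cols[-1])
    pct = (np.arange(w) - first) / max(1, last - first) * 100.0

    channels: dict[str, np.ndarray] = {}
    for name, (ant, post) in zip(channel_names, (domain_a, domain_b)):
        if edge_softness > 0:
            profile = _logistic((pct - ant) / edge_softness) * _logistic(
                (post - pct) / edge_softness
            )
        else:
            profile = ((pct >= ant) & (pct < post)).astype(float)
        img = amplitude * np.broadcast_to(profile, (h, w)).copy()
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    expected_overlap = max(
        0.0, min(domain_a[1], domain_b[1]) - max(domain_a[0], domain_b[0])
    )
    gt = GroundTruth(
        "gen_embryo_image",
        seed,
        {
            "shape": list(shape),
            "domain_a": list(domain_a),
            "domain_b": list(domain_b),
            "edge_softness": edge_softness,
            "noise_sd": noise_sd,
            "amplitude": amplitude,
        },
        {
            "expected_overlap_pct": expected_overlap,
            "embryo_span": [first, last],
        },
    )
    return EmbryoImage(channels, mask), gt


def gen_gene_sets(
    seed: int,
    universe_size: int,
    set_sizes: tuple[int, int],
    planted_overlap: int,
) -> tuple[tuple["GeneSet", "GeneSet"], "GeneSet", GroundTruth]:
    """Two gene sets with an exact planted overlap inside a universe.

    ``planted_overlap`` genes are shared; the remaining members of the two
    sets are disjoint draws from the rest of the universe.
    """
    from .genesets import GeneSet

    n_a, n_b = set_sizes
    if planted_overlap > min(n_a, n_b):
        raise ValueError("planted_overlap exceeds a set size")
    if n_a + n_b - planted_overlap > universe_size:
        raise ValueError("sets cannot fit disjointly in the universe")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:05d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    shared = [universe[i] for i in perm[:planted_overlap]]
    a_only = [
        universe[i] for i in perm[planted_overlap : n_a]
    ]
    b_only = [
        universe[i] for i in perm[n_a : n_a + n_b - planted_overlap]
    ]
    A = GeneSet("A", shared + a_only)
    B = GeneSet("B", shared + b_only)
    gt = GroundTruth(
        "gen_gene_sets",
        seed,
        {
            "universe_size": universe_size,
            "set_sizes": [n_a, n_b],
            "planted_overlap": planted_overlap,
        },
        {"overlap_exact": planted_overlap, "shared_genes": sorted(shared)},
    )
    return (A, B), GeneSet("universe", universe), gt
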