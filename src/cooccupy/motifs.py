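"""PWM motif scanning and aggregation around ChIP peak centers.

A PWM is a per-position probability matrix over A, C, G, T scored against
sequence as summed log2 odds versus a background composition. Scanning
covers both strands (minus-strand hits are reported in forward
coordinates), with a match threshold expressed as a fraction of the PWM's
maximum attainable score. Aggregation histograms count hit centers in
fixed-width bins of distance from region centers, emulating
HOMER-style ``-size 2000 -hist 50`` motif aggregation plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "PWM",
    "MotifHit",
    "PeakSequenceSet",
    "AggregationProfile",
    "read_jaspar_pfm",
    "read_fasta",
    "reverse_complement",
    "information_content",
    "log_odds_score",
    "scan_sequence",
    "extract_centered_sequences",
    "peak_motif_fraction",
    "aggregation_profile",
]

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int codes (A=0, C=1, G=2, T=3, anything else=N=4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in zip("ACGT", range(4)):
        codes[arr == ord(base)] = code
    return codes


class PWM:
    """Position weight matrix with background and log-odds scoring.

    Parameters
    ----------
    name : motif identifier.
    probs : (L, 4) per-position probabilities over A, C, G, T; each row
        must sum to 1 within 1e-9.
    background : length-4 base frequencies, default uniform.
    pseudocount : the per-cell pseudocount applied at construction from
        counts (recorded for provenance; not re-applied here).
    """

    def __init__(
        self,
        name: str,
        probs: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.0,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 4-vector summing to 1")
        self.name = name
        self.probs = probs
        self.background = bg
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: Sequence[float] | None = None,
    ) -> "PWM":
        """Build from a (L, 4) count matrix, adding ``pseudocount`` per cell."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be (L, 4)")
        if (counts < 0).any():
            raise ValueError("negative counts")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=1, keepdims=True)
        return cls(name, probs, background, pseudocount)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, p_match: float = 0.997) -> "PWM":
        """Near-deterministic PWM from a consensus string (testing aid)."""
        L = len(consensus)
        probs = np.full((L, 4), (1.0 - p_match) / 3)
        for i, b in enumerate(consensus.upper()):
            probs[i, _CODE[b]] = p_match
        return cls(name, probs)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def __repr__(self) -> str:
        return f"PWM({self.name!r}, L={len(self)})"

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds matrix; the 5th column (N) scores 0."""
        with np.errstate(divide="ignore"):
            lods = np.log2(self.probs / self.background)
        return np.hstack([lods, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        """Maximum attainable log-odds score (consensus score)."""
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds[:, :4].min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1].copy()
        return PWM(self.name + "_rc", rc, self.background[::-1], self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """A PWM match; ``offset`` is the match start in forward coordinates
    regardless of strand."""

    sequence_id: str
    offset: int
    strand: str
    score: float


@dataclass
class PeakSequenceSet:
    """Fixed-length sequences centered on peak centers.

    Repeat-masked (lowercase) genome bases and out-of-chromosome positions
    appear as N; ``n_masked`` records the N count per sequence.
    """

    ids: list[str]
    sequences: list[str]
    size: int
    n_masked: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sequences:
            if len(s) != self.size:
                raise ValueError("all sequences must have the stated length")
        if not self.n_masked:
            self.n_masked = [s.count("N") for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class AggregationProfile:
    """Binned counts of motif-hit centers around region centers."""

    window: int
    bin_width: int
    counts: np.ndarray
    n_regions: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.counts) != 2 * self.window // self.bin_width:
            raise ValueError("counts length must be 2*window/bin_width")

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin center offsets in bp relative to the region center."""
        edges = np.arange(-self.window, self.window + 1, self.bin_width)
        return (edges[:-1] + edges[1:]) / 2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_jaspar_pfm(
    path: str | Path,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> PWM:
    """Read a JASPAR-format position frequency matrix into a PWM.

    Accepts the standard JASPAR layout: a ``>`` header followed by four
    labelled count rows (``A [ ... ]``). Counts are normalized per column
    after adding ``pseudocount`` to every cell.
    """
    from Bio import motifs as bio_motifs

    path = Path(path)
    with open(path) as fh:
        try:
            motif = bio_motifs.read(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"{path}: not a valid JASPAR PFM ({exc})") from exc
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float).T
    name = motif.matrix_id or motif.name or path.stem
    return PWM.from_counts(name, counts, pseudocount=pseudocount, background=background)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {name: sequence}; case is preserved so that
    lowercase repeat masking can be honoured downstream."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Scoring and scanning
# ---------------------------------------------------------------------------

def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits, ``2 + sum_b p_b log2 p_b``
    (uniform background), with 0*log(0) = 0."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


def log_odds_score(pwm: PWM, kmer: str) -> float:
    """Log2-odds score of a single k-mer; N positions contribute 0."""
    if len(kmer) != len(pwm):
        raise ValueError(f"k-mer length {len(kmer)} != PWM length {len(pwm)}")
    codes = _encode(kmer)
    bad = (codes == 4) & (np.frombuffer(kmer.upper().encode(), np.uint8) != ord("N"))
    if bad.any():
        raise ValueError(f"invalid character in k-mer {kmer!r}")
    return float(pwm.log_odds[np.arange(len(pwm)), codes].sum())


def _scan_one_strand(lods: np.ndarray, codes: np.ndarray, threshold: float):
    L = lods.shape[0]
    if len(codes) < L:
        return np.empty(0, int), np.empty(0, float)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = lods[np.arange(L)[None, :], windows].sum(axis=1)
    idx = np.flatnonzero(scores >= threshold)
    return idx, scores[idx]


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold_frac: float = 0.8,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All PWM matches on both strands scoring >= threshold_frac * max score.

    Minus-strand matches are scored against the reverse-complement PWM and
    reported at their forward-strand start offset. Hits are returned sorted
    by (offset, strand).
    """
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    threshold = threshold_frac * pwm.max_score
    codes = _encode(seq)
    hits: list[MotifHit] = []
    fwd_idx, fwd_scores = _scan_one_strand(pwm.log_odds, codes, threshold)
    for off, sc in zip(fwd_idx, fwd_scores):
        hits.append(MotifHit(sequence_id, int(off), "+", float(sc)))
    rc_lods = pwm.reverse_complement().log_odds
    rev_idx, rev_scores = _scan_one_strand(rc_lods, codes, threshold)
    for off, sc in zip(rev_idx, rev_scores):
        hits.append(MotifHit(sequence_id, int(off), "-", float(sc)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def extract_centered_sequences(
    genome: Mapping[str, str],
    peaks: PeakSet,
    size: int = 200,
    mask_lowercase: bool = True,
) -> PeakSequenceSet:
    """Extract ``size``-bp windows centered on each peak center.

    Lowercase (repeat-masked) bases become N when ``mask_lowercase`` is
    set; windows truncated at chromosome edges are N-padded so every
    sequence has exactly ``size`` bases.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for i, iv in enumerate(peaks):
        if iv.chrom not in genome:
            raise ValueError(
                f"chromosome {iv.chrom!r} missing from genome for peak "
                f"{iv.chrom}:{iv.start}-{iv.end}"
            )
        chrom_seq = genome[iv.chrom]
        c = iv.center
        lo, hi = c - size // 2, c - size // 2 + size
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(chrom_seq))
        window = chrom_seq[max(0, lo) : min(len(chrom_seq), hi)]
        if mask_lowercase:
            window = "".join(b if b.isupper() else "N" for b in window)
        else:
            window = window.upper()
        window = "".join(b if b in "ACGTN" else "N" for b in window)
        seqs.append("N" * left_pad + window + "N" * right_pad)
        ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}:{i}")
    return PeakSequenceSet(ids, seqs, size)


def peak_motif_fraction(
    pwm: PWM,
    seqs: PeakSequenceSet | Sequence[str],
    threshold_frac: float = 0.8,
) -> float:
    """Fraction of sequences containing >= 1 match (ZOOPS counting)."""
    sequences = seqs.sequences if isinstance(seqs, PeakSequenceSet) else list(seqs)
    if not sequences:
        raise ValueError("empty sequence set")
    with_hit = sum(
        1 for s in sequences if scan_sequence(pwm, s, threshold_frac)
    )
    return with_hit / len(sequences)


def aggregation_profile(
    pwm: PWM,
    regions: PeakSet,
    genome: Mapping[str, str],
    window: int = 1000,
    bin_width: int = 50,
    threshold_frac: float = 0.8,
    normalized: bool = False,
) -> AggregationProfile:
    """Histogram of motif-hit centers around region centers.

    For each region a ``2*window`` bp sequence centered on the region
    center is scanned on both strands; each hit is binned by its center
    (match start + L//2) minus the region center. ``normalized`` divides
    counts by the number of regions (per-region average), otherwise raw
    summed counts are returned.
    """
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    n_bins = 2 * window // bin_width
    counts = np.zeros(n_bins)
    seqset = extract_centered_sequences(genome, regions, size=2 * window)
    L = len(pwm)
    for seq in seqset.sequences:
        for hit in scan_sequence(pwm, seq, threshold_frac):
            center = hit.offset + L // 2
            d = center - window  # distance from region center
            if -window <= d < window:
                counts[(d + window) // bin_width] += 1
    if normalized:
        counts = counts / len(seqset)
    return AggregationProfile(window, bin_width, counts, len(seqset), normalized)
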