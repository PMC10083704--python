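import numpy as np
import pytest

from cooccupy.intervals import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peak_set(rng, label, n, chrom_lengths, max_len=400):
    """Random (possibly overlapping) peaks across the given chromosomes."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    ivs = []
    for _ in range(n):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        L = int(rng.integers(20, max_len))
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - L)))
        ivs.append(GenomicInterval(chrom, start, start + L))
    return PeakSet(label, ivs)


def per_base_union(peak_sets, chrom_lengths):
    """Brute-force oracle: per-base membership arrays and union runs.

    Returns {chrom: (covered bool array, {label: bool array})}.
    """
    out = {}
    for chrom, L in chrom_lengths.items():
        covered = np.zeros(L, dtype=bool)
        per_label = {}
        for ps in peak_sets:
            mask = np.zeros(L, dtype=bool)
            for iv in ps:
                if iv.chrom == chrom:
                    mask[iv.start : iv.end] = True
            per_label[ps.label] = mask
            covered |= mask
        out[chrom] = (covered, per_label)
    return out


def runs_of(mask):
    """Half-open (start, end) runs of True in a boolean array."""
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
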