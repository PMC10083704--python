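"""FISH image quantification along the embryo anterior-posterior axis.

The embryo is assumed pre-aligned with its AP axis along the image x
dimension, anterior at x = 0, with a segmentation mask (from upstream
tools) marking embryo pixels. Channel intensities are averaged over
masked pixels in fixed-width slices along x; expression-domain boundaries
are called on the per-channel-normalized profile as the longest contiguous
run of slices at or above a half-max threshold, reported in percent egg
length (0 = anterior pole) at the run's slice edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EmbryoImage",
    "APProfile",
    "DomainCall",
    "NucleusRecord",
    "ap_profile",
    "normalize_profile",
    "call_domain",
    "overlap_extent",
    "nuclei_coexpression_count",
]


class EmbryoImage:
    """Named 2-D channel intensity grids plus a boolean embryo mask."""

    def __init__(self, channels: Mapping[str, np.ndarray], mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty embryo mask")
        self.channels: dict[str, np.ndarray] = {}
        for name, arr in channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != mask.shape:
                raise ValueError(f"channel {name!r} shape differs from mask")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr
        self.mask = mask

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) masked column indices, inclusive."""
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(cols[0]), int(cols[-1])


@dataclass
class APProfile:
    """Per-slice mean channel intensities along the AP axis.

    Slices tile the masked embryo span from the anterior-most masked
    column in ``slice_width``-pixel steps; the final partial slice is
    kept. ``x_starts``/``x_ends`` are half-open pixel column ranges.
    """

    slice_width: int
    x_starts: np.ndarray
    x_ends: np.ndarray
    values: dict[str, np.ndarray]
    embryo_span: tuple[int, int]

    @property
    def n_slices(self) -> int:
        return len(self.x_starts)

    def midpoints_pct(self) -> np.ndarray:
        """Slice midpoints in % egg length (anterior pole = 0)."""
        first, last = self.embryo_span
        span = max(1, last - first)
        mids = (self.x_starts + self.x_ends - 1) / 2.0
        return (mids - first) / span * 100.0


@dataclass(frozen=True)
class DomainCall:
    """An expression domain in % egg length, 0 = anterior."""

    channel: str
    anterior_boundary: float
    posterior_boundary: float
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.anterior_boundary < self.posterior_boundary <= 100.0:
            raise ValueError("require 0 <= anterior < posterior <= 100")

    @property
    def extent(self) -> float:
        return self.posterior_boundary - self.anterior_boundary


@dataclass(frozen=True)
class NucleusRecord:
    """A segmented nucleus with per-gene boolean transcription calls."""

    nucleus_id: str
    x: float
    y: float
    calls: Mapping[str, bool]


def ap_profile(image: EmbryoImage, slice_width: int = 10) -> APProfile:
    """Average each channel over masked pixels in ``slice_width``-px
    slices along the AP axis.

    Pixels outside the mask never contribute; a slice whose columns hold
    no masked pixels reports 0. The terminal partial slice is retained so
    the embryo span is fully covered.
    """
    if slice_width < 1:
        raise ValueError("slice_width must be >= 1")
    first, last = image.span
    starts = np.arange(first, last + 1, slice_width)
    ends = np.minimum(starts + slice_width, last + 1)
    values: dict[str, np.ndarray] = {}
    mask = image.mask
    for name, arr in image.channels.items():
        means = np.zeros(len(starts))
        for i, (s, e) in enumerate(zip(starts, ends)):
            m = mask[:, s:e]
            n = m.sum()
            means[i] = arr[:, s:e][m].sum() / n if n else 0.0
        values[name] = means
    return APProfile(slice_width, starts, ends, values, (first, last))


def normalize_profile(profile: APProfile) -> APProfile:
    """Divide each channel by its own maximum slice value (max becomes 1)."""
    values = {}
    for name, v in profile.values.items():
        peak = v.max()
        if peak <= 0:
            raise ValueError(f"channel {name!r} is all zero; cannot normalize")
        values[name] = v / peak
    return APProfile(
        profile.slice_width,
        profile.x_starts,
        profile.x_ends,
        values,
        profile.embryo_span,
    )


def call_domain(
    profile: APProfile,
    channel: str,
    threshold_frac: float = 0.5,
) -> DomainCall:
    """Call the expression domain of one channel.

    The domain is the longest contiguous run of slices with (normalized)
    value >= ``threshold_frac``; ties go to the anterior-most run.
    Boundaries are the outer edges of the run's first and last slices in
    % egg length, so the true edge (which falls inside the adjacent
    partial slice) is within one slice width of the call.
    """
    if channel not in profile.values:
        raise KeyError(f"unknown channel {channel!r}")
    above = profile.values[channel] >= threshold_frac
    if not above.any():
        raise ValueError(f"no slice reaches threshold {threshold_frac} in {channel!r}")
    # longest run of True; anterior-most wins ties
    best_start = best_len = -1
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    first, last = profile.embryo_span
    span = max(1, last - first)
    ant_px = profile.x_starts[best_start]
    post_px = profile.x_ends[best_start + best_len - 1]
    ant = float(np.clip((ant_px - first) / span * 100.0, 0.0, 100.0))
    post = float(np.clip((post_px - first) / span * 100.0, 0.0, 100.0))
    return DomainCall(channel, ant, post, threshold_frac)


def overlap_extent(a: DomainCall, b: DomainCall) -> float:
    """Overlap of two domains in % egg length, clipped at 0."""
    lo = max(a.anterior_boundary, b.anterior_boundary)
    hi = min(a.posterior_boundary, b.posterior_boundary)
    return max(0.0, hi - lo)


def nuclei_coexpression_count(
    nuclei: Sequence[NucleusRecord],
    gene_a: str,
    gene_b: str,
    nucleus_diameter: float = 1.0,
) -> tuple[int, int]:
    """Count double-positive nuclei and the AP width they occupy.

    Returns ``(count, width_in_columns)`` where width is the number of
    distinct AP column ranks (x quantized by ``nucleus_diameter``)
    containing at least one nucleus with both transcription calls true.
    """
    if nucleus_diameter <= 0:
        raise ValueError("nucleus_diameter must be > 0")
    double = [
        nuc
        for nuc in nuclei
        if nuc.calls.get(gene_a, False) and nuc.calls.get(gene_b, False)
    ]
    columns = {int(np.floor(nuc.x / nucleus_diameter)) for nuc in double}
    return len(double), len(columns)
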