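"""Order clone averages along the chromosome, smooth, and call regions.

A centred moving average over a fixed number of clones (default 5) smooths
the per-clone log2 track; maximal runs of consecutive clones whose signal
exceeds a log2 threshold (default 0.2, strict) become called regions.
Calling can run on the smoothed track (default, matching how regions of
interest are highlighted on the smoothed line) or on the raw per-clone
averages (clone-resolution mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ratios import CloneProfile
from .tiling import TilingPath

__all__ = [
    "SmoothedTrack",
    "Region",
    "build_track",
    "smooth_track",
    "call_regions",
    "DEFAULT_WINDOW",
    "DEFAULT_CALL_THRESHOLD",
]

DEFAULT_WINDOW = 5
DEFAULT_CALL_THRESHOLD = 0.2


@dataclass(frozen=True)
class SmoothedTrack:
    """Per-clone mean log2 and its windowed average, in path order.

    Only clones that survived the replicate filter appear; excluded clones
    are absent, so the window spans surviving neighbours.
    """

    clone_ids: tuple[str, ...]
    mean_log2: np.ndarray
    smoothed_log2: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.clone_ids)


@dataclass(frozen=True)
class Region:
    """A maximal run of consecutive above-threshold clones."""

    chrom: str
    start: int  # min start over member clones
    end: int  # max end over member clones
    clone_ids: tuple[str, ...]
    peak_smoothed_log2: float
    n_clones: int

    @property
    def length(self) -> int:
        return self.end - self.start


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centred moving average; the window truncates at the ends (never pads).

    Position i averages values[max(0, i-h) : i+h+1] with h = window // 2.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or window == 1:
        return v.copy()
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def build_track(
    path: TilingPath,
    profiles: Sequence[CloneProfile],
    window: int = DEFAULT_WINDOW,
) -> SmoothedTrack:
    """Order surviving clone means along the path and smooth them.

    Profiles without a mean (insufficient replicates) and profiles for
    clones not on the path are left out of the track.
    """
    by_id = {p.clone_id: p for p in profiles}
    ids = [
        c.clone_id
        for c in path
        if c.clone_id in by_id and by_id[c.clone_id].mean_log2 is not None
    ]
    means = np.array([by_id[cid].mean_log2 for cid in ids], dtype=float)
    return SmoothedTrack(
        clone_ids=tuple(ids),
        mean_log2=means,
        smoothed_log2=moving_average(means, window),
        window=window,
    )


def smooth_track(values: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed average of an ordered log2 track (see :func:`moving_average`)."""
    return moving_average(values, window)


def call_regions(
    track: SmoothedTrack,
    path: TilingPath,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    use_smoothed: bool = True,
) -> list[Region]:
    """Maximal runs of consecutive track clones with signal > threshold (strict).

    Region genomic bounds come from the member clones' intervals. Regions
    are returned proximal → distal. A single below-threshold clone splits a
    region; there is no gap merging.
    """
    values = track.smoothed_log2 if use_smoothed else track.mean_log2
    above = values > threshold
    regions: list[Region] = []
    i = 0
    n = len(track)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        members = track.clone_ids[i:j]
        intervals = [path.clone(cid) for cid in members]
        regions.append(
            Region(
                chrom=path.chrom,
                start=min(c.start for c in intervals),
                end=max(c.end for c in intervals),
                clone_ids=tuple(members),
                peak_smoothed_log2=float(np.max(values[i:j])),
                n_clones=j - i,
            )
        )
        i = j
    return regions


def high_single_clones(
    track: SmoothedTrack, threshold: float = DEFAULT_CALL_THRESHOLD
) -> list[str]:
    """Clones individually above threshold on the raw per-clone track.

    Complements smoothed calling: an isolated high clone can be diluted
    below threshold by its neighbours yet still merit follow-up.
    """
    return [
        cid
        for cid, v in zip(track.clone_ids, track.mean_log2)
        if v > threshold
    ]


def regions_to_bed6(regions: Sequence[Region]) -> str:
    """BED6 text: name = region index, score = 1000×peak log2 clipped to [0, 1000]."""
    lines = []
    for i, r in enumerate(regions, start=1):
        score = int(np.clip(round(1000 * r.peak_smoothed_log2), 0, 1000))
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
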