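"""Chromosome-track plot: per-clone and smoothed log2 with regions shaded."""

from __future__ import annotations

from typing import Optional, Sequence

from .regions import Region, SmoothedTrack
from .tiling import TilingPath

MB = 1_000_000


def plot_track(
    track: SmoothedTrack,
    path: TilingPath,
    regions: Sequence[Region] = (),
    threshold: Optional[float] = 0.2,
    ax=None,
):
    """Clone midpoint position (Mb) vs mean log2 (crosses) and the windowed
    average (line); called regions are shaded."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    pos = [path.clone(cid).midpoint / MB for cid in track.clone_ids]
    ax.plot(pos, track.mean_log2, "+", color="grey", ms=4, label="clone mean")
    ax.plot(pos, track.smoothed_log2, "-", color="black", lw=1.2,
            label=f"{track.window}-clone average")
    for r in regions:
        ax.axvspan(r.start / MB, r.end / MB, color="black", alpha=0.15)
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel(f"position on {path.chrom} (Mb)")
    ax.set_ylabel("log2 ratio")
    ax.legend(loc="upper right", fontsize=8)
    return ax
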