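"""Model/results interface over the sex-comparison CGH pipeline.

:class:`CGHSexComparison` bundles the data for one experiment — replicate
spot tables, the clone tiling path, optional FISH annotations — with the
analysis parameters. ``fit()`` runs the full chain (log2 transform,
block-median normalization, confidence filtering, spot→clone collapse,
replicate averaging, windowed smoothing, region calling, and — when the
annotations support it — boundary inference) and returns a
:class:`CGHResults` carrying the estimates and diagnostics.

    >>> model = CGHSexComparison(spot_tables, path, annotations)
    >>> res = model.fit()
    >>> res.pab_call.report()["width_label"]
    '~400 kb'
    >>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import pab as pab_mod
from . import ratios, regions as regions_mod
from .pab import PABCall, PABInferenceError, RegionLabel
from .ratios import CloneProfile, profiles_to_frame
from .regions import Region, SmoothedTrack
from .tiling import AnnotatedPath, FishStatus, TilingPath, join_annotations

__all__ = ["CGHSexComparison", "CGHResults"]


class CGHSexComparison:
    """A male-vs-female array-CGH experiment on a BAC tiling path.

    Parameters
    ----------
    spot_tables
        Mapping replicate id → spot table (clone_id, block, intensity_test,
        intensity_ref, confidence), or a plain sequence of tables.
    path
        The assembly-ordered clone tiling path.
    annotations
        Optional per-clone FISH statuses; clones without one are UNTESTED.
    confidence_threshold, min_experiments, window, call_threshold
        Pipeline parameters; the defaults (0.7, 2, 5, 0.2) are the
        standard operating point for this design.
    smoothed_calling
        Call regions on the smoothed track (default) or on raw per-clone
        averages.
    """

    def __init__(
        self,
        spot_tables: Union[Mapping[str, pd.DataFrame], Sequence[pd.DataFrame]],
        path: TilingPath,
        annotations: Optional[Mapping[str, FishStatus]] = None,
        confidence_threshold: float = ratios.DEFAULT_CONFIDENCE_THRESHOLD,
        min_experiments: int = ratios.DEFAULT_MIN_EXPERIMENTS,
        window: int = regions_mod.DEFAULT_WINDOW,
        call_threshold: float = regions_mod.DEFAULT_CALL_THRESHOLD,
        smoothed_calling: bool = True,
    ):
        if not isinstance(spot_tables, Mapping):
            spot_tables = {f"rep{i + 1}": df for i, df in enumerate(spot_tables)}
        self.spot_tables = dict(spot_tables)
        self.path = path
        self.annotated: AnnotatedPath = join_annotations(path, annotations or {})
        self.confidence_threshold = confidence_threshold
        self.min_experiments = min_experiments
        self.window = window
        self.call_threshold = call_threshold
        self.smoothed_calling = smoothed_calling

    def fit(self) -> "CGHResults":
        profiles = ratios.clone_profiles(
            self.spot_tables,
            confidence_threshold=self.confidence_threshold,
            min_experiments=self.min_experiments,
        )
        track = regions_mod.build_track(self.path, profiles, window=self.window)
        called = regions_mod.call_regions(
            track,
            self.path,
            threshold=self.call_threshold,
            use_smoothed=self.smoothed_calling,
        )
        labels = pab_mod.classify_regions(called, self.annotated)

        pab_call: Optional[PABCall] = None
        pab_error: Optional[str] = None
        has_fish = any(
            s is not FishStatus.UNTESTED for s in self.annotated.status.values()
        )
        try:
            if has_fish:
                pab_call = pab_mod.infer_pab(self.annotated)
            elif len(track):
                pab_call = pab_mod.infer_pab_array_only(
                    track, self.path, threshold=self.call_threshold
                )
        except PABInferenceError as exc:
            pab_error = str(exc)

        return CGHResults(
            model=self,
            profiles=profiles,
            track=track,
            regions=called,
            region_labels=labels,
            pab_call=pab_call,
            pab_error=pab_error,
        )


@dataclass
class CGHResults:
    """Fitted estimates of one sex-comparison CGH analysis."""

    model: CGHSexComparison
    profiles: list[CloneProfile]
    track: SmoothedTrack
    regions: list[Region]
    region_labels: list[RegionLabel]
    pab_call: Optional[PABCall]
    pab_error: Optional[str] = None

    @property
    def clone_table(self) -> pd.DataFrame:
        """Per-clone per-replicate values, survival counts, and means."""
        return profiles_to_frame(self.profiles)

    @property
    def n_surviving_clones(self) -> int:
        return sum(1 for p in self.profiles if p.mean_log2 is not None)

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "n_clones": [r.n_clones for r in self.regions],
                "peak_log2": [r.peak_smoothed_log2 for r in self.regions],
                "label": [l.value for l in self.region_labels],
            }
        )

    def par_size(self) -> Optional[dict]:
        return None if self.pab_call is None else pab_mod.par_size(self.pab_call)

    def plot(self, ax=None):
        """Position vs per-clone and smoothed log2, called regions shaded."""
        from .plotting import plot_track

        return plot_track(self.track, self.model.path, self.regions, ax=ax)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Sex-comparison array-CGH results",
            "=" * 40,
            f"chromosome:          {m.path.chrom or '(empty)'}",
            f"clones on path:      {len(m.path)}",
            f"replicates:          {len(m.spot_tables)}",
            f"surviving clones:    {self.n_surviving_clones}"
            f" (>= {m.min_experiments} replicates at confidence >= {m.confidence_threshold})",
            f"smoothing window:    {m.window} clones",
            f"calling threshold:   log2 > {m.call_threshold}"
            f" ({'smoothed' if m.smoothed_calling else 'per-clone'})",
            f"regions called:      {len(self.regions)}",
        ]
        for i, (r, lab) in enumerate(zip(self.regions, self.region_labels), 1):
            lines.append(
                f"  region {i}: {r.chrom}:{r.start:,}-{r.end:,}"
                f"  clones={r.n_clones}  peak_log2={r.peak_smoothed_log2:.2f}  {lab.value}"
            )
        if self.pab_call is not None:
            rep = self.pab_call.report()
            lines += [
                "pseudoautosomal boundary:",
                f"  flanking clones:   {rep['last_par_clone']} (XY) | "
                f"{rep['first_xspecific_clone']} (X-only)"
                if rep["evidence"] == "fish"
                else f"  flanking clones:   {rep['last_par_clone']} | {rep['first_xspecific_clone']}",
                f"  interval:          {rep['interval_mb'][0]:.2f}-{rep['interval_mb'][1]:.2f} Mb"
                f" (width {rep['width_label']})",
                f"  PAR size:          ~{rep['par_size_mb']} Mb"
                f" (range {rep['par_size_range_mb'][0]}-{rep['par_size_range_mb'][1]} Mb)",
                f"  evidence:          {rep['evidence']}",
            ]
        elif self.pab_error:
            lines.append(f"pseudoautosomal boundary: not inferred ({self.pab_error})")
        return "\n".join(lines)
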