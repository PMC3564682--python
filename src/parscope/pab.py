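"""Pseudoautosomal boundary inference from an annotated tiling path.

The boundary (PAB) separates the pseudoautosomal region — shared by X and
Y, hence XY-homologous by FISH and balanced in male:female dosage — from
the X-specific region. On an ordered clone path the boundary must lie
between the most distal XY-homologous clone that precedes the first
X-only clone and that X-only clone itself: after the end of the last
clone with a Y signal, before the start of the first clone without one.

FISH evidence dominates array signal when both are available; an
array-only mode reports a wider, clone-resolution interval from the
proximal above-threshold run of the log2 track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .regions import Region, SmoothedTrack
from .tiling import AnnotatedPath, FishStatus, TilingPath

__all__ = [
    "PABCall",
    "PABInferenceError",
    "InconsistentAnnotationError",
    "RegionLabel",
    "infer_pab",
    "infer_pab_array_only",
    "par_size",
    "classify_regions",
    "format_mb",
]

MB = 1_000_000


class PABInferenceError(ValueError):
    """The annotated path carries no usable boundary evidence."""


class InconsistentAnnotationError(PABInferenceError):
    """X-only and XY-homologous clones interleave at the boundary."""


@dataclass(frozen=True)
class PABCall:
    """An inferred boundary interval and the PAR size it implies.

    The interval runs from the end of the last XY-homologous (pseudo-
    autosomal) clone to the start of the first X-only clone. The PAR size
    point estimate is the interval midpoint measured from the p-terminus
    (position 0); the size range is the interval itself.
    """

    chrom: str
    last_par_clone: str
    first_xspecific_clone: str
    interval_start: int
    interval_end: int
    evidence: str = "fish"
    provenance: str = ""  # free text for external evidence (e.g. sequence alignment)

    @property
    def width(self) -> int:
        return self.interval_end - self.interval_start

    @property
    def par_size_point_estimate(self) -> float:
        return (self.interval_start + self.interval_end) / 2

    @property
    def par_size_range(self) -> tuple[int, int]:
        return (self.interval_start, self.interval_end)

    def brackets(self, position: int) -> bool:
        """Whether a genomic position lies within the boundary interval."""
        return self.interval_start <= position <= self.interval_end

    def report(self) -> dict:
        """Human-readable summary at the field's customary precision.

        Interval endpoints in Mb to 2 decimals, width to the nearest
        100 kb with a "~" prefix, PAR size to 0.1 Mb.
        """
        return {
            "chrom": self.chrom,
            "last_par_clone": self.last_par_clone,
            "first_xspecific_clone": self.first_xspecific_clone,
            "interval_bp": [self.interval_start, self.interval_end],
            "interval_mb": [
                round(self.interval_start / MB, 2),
                round(self.interval_end / MB, 2),
            ],
            "width_bp": self.width,
            "width_kb_rounded": round(self.width / 100_000) * 100,
            "width_label": f"~{round(self.width / 100_000) * 100} kb",
            "par_size_mb": round(self.par_size_point_estimate / MB, 1),
            "par_size_range_mb": [
                round(self.interval_start / MB, 1),
                round(self.interval_end / MB, 1),
            ],
            "evidence": self.evidence,
            "provenance": self.provenance,
        }


def infer_pab(annotated: AnnotatedPath) -> PABCall:
    """Locate the boundary from FISH-typed clones on an ordered path.

    The last XY-homologous clone preceding the first X-only clone marks the
    distal edge of the PAR; the boundary interval is [that clone's end, the
    first X-only clone's start]. XY-homologous clones further distal (a
    separate homology block) do not participate, but an XY clone embedded
    *within* the first run of X-only clones is genuinely ambiguous and
    raises :class:`InconsistentAnnotationError` naming the clones involved.

    If the two flanking clones overlap, the interval width floors at 0 (a
    warning is emitted and the shared region midpoint is used as a point
    boundary).
    """
    path = annotated.path
    statuses = [annotated.status[c.clone_id] for c in path]

    first_xonly = next(
        (i for i, s in enumerate(statuses) if s is FishStatus.X_ONLY), None
    )
    if first_xonly is None:
        raise PABInferenceError(
            "no PAR evidence: no X-only clone on the path to bound the PAR distally"
        )
    last_xy = next(
        (
            i
            for i in range(first_xonly - 1, -1, -1)
            if statuses[i] is FishStatus.XY_HOMOLOGOUS
        ),
        None,
    )
    if last_xy is None:
        raise PABInferenceError(
            "no PAR evidence: no XY-homologous clone proximal to the first "
            f"X-only clone ({path[first_xonly].clone_id})"
        )

    # tight interleave check: an XY clone inside the first contiguous run of
    # informative clones that starts X-only is ambiguous, not a distal block
    j = first_xonly
    informative = [
        i
        for i in range(first_xonly, len(path))
        if statuses[i] in (FishStatus.X_ONLY, FishStatus.XY_HOMOLOGOUS)
    ]
    run_xonly: list[int] = []
    for i in informative:
        if statuses[i] is FishStatus.X_ONLY:
            run_xonly.append(i)
        else:
            # an XY clone re-appearing immediately after a single X-only clone
            # leaves the boundary undefined between them
            if len(run_xonly) < 2:
                bad = [path[k].clone_id for k in run_xonly + [i]]
                raise InconsistentAnnotationError(
                    "interleaved FISH statuses at the boundary: X-only clone(s) "
                    f"{bad[:-1]} proximal to XY-homologous clone {bad[-1]!r}"
                )
            break  # a distal homology block after an established X-only run

    last_par = path[last_xy]
    first_xspec = path[j]
    start, end = last_par.end, first_xspec.start
    if end < start:
        warnings.warn(
            f"flanking clones {last_par.clone_id} and {first_xspec.clone_id} "
            "overlap; boundary interval width floored at 0",
            stacklevel=2,
        )
        point = (max(start, first_xspec.start) + min(end, last_par.end)) // 2
        start = end = point
    return PABCall(
        chrom=path.chrom,
        last_par_clone=last_par.clone_id,
        first_xspecific_clone=first_xspec.clone_id,
        interval_start=start,
        interval_end=end,
        evidence="fish",
    )


def infer_pab_array_only(
    track: SmoothedTrack,
    path: TilingPath,
    threshold: float = 0.2,
) -> PABCall:
    """Clone-resolution boundary from the log2 track alone.

    On a male-vs-female comparison normalized to the X-specific level, the
    PAR is the proximal run of clones above the calling threshold. The run
    is taken on the raw per-clone averages (smoothing bleeds the boundary
    outward by half a window). The interval spans from the end of the last
    above-threshold clone of the proximal run to the start of the next
    clone on the track.
    """
    if len(track) == 0:
        raise PABInferenceError("empty track")
    values = track.mean_log2
    if values[0] <= threshold:
        raise PABInferenceError(
            "no PAR evidence: proximal end of the track is not above threshold"
        )
    i = 0
    while i < len(track) and values[i] > threshold:
        i += 1
    if i >= len(track):
        raise PABInferenceError(
            "no boundary: the whole track is above threshold"
        )
    last = path.clone(track.clone_ids[i - 1])
    nxt = path.clone(track.clone_ids[i])
    return PABCall(
        chrom=path.chrom,
        last_par_clone=last.clone_id,
        first_xspecific_clone=nxt.clone_id,
        interval_start=last.end,
        interval_end=max(nxt.start, last.end),
        evidence="array_only",
    )


def par_size(call: PABCall) -> dict:
    """PAR size report: midpoint point estimate plus the interval range.

    Sizes are reported in Mb to one decimal; the range endpoints are the
    boundary interval itself.
    """
    return {
        "point_estimate_bp": call.par_size_point_estimate,
        "point_estimate_mb": round(call.par_size_point_estimate / MB, 1),
        "range_bp": list(call.par_size_range),
        "range_mb": [
            round(call.interval_start / MB, 1),
            round(call.interval_end / MB, 1),
        ],
    }


class RegionLabel(Enum):
    PAR = "PAR"
    XY_HOMOLOGY = "XY_HOMOLOGY"
    REPETITIVE = "REPETITIVE"
    UNCONFIRMED = "UNCONFIRMED"
    CONFLICTING = "CONFLICTING"


def classify_regions(
    regions: Sequence[Region], annotated: AnnotatedPath
) -> list[RegionLabel]:
    """Label called regions by the FISH evidence of their member clones.

    A region is XY-homologous if at least one member is XY-homologous and
    none is X-only; it is the PAR if it additionally abuts the p-terminus
    (contains the first path clone). Regions of repetitive or X-autosomal
    clones are REPETITIVE; all-untested regions are UNCONFIRMED; any other
    mixture is CONFLICTING.
    """
    labels: list[RegionLabel] = []
    first_clone = annotated.path[0].clone_id if len(annotated.path) else None
    for region in regions:
        statuses = {annotated.status[cid] for cid in region.clone_ids}
        if (
            FishStatus.XY_HOMOLOGOUS in statuses
            and FishStatus.X_ONLY not in statuses
        ):
            if first_clone in region.clone_ids:
                labels.append(RegionLabel.PAR)
            else:
                labels.append(RegionLabel.XY_HOMOLOGY)
        elif statuses <= {FishStatus.UNTESTED}:
            labels.append(RegionLabel.UNCONFIRMED)
        elif statuses <= {
            FishStatus.PANGENOMIC_REPETITIVE,
            FishStatus.X_AUTOSOMAL,
            FishStatus.UNTESTED,
        } and statuses & {FishStatus.PANGENOMIC_REPETITIVE, FishStatus.X_AUTOSOMAL}:
            labels.append(RegionLabel.REPETITIVE)
        else:
            labels.append(RegionLabel.CONFLICTING)
    return labels


def format_mb(position_bp: float, decimals: int = 2) -> str:
    return f"{position_bp / MB:.{decimals}f} Mb"
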