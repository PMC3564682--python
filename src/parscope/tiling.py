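"""Clone interval model for a BAC tiling path.

A tiling path is an ordered set of BAC clones covering one chromosome
end-to-end; each clone is one array probe. Coordinates are 0-based,
half-open throughout (BED convention); human-readable reports convert to
1-based Mb.

FISH hybridisation outcomes enter the analysis as per-clone annotations:
a clone may hybridise to both X and Y (XY-homologous, i.e. pseudoautosomal
or within an XY homology block), to the X only, to the X plus an autosome,
to repetitive sequence genome-wide, or to an autosome only (a misassigned
library clone).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "CloneInterval",
    "TilingPath",
    "FishStatus",
    "AnnotatedPath",
    "TilingPathError",
    "AnnotationError",
    "load_tiling_path",
    "load_fish_annotations",
    "join_annotations",
]


class TilingPathError(ValueError):
    """Malformed tiling-path input (bad interval, duplicate clone, mixed chromosomes)."""


class AnnotationError(ValueError):
    """Malformed or conflicting FISH annotation input."""


class FishStatus(Enum):
    """FISH hybridisation category of a clone.

    ``XY_HOMOLOGOUS`` and ``X_ONLY`` are the two evidentiary classes for
    boundary inference: the pseudoautosomal boundary lies between the most
    distal XY-homologous clone and the first X-only clone.
    """

    XY_HOMOLOGOUS = "XY_HOMOLOGOUS"
    X_ONLY = "X_ONLY"
    X_AUTOSOMAL = "X_AUTOSOMAL"
    PANGENOMIC_REPETITIVE = "PANGENOMIC_REPETITIVE"
    AUTOSOMAL = "AUTOSOMAL"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class CloneInterval:
    """One BAC clone's assembly placement (0-based, half-open)."""

    clone_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TilingPathError(
                f"clone {self.clone_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _sort_key(c: CloneInterval):
    # ties on start broken by end, then clone_id, for a deterministic order
    return (c.start, c.end, c.clone_id)


class TilingPath:
    """Assembly-ordered BAC clones on one chromosome.

    Clones are kept sorted by (start, end, clone_id). Overlap and
    containment between clones are permitted — it is a tiling path, not a
    partition.
    """

    def __init__(self, chrom: str, clones: Iterable[CloneInterval]):
        clones = sorted(clones, key=_sort_key)
        seen: set[str] = set()
        for c in clones:
            if c.chrom != chrom:
                raise TilingPathError(
                    f"clone {c.clone_id!r} is on {c.chrom!r}, path is on {chrom!r}"
                )
            if c.clone_id in seen:
                raise TilingPathError(f"duplicate clone_id {c.clone_id!r}")
            seen.add(c.clone_id)
        self.chrom = chrom
        self.clones: tuple[CloneInterval, ...] = tuple(clones)
        self._index = {c.clone_id: i for i, c in enumerate(self.clones)}

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)

    def __getitem__(self, i: int) -> CloneInterval:
        return self.clones[i]

    def __contains__(self, clone_id: str) -> bool:
        return clone_id in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TilingPath)
            and self.chrom == other.chrom
            and self.clones == other.clones
        )

    def index(self, clone_id: str) -> int:
        """Position of a clone in path order."""
        return self._index[clone_id]

    def clone(self, clone_id: str) -> CloneInterval:
        return self.clones[self._index[clone_id]]

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.clones],
                "start": [c.start for c in self.clones],
                "end": [c.end for c in self.clones],
                "clone_id": [c.clone_id for c in self.clones],
            }
        )

    def write_bed(self, path: Union[str, Path, io.TextIOBase]) -> None:
        """Canonical 4-column BED output in path order."""
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


PathLike = Union[str, Path, io.IOBase]


def load_tiling_path(bed_source: PathLike) -> TilingPath:
    """Read a 4+-column BED (chrom, start, end, name) into a TilingPath.

    Input row order is irrelevant; the result is sorted. All rows must be on
    a single chromosome. Rejects duplicate clone names and rows with
    end <= start (reported with their 1-based line number).
    """
    df = pd.read_csv(
        bed_source,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "clone_id"],
    )
    if df.empty:
        return TilingPath(chrom="", clones=[])
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise TilingPathError(
            f"tiling path must be on a single chromosome, got {sorted(chroms)}"
        )
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        i = int(bad[0])
        row = df.loc[i]
        raise TilingPathError(
            f"line {i + 1}: end ({row['end']}) must exceed start ({row['start']}) "
            f"for clone {row['clone_id']!r}"
        )
    dups = df["clone_id"][df["clone_id"].duplicated()]
    if len(dups):
        raise TilingPathError(f"duplicate clone_id {dups.iloc[0]!r}")
    clones = [
        CloneInterval(str(r.clone_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    return TilingPath(chrom=str(chroms[0]), clones=clones)


def load_fish_annotations(source: PathLike) -> dict[str, FishStatus]:
    """Read a two-column TSV (clone_id, status) of FISH outcomes.

    Duplicate rows for one clone are rejected if they conflict; exact
    duplicates are collapsed.
    """
    df = pd.read_csv(
        source, sep="\t", header=None, comment="#", names=["clone_id", "status"]
    )
    ann: dict[str, FishStatus] = {}
    for r in df.itertuples():
        cid = str(r.clone_id)
        try:
            status = FishStatus(str(r.status).strip().upper())
        except ValueError:
            raise AnnotationError(
                f"clone {cid!r}: unknown FISH status {r.status!r}"
            ) from None
        if cid in ann and ann[cid] is not status:
            raise AnnotationError(
                f"conflicting annotations for clone {cid!r}: "
                f"{ann[cid].value} vs {status.value}"
            )
        ann[cid] = status
    return ann


@dataclass(frozen=True)
class AnnotatedPath:
    """A tiling path with one FISH status per clone.

    ``unknown_clones`` lists annotation clone_ids absent from the path —
    they are reported, never silently dropped.
    """

    path: TilingPath
    status: Mapping[str, FishStatus]
    unknown_clones: tuple[str, ...] = ()

    def status_of(self, clone_id: str) -> FishStatus:
        return self.status[clone_id]

    def clones_with_status(self, status: FishStatus) -> list[CloneInterval]:
        return [c for c in self.path if self.status[c.clone_id] is status]


def join_annotations(
    path: TilingPath, annotations: Mapping[str, FishStatus]
) -> AnnotatedPath:
    """Attach FISH statuses to a tiling path.

    Clones without an annotation get UNTESTED. Annotations for clones not
    in the path are returned in ``unknown_clones``. Never changes clone
    count or order.
    """
    status = {
        c.clone_id: annotations.get(c.clone_id, FishStatus.UNTESTED) for c in path
    }
    unknown = tuple(sorted(cid for cid in annotations if cid not in path))
    return AnnotatedPath(path=path, status=status, unknown_clones=unknown)


def annotate(
    path: TilingPath, statuses: Sequence[FishStatus]
) -> AnnotatedPath:
    """Convenience: annotate every clone positionally (mostly for tests/simulation)."""
    if len(statuses) != len(path):
        raise AnnotationError(
            f"{len(statuses)} statuses for {len(path)} clones"
        )
    return AnnotatedPath(
        path=path,
        status={c.clone_id: s for c, s in zip(path, statuses)},
    )
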