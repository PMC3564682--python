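"""Spot table → one filtered, normalized, averaged log2 ratio per clone.

The processing chain for two-channel comparative genomic hybridisation:

1. log2-transform the test/reference intensity ratio of every spot;
2. block-median normalization — subtract each print block's median log2 so
   block-to-block technical variation cancels;
3. drop measurements with quantification confidence below a threshold
   (default 0.7), per replicate;
4. collapse a clone's surviving spots to one value per replicate (mean);
5. average across replicates, keeping only clones with values surviving in
   at least ``min_experiments`` replicates (default 2).

Each hybridisation replicate is treated as a separate experiment
throughout; a clone excluded in one replicate can still survive in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CloneProfile",
    "compute_log2_ratios",
    "block_median_normalize",
    "filter_confidence",
    "collapse_spots_to_clone",
    "average_replicates",
    "clone_profiles",
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "DEFAULT_MIN_EXPERIMENTS",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.7
DEFAULT_MIN_EXPERIMENTS = 2

REASON_OK = "ok"
REASON_INSUFFICIENT = "insufficient_replicates"


@dataclass(frozen=True)
class CloneProfile:
    """One clone's per-replicate normalized log2 ratios and their average.

    ``mean_log2`` is present iff the clone has values in at least the
    required number of replicates.
    """

    clone_id: str
    per_replicate_log2: dict[str, float]
    n_surviving: int
    mean_log2: Optional[float]
    reason: str = REASON_OK


def compute_log2_ratios(spots: pd.DataFrame) -> pd.DataFrame:
    """Add a ``log2`` column = log2(intensity_test / intensity_ref).

    Spots with a non-positive intensity in either channel are excluded
    (logged with a count), never propagated as NaN/inf.
    """
    valid = (spots["intensity_test"] > 0) & (spots["intensity_ref"] > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("excluding %d spots with non-positive intensities", n_bad)
    out = spots.loc[valid].copy()
    out["log2"] = np.log2(out["intensity_test"].to_numpy() / out["intensity_ref"].to_numpy())
    return out


def block_median_normalize(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract each print block's median log2 from its spots.

    After normalization every block's median is 0. The number of blocks is
    taken from the data. A block present in the input but holding no valid
    spots is an error naming the block.
    """
    if "block" not in spots.columns:
        raise ValueError("spots lack a 'block' column")
    if spots["log2"].isna().any():
        bad_blocks = sorted(spots.loc[spots["log2"].isna(), "block"].unique())
        raise ValueError(f"NaN log2 values in blocks {bad_blocks}")
    counts = spots.groupby("block")["log2"].count()
    empty = counts.index[counts == 0].tolist()
    if empty:
        raise ValueError(f"block(s) {empty} contain no valid spots")
    out = spots.copy()
    out["log2"] = out["log2"] - out.groupby("block")["log2"].transform("median")
    return out


def filter_confidence(
    spots: pd.DataFrame, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> pd.DataFrame:
    """Keep spots whose confidence is at or above the threshold.

    Exclusion is strict: confidence < threshold is dropped, confidence ==
    threshold survives. Applied per replicate — a clone failing here in one
    replicate may still survive in another.
    """
    return spots.loc[spots["confidence"] >= threshold].copy()


def collapse_spots_to_clone(spots: pd.DataFrame) -> pd.Series:
    """One value per clone in one replicate: mean of its surviving spots.

    Clones with zero surviving spots are simply absent from the result.
    Single-spot clones pass through unchanged.
    """
    return spots.groupby("clone_id")["log2"].mean()


def average_replicates(
    per_replicate: Mapping[str, pd.Series],
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> list[CloneProfile]:
    """Average each clone's per-replicate values across experiments.

    Clones with fewer than ``min_experiments`` surviving values carry no
    mean and are flagged ``insufficient_replicates``; they stay in the
    output (so exclusions are auditable) but must not feed region calling.
    """
    clone_ids: list[str] = sorted(
        {cid for series in per_replicate.values() for cid in series.index}
    )
    profiles = []
    for cid in clone_ids:
        values = {
            rep: float(series.loc[cid])
            for rep, series in per_replicate.items()
            if cid in series.index
        }
        n = len(values)
        if n >= min_experiments:
            mean = float(np.mean(list(values.values())))
            profiles.append(CloneProfile(cid, values, n, mean, REASON_OK))
        else:
            profiles.append(CloneProfile(cid, values, n, None, REASON_INSUFFICIENT))
    return profiles


def clone_profiles(
    replicates: Union[Mapping[str, pd.DataFrame], Sequence[pd.DataFrame]],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> list[CloneProfile]:
    """Run the full chain on a set of replicate spot tables.

    ``replicates`` may be a mapping replicate_id → spot table or a plain
    sequence (ids then default to ``rep1..repN``). The result is invariant
    to the order in which replicate tables are supplied.
    """
    if not isinstance(replicates, Mapping):
        replicates = {f"rep{i + 1}": df for i, df in enumerate(replicates)}
    per_rep: dict[str, pd.Series] = {}
    for rep_id in sorted(replicates):
        df = compute_log2_ratios(replicates[rep_id])
        df = block_median_normalize(df)
        df = filter_confidence(df, threshold=confidence_threshold)
        per_rep[rep_id] = collapse_spots_to_clone(df)
    return average_replicates(per_rep, min_experiments=min_experiments)


def profiles_to_frame(profiles: Sequence[CloneProfile]) -> pd.DataFrame:
    """Tabular view: clone_id, one column per replicate, n_surviving, mean_log2, status."""
    rep_ids = sorted({r for p in profiles for r in p.per_replicate_log2})
    rows = []
    for p in profiles:
        row: dict = {"clone_id": p.clone_id}
        for r in rep_ids:
            row[r] = p.per_replicate_log2.get(r, np.nan)
        row["n_surviving"] = p.n_surviving
        row["mean_log2"] = np.nan if p.mean_log2 is None else p.mean_log2
        row["status"] = p.reason
        rows.append(row)
    return pd.DataFrame(rows)
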