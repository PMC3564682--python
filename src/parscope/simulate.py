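"""Synthetic two-channel array-CGH data with known dosage ground truth.

The generator emulates a male-vs-female co-hybridisation onto an
X-chromosome BAC tiling-path array. Male genomic DNA is the test
(numerator) channel, female the reference channel, so on the raw log2 scale:

* X-specific clones (1 male copy vs 2 female) sit at -1.0,
* pseudoautosomal and XY-homologous clones (2 vs 2) sit at 0.0,
* misassigned autosomal clones (2 vs 2) sit at 0.0,
* pangenomic-repetitive clones pick up extra cross-hybridising test signal
  (configurable positive shift).

Because X-specific clones are the within-block majority on an X tiling
array, block-median normalization anchors the X-specific level at 0 and
moves balanced-dosage clones to about +1 — the orientation under which a
positive log2 threshold marks XY homology.

Spot-level noise is additive Gaussian on the log2 scale (multiplicative
lognormal on intensities); each print block carries its own intensity bias;
each spot carries a quantification confidence score with a dropout
mechanism that pushes a configured fraction of spots below the 0.7 quality
threshold. Replicates are generated i.i.d. (no dye-swap structure is
modelled).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .tiling import AnnotatedPath, CloneInterval, FishStatus, TilingPath, annotate

__all__ = [
    "CloneClass",
    "SimulationConfig",
    "DosageTruth",
    "generate_truth",
    "simulate_arrays",
    "fish_status_for_class",
    "annotate_from_truth",
    "write_spot_table",
    "read_spot_table",
    "write_truth",
]

CONFIDENCE_THRESHOLD = 0.7  # the downstream quality filter the dropout targets


class CloneClass(Enum):
    """Ground-truth dosage class of a simulated clone."""

    PAR = "PAR"
    X_SPECIFIC = "X_SPECIFIC"
    XY_HOMOLOGY_BLOCK = "XY_HOMOLOGY_BLOCK"
    REPETITIVE = "REPETITIVE"
    AUTOSOMAL_MISASSIGNED = "AUTOSOMAL_MISASSIGNED"


# expected pre-normalization log2(test/ref) per class; REPETITIVE adds
# `repetitive_shift` on top of its balanced baseline
_BASE_OFFSET = {
    CloneClass.PAR: 0.0,
    CloneClass.XY_HOMOLOGY_BLOCK: 0.0,
    CloneClass.AUTOSOMAL_MISASSIGNED: 0.0,
    CloneClass.REPETITIVE: 0.0,
    CloneClass.X_SPECIFIC: None,  # filled from config (−balanced shift)
}


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated experiment.

    Defaults mirror the design the analysis assumes: four technical
    replicates, sixteen print blocks, a proximal PAR occupying ~4.7% of a
    144 Mb X chromosome (~6.7 Mb), a three-clone XY homology block near the
    q-terminus, and moderate spot noise/dropout.
    """

    n_clones: int = 600
    chrom_length: int = 144_000_000
    chrom: str = "X"
    par_fraction: float = 0.047
    xy_block_n_clones: int = 3
    xy_block_offset_from_end: int = 5
    repetitive_fraction: float = 0.03
    misassigned_fraction: float = 0.01
    n_replicates: int = 4
    n_blocks: int = 16
    spots_per_clone: int = 1
    mean_log2_shift_balanced: float = 1.0  # balanced-dosage minus X-specific level
    spot_noise_sd: float = 0.2  # log2 units
    block_bias_sd: float = 0.15  # log2 units
    repetitive_shift: float = 0.8  # log2 units of extra test signal
    confidence_alpha: float = 8.0
    confidence_beta: float = 2.0
    dropout_rate: float = 0.15  # fraction of spots forced below 0.7 confidence
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.spots_per_clone < 1:
            raise ValueError("spots_per_clone must be >= 1")
        for name in ("par_fraction", "repetitive_fraction", "misassigned_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("spot_noise_sd", "block_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.confidence_alpha <= 0 or self.confidence_beta <= 0:
            raise ValueError("confidence beta-distribution parameters must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DosageTruth:
    """Ground truth attached to a simulated tiling path."""

    clone_class: dict[str, CloneClass]
    true_pab_position: int
    xy_block_interval: Optional[tuple[int, int]] = None

    def clones_of(self, cls: CloneClass) -> list[str]:
        return [cid for cid, c in self.clone_class.items() if c is cls]


def generate_truth(config: SimulationConfig) -> tuple[TilingPath, DosageTruth]:
    """Lay out a synthetic tiling path and assign dosage classes.

    Clones abut end-to-start at uniform spacing, so the true boundary is
    the shared coordinate between the last pseudoautosomal clone and the
    first X-specific one. Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_clones
    spacing = config.chrom_length // n
    clones = [
        CloneInterval(f"SYN-{i:04d}", config.chrom, i * spacing, (i + 1) * spacing)
        for i in range(n)
    ]
    path = TilingPath(config.chrom, clones)

    boundary = config.par_fraction * config.chrom_length
    n_par = sum(1 for c in path if c.end <= boundary)
    if n_par == 0:
        raise ValueError(
            f"par_fraction={config.par_fraction} leaves no whole clone in the PAR "
            f"(clone spacing {spacing} bp)"
        )
    true_pab = path[n_par - 1].end  # == path[n_par].start (abutting layout)

    classes: dict[str, CloneClass] = {}
    for i, c in enumerate(path):
        classes[c.clone_id] = CloneClass.PAR if i < n_par else CloneClass.X_SPECIFIC

    # one contiguous XY homology block near the distal end
    xy_interval = None
    k = config.xy_block_n_clones
    if k > 0:
        hi = n - config.xy_block_offset_from_end
        lo = hi - k
        if lo <= n_par:
            raise ValueError("XY homology block would overlap the PAR; shrink it")
        for i in range(lo, hi):
            classes[path[i].clone_id] = CloneClass.XY_HOMOLOGY_BLOCK
        xy_interval = (path[lo].start, path[hi - 1].end)
    else:
        lo, hi = n, n

    # sprinkle repetitive and misassigned clones over PAR/X-specific clones,
    # never inside the XY block (it must stay one contiguous class run)
    eligible = np.array([i for i in range(n) if not lo <= i < hi])
    n_rep = int(round(config.repetitive_fraction * n))
    n_mis = int(round(config.misassigned_fraction * n))
    chosen = rng.choice(eligible, size=min(n_rep + n_mis, len(eligible)), replace=False)
    for i in chosen[:n_rep]:
        classes[path[int(i)].clone_id] = CloneClass.REPETITIVE
    for i in chosen[n_rep:]:
        classes[path[int(i)].clone_id] = CloneClass.AUTOSOMAL_MISASSIGNED

    return path, DosageTruth(
        clone_class=classes,
        true_pab_position=int(true_pab),
        xy_block_interval=xy_interval,
    )


def _raw_offsets(classes: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Expected pre-normalization log2 per clone, by class."""
    out = np.zeros(len(classes))
    out[classes == CloneClass.X_SPECIFIC.value] = -config.mean_log2_shift_balanced
    out[classes == CloneClass.REPETITIVE.value] = config.repetitive_shift
    return out


def simulate_arrays(
    path: TilingPath,
    truth: DosageTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[pd.DataFrame]:
    """Simulate one spot table per technical replicate.

    Each returned DataFrame has columns ``clone_id, block, intensity_test,
    intensity_ref, confidence``. Spots are assigned to print blocks
    round-robin in path order, so every block is populated and every block
    keeps the X-specific majority needed for block-median normalization to
    anchor on the X-specific level.
    """
    config.validate()
    missing = [c.clone_id for c in path if c.clone_id not in truth.clone_class]
    if missing:
        raise ValueError(f"truth does not cover clones: {missing[:5]}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_spots = len(path) * config.spots_per_clone
    clone_ids = np.repeat([c.clone_id for c in path], config.spots_per_clone)
    classes = np.repeat(
        [truth.clone_class[c.clone_id].value for c in path], config.spots_per_clone
    )
    blocks = (np.arange(n_spots) % config.n_blocks) + 1
    _check_block_majority(classes, blocks, config.n_blocks)

    offsets = _raw_offsets(classes, config)
    replicates: list[pd.DataFrame] = []
    for _ in range(config.n_replicates):
        block_bias = rng.normal(0.0, config.block_bias_sd, size=config.n_blocks)
        log2 = (
            offsets
            + block_bias[blocks - 1]
            + rng.normal(0.0, config.spot_noise_sd, size=n_spots)
        )
        # reference-channel brightness varies lognormally per spot; the test
        # channel is derived from it so the intensity ratio is exact
        ref = 1000.0 * np.exp(rng.normal(0.0, 0.3, size=n_spots))
        test = ref * np.exp2(log2)

        conf = _simulate_confidence(rng, n_spots, config)
        replicates.append(
            pd.DataFrame(
                {
                    "clone_id": clone_ids,
                    "block": blocks,
                    "intensity_test": test,
                    "intensity_ref": ref,
                    "confidence": conf,
                }
            )
        )
    return replicates


def _simulate_confidence(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    """Beta-distributed confidence with a forced-dropout mixture.

    A ``dropout_rate`` fraction of spots is drawn uniformly below the 0.7
    quality threshold; the remainder from 0.7 + 0.3·Beta(α, β), so the
    fraction failing the filter equals the configured rate exactly in
    expectation.
    """
    drop = rng.random(n) < config.dropout_rate
    conf = CONFIDENCE_THRESHOLD + (1 - CONFIDENCE_THRESHOLD) * rng.beta(
        config.confidence_alpha, config.confidence_beta, size=n
    )
    conf[drop] = rng.uniform(0.0, CONFIDENCE_THRESHOLD, size=int(drop.sum()))
    # guard against beta draws rounding just under the threshold
    conf[~drop] = np.maximum(conf[~drop], CONFIDENCE_THRESHOLD)
    return conf


def _check_block_majority(classes: np.ndarray, blocks: np.ndarray, n_blocks: int) -> None:
    for b in range(1, n_blocks + 1):
        mask = blocks == b
        if mask.sum() == 0:
            continue
        frac = (classes[mask] == CloneClass.X_SPECIFIC.value).mean()
        if frac <= 0.5:
            warnings.warn(
                f"block {b}: X-specific clones are not a strict majority "
                f"({frac:.0%}); block-median normalization will not anchor "
                "on the X-specific level",
                stacklevel=3,
            )


def fish_status_for_class(cls: CloneClass) -> FishStatus:
    """The FISH outcome a clone of this dosage class would show.

    PAR and XY-homology-block clones hybridise to both X and Y; X-specific
    clones to the X only; repetitive clones paint the genome; misassigned
    clones land on an autosome.
    """
    return {
        CloneClass.PAR: FishStatus.XY_HOMOLOGOUS,
        CloneClass.XY_HOMOLOGY_BLOCK: FishStatus.XY_HOMOLOGOUS,
        CloneClass.X_SPECIFIC: FishStatus.X_ONLY,
        CloneClass.REPETITIVE: FishStatus.PANGENOMIC_REPETITIVE,
        CloneClass.AUTOSOMAL_MISASSIGNED: FishStatus.AUTOSOMAL,
    }[cls]


def annotate_from_truth(path: TilingPath, truth: DosageTruth) -> AnnotatedPath:
    """Fully FISH-annotate a simulated path from its ground truth."""
    return annotate(
        path, [fish_status_for_class(truth.clone_class[c.clone_id]) for c in path]
    )


# ---------------------------------------------------------------------------
# I/O: GPR-like TSV spot tables, truth tables

SPOT_COLUMNS = ["clone_id", "block", "intensity_test", "intensity_ref", "confidence"]


def write_spot_table(
    df: pd.DataFrame, dest: Union[str, Path], seed: Optional[int] = None
) -> None:
    """Write one replicate's spots as a GPR-like TSV with a comment header."""
    dest = Path(dest)
    with dest.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# columns: " + "\t".join(SPOT_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=True, index=False, columns=SPOT_COLUMNS)


def read_spot_table(source: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {source}: missing columns {missing}")
    return df[SPOT_COLUMNS]


def write_truth(
    path: TilingPath, truth: DosageTruth, dest_tsv: Union[str, Path],
    dest_json: Optional[Union[str, Path]] = None,
) -> None:
    """Write per-clone truth as TSV and scalar truth (boundary, block) as JSON."""
    df = path.to_dataframe()
    df["clone_class"] = [truth.clone_class[c].value for c in df["clone_id"]]
    df.to_csv(dest_tsv, sep="\t", index=False)
    if dest_json is not None:
        payload = {
            "true_pab_position": truth.true_pab_position,
            "xy_block_interval": list(truth.xy_block_interval)
            if truth.xy_block_interval
            else None,
        }
        Path(dest_json).write_text(json.dumps(payload, indent=2) + "\n")
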