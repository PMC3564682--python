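# Methods

## Signal model

Two-channel CGH between male (test, Cy-labelled) and female (reference)
genomic DNA on an X-chromosome BAC tiling array measures relative copy
number per clone. On the log2 scale the expected pre-normalization ratio is

* −1 for X-specific clones (one male copy vs two female copies),
* 0 for pseudoautosomal and XY-homologous clones (two vs two),
* 0 for clones misassigned to the X from an autosome (two vs two),
* 0 + δ for clones dominated by dispersed repetitive sequence, where δ > 0
  reflects cross-hybridising test signal (default 0.8).

Print-block technical bias is additive on the log2 scale; spot noise is
additive Gaussian on log2 (equivalently, multiplicative lognormal on
intensities), the standard two-channel assumption.

**Normalization anchor.** Block-median normalization subtracts each print
block's median log2. On an X tiling array the X-specific clones are the
strict within-block majority, so the block median estimates the X-specific
level plus the block bias: after subtraction X-specific clones sit at ~0
and balanced-dosage clones at ~+1. This is the only orientation under
which a positive threshold (log2 > 0.2) marks XY homology, and it is why
the simulator warns if a block configuration breaks the X-specific
majority. Normalization is computed over all valid spots *before* the
confidence filter, matching a workflow in which the quantification
software normalizes at export and quality exclusion happens downstream.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| confidence threshold | 0.7 | – | a spot survives iff confidence ≥ 0.7; exclusion is per replicate (strict `<` excludes) |
| min. experiments | 2 | replicates | a clone gets an average iff it survives in ≥ 2 replicates; otherwise it is retained with reason `insufficient_replicates` and excluded from calling |
| smoothing window | 5 | clones | centred moving average along the ordered path; truncates at the ends, never pads; must be odd |
| calling threshold | 0.2 | log2 | maximal runs of consecutive clones strictly above threshold become regions; no gap merging |

Spot → clone collapse within a replicate is the mean of surviving spots
(single-spot clones pass through unchanged). Replicate averaging is the
arithmetic mean of the surviving per-replicate values.

Region calling runs on the smoothed track by default (regions of interest
are highlighted on the smoothed line); `--raw-calling` switches to raw
per-clone averages, the reading under which calling is exact at sharp
class edges. Individually high clones diluted by smoothing are surfaced
separately (`high_single_clones`).

## Boundary inference

With FISH evidence, the boundary interval is
`[end of the most distal XY-homologous clone preceding the first X-only
clone, start of that X-only clone]`. FISH dominates array signal when both
are present: the boundary rests on presence/absence of a Y signal, not on
the smoothed track. The PAR size point estimate is the interval midpoint
measured from position 0 — a single rule that reproduces both the interval
range and the single-figure size at their customary precision (width to
the nearest 100 kb with a `~` prefix; sizes to 0.1 Mb; interval endpoints
to 0.01 Mb). If the flanking clones overlap, width floors at 0 with a
warning. The interval endpoints are read as end-of-XY-clone /
start-of-X-only-clone; this is the reading that leaves a positive-width
gap between flanking clones rather than a negative one.

Annotation sanity: no XY-homologous clone before the first X-only clone is
an error (`no PAR evidence`). An XY clone re-appearing *inside* the first
contiguous run of X-only clones (fewer than two X-only clones establish
the run) is a genuinely ambiguous interleave and raises an error naming
the clones. XY clones beyond an established X-only run are legitimate —
they are a separate homology block, exactly as a real X chromosome with a
distal XY homology region looks — and are labelled through region
classification instead (`PAR` if the region abuts the p-terminus,
`XY_HOMOLOGY` otherwise, `REPETITIVE`/`UNCONFIRMED`/`CONFLICTING` for the
rest).

**Array-only mode.** Without FISH annotations the boundary is the end of
the proximal above-threshold run of the *raw* per-clone track (smoothing
necessarily bleeds ⌊window/2⌋ clones past a sharp dosage edge, so the raw
track is the clone-resolution reading); the reported interval spans to the
start of the next surviving clone and is wider and noisier than the FISH
interval by construction.

## Synthetic data: what it emulates, what it does not

The generator reproduces the features the pipeline is sensitive to: four
i.i.d. technical replicates; sixteen print blocks with per-replicate
Gaussian block biases (sd 0.15); class-structured dosage offsets; lognormal
spot noise (sd 0.2 in log2); beta-distributed confidence scores with a
forced-dropout mixture placing a `dropout_rate` fraction of spots (default
0.15, Bernoulli per spot) below the 0.7 filter; a proximal PAR occupying 4.7% of a 144 Mb
chromosome (~6.7 Mb); a contiguous three-clone XY homology block five
clones from the distal end; 3% repetitive and 1% misassigned clones
sprinkled outside the block. Clones abut end-to-start at uniform spacing,
so the true boundary is a single shared coordinate and the recovery
question is well-posed.

It does **not** model: dye-swap designs or dye-specific bias (replicates
are i.i.d.), spatial print-tip gradients beyond the per-block constant,
background subtraction, intensity-dependent (loess-type) trends, clone
positional uncertainty, or spot morphology artefacts. Passing recovery
tests therefore demonstrate correctness of the computation under the
stated noise model, not robustness to systematic effects the model
excludes.

Misassigned autosomal clones are balanced-dosage (2:2), so they genuinely
appear above threshold after normalization — as isolated called regions —
which is the behaviour such clones show in practice; recovery tests count
them as expected calls, and FISH-based region classification is what
separates them from true XY homology.

## Numerical choices and edge cases

* Coordinates are 0-based half-open internally (BED convention); reports
  print Mb at 1-based-friendly precision. Ties in clone ordering break by
  (start, end, clone_id).
* The moving average uses a cumulative-sum formulation with truncated
  windows at the ends; window 1 is an exact identity (no cumsum rounding).
* Thresholds are strict (`>` for calling, `<` for confidence exclusion);
  confidence exactly 0.7 survives.
* Median subtraction keeps exact binary floats exact: in the noise-free
  limit X-specific clones land at exactly 0.0 and balanced clones at
  exactly +1.0, and the tests assert bit-exact equality there.
* A block with no valid spots is an error naming the block; non-positive
  intensities are excluded with a logged count rather than propagated.
* Degenerate boundary cases: abutting flanking clones give a width-0
  interval at the shared coordinate; overlapping flanking clones floor the
  width at 0 with a warning.
* The gene classifier resolves multi-chromosome matches by the first
  listed location (the closest match) and accepts a `par_region` flag for
  matches that hit pseudoautosomal sequence without a gene-level
  coordinate; a position on a no-match row is a per-row error.

## Problem sizes

Default simulations use 600 clones × 4 replicates × 1 spot per clone. The
boundary-recovery check runs 100 independent seeded simulations at the
default noise point and completes in a few seconds; at that operating
point the FISH-annotated interval brackets the truth in ≥95% of runs and
the array-only boundary lands within ±2 clones of truth in ≥90% (observed:
100/100 and 100/100, with array-only offsets concentrated at 0 or +1
clone).

## Known limitations

* Positions are treated as exact inputs; "approximate" assembly placements
  are not propagated as uncertainty in the boundary interval.
* Single-chromosome analyses only; no liftover between assembly builds.
* No change-point segmentation (HMM/CBS) or FDR control over regions —
  calling uses the fixed visual threshold the design specifies.
* Sequence-level refinement of the boundary (e.g. by alignment into a
  flanking clone) is out of scope; the boundary report carries a free-text
  provenance field where such external evidence can be recorded.
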