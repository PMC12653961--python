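# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, what the synthetic generator does and does not emulate,
and the design decisions taken where the problem left the design open.

## Coordinate and unit conventions

All image-space quantities are 0-based pixel centers, origin at the top-left
corner, x rightward, y downward; every module shares this convention. Machine
space is millimetres with the origin at the plate's bottom-left and y upward;
the `Calibration` affine map (per-axis mm/px scale, offsets, optional y-flip)
converts between the two and is exactly invertible.

## Synthetic scenes

The generator emulates the imaging geometry of a sorting workstation: dark
flies on a light CO₂-anesthesia plate photographed from above under flat
illumination. Flies are schematic — an ellipsoidal body (gray 0.20) with one
or two wing ellipses (0.55) on a 0.88 plate background with Gaussian sensor
noise (σ = 0.012) — because detection and classification here operate on
shape and contrast cues, and schematic rendering makes the ground truth
(centroid, sex, view, touching group) exact by construction. The two
dimorphic markers are the ones a human sorter uses: males carry one very dark
(0.05) circular spot per wing; females a serrated ovipositor (an elliptical
base fringed with four small teeth). Dorsal and lateral views are both
supported (80 / 20 by default; the true frequency in field imagery is
unknown, and nothing downstream depends on the ratio).

Placement: non-touching flies are separated by at least two body lengths
center-to-center, which provably keeps their masks disjoint (maximum sprite
radius is ≈ 0.8 lengths); members of an overlap pair are nudged together
until their binary masks intersect or are 8-adjacent. Stains are irregular
mid-gray (0.45) blobs built from a short random walk of disks, sized to the
same order as a fly, drawn only where no fly already is; a touching stain
therefore merges with the fly's connected component without repainting it.
Plate scenes default to 1000×750 px with 24 px flies — a quarter of the
full 4000×3000 sensor scale, so suites run in seconds; all sizes are
configurable and the detection thresholds are scale-free.

A hand-coded rule (`rule_based_sex`) decodes the class from the markers
alone — any connected blob of pixels darker than 0.13 is a male wing spot;
its absence means female — and is exact on generator output. It guarantees
the classifier's task is learnable and serves as the independent oracle for
the training tests. The male spot radius is floored at 1.8 px so a solid
core survives the bilinear interpolation of arbitrary rotations.

What the generator does **not** emulate: photographic texture, specular
highlights, body-pose articulation, occlusion by condensation, or the real
species' appearance variation. Passing tests therefore demonstrate pipeline
correctness and model capacity, not field accuracy.

## Detection

Segmentation is deliberately classical and deterministic: grayscale →
Gaussian blur (radius 2 px) → Otsu threshold with dark foreground →
morphological opening (1 px) → 8-connected components. No illumination
correction is applied (ring-light imaging is assumed flat). Components below
8 px² are discarded as noise specks. Each remaining component is triaged
purely by area: `ready` within [min, max], `overlap` above max (merged
individuals — no contour splitting is attempted; operators correct these),
`out_of_threshold` below min. Components touching the image border follow
the same area rules.

The scale-free thresholds min = 0.18 L², max = 0.58 L² (L = fly length in
px) were calibrated once against the renderer's measured component areas:
single flies span 0.29–0.50 L², merged pairs 0.64–0.81 L², so both bands
clear the thresholds with ≥ 15 % margin. The full-scale defaults
(400 / 4000 px²) correspond to L ≈ 85 px at sensor resolution.

Manual corrections are declarative edits (add / remove / relabel) applied
functionally — a new report is returned, ids stay unique, added detections
are `source=manual`, `status=ready`.

## Classifier

Architecture: four stages of 3×3 same-padding convolution + ReLU + 2×2
max-pool with channels (8, 16, 32, 64), then FC-64 + ReLU and a 2-logit
output — 41 106 parameters at the default 32×32×3 input. The width/input
sizing is chosen so a pure-NumPy training loop converges in minutes on one
CPU; the architecture contract (four conv+pool stages, two fully connected
layers) is what matters, and wider variants (e.g. 128 px input, 32–256
channels) remain constructible through `Cnn6Spec`. Forward/backward passes
are im2col-lowered matrix multiplies; max-pool backward routes gradients via
argmax; gradients are verified against central finite differences in the
test suite.

Training: softmax cross-entropy, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), batch 32,
from scratch (no pretraining). Crops are scaled to [0, 1] per channel with no
dataset-level normalization. Weight init, epoch shuffling and batch order all
derive from the config seed, so identical runs give identical curves. The
weights of the best-validation-accuracy epoch are retained (earliest epoch
wins ties); `early_plateau_epoch` optionally stops training after that many
epochs without validation improvement. Train-accuracy curves report running
minibatch accuracy.

Class balancing duplicates minority crops rotated exactly ±90° (chosen
uniformly per copy, seeded) until counts match — a quarter turn is lossless
on square rasters and label-preserving. Splitting is stratified per sex with
floor rounding for validation and test and the remainder to train, which is
what makes a 3 272-crop balanced set partition into exactly 1 964 / 654 / 654.

Dataset/pipeline consistency: training crops are generated at the same side
the pipeline extracts (56 px for 24 px flies, fly ≈ 0.42 of the crop side)
and pass through the same canonical resize to the model input, so there is
no train/serve scale or blur mismatch. Crops in the training dataset are
uniformly rotated 0–360°, matching the orientation statistics of plate
detections.

## Route planning

The path is open (the laser parks wherever the last female was; no return
leg is scored) and starts at the configured laser origin. The unoptimized
baseline visits targets in detection-index order. Greedy breaks distance
ties toward the lower index. Local search is best-improvement 2-opt on the
open path: each sweep evaluates every segment reversal (the boundary-edge
delta is O(1) per move via the distance matrix) and applies the single best
strictly-improving move, so length decreases monotonically and termination
is guaranteed; the default initial solution is the greedy route.

ACO: ants construct tours in lockstep from pheromone^α × (1/d)^β (α = 1,
β = 2), with evaporation 0.5, per-ant deposit Q/L (Q = mean pairwise
distance), a pheromone floor keeping trails strictly positive, and elitist
reinforcement of the best-so-far tour. Each iteration's best constructed
tour receives a bounded 2-opt polish (3 sweeps by default) before competing
for best-so-far — pure ant-system construction at ~120 targets stalls
several percent above the 2-opt optimum, and coupling construction with
local search is the standard remedy in the TSP literature;
`refine_sweeps=0` restores the pure variant. Defaults: 20 ants × 100
iterations. Best-so-far length is non-increasing by construction and every
run is seed-reproducible.

The exhaustive oracle enumerates all permutations and is capped at 9 targets
(9! ≈ 3.6 × 10⁵ routes, evaluated vectorized); it anchors the dominance
tests (no heuristic ever beats it) and the comparison-ranking checks. The
optimizer comparison reports mean ± sd path length per method and percent
reduction 100·(L₀ − L)/L₀ against the per-instance unoptimized baseline;
reduction percentages depend on the target distribution and are meaningful
as an ordering, not as universal constants.

## GCode

Dialect: `G21` (mm), `G90` (absolute), `G0` rapid moves, `M3 S<power>` /
`G4 P<ms>` / `M5` fire blocks — the common grbl-style command set of hobby
laser controllers. Every target is mapped to machine coordinates before the
first line is emitted, so out-of-bounds targets abort with no partial
program. Safety invariants, enforced by construction and asserted by a
parser round-trip in the tests: the program begins and ends with the laser
off, the laser is never powered during a `G0` move, and the fire-block count
equals the routed female count. Coordinates are printed at fixed 3-decimal
precision, making emission byte-stable. Defaults: full power (S255),
500 ms dwell — placeholders for hardware-calibrated values.

## RISE explainability

Masks follow the standard recipe: a grid_cells × grid_cells (default 7×7)
binary grid with keep probability 0.5, bilinearly upsampled to image size
with a uniform random sub-cell shift. The score is the softmax probability
of the target class on the masked crop; saliency is the score-weighted mask
average divided by N·p, then min-max normalized to [0, 1]. The heatmap also
retains the pre-normalization map: for a constant-score model the raw map is
flat up to O(1/√N) sampling noise, a property normalization would otherwise
amplify to full range. The documented default is 10 000 masks; the test
suite uses 200–2 000 (saliency structure is stable well before 10⁴ masks at
32 px). Batched inference keeps a 2 000-mask probe of the default network
to a few seconds.

## Pipeline

`run_pipeline` executes detect → (declarative detection edits) → crop /
classify → (declarative label corrections, appended to a CSV store with the
crops exported for retraining) → route over females only → GCode, and writes
every stage artifact plus a run report whose counts are internally
consistent (routed = females after corrections = fire blocks). Males are
never targeted. Corrections are files rather than interactive input so runs
are reproducible; the operator-facing status colors (green/red/orange boxes,
pink/blue sex labels) survive as the annotated overlay PNG.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen for seconds-to-minutes
turnaround on one CPU: 1000×750 px plates with 24 px flies (90 per plate),
a 500-per-sex 32 px crop dataset trained 30 epochs, 20 routing instances of
123 targets (a realistic per-plate female count), 200 brute-force instances
of 3–8 targets, and 800–2 000 RISE masks. Tolerances: geometric assertions
use 10⁻⁹ absolute slack; detection centroid matches must fall within half a
fly length; the classifier property asserts ≥ 95 % test accuracy; the
wing-spot attention property is a one-sided Wilcoxon test (p < 0.01) over
20 crops.

## Known limitations

Touching flies are only flagged, never split (no watershed / instance
segmentation). The classifier has no rejection class for non-fly detections:
a stain triaged `ready` will receive a sex label and must be removed by a
detection edit. Calibration assumes a rigid affine camera-to-stage mapping
(no lens distortion model). The GCode layer emits programs; it does not
transmit them or model laser-tissue interaction.
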