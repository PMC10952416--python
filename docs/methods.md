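# Methods

`twobox` implements the place-cell analysis of a two-compartment ("2-box")
experiment: two congruent rectangular compartments joined by a doorway, with
180°-reversed visual layouts (one cue card at the north end, one at the
south) and distinct floor odors (vanilla / lemon). The scientific question
the analysis serves is how hippocampal place fields treat the two visually
identical but odor-distinct compartments: do fields *repeat* at the same
global position, *remap* (fire in one compartment, or at unrelated positions
in the two), or *rotate* with the local visual layout?

## Rate maps

Positions and spikes are speed-filtered first: spikes emitted while the
animal's instantaneous speed is below 5 cm/s are removed (non-local
activity), and samples or spikes above 100 cm/s are discarded as tracking
errors. Instantaneous speed is the central difference of position over one
sample interval; each spike takes the speed and position of its nearest
position sample. Slow *samples* are kept — they are genuine dwell.

Dwell and spike counts are accumulated into 3 × 3 cm bins (partial edge bins
included), smoothed separately with a truncated Gaussian kernel (σ = 5 cm,
zero weight for bin centres more than 9 cm away), and divided:
`rate = smooth(spikes) / smooth(dwell)`. Bins occupied for less than 0.1 s
are unvisited and carry NaN. Two declared choices where the recipe is
underdetermined:

- the "5 cm smoothing factor" is interpreted as the Gaussian σ;
- kernel weights are renormalised over visited in-range bins, so rate never
  bleeds into unvisited territory and a lone visited bin keeps its exact raw
  rate (the renormalisation cancels in the spike/dwell ratio).

Grid convention: origin at the box's lower-left corner, x rightward, y
upward, arrays indexed `[iy, ix]`. All rotations (rotation-trial
realignment, rotational correlations, orientation correction) act on this
convention through `numpy.rot90`.

## Unit admission

A unit enters the analysis only if:

1. **QC** — at most 0.2% of inter-spike intervals below 2 ms; mean rate in
   both baseline trials within [0.1, 5] Hz (putative pyramidal); waveform
   peak-to-trough time above 250 µs, measured on the largest-amplitude
   tetrode channel.
2. **Fields** — the baseline-1 map has a peak above 1 Hz and at least one
   connected component (8-connectivity, configurable to 4) of ≥ 16 pixels
   above 40% of the peak; cells whose field pixels cover more than half of
   the visited pixels are "messy" and excluded.
3. **Spatial tuning** — Skaggs information
   `I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` (bits/spike, occupancy-weighted over
   visited bins) must exceed the 95th percentile of 100 circular spike-time
   shifts, each drawn uniformly from [20 s, T − 20 s] and applied modulo the
   trial duration against the un-shifted trajectory. Bits/spike is used; the
   criterion is rank-based, so the log base cannot change any admission.

A note on the shuffle's error rate: the 20 s margin removes a `40/T`
fraction of the shift circle around the identity. Because information values
at nearby shifts are correlated, excluding the identity's neighbourhood
biases the false-positive rate slightly above the nominal 5%. At the
protocol's two-box trial length (≈ 900 s) the excluded fraction is 4.4% and
the measured false-positive rate stays within the exact binomial 99% CI of
5%; substantially shorter trials would not.

Every excluded cell appears in `cells_admitted.csv` with a reason code; the
pipeline never drops a cell silently.

## Null thresholds and classification

Chance-level map similarity is estimated by correlating 10,000 randomly
drawn pairs of rate maps from *distinct* cells (Pearson r over jointly
visited bins; at least 20 joint bins or the correlation is undefined; the
smaller map is NaN-padded to the larger's extent with origins aligned). The
95th percentile is the similarity threshold — one null for whole-apparatus
maps, one for single-compartment submaps (equal shapes). Same-session pairs
are allowed. On single-bump synthetic pools these thresholds land around
0.5–0.6, higher than values reported for real multi-field CA1 maps (0.37 /
0.45): a pool of clean unimodal maps has heavier-tailed pair correlations.
They are recomputed per run, never hard-coded.

Each admitted cell (orientation-corrected, see below) is then classified
from its two compartment submaps: `r_trans` overlays them in the global
frame; `r_rot` rotates one by 180° (same position relative to each reversed
local layout). Against the sub-compartment threshold: high/low → **repeat**,
low/high → **rotate**, both low → **remap**, both high → **ambiguous**
(e.g. a field in the doorway; reported but excluded from proportions). Two
gates mirror the protocol's final exclusions: stability (baseline-1 vs
baseline-2 whole-map r above the whole-box threshold) and cue control
(baseline-1 vs realigned rotation-trial r above it). A compartment whose map
never reaches 1 Hz cannot contain a field, so repeat/rotate calls that hinge
on it are the classic few-spike spurious correlations; such cells are
flagged low-confidence and reported as remap.

## Ensemble orientation ("odor-switching")

Whole ensembles sometimes rotate their 2-box pattern 180° relative to the
odor frame between trials. Detection: correlate every cell's baseline-1 map
with its (realigned) rotation-trial map, unrotated and with an extra 180°
rotation, and assign each cell a quadrant against the whole-box threshold —
consistent (high/low), switched (low/high), or abstaining. The trial is
switched when switched cells form a strict majority of informative cells;
with no informative cells the orientation is undetermined and nothing is
corrected. Genuine rotate-category cells have 180°-symmetric whole-box
patterns and therefore abstain, which is why a rotate-rich session is not
falsely called switched. Correction rotates all maps of a switched trial by
180°; it tracks which trials were already corrected and is idempotent.

## Single-compartment odor retrieval

For each door-closed trial, the occupied compartment's map is compared —
after aligning compartments by their visual scene (compartment 2 rotated
180°) — with the same compartment's map from the preceding rotation trial
(same odor) and with the other compartment's (different odor). Odor-based
map retrieval predicts higher same-odor correlations; the paired medians and
a Wilcoxon signed-rank statistic are reported descriptively.

## Duplicate-cell tracking

Cells recorded across sessions are identified assuming fields are stable
over days. Candidates are same-tetrode pairs in consecutive sessions with
rate-map correlation above 0.375. Waveform similarity uses the two Tolias
distances; the source construction leaves the normalisations open, so the
declared forms are:

- `d1 = Σ_c ‖a_c − α_c b_c‖ / Σ_c ‖a_c‖` with
  `α_c = (a_c·b_c)/(b_c·b_c)` — shape residual after optimal per-channel
  rescaling; 0 for identical shapes at any uniform gain, 1 for channel-wise
  orthogonal waveforms. The α-fit is directional; the pipeline always
  computes earlier → later and records the direction.
- `d2 = sd(log α_c)` across the four channels (population sd) — 0 iff the
  amplitude profile is preserved; non-positive α (sign flips) invalidates
  the pair.

A per-animal linear discriminant on (d1, d2) — equal priors, trained on
within-session trial pairs ("same") and first-vs-last-session pairs
("different") — converts distances to a posterior. Pairs with posterior
> 0.5 are the same cell; convergence/divergence conflicts are resolved by
posterior when the gap exceeds 0.1, otherwise by spatial correlation. Chains
are collapsed across consecutive-session links only and keep their
first-session member. Duplicate removal runs before null construction and
classification so duplicated cells do not bias the pool.

## Behavioral preference

`PI = (T_V − T_L)/(T_V + T_L)` from per-compartment dwell of two-compartment
trials; samples in the doorway belong to the compartment with the nearest
centroid (which reduces to thresholding x at the shared wall). Door-closed
trials are refused.

## Synthetic sessions and what they do (not) show

The generator produces the five-trial protocol — baseline, rotation trial
(box rotated 90° or 180°; positions are stored in the room frame and fields
follow the box cues), two 10-min door-closed single-compartment trials, and
a second baseline — with two-box trials of 900 s by default (the protocol's
15–25 min range; 900 s keeps simulation sweeps fast).

- **Geometry.** Compartments default to 60 × 90 cm with a 20 cm doorway
  (not specified by the protocol; declared, configurable).
- **Movement.** An Ornstein–Uhlenbeck velocity process (per-axis stationary
  s.d. 13 cm/s, correlation time 0.7 s, 50 Hz sampling) with specular wall
  reflection, plus a weak pull (15 cm/s²) toward a foraging target
  resampled every 6 s and routed through the doorway, with 40% per-
  coordinate bias into the 6 cm wall band (thigmotaxis). This emulates
  food-scatter foraging: ≥ 90% of 3 × 3 cm bins per compartment are visited
  in 900 s, speeds have genuine sub-5 cm/s mass and essentially none above
  100 cm/s. It does not model rearing, grooming or odor-driven behavior.
- **Cells.** Fields are single per-compartment Gaussians (σ ~ U[6, 12] cm,
  peak ~ U[1.5, 10] Hz, baseline ~ U[0.1, 0.3] Hz so weak cells still clear
  the 0.1 Hz QC floor). Categories impose geometric relations: repeat =
  same global-frame local position; rotate = 180°-reversed local position;
  remap_single = one compartment only; remap_shift = independent positions.
  Because the categories *are* geometric relations, a remap_shift draw
  whose second centre happens to land on the repeat- or rotate-consistent
  locus would be a mislabelled configuration; centres are rejection-sampled
  to keep bump overlap with the competing locus ≤ 0.3 (separation
  ≥ 2.2 σ), making ground truth identifiable. Non-spatial "distractor"
  cells (homogeneous Poisson, 0.3–1.5 Hz) exercise the rejection paths.
- **Spikes.** Inhomogeneous Poisson from
  `λ = baseline + peak·exp(−d²/2σ²)`, d measured to the centre active in
  the currently occupied compartment, thinned by a 2 ms absolute
  refractory period. Without the refractory period the in-field ISI
  statistics would violate the 0.2% ISI QC that real (refractory) pyramidal
  cells satisfy. No bursting, theta phase precession or replay is
  modelled; speed filtering makes replay moot.
- **Odor switching** is generated as a whole-trial, whole-ensemble 180°
  rotation relative to the odor frame (never per-cell), matching the
  observation that switching cells co-occur. On door-closed trials,
  odor-gated cells (default) retrieve the occupied compartment's map;
  the `odor_gated=False` variant anchors a single field to the visual
  scene instead, which is the negative control for the retrieval analysis.
- **Waveforms.** Four-channel pyramidal-like templates (peak-to-trough
  ≈ 350 µs > 250 µs) with per-channel amplitudes, small per-trial jitter
  and cumulative per-session amplitude drift (`1 + drift·ε`).

Passing tests on these sessions shows the *analysis logic* is correct and
calibrated under its own assumptions; it does not certify performance on
real CA1 data, whose maps are multi-field and noisier (their null
thresholds are lower, and few-spike artefacts are more prevalent — which is
exactly why the low-confidence demotion exists).

## Numerical and problem-size choices

- Pearson correlations require ≥ 20 jointly visited bins; below that the
  value is undefined and the comparison abstains rather than votes.
- `numpy.percentile` (linear interpolation) defines both the shuffle and
  null thresholds.
- The trajectory stepper is compiled with numba when available and falls
  back to the identical pure-Python loop otherwise.
- Identical seeds give bit-identical sessions and byte-identical CSV
  outputs (fixed float formats); all randomness flows through
  `numpy.random.SeedSequence`.
- Validation sweeps use 200-cell sessions for calibration/recovery checks
  and 60-cell sessions (well above the ≥ 5 informative cells the
  orientation detector requires) for the 20-session odor-switch sweep;
  these sizes keep full sweeps to a few minutes without changing any
  statistical conclusion.

## Known limitations

- Orientation detection is defined for two-box trials (baseline vs
  rotation/baseline-2); door-closed trials are not orientation-corrected.
- The null thresholds, being pool-derived, shift with ensemble composition;
  comparisons across datasets should rebuild them, not reuse numbers.
- Tracking assumes stable fields across sessions; a cell that genuinely
  remaps across days would evade the spatial prescreen by design.
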