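# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `locustal`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Cue-integration patch-choice model

Each of four information classes (socio-visual, food-visual,
socio-olfactory, food-olfactory) carries a reliability `C_i > 0`. A patch is
judged "good" through each class independently,
`P(x good | C_i) = 1/(1 + C_i^(-w))`, where the binary availability `w` is 1
when class `i` is on offer at patch `x` under the current sensory condition
(occluding a modality zeroes the corresponding availability columns). The
factor is 1/2 whenever the cue is absent or uninformative (`C_i = 1`), so an
all-zero availability matrix yields uniform choice. Per-patch probabilities
multiply the four factors and normalize over patches.

*Fitting.* The objective is the summed squared error between model
probabilities and the mean observed quarter occupancies, jointly over all
sensory conditions with one shared `C` vector (per-condition fitting would be
under-identified: a single condition leaves only three degrees of freedom for
four parameters, whereas the three standard conditions jointly identify all
four). The search runs on `log10(C)` in the box `[-1, 1]^4` by L-BFGS-B from
8 starts (the origin — the uninformative model — plus 7 random corners of the
box); the objective is smooth and 4-dimensional, so multistart local search
reliably finds the global optimum. Repetitions (default 5000; analyses here
use far fewer) resample animals with replacement and re-seed the optimizer,
and the reported score is the repetition mean with a 2.5/97.5-percentile
interval (computed with lower/upper interpolation so that two repetitions
degenerate to their min/max). Parameter recovery over 20 simulated assays
(50 agents × 10⁴ frames × 3 conditions, true scores uniform in [-1, 1])
achieves a median absolute score error of ~0.05.

## Behavioral trajectories

Trajectories are smoothed with a truncated, renormalized temporal Gaussian
(half-width 2 s, σ = 2/3 s). Visit density deposits one unit per frame on a
1000 × 1000 grid (the arena bounding box rescaled linearly onto the grid) and
smooths with a 2-D Gaussian of σ = 78 grid pixels whose support is clipped at
the grid edge — mass may fall off the map; normalization is by frame count,
not residual mass. Quarters are cut by the two diagonals through the arena
center (patches sit at 90° spacing near the wall) and realigned to the
canonical patch order (Lvs, Lct, LvsLct, Ctr) so differently rotated layouts
pool. For large simulation studies, `quarter_occupancy_from_trajectories`
counts frames per quadrant directly; the wide smoothing kernel moves
negligible mass across the diagonal cuts, and unit tests confirm the two
routes agree on the quantities derived from them.

## Synthetic data

The generators define the study conditions under which all recovery claims
hold.

*Imaging scenes.* Cells are isotropic Gaussian discs (σ = radius/2, default
radius 4 px) placed by rejection sampling with center distance > 2·radius on
a 100 × 100 frame, 20 cells, 40 frames at 1 Hz, onset at frame 10. A pixel's
time course is `baseline·(1 + amplitude·disc·motif(t − onset))` plus a linear
bleaching trend (−0.05 intensity/frame on a baseline of 100) and Gaussian
noise (default s.d. 2, i.e. 2% of baseline; recovery is also verified at 5%).
Rigid integer jitter (≤ `jitter_px`, drawn per frame) displaces the whole
scene. The ground-truth label image covers each disc's 1.5σ core — the
region where the cell contributes at least ~32% of its peak amplitude;
beyond that the Gaussian skirt is dominated by background and pixel
ownership is not a meaningful notion. The six motif templates (two
inhibitory, one delayed, one phasic, one strong phasic, one sustained) are
parametric curves with time constants of 1.5–8 s, sized for 1 Hz sampling of
a 2 s odor pulse; the strong phasic motif differs from the plain phasic one
in shape (sharper, earlier peak), not only amplitude, because row z-scoring
— deliberately part of the motif pipeline — erases pure scale differences.
A flat "silent" template (id 0) is available for planting non-responders.
Recovery scenes guarantee each cell at least one excitatory motif across the
stimuli: a cell that only ever shows inhibition is non-active by definition
and cannot appear as an active granule.

*Choice trajectories.* Each agent holds a target patch drawn from the model
probabilities at the true reliabilities, re-drawn each frame with probability
0.005 (mean dwell ~8 s at 25 fps, chosen so a trial mixes over many dwell
segments), and relaxes toward the target center under discrete
Ornstein-Uhlenbeck dynamics (pull 0.3/frame, wander s.d. 1.8 cm/frame in a
90 cm arena with patches 7 cm from the wall). Occupancy converges to the
model probabilities (max deviation < 0.02 at 50 agents × 10⁵ frames); the
dominant error at smaller sizes is dwell-segment sampling noise, roughly
`sqrt(2·p(1−p)/n_segments)` per quarter.

All generators consume a single explicit seed and never touch global random
state.

## Imaging preprocessing

Fixed order: 3×3 median then Gaussian σ = 1 px per frame (reflect
boundaries); linear detrend of the per-frame median intensity with the slope
removed and the level preserved, keeping F₀ on the raw intensity scale;
rigid phase-correlation alignment of each frame against the stimulus-mean
template with subpixel application (recovered within 0.25 px RMS for shifts
≤ 1.5 px); a 3-frame temporal box filter with renormalized edges; ΔF/F₀ with
F₀ the per-pixel mean of the five frames before onset, taken from the same
filtered trace as the numerator. Pixels with F₀ below 10⁻⁶ of the dynamic
range are masked invalid rather than erroring. Shift estimates larger than
10% of the frame size are treated as failed estimates and zeroed with a log
entry: phase correlation on a near-featureless frame (e.g. a pre-onset
baseline frame of a low-background preparation) peaks at a random
wrap-around offset instead of the true small drift. Repetition averaging
registers set b onto set a via the time-mean images and averages frame-wise.
Non-rigid motion correction is out of scope; the alignment implemented here
is the rigid phase-difference step, which matches the rigid jitter the
generator produces.

## Granule segmentation

The s.d.-projection is taken over all frames of all stimuli concatenated
(not the mean of per-stimulus projections — the two differ whenever stimulus
means differ). Its 8-connected regional maxima and minima become seeds, with
a connected plateau contributing one seed at its centroid; pixels join the
nearest seed (ties to the lowest seed id). Boundary refinement runs
synchronously for up to 50 iterations: granule mean time courses are
recomputed once per iteration, every pixel with a 4-neighbor of another
granule is compared to its home and neighboring granules by
`RMedSE(a, b) = sqrt(median_t((a_t − b_t)²))` over the concatenated stimulus
set, and moves only on strict improvement (ties keep the home granule, which
makes the procedure a no-op wherever a pixel's trace fits both equally).
Granules below 5 px are then fused into the neighbor sharing the longest
border. Activity calls apply Otsu's threshold (256-bin histogram) to the
granule-level window-mean ΔF/F₀ magnitudes per stimulus, floored at a
minimal effect size of 0.02 ΔF/F₀: Otsu's criterion always produces a split,
even on the unimodal magnitude distribution of a stimulus that evokes
nothing, and responses below ~2% ΔF/F₀ are beneath what the imaging
resolves. Granule-level thresholding is the default; seed type (maximum- vs
minimum-seeded) is kept as metadata, but activity is decided by the
magnitude call — after refinement a minimum-seeded granule can legitimately
own responsive pixels. An optional binary anatomical mask excludes granules
lying mostly outside it from response statistics. Under the default scene
(20 responsive cells, noise ≤ 5% of baseline) at least 90% — typically
20/20 — of planted cells are recovered one-to-one as active granules.

## Response vectors and consistency

Cross-animal response matrices are normalized per animal (subtract the
animal minimum, square root, center/scale to the animal's mean and s.d.) and
then per row (rescale to [-1, 1]); constant rows map to zeros with a
warning. The square root is the "root transform" reading adopted here.
Clustering runs in PCA space retaining ≥ 99% cumulative variance, with
best-of-replicates k-means (replicate = independent initialization; default
500 replicates, analyses here use 50) followed by an online phase of
single-point reassignment passes using the exact `n/(n±1)` SSE increments,
until no point moves. `k` is chosen as the point of the VRC curve farthest
from the chord joining its first and last finite values; ties and an exactly
linear curve give the smallest `k`, and a curve that is infinite everywhere
(zero within-cluster variance) forces the minimum `k` with a degeneracy
flag. Consistency analysis rescales each trial map to [0, 1], treats maps as
observations and pixels as features, keeps ≥ 95% variance in PCA, and
reports mean within- vs between-odor Euclidean distances plus an
average-linkage tree (exported as Newick) with its cophenetic correlation.

## Motifs, transitions, classification

Motif clustering applies the same PCA + VRC-elbow k-means to row-z-scored
time courses, with each (cell, stimulus) pair one observation. Motif ids are
re-indexed canonically by (peak sign, peak magnitude, peak latency), putting
inhibitory motifs first; the re-indexing is a pure relabeling and all
downstream results are invariant to it. Each unit's ordered motif triplet
over (Lct, Laa, LaaLct) yields per-animal transition matrices (joint
proportions over units) for the three ordered stimulus pairs
Lct→Laa, Lct→LaaLct, Laa→LaaLct; these flattened matrices are the classifier
features. Leave-one-animal-out classification refits PCA inside each
training fold (no leakage; a compatibility flag is deliberately absent —
fold-internal fitting is the only mode) retaining ≥ 83% variance, then
applies a linear discriminant with pooled diagonal covariance and uniform
class priors (the prior reweighting is the compensation for unequal group
sizes); score ties predict the globally rarer class. On synthetic
populations with synergy-enriched vs antagonism-enriched triplet
repertoires (15 animals per phenotype, 60 units each) accuracy exceeds 0.8,
while identically distributed populations stay at chance.

## Bliss synergy

With `f1, f2` the ΔF/F₀ responses (decimals) to the two components and `f3`
the observed mixture response, the no-interaction expectation is the
inclusion-exclusion of the halved components — halved because the mixture
carries half of each component — and the score is
`100·(f3 − f_expected)`; it is symmetric in `f1, f2`, and negative
(inhibitory) responses pass through unclipped. The per-unit summary is the
mean frame-wise score over the analysis window. Units whose motif triplet is
identical across all three stimuli are still scored but excluded from
population pooling. The strongly-synergistic fraction uses a threshold of
one standard deviation of the pooled score distribution (both phenotypes
pooled), counting scores strictly above it; on a standard normal population
this reproduces Φ(−1) ≈ 0.159.

## Randomization statistics

Both tests use studentized statistics (s.d. with the n−1 denominator):
`|x̄|/(σ_x/√n)` for paired differences and `|z̄−ȳ|/√(σ_z²/n + σ_y²/m)` for two
samples. Null resampling draws B samples with replacement — sign flips of
the differences (paired) or group-label reassignments preserving sizes
(two-sample); the schemes are declared, pluggable choices. The p-value is
`max(#{T* ≥ T}, 1)/B`, so ties count (conservative) and the smallest
returnable p is exactly 1/B; two-tailedness is carried by the absolute
values. Resampling is vectorized in chunks, so B = 10⁷ completes in seconds.
Exact enumeration oracles (all 2ⁿ sign patterns; all label assignments)
validate the Monte-Carlo p-values at small n, and the two-sample test's
type-I error calibrates to 5% ± 1% over 2000 null simulations. Grand means
are means of animal means with percentile bootstrap 95% CIs (default 5000
resamples); Bonferroni adjustment is `min(1, p·m)`.

## Pipeline and reproducibility

`locustal.pipeline.run_pipeline` executes either arm (or a synthetic demo of
both) from a single validated config; the demo simulates one agent cohort
per sensory condition and one planted imaging scene, and writes occupancy
tables, fitted scores, label maps, response/triplet tables and a synergy
summary to a report directory. The default analysis window is the 10 frames
after onset at 1 Hz (configurable). All randomness is threaded from the
config seed; identical configs reproduce identical reports (verified by
hashing outputs). The click CLI is a thin wrapper over this function.

## Problem sizes

Recovery analyses here run at: 20 simulated assays of 50 agents × 10⁴
frames for reliability recovery; two 20-cell scenes (2% and 5% noise) for
segmentation recovery; 300 profile rows for motif recovery; 15 + 15 animals
× 60 units for classification; 2000 null simulations at B = 2000 for
calibration. These sizes were chosen so the statistical claims are
well-powered while the whole validation remains desk-scale.

## Limitations

The generators idealize: Gaussian-disc cells without neuropil texture or
optics (no PSF or depth sectioning), purely rigid jitter, linear bleaching,
Gaussian noise, and motif time courses that match the clustering's
assumptions better than real PNs will. Passing recovery tests therefore
demonstrates correctness of the algorithms under their stated assumptions,
not performance on recorded movies — in particular, real non-rigid tissue
motion is outside the rigid aligner's scope, and raw-noise statistics of
the original recordings are not modeled. Occupancy-based reliability
fitting assumes the availability matrices are known exactly. The
boundary-refinement step inherits the known property of median-based errors
that temporally sparse responses (active in fewer than half of the
concatenated frames) do not influence pixel reassignment.
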