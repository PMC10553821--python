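# Methods

`dermadisperse` quantifies how embryonic skin mesenchyme disperses: how
newly born (post-mitotic) cells move relative to non-dividing neighbours,
how often and from how far each group is recruited into dermal condensates,
how the orientation of mitoses is organised in space around condensates and
across whole-embryo fields, and whether a minimal agent-based model of the
post-mitotic "fast phase" is sufficient to explain the recruitment bias.
This note records the models, the parameter choices, and the places where
the design was genuinely open.

## Data model and conventions

Trajectories are planar (x right, y down, origin at the field's top-left;
μm and minutes), sampled at a fixed frame interval (10 min for mouse-style
data, 15 min for chicken-style). Missed frames are retained as time gaps and
never interpolated; per-step quantities always use the actual Δt, and an MSD
pair is valid only if both endpoints were observed. Lineage roles (mother,
daughter, non-dividing) are observational labels carried in the input
tables, not inferred from the coordinates.

All mitosis axes, nucleus orientations and fibre directions are *axial*
quantities (defined modulo 180°). Differences use the acute axial distance
d_ax ∈ [0, 90]°; averaging and kriging use doubled-angle unit vectors, where
the axial circle maps bijectively onto the full circle. Two useful
constants: the semivariance plateau of i.i.d. uniform axial angles is
90²/3/2 = 1350 deg²; for condensate-relative angles (values in [0, 90]) it
is 90²/12 × 2/2 = 675 deg².

## Motility metrics

Per track: instantaneous speed (step length over actual Δt), Euclidean and
accumulated displacement over a window, and persistence
(Euclidean/accumulated ∈ [0, 1], undefined for a stationary window).
Dividing lineages are stratified into 180-min windows anchored at the
division time (mother −180–0, daughters 0–180 and 180–360 min);
non-dividing tracks form one window.

The population MSD uses time-ensemble averaging over all tracks and start
times. Its fitted OLS slope is reported as the "diffusion coefficient" in
the imaging-analysis convention (the raw MSD slope, μm²/min); the
physically normalised planar D = slope/4 is exposed alongside. The default
fit window runs from the first lag to a quarter of the shortest
contributing track duration — a standard guard against noisy large-lag
estimates; it is configurable. Tracks at different frame intervals are
never pooled into one MSD curve.

## Condensate recruitment

Condensates are static absorbing discs. A track "enters" at the first frame
whose nucleus centroid lies inside a disc (nearest entered disc wins); from
that frame it is censored. Tracks whose first observed point is already
inside a disc are flagged and excluded from rates. The reference starting
position of a dividing lineage is the mother's position at the division
frame (falling back to the daughter's first point); for non-dividing cells
it is the first tracked point. Entry rates are compared per 180-min window
— anchored to the division for dividing cells, to the first frame otherwise
— with a two-sided Fisher exact test (probability-mass summation; a zero
margin yields p = 1 by convention). Entry-distance distributions are
reported as a 10-μm-bin histogram density plus a boundary-reflected
Gaussian KDE (distances cannot be negative), both integrating to 1.

## Condensate-referenced angular variography

The variogram of mitosis orientation is referenced to the condensate: a
sample's lag is its distance to the condensate centre, samples are binned
by lag (default 15 equal-width bins, bins with fewer than 10 pairs merged
into a neighbour), and the semivariance of a bin is half the mean squared
acute angle difference over all pairs of samples sharing that bin.
Directional variants keep samples whose bearing from the centre falls in a
±22.5° cone about 0, 45, 90 or 135°.

Two angle frames are supported. In the *absolute* frame the axial angle
itself is differenced. In the *radial* frame each angle is first converted
to its acute angle against the radial line to the centre (0 = pointing at
the condensate, 90 = tangential). A field organised tangentially around a
condensate is homogeneous in the radial frame but maximally heterogeneous
in the absolute frame (tangents around a ring span every orientation), so
condensate-referenced analyses default to the radial frame. For fields with
no condensate (whole-embryo maps) a classical isotropic mitosis-to-mitosis
variogram is provided instead (`empirical_pairwise_variogram`, lags up to
half the maximum separation).

Empirical variograms are fitted with nested exponential models
γ(h) = c₀ + Σₖ cₖ(1 − e^(−h/aₖ)) by non-negative weighted least squares.
The default weight is each bin's pair count; the classical pair-count/h²
weighting is available and preferred for pairwise variograms whose lag
window shows no plateau, since it anchors the nugget on the short-lag bins.
One-structure fits profile the range on a log grid (the model is linear in
c₀, c given a) and refine with bounded scalar minimisation; two-structure
fits use seeded multistart trust-region least squares. The effective range
of a structure is 3a (95% of its sill); the nugget-to-sill ratio
c₀/(c₀+Σcₖ) is the variance fraction without spatial structure, and each
structure's share of the structured variance is reported.

## Permutation test of condensate influence

Angles are permuted across the fixed sample locations and the variogram
re-estimated per permutation. The test statistic is the *integral range* of
the condensate-referenced variogram, Σ_h Δh·(1 − γ̂(h)/S), with S the
pair-weighted overall semivariance (invariant under permutation). For an
exponential model this equals a·c/(c₀+c) — range times structured-variance
fraction — and it is zero in expectation for a structureless field. The
Monte Carlo p is the fraction of permutations whose integral range is at
least the observed one; "no condensate influence" is rejected at p < 0.001
(1,000 permutations by default). Because the statistic is continuous and
exchangeable under the null, the test is exactly calibrated; this is
verified by a 200-replicate null calibration test at q = 0.1.

The statistic was chosen after the direct alternative — comparing fitted
exponential ranges permutation by permutation — proved to have essentially
no power: on permuted (flat) variograms the range parameter is
unidentifiable, and noise fits scatter from tiny to enormous ranges, so the
observed range of a genuinely structured field is never in an extreme tail.
The fitted effective range 3a of the observed field is still reported as
the quoted "range of influence"; only the permutation statistic is the
integral range.

## Ordinary kriging and randomness maps

Kriged orientation maps solve the standard ordinary-kriging system built
from the fitted variogram model, per doubled-angle component, with the
weights (which sum to 1 by the unbiasedness constraint, asserted on every
solve) shared between components; co-located samples are averaged first.
Zero-nugget kriging interpolates the samples exactly.

The local randomness map kriges the experimental field and `n_perm`
(default 100) permutations of its angles onto a grid (default 100×100) with
the same model and weights, then classifies each pixel by the experimental
kriged angle's axial deviation from the permutation circular mean. Two
verdict rules are provided, because they answer different questions:

* **quantile** (default): the pixel is "random" if the experimental
  deviation is within the permutations' own (1 − α) deviation quantile.
  This is exactly calibrated — an exchangeable (structureless) field yields
  a randomness ratio near 1 − α — but it is conservative: a single
  experimental draw must escape the full spread of permutation kriging,
  which only happens where local orientation coherence is strong relative
  to the per-pixel kriging noise.
* **mean_test**: the pixel is "random" if the experimental value is
  indistinguishable from the *mean* of the permutation distribution
  (t-interval on the standard error of that mean). This mirrors how such
  maps have been computed for embryonic mitosis fields. It is
  anti-conservative under the null; in practice it marks nearly every
  kriging-covered pixel non-random, and the "random" area largely traces
  where the kriged surface collapses to the permutation mean (far from
  samples, or where coherence vanishes). Randomness ratios in the
  10–20% band arise naturally from this rule at realistic sampling
  densities.

The randomness ratio is the "random" fraction of the grid; the correlated
area fraction is its complement.

## Agent-based model

Cells move off-lattice on a periodic square (minimal-image distances).
Interphase motion is an isotropic Gaussian walk with per-axis step variance
2·D·Δt. A cell selected to divide (per-cell Bernoulli per step, or a fixed
division schedule) is replaced by two daughters displaced jump/2 each in
diametrically opposite directions at an axial angle θ (uniform by default,
optionally von Mises-concentrated about a preferred axis to model tissue
tension). Each daughter runs a persistent random walk for the fast phase —
Rayleigh step lengths about a target mean, von Mises turning about the
previous heading, first heading along its mitotic-jump direction — then
reverts to the interphase walk. Fast-phase daughters cannot divide.
Absorption is checked on end-of-step positions (consistent with the 10-min
observation cadence; steps are small relative to disc radii). Per step the
draw order is fixed — movement, division, absorption — and all randomness
comes from one seeded generator per replicate, so runs are bit-reproducible
and a rigid translation of the seeding field and condensates (same seed)
reproduces the same history exactly.

Default parameters, with the reasoning:

| parameter | default | why |
|---|---|---|
| frame_dt | 10 min | imaging cadence |
| duration | 1,500 min | a 25-h time-lapse |
| D | 0.00127 μm²/min | equivalent to a 0.02 μm/min mean step speed at 10-min frames (σ = v·Δt/√(π/2), D = σ²/2Δt) |
| division_rate | 0.002 /cell/step | roughly half the population divides over 25 h, matching the tracked dividing:non-dividing ratio |
| jump_length | 10 μm | about two nuclear diameters at cytokinesis |
| persist_steps | 18 | a 180-min fast phase at 10-min steps |
| d_pers_mean | 0.6 μm | 3× the interphase mean step, the observed post-division speed ratio |
| phi_kappa | 6 | reproduces the high persistence of tracked daughters |
| condensates | none | supplied per experiment; analysis scenarios use 40–50 μm discs at placode-like ~150–200 μm spacing |

Entry statistics classify daughters as the "dividing" group; initial cells
that divided leave the non-dividing denominator (they can no longer be
absorbed), and agents born or seeded inside a disc are excluded from rates
on both sides, as in the tracking analysis. Group fractions are summarised
per replicate (mean ± SEM over 8 seeded replicates by default) with a
paired one-sided Wilcoxon test of the dividing > non-dividing ordering, and
entry-distance densities use minimal-image starting distances.

## Synthetic data

The generators share the simulator's kinematic core and emit a ground-truth
JSON record beside every dataset.

* **Tracking tables**: diffusive non-dividing cells at a target mean step
  speed (default 0.02 μm/min — Gaussian step scale chosen via the Rayleigh
  mean relation, since mean speeds rather than D are the reported
  quantity); dividing lineages with a diffusive mother, a diametric
  separation (default 10 μm), an optional pause, a fast persistent phase
  (default 3× speed for 180 min) and reversion to diffusion.
* **Mitosis-angle fields**: positions uniform; near a condensate, angles
  tangential (radial-relative angle about 90°) with von Mises concentration
  κ(d) = κ₀·e^(−d/decay_range) on the doubled angle, hence uniform far
  away; alternatively globally aligned fields or rectangular coherent
  zones with per-zone axis and concentration for randomness-map tests.
* **Fibre images**: anti-aliased ~3-px-wide line segments with axial
  orientations von Mises-distributed about a target (infinite concentration
  renders evenly spaced parallel stripes), drawn in a magenta-violet stain
  colour (positive a, negative b in L*a*b) over a dark noisy background.

What the generators deliberately do not emulate: imaging noise,
segmentation error, tracking identity swaps, condensate growth or
attraction, cell–cell exclusion, and 3D motion. Passing tests therefore
demonstrate correctness of the computations under the stated statistical
structure, not robustness to real-data artefacts.

## Fibre alignment pipeline

sRGB→L*a*b (D65); fibre map = a-channel plus rectified negative b-channel;
grayscale normalisation; two passes of a 3×3 median filter (a single 5×5
pass is available — both readings of a "second-order" median are offered);
1st–99th percentile linear contrast stretch; Otsu threshold with
connected components below 20 px removed; Hann window; 2D FFT power
spectrum (amplitude optional); polar resampling about the spectrum centre;
intensity sums per 1° bin over radii from 3 (excluding the DC/low-frequency
disc) to Nyquist; spectral orientations rotated 90° to real-space fibre
orientations; histogram fractions scored by the axial alignment
coefficient. A constant or empty image is returned as a flagged degenerate
result rather than a score.

The alignment coefficient itself is the mean dot product over all n²
ordered pairs of orientation unit vectors — equivalently the squared
resultant length — with angles doubled first in axial mode: exactly 1 for
identical orientations, approaching 0 for isotropy with an O(1/n) positive
bias (≈10⁻⁴ at n = 10,000).

## Numerical choices and degenerate inputs

Variogram bins with fewer than 10 pairs merge leftward (a deficient leading
bin merges right, with a warning). Fit ranges are bounded in
[max(h₁/10, h_max·10⁻³), 2·h_max]. A flat variogram fits to pure nugget; a
constant angle field has zero semivariance everywhere and is rejected by
the permutation test as having nothing to permute. Kriging systems with
duplicate locations average the co-located doubled-angle vectors rather
than failing. Fisher tests with a zero margin return p = 1. The simulator
treats a condensate covering the whole domain as a valid degenerate run
(everyone absorbed at t = 0, with a warning), and conservation
(alive + absorbed = initial + divisions) is checked at every step.

## Problem sizes used in the shipped analyses

The test-suite analyses run at the scale of the source imaging study:
tracking fixtures with 100–300 lineage/non-dividing tracks over 25 h;
condensate-referenced variography and its 1,000-permutation test at 3,000
mitoses (five fields of ~600, pooled); randomness maps on 100×100 grids
with 100 permutations over fields of 45–500 mitoses; the simulator at 400
agents × 150 steps × 8 replicates. Brownian/parameter-recovery checks use
500 tracks × 100 frames. All are seeded.

## Known limitations

* The condensate-referenced variogram pairs samples *within* lag bins; a
  construction pairing by distance difference is conceivable and would
  change bin occupancy (both are exposed through the two estimators).
* The 70%/30% two-band decomposition comes from a single nested
  two-structure fit; fitting the two bands separately is not attempted.
* Kriging is isotropic and stationary; no trend surfaces, no anisotropy,
  no 3D.
* The mean-test randomness verdict is knowingly anti-conservative under
  the null (see above); the quantile verdict is the calibrated default.
* The simulator has no re-division cool-down beyond the fast phase, no
  volume exclusion, and static condensates.
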