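# Methods

This note documents the models, conventions, and design choices behind
`reachkin`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates a seated object-lifting task recorded by an
optical capture system.  What it reproduces, and what it does not, bounds
what green tests say about clinical data: the generator captures the
*statistical structure* the selection machinery relies on (class-labeled
recordings, smooth bell-velocity kinematics, distal-to-proximal amplitude
gradation, rest frames around the movement, controllable class effects),
not the biomechanics of real reaching (no joint constraints, no grasp, no
trunk compensation, no inter-trial learning).

**Trajectories.**  Each marker's axis follows a minimal-jerk rise of half
the movement duration followed by a minimal-jerk return, scaled by a
per-axis base excursion (x 0.06 m, y 0.18 m, z 0.45 m — the vertical lift
dominates) and a per-marker amplitude factor (FN 1.0, LEP 0.7, MPH 0.4,
ACR 0.15), plus a per-recording, per-axis amplitude jitter drawn from
U(0.85, 1.15).  The jitter is identically distributed in every class, so
a cohort without class effects is exchangeable across classes — the
property the null-selectivity tests rely on.  Rest padding (default
0.5 s) frames the movement with still samples so the crop stage is
exercised.  Units are meters and seconds; sampling is 100 Hz.

**Cohort rule.**  Post-stroke participants contribute
`recordings_per_limb` recordings per limb — non-affected limb labeled G0,
affected limb G1, the affected side alternating across participants;
controls contribute both limbs as G2.  Defaults (35 post-stroke, 19
control, 3 recordings per limb) give 105/105/114 recordings.

**Measurement noise.**  Band-limited Gaussian noise with marginal sd
0.2 mm, temporally correlated by a Gaussian kernel of sd 80 ms.  The
marginal sd matches the sub-millimeter accuracy of marker-based optical
capture; the correlation reflects that capture software tracks and
low-passes marker centroids.  The correlation is not cosmetic: white
positional noise is amplified by rate² under double differentiation, and
at 100 Hz even 0.2 mm of white noise would bury every acceleration
signal — filtered capture output does not behave that way.

**Class effects.**  Three kinds, each targeting one (class, marker, axis):

* `amplitude_scale` — multiplies the movement amplitude.  Note that the
  downstream per-series min–max normalization absorbs any positive affine
  per-axis map, so a pure amplitude effect is intentionally invisible to
  the pipeline (this is verified as an invariance test).  It exists for
  raw-trajectory work and as a negative control.
* `submovement_count` — superimposes `round(magnitude)` small minimal-jerk
  pulses (width 0.15 s, 30% of the axis amplitude) at random positions in
  the movement window, modeling segmented, corrective reaching.
* `jerk_noise_sd` — adds *white* positional noise of the given sd over
  the movement window, modeling rough, jerky movement.  Because white
  noise is rate²-amplified by differentiation while the baseline noise is
  band-limited, this effect is an acceleration-domain signature, visible
  in velocity at larger magnitudes and in the trajectory only when the sd
  rivals the movement amplitude.

**Seeding.**  A single global seed fans out to per-recording seeds by
hashing the recording id (CRC32 mixed with a Weyl constant, kept below
2³¹), so subsetting a cohort never shifts the noise of other recordings.
Identical (config, class, participant, side, seed) reproduce bit-identical
recordings.

## Preprocessing

Order: reflect → crop → derive → normalize.

* Reflection negates x for right-limb recordings before derivation, so
  velocity/acceleration signs are consistent; normalizing first would
  make the reflection a no-op or an inversion ambiguity.
* Crop threshold θ = `threshold_frac` (default 0.10) times the FN z
  range; window = first..last sample with FNz > FNz[0] + θ.  A constant
  FNz raises a degenerate-input error; a recording whose FNz never
  exceeds the threshold raises a no-movement error.
* Displacement is cumulative (Mdx[i] = Mx[i] − Mx[0]), not frame-to-frame:
  frame differences would duplicate velocity up to a constant, whereas the
  cumulative reading makes MD a distance-from-start signal.
* Velocity by central differences (one-sided at the ends, matching
  `np.gradient`); acceleration by central second differences with
  one-sided ends; both scaled by the sampling rate.  No smoothing is
  applied by default; an optional moving-average window exists but is off.
* Min–max normalization is per series, per recording.  A constant series
  maps to zeros and is flagged rather than erroring.

A consequence worth knowing: any positive affine transform applied
uniformly to the coordinates (one scale for all axes, per-axis offsets)
leaves all 60 normalized series bit-for-bit unchanged.  Per-axis *scales*
are not invariant for the module series, which mix axes.

## Feature catalog

The core catalog fixes 42 features per series (36 real, 6 binary) by
explicit formula.  Conventions pinned in the tests: population (biased)
moments inside skewness/kurtosis/autocorrelation; the autocorrelation
estimator is Σ(xᵢ−x̄)(xᵢ₊ₗ−x̄)/(n·σ²ₚₒₚ) (the standard ACF normalization
by n, not n−lag); extremum locations are relative positions in [0, 1];
features undefined on a series (autocorrelation of a constant, FFT bin
beyond Nyquist) return NaN, which is kept and flagged.  Every core
feature is checked against an independent plain-Python reimplementation
at 1e-9 relative tolerance on random series.

`reference_catalog(size)` extends the core with deterministic parameter
grids (autocorrelation lags, FFT bins, quantiles, c3 lags, peak supports,
threshold grids for the binary families) up to any requested size;
794 — the dimensionality of the large systematic catalogs used for
FRESH-style testing, giving 47,640 features per recording — is treated
purely as a configuration constant for count arithmetic.  The statistics
layer needs only the real/binary typing, so the method is
catalog-agnostic.

## Selection statistics

* **Mann–Whitney U** (real features): exact two-sided p by full
  enumeration of label assignments when n₁+n₂ ≤ 12 and the pooled sample
  is tie-free; otherwise the normal approximation with midranks,
  tie-corrected variance, and a 0.5 continuity correction.  The exact
  branch is verified against an independent rank-sum counting recursion
  for every partition with n₁+n₂ ≤ 10; the approximate branch against
  SciPy and a 10⁵-resample permutation estimate.
* **Fisher exact** (binary features): two-sided p by the
  point-probability method — the sum of hypergeometric point
  probabilities not exceeding the observed one (with the conventional
  1+1e-7 relative slack against round-off).  Two-sided Fisher definitions
  vary; this is the convention of the standard references and of the
  common statistical software.
* **Benjamini–Yekutieli** at q = 0.05, applied *within each one-vs-rest
  problem separately* (three p-vectors), since the selection problem is
  decomposed into three separate binary problems; the common set is the
  intersection of the three rejection sets.  Constant and all-NaN columns
  are excluded before the correction so m counts only testable features;
  the skip counts are reported.

A structural point about the intersection: a rank test cannot distinguish
a middle class from a symmetric mixture of a lower and a higher class, so
a feature with three well-separated class levels is never common.  Common
features are two-level by nature — one class extreme, the others similar —
and the two "rest" problems detect them only through the mixture shift
(AUC ≈ 0.75 when the separated class fully separates).  This makes the
common count far smaller than the per-problem counts and strongly
dependent on cohort size, which is the expected and intended behavior of
the design.

## Reporting

Series names map deterministically to (marker, domain, axis); module
series MD/MV/MA count under displacement/velocity/acceleration with
axis = "module", mirroring the wide grid layout (Module column split
A/V/D per marker).  Marginals by marker, axis, and domain each sum to the
grand total; the arithmetic is exercised on a published-style 60-cell
grid whose totals are 338/459/104/103 by marker and 1004 overall.

## Problem sizes used in the checks

* FDR benchmark: 900 null + 100 shift-1.0 features, 50 samples/group,
  200 replicates — mean false discovery proportion ≤ 0.05, typically
  ≈ 0.005 because BY is conservative under independence.
* Effect recovery: full-size cohort (324 recordings), one `jerk_noise_sd`
  = 0.15 mm effect on MPH/x for G1; the mixture problems need a cohort of
  roughly this size to clear the BY thresholds, which is why the recovery
  check runs at full scale.
* Null selectivity: 50 cohorts of 6+4 participants, 1 recording/limb —
  the exchangeability argument is size-free, so a small cohort suffices.

## Known limitations

* The generator's class effects are phenomenological (amplitude, extra
  submovements, roughness), not a model of hemiparetic motor control;
  effect magnitudes are user parameters with no clinical calibration.
* Features are univariate per series; cross-marker or windowed features
  are out of scope.
* The exact Mann–Whitney branch refuses ties and falls back to the
  corrected approximation, which is anti-conservative for very small tied
  samples; at the cohort sizes the pipeline targets this is immaterial.
* TRC support covers the common four-marker dialect written by this
  package; full-body marker sets and binary capture formats are not
  parsed.
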