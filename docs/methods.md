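# Methods

This note documents the models implemented in `phasekit`, the conventions
and defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence metrics

**Charge.** Two charge models are provided. *Formal*: +1 per lysine and
arginine, −1 per aspartate and glutamate, 0 otherwise (histidine carries no
formal charge). *Henderson–Hasselbalch*: the average protonation-state
charge at a given pH, +1/(1+10^(pH−pKa)) per basic site (H, K, R, free
N-terminus) and −1/(1+10^(pKa−pH)) per acidic site (D, E, C, Y, free
C-terminus). The default pKa table (N-term 9.0, C-term 3.55, D 4.05,
E 4.45, C 9.0, Y 10.0, H 6.0, K 10.0, R 12.0) is one of several in common
use; published tables differ enough to move a ~30-residue peptide's net
charge at pH 7.4 by ±0.3 e, so the table is user-overridable and recorded
in reports. Termini are included by default (fragments produced by
cleavage carry free termini).

**Composition.** Category fractions are reported under a configurable
residue grouping. The default singles out glycine (the defining residue of
glycine-rich proteins), groups A/P/M/C as other non-polar, V/I/L as
hydrophobic, F/Y/W as aromatic, and the remainder — including E, D, K, R
and H — as polar. That last choice mirrors how composition is commonly
reported for these proteins but is a convention, not a fact of chemistry;
the map is validated (all 20 residues covered, no overlaps) and any map
can be substituted.

**NCPR / FCR / Das–Pappu region.** The per-position NCPR is the mean
formal charge over a centred window (default 5 residues) truncated — not
padded — at the sequence edges. Global f⁺ and f⁻ are the fractions of
formally positive/negative residues; FCR = f⁺ + f⁻ and NCPR = f⁺ − f⁻.
The (f⁺, f⁻) pair is classified into the standard five regions of the
diagram used for disordered-sequence conformational classes: R1 when
FCR < 0.25, R2 when 0.25 ≤ FCR ≤ 0.35, R3 when FCR > 0.35 with both
fractions ≤ 0.35, R4 when f⁻ > 0.35, R5 when f⁺ > 0.35.

**Aromatic spacing.** Gaps are differences between successive aromatic
positions (F/Y/W by default); fewer than two aromatics yields an empty
list. Median/min/max summarise the "sticker" periodicity.

## Droplet fusion

**Shape measurement.** Droplets are segmented by Otsu (or fixed)
thresholding and connected-component labelling; the aspect ratio of a mask
is taken from the moment-equivalent ellipse — the ratio of the square
roots of the eigenvalues of the foreground-pixel coordinate covariance
(population normalisation). This equals the major/minor axis ratio for an
ideal ellipse, is rotation invariant up to pixelation, and is tested
against an independent brute-force covariance oracle to 1e−6.

**Relaxation fit.** A(t) = 1 + (A₀ − 1)e^(−t/τ) is fitted by
Levenberg–Marquardt with A₀ ≥ 1 and τ > 0, starting values taken from the
data (A₀ from the first sample; τ from the time the trace first reaches
1 + (A₀−1)/e). A constant trace is reported with τ = NaN and a
`degenerate` flag; a non-decaying trace is fitted but flagged, not
rejected.

**Inverse capillary velocity.** For viscous liquid droplets the
coalescence time scales as τ ≈ ℓ·(η/γ). The cohort regression of τ on ℓ is
through the origin by default because the physical relation has no
intercept; a with-intercept mode is available and both R² values are
computed against the fitted line. **Length convention:** ℓ is taken as the
*mean pre-fusion droplet radius*. Radius-versus-diameter conventions both
appear in the literature and rescale η/γ by exactly 2×; the CLI exposes
`--length-convention` and the choice is recorded in every report.

**Image path.** In a fusion movie the time origin is the first frame where
two components merge into one; ℓ is the mean equivalent-circle radius of
the two components in the last pre-merge frame.

## FRAP

**Normalisation.** With I(t) the bleached-ROI intensity and R(t) a
reference-region intensity, acquisition photofading is removed by
C(t) = R(0)/R(t), I_corr = C·I, and the recovery is rescaled as
f(t) = (I_corr − floor)/(I_corr(0) − floor). Two conventions are explicit
and configurable:

* I_corr(0) is the **mean of the pre-bleach samples** (default), not the
  first frame alone — averaging reduces the variance of the scale.
* The floor is the **first post-bleach sample** (default, `floor="first"`)
  — the value obtained immediately after bleaching. The alternative
  (`floor="min"`, the global post-bleach minimum) is provided but is an
  extreme-value statistic under noise: it sits systematically below the
  true bleach level and biases the mobile fraction upward.

The normalisation is exactly invariant to joint rescaling of I and R and
cancels any shared exponential photofading (both properties are tested).

**Recovery fit.** f(t) = A(1 − e^(−t/τ)) on the post-bleach samples, time
re-zeroed at the bleach. A is the mobile fraction (also reported as a
percentage), t½ = ln 2·τ. Numerical choices: A is bounded to [0, 1.5]
(physically ≤ 1, with slack for noise overshoot) and τ is bounded to the
observed post-bleach time span — a recovery slower than the acquisition
window is not identifiable from it, and an unconstrained τ lets slow noise
drifts ride the A/τ ridge to arbitrarily inflated amplitudes. Fits at the
τ bound are flagged (`tau_at_window_bound`), as are low-recovery and
wide-uncertainty fits. The optimiser is Levenberg–Marquardt with a small
multi-start over τ (data-driven, span/10, span/3) keeping the best
least-squares solution.

**Cohort averaging.** FRAP studies typically report the mean ± s.d.
recovery over several condensates and fit the mean curve;
`average_recovery` implements this (per-trace normalisation, then
averaging on the shared post-bleach grid). The benchmark script uses
cohorts of 6 (fresh) and 4 (aged) traces accordingly.

**Material properties.** D_app = ω²/t½ with ω² the bleach-ROI **area**
(default 0.75 µm², a 1.5 × 0.5 µm ROI). The ω convention is genuinely
ambiguous in the literature — area versus squared half-width differ by the
ROI's geometric factor, and for this system the printed D_app
(~2.2 × 10⁻³ µm²/s) is not what the area convention gives from τ = 160 s
(~6.8 × 10⁻³ µm²/s). The package therefore treats ω² as an explicit input,
defaults to the area reading, and reports the convention in force rather
than guessing; both readings are a single parameter change apart.
Viscosity follows from Stokes–Einstein, η = k_BT/(6π D R_h), with
T = 298 K by default (room temperature) and R_h = 2.5 nm (an unfolded
~8 kDa chain); interfacial tension from γ = η/(η/γ) with the inverse
capillary velocity converted from s/µm to SI (1 s/µm = 10⁶ s/m). The full
chain is dimensionally consistent to 1e−10 under unit changes (tested).

## Work of adhesion

Retract force–distance curves are baseline-corrected by fitting a straight
line to the far-from-surface tail (default: the 20% of samples at largest
distance) and subtracting it, removing constant offset and linear drift.
The adhesion energy is the trapezoidal integral of |F| over the contiguous
negative-force region containing the global force minimum; other negative
regions are reported as secondary wells, never merged. W_adh divides that
energy by the tip contact area. **Contact-area convention:** a circle
π R_tip² with R_tip = 10 nm by default. A hemispherical-cap convention
(2π R_tip²) differs by exactly 2× and is selectable; published values
rarely state which was used, so the model choice is always recorded. No
smoothing is applied before integration.

## Onset detection and phase grids

Published onset times for evaporation-driven coacervation are identified
visually; the detector here is an explicit operationalisation: baseline
mean and s.d. from the first 20% of samples, onset at the earliest time
the trace exceeds mean + z·s.d. (default z = 5) for at least `min_run`
(default 3) consecutive samples. It is invariant to affine intensity
rescaling and returns "no onset" rather than erroring on flat traces.

Phase-diagram observations (axis1, axis2, boolean call) are assembled onto
a rectangular lattice; unobserved cells are flagged, conflicting duplicate
calls are an error naming the cell. The regime boundary per axis-2 level
is the minimal axis-1 value with a positive call, under the assumption
that condensation is monotone in concentration and time; violations of
that assumption are reported alongside the boundary and the data are never
altered.

## Synthetic-data generators

Each generator produces exactly the structure its analyser assumes, with a
seed making output bit-identical; a single top-level seed fans out to
per-stage substreams (`stage_rng`).

* *Fusion events*: the exponential relaxation model plus additive Gaussian
  noise; image mode renders an area-preserving ellipse per frame.
* *Fusion cohorts*: radii uniform on 1–5 µm and τ = ℓ·(η/γ) times a
  unit-mean lognormal factor (relaxation times are positive, so scatter is
  multiplicative; default coefficient of variation 0.3, matching the
  scatter visible in published τ–ℓ cohorts of n ≈ 16).
* *FRAP traces*: pre-bleach plateau (5 frames), bleach drop to 20% of the
  plateau, exponential recovery to the mobile-fraction level, shared
  exponential photofading on ROI and reference, and Gaussian noise whose
  s.d. is a fraction of the instantaneous signal (shot-noise-like;
  reference noise is zero by default since reference regions are large).
  Defaults mirror a confocal protocol: 5 s sampling over 6 min.
* *Force curves*: linear repulsive contact plus a parabolic adhesive well
  whose integrated area equals W_adh·πR_tip², sampled densely (500 points
  across the well by default).
* *Onset traces*: a sigmoidal step (10–90% rise within half a sampling
  interval) on a constant baseline.
* *Droplet fields*: non-overlapping discs, Gaussian blur, additive noise.

**What the generators do not emulate** — and therefore what passing round
trips do and do not show: real microscopy has structured backgrounds,
uneven illumination, depth-dependent blur and droplet motion; real FRAP
has diffusive (non-exponential) early recovery, bleaching during
acquisition beyond a single shared exponential, and ROI drift; real AFM
curves have hysteresis, viscoelastic creep and multi-peak rupture events;
real onset traces ride on evaporation-driven intensity ramps. Passing the
suite demonstrates that the estimators are correct and stable for the
stated models at realistic noise levels, not that those models capture
every artefact of the instruments.

## Benchmark problem sizes

`scripts/acceptance.py` uses the cohort sizes of the study it benchmarks
against: 16 fusion events (30% τ scatter), one noise-free example fusion
trace (dt = 0.25 s over 15 s), FRAP cohorts of 6 fresh and 4 aged traces
(5 s sampling, 6 min, 5% noise, 0.1%/s photofading), and noise-free force
curves with 500 samples across a 20 nm well. All runs complete in seconds
on one CPU.

## Known limitations

* Single-exponential FRAP recovery only; no diffusion-equation
  (Soumpasis-type) or multi-component models.
* The recovery fit cannot distinguish mobile fractions whose τ exceeds
  the acquisition window (reported at the bound, flagged).
* Charge models ignore post-translational modifications, local
  electrostatic environment and charge regulation.
* The onset detector's defaults are an operationalisation of a visual
  criterion; absolute onset times depend on them.
* No vendor binary formats (AFM or microscope); text tables and TIFF only.
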