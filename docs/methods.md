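# Methods

This note documents the models implemented in `fingerrsa`, the
assumptions behind them, the parameter defaults and why they were
chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Crossnobis dissimilarities

Activity patterns are beta estimates per repetition × condition ×
voxel (finger × modality conditions). The six repetitions are split
into odd (1st, 3rd, 5th) and even partitions, averaged per condition
within partition. Each condition's across-voxel mean is subtracted so
that a different average activation level in the motor and tactile
tasks cannot masquerade as pattern dissimilarity (`mean_removal:
voxel`; the alternative `condition_set` subtracts each modality's mean
pattern across conditions instead — the two readings of "average
activity" cannot be distinguished from the verbal description, so both
are available, with `voxel` the default).

The dissimilarity is the cross-validated inner product

d(i, j) = ⟨ b̃ᵢᴬ − b̃ⱼᴬ , b̃ᵢᴮ − b̃ⱼᴮ ⟩ / P,

with P the voxel count and b̃ the (optionally whitened) partition-mean
patterns. Because the two factors carry independent noise, E[d] = 0
when the true patterns are identical — negative estimates are expected
and preserved everywhere except the MDS embedding. Division by P makes
values comparable across ROIs of different sizes; they are unitless.

Whitening uses the inverse Cholesky factor of a shrinkage covariance
estimated from residual draws: the sample covariance blended toward
its diagonal with the analytic intensity λ\* = Σ Var(ŝᵢⱼ) / Σ ŝᵢⱼ²
(off-diagonal sums, clipped to [0, 1]). The noise estimator behind a
Mahalanobis metric is rarely reported in full; `whitening: identity`
gives plain cross-validated Euclidean distances for sensitivity
analysis. Zero-variance voxels are floored at 1e-12 and logged.

Only two-fold (even/odd) cross-validation is implemented; the design
has no run structure to support leave-one-run-out.

## Behavioral hand models

* **Real hand**: 3D Euclidean distances between fingertip rest
  positions.
* **Perceived hand**: each fingertip's perceived position is the mean
  of its repeated landmark-pointing judgments; distances as above.
* **Manipulation**: per trial, fingertip-speed traces (100 Hz) are
  low-pass filtered at 10 Hz (zero-phase Butterworth), windowed from
  the first to the last crossing of 10 mm/s, min-max normalized to
  [0, 1], and compared between fingers by Euclidean distance; trial
  RDMs are averaged over trials, the 12 objects, and participants.
  Three choices are under-determined by the verbal protocol and fixed
  as follows:
  * normalization scope is per trial *jointly across fingers*
    (preserving between-finger amplitude ratios, which carry the
    synergy signal); per-finger scope is available via
    `normalization="finger"`;
  * the movement window is defined on the fastest finger's trace and
    applied to all fingers (onset/offset is a property of the trial,
    not of a finger);
  * windowed traces are linearly resampled to 101 samples before the
    distance (Euclidean distance needs equal dimension across trials).
  Trials that never cross the threshold are excluded with a logged
  warning. The filter order for the kinematic low-pass is not stated
  in the protocol; 4th order is used, matching the EMG stage.
* **Muscle**: EMG (2 kHz) is downsampled to 1 kHz (direct decimation,
  matching the stated order of operations — the subsequent 40 Hz
  low-pass bounds any aliased content), full-wave rectified, low-pass
  filtered at 40 Hz
  (4th-order zero-phase Butterworth), averaged over time within trial
  and then over trials per moved finger, giving one 13-channel vector
  per finger; the RDM is the pairwise Euclidean distance of those
  vectors, averaged over participants. Averaging over time before
  trials (rather than on concatenated trials) is a documented choice;
  for rectified, low-pass signals the two differ negligibly.

Both filtering stages are zero-phase (forward–backward): the analysis
is offline and phase lag would distort inter-finger alignment. Group
models are unweighted means of participant RDMs.

## PCM correlation models

Voxel activity profiles are modeled as i.i.d. Gaussian draws with
condition covariance (second moment)

G(θ, r) = [[s₁·Ĝ, r√(s₁s₂)·Ĝ], [r√(s₁s₂)·Ĝ, s₂·Ĝ]],

where Ĝ is a fixed unit within-modality finger geometry and
θ = (log s₁, log s₂, log σ²). The observations are the two
partition-mean pattern matrices (condition-mean removed), stacked; the
marginal likelihood is evaluated through the eigendecomposition of
V = ZGZᵀ + σ²I (eigenvalues floored at 1e-10) and maximized by
L-BFGS-B with analytic gradients. Starting points are five
deterministic multiplicative offsets of a method-of-moments estimate
plus a warm start at the neighboring model's optimum; by default the
candidates are screened by objective value and only the best is
optimized (verified equivalent to full multi-start to ~1e-5 on this
3-parameter problem), `screen_starts=False` restores full multi-start.

Ĝ is estimated from the data as the cross-validated second moment
(YᴬYᴮᵀ + YᴮYᴬᵀ)/2P, averaged over the two within-modality blocks,
PSD-projected and trace-normalized; a model-derived Ĝ can be supplied
instead. The free parameters are deliberately minimal (two signal
variances + one noise variance, no per-finger variances): the smallest
family that realizes the correlation sweep. The default grid is 20
models, r from 0.05 to 1.0 in steps of 0.05; ties in the best model
resolve toward lower r (conservative). Partition/run effects are not
modeled; the partition means are the observations.

Group inference compares the best model's log-likelihood (highest mean
across subjects) against every other model by paired t tests;
zero-variance differences are reported as masked.

## Non-negative RSA and noise ceilings

RDMs and model RDMs are vectorized (strict upper triangle) and
z-scored with the *population* SD (the sample/population choice is not
observable downstream but is fixed and tested). No intercept is fitted
in either regression — all variables are centered by the z-scoring.
The multiple regression is solved by active-set NNLS (deterministic;
KKT conditions are property-tested). Simple regressions are plain OLS
slopes, numerically the Pearson correlation for z-scored variables;
a non-negative variant is available by flag. z-scoring is per vector
(per subject/cell), not pooled; coefficients are estimated per
subject, hemisphere, region and task and aggregated afterwards.

The noise ceiling for a task × region cell regresses each subject's
z-scored RDM vector on the z-scored leave-one-out group mean and
averages the coefficients. It estimates the fit an ideal group-level
model could reach given between-subject variability; it exceeds any
imperfect model's fit because the group mean captures shared structure
the model misses. With identical subjects it equals 1 exactly.

Group summaries use cell means/SDs, paired t statistics and
Benjamini–Hochberg FDR within each declared family.

## Somatotopy Bayes factors

Inputs are per-hand distances (D1–D2, D1–D3, D1–D4, D1–D5) between
finger ROI centers. Group means and their sampling covariance define a
normal approximation to the posterior; no full Bayesian ANOVA model is
fitted. For a constrained hypothesis, BF = f/c where f is the
posterior probability of the constraint region and c its probability
under a fractional prior: a normal centered on the equality point with
the sampling covariance inflated by n/J (J = number of constraints;
the fraction b = J/n is the conventional default and is exposed).
The prior covariance is symmetrized to exchangeable form (common
variance, common covariance), which makes the prior probability of a
full ordering of k quantities exactly 1/k! by symmetry — hence
BF_ordering saturates at 4! = 24 — and makes c estimable by Monte
Carlo with small error. Both probabilities use antithetic Monte Carlo
(default 1e6 draws) with reported standard errors; results with MC
error above 10% of the BF are flagged. The about-equality region is
max(D) − min(D) < 0.25·(pooled SD), equivalent to all pairwise
|Dᵢ − Dⱼ| below the margin. Posterior model probabilities use equal
prior weights by default.

Calibration: under exchangeable truth the BF for a given ordering is
mean-calibrated (E[BF] = 1, since E[f] = c); its distribution is
right-skewed, so the median across replicate datasets sits near 0.4,
not near 1. The validation asserts the mean property and the
oracle-derived median band.

Bayes factors reported for the original cohort depend on unreported
details of the covariance structure and prior fraction, so specific
published values are not reproduction targets; the implementation is
validated on its limiting values and calibration instead.

## Connectivity and geometry summaries

Functional connectivity is the Fisher z (atanh) of pairwise Pearson
correlations of ROI time series; structural connectivity is the fiber
count matrix divided by its maximum. Both are divided elementwise by
the inter-ROI Euclidean distance matrix to remove the shared distance
bias — the transform/normalization happens first, the distance
correction second (the reverse order is defensible; this one is fixed
and documented). Zero or missing distances mask the corresponding
entries, and every block summary excludes masked cells and reports
effective counts.

Block summaries on joint 2n × 2n matrices (motor block first): means
over |i−j| = 1 pairs within each modality block, over the cross-block
diagonal (same finger across modalities) and over |i−j| = 1 entries of
the cross block. Adjacency is radial order D1..Dn.

Classical MDS is the Torgerson construction (clip negative
dissimilarities at 0, double-center the squared distances, top-d
eigenvectors scaled by √eigenvalue) with a deterministic sign
convention (first nonzero coordinate of each axis positive) and
zero-padding when fewer positive eigenvalues than requested dimensions
exist.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 5 fingers (6 supported), motor
and tactile modalities, precentral and postcentral regions, 6
repetitions per finger, modality-specific mean-activation offsets, 12
manipulated objects × 10 trials of 100 Hz fingertip kinematics, 13 EMG
channels at 2 kHz with 6 trials per finger, somatotopic ROI centers on
a lateromedial D1→Dn line with jitter, and occasional missing finger
ROIs (dropped uniformly at random — the real mechanism, overlap or
absent activation peaks, is not modeled).

The joint second moment is built from a model RDM D by double-centering
−½HD²H, unit-normalizing the diagonal mean, scaling by per-modality
signal variances, and coupling the modalities by r times the same unit
geometry (no free rotation — exactly the family the correlation models
test). Eigenvalues are clipped at 0 (tolerance 1e-10). Condition
profiles are drawn once per subject and shared across repetitions, so
repetition variability is purely additive i.i.d. noise and crossnobis
expectations are analytic; real betas additionally vary with slow
drifts, motion and correlated noise, none of which is simulated.
Because the voxel noise is generated i.i.d., whitening is close to
identity here; passing synthetic tests therefore says nothing about
the benefit of shrinkage whitening on real, spatially correlated
noise. There is no image space, no hemodynamics and no time-series
GLM: patterns are ROI-extracted matrices by construction.

Behavioral defaults: fingertip rest coordinates are plausible
millimeter positions of a hand flat on a table; the perceived-hand
distortion is the classic overestimated width (×1.2) and
underestimated length (×0.8) with 5 mm judgment noise; kinematic
synergies are neighbor-correlated Gaussian loadings (enslaving);
EMG coactivation gives each finger a preferred channel with spillover
to its neighbors. EMG trials default to 1 s (the protocol's 6 s
carries no additional structure in this stationary generator and
would multiply memory sixfold). Resting time series come from a
latent-factor model whose expected correlation matches the
same-finger/adjacent-finger coupling design; structural counts are
Poisson around the same design.

## Validation problem sizes

The property-based validation (tests and `scripts/acceptance.py`)
uses: 1000 zero-signal crossnobis simulations at 20 voxels; 50
replicates × 20 subjects × 200 voxels per generating correlation for
PCM recovery; 100 replicates × 50 subjects for NNLS recovery; 100
replicate groups of 20 subjects for the noise ceiling; 1e6 Monte Carlo
draws (200 replicate datasets for calibration) for the Bayes factors;
and 50 full-pipeline replicates at 6 subjects × 120 voxels for the
direction checks. These sizes give stable rates while keeping the full
validation within a few minutes on one CPU.

## Known limitations

* The correlation-model family assumes a shared within-modality
  geometry up to scale; genuinely different motor and tactile
  geometries would be mis-modeled (only the overall correlation is
  estimated).
* The Bayes factors rest on a normal approximation to the posterior of
  four group means — adequate for n ≳ 10 hands, untested below.
* Classical repeated-measures ANOVAs on group tables are provided only
  as thin summaries (cell means, paired contrasts with FDR), not as a
  full mixed-model machinery.
* The synthetic generator's fixed-profile assumption (no true
  repetition-level pattern variability) is a modeling choice the
  protocol text does not determine.
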