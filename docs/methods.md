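# Methods

This note documents the models implemented in `phasl`, the defaults and
why they were chosen, what the simulators do and do not emulate, and
the numerical decisions a maintainer would want to know.

## Acquisition model and forward simulation

The simulated protocol mirrors a 3 T pCASL acquisition: TR 4.0 s,
TE 14 ms, post-labeling delay (PLD) 1.650 s, label duration τ 1.525 s,
75 control/label pairs (150 interleaved volumes, control first), voxel
size 3×3×7 mm, no background suppression. "75 dynamics" is interpreted
as 75 pairs — i.e. 75 `M_diff` images — because the outlier statistic
is defined per subtraction image; the series container stores the
interleaved 150 volumes and the pairing convention `(2k, 2k+1)`.

The phantom is a smooth concentric-ellipsoid brain: CSF core, WM
interior, cortical GM shell, and three pure-GM blobs standing in for
striatum, thalamus and ACC (deep gray nuclei embedded in WM, plus a
midline frontal blob). Tissue partial volumes have linear transition
bands about one voxel wide so that the image is smooth enough for
gradient-free registration; true CBF is 60 (GM) and 20 (WM)
ml/100 g/min, and M0 is a positive tissue-weighted combination. The
forward signal is the exact algebraic inverse of the quantification
formula below, so noiseless round-trips are machine-precision tests of
the implementation rather than approximate ones.

Motion is simulated per pair (both members share the pair's rigid
parameters), measurement noise is i.i.d. Gaussian per voxel and volume,
and outlier dynamics receive an additive bright slab over a random
contiguous run of slices with amplitude expressed in noise-SD units —
a caricature of a sudden-motion subtraction artifact that is sufficient
to exercise the SSD statistic. The simulator does not model k-space/EPI
artifacts, physiological noise correlations, arterial transit effects
or pharmacokinetics; passing tests therefore validate the algorithms'
correctness and operating characteristics under the stated noise model,
not robustness to every artifact of real scanner data.

## Outlier rejection

For pairs *i*, *j*: `SSD(i,j) = Σ_v (M_diff,i − M_diff,j)²`. A common
threshold is formed as `median + 3·SD` where the median is over all
off-diagonal SSD values and the SD is computed (population form,
denominator n) from only the values strictly below that median — a
robust scale estimate that large artifacts cannot inflate. Timepoint
*i* is rejected when strictly more than 50% of its n−1 SSD values
exceed the threshold. Degenerate cases (fewer than two below-median
values, or zero SD) collapse the threshold to the median, and the
strict comparison then leaves all-identical series unflagged.

A per-timepoint variant (median/SD from the row's own values) is
available as `scope="per_timepoint"` for sensitivity analysis, but note
it is essentially inert: at most half of a row's values can strictly
exceed the row's own median, so with a non-negative SD the majority
criterion can never fire. The pooled threshold is the reading under
which the rule actually detects artifacts, and it achieves 100%
sensitivity/specificity on simulated series with up to 10 of 75
dynamics corrupted at ≥ 20× noise SD.

Rejection is applied once (no iteration) and operates on `M_diff`
computed from uncorrected volumes; motion correction is applied
afterwards to the retained pairs only.

## Motion estimation and framewise displacement

Rigid motion (3 translations, 3 rotations about the grid center) is
estimated per volume by derivative-free coordinate descent on an SSD
cost against an evolving reference, with step halving from 1 mm/0.02 rad
down to 0.01 mm/0.0005 rad and an evaluation cap of 400. Controls and
labels are referenced to their own class means: the label volumes
differ from controls by the perfusion signal, and a pooled mean would
bias the registration (this is visible as a non-zero round-trip error
if disabled). Two refinement passes rebuild the class means from
corrected volumes. A groupwise PCA-style cost (residual eigenvalue mass
of the timepoint Gram matrix) is provided as a non-default `metric`
option with the same interface.

Mean-referenced groupwise estimation fixes the transforms only up to a
common gauge (the average transform, not any individual one, is pulled
toward zero), so recovery is validated on relative displacements
between timepoints — also the quantity framewise displacement uses:
`FD_t = Σ|Δtranslations| + r·Σ|Δrotations|` with head radius
r = 50 mm, `FD_1 = 0`. This is the dominant convention for scalar
motion summaries; the radius converts rotations to an equivalent arc
length at the head surface.

ΔM is the voxelwise mean of retained pairs after trilinear resampling
under the per-pair transform (the control volume's estimate). Exact
identity transforms short-circuit the interpolation so that noiseless
pipelines remain bit-exact.

## CBF quantification

Single-compartment model for pCASL, inverted for CBF in ml/100 g/min:

    CBF(v) = 6000 λ ΔM(v) e^{PLD(v)/T1} / (2 α T1 M0(v) (1 − e^{−τ/T1}))

with `PLD(v) = PLD + z(v)·Δt_slice` accounting for the per-slice delay
of the 2D readout. Defaults: α = 0.85, λ = 0.95 mL/g, T1 = 1.6 s —
T1 is stored in seconds and deliberately uses the gray-matter value
rather than the arterial-blood T1 of the consensus implementation; the
parameter is configurable for users who prefer the white-paper choice.
The 6000 factor converts mL/g/s to ml/100 g/min. `Δt_slice` defaults to
`(TR − τ − PLD)/n_slices` with the slice count taken from the image,
since readout timing is not otherwise recoverable. M0 is the mean of
the control images (no separate proton-density scan is modeled). CBF
is computed only where GM probability ≥ 0.3; voxels with non-positive
M0 inside the mask are marked undefined and counted in the QC dict
rather than silently propagated.

## Partial-volume correction

Local linear regression on the tissue fractions: within each voxel's
window, `y_j ≈ P_GM,j·m_GM + P_WM,j·m_WM` is solved by least squares
from windowed sums (uniform-filter accumulation, zero-padded edges;
Cramer's rule on the 2×2 normal equations). CSF is excluded from the
design because it contributes no perfusion signal. The correction is
applied to ΔM and M0 separately and the corrected GM CBF is the
quantification of the two GM fields — correcting the inputs rather
than the quantified map keeps the operation linear in the signal.

The default kernel is 5×5×1, in-plane only: with 7 mm slices a 3D
kernel would regress across tissue far out of plane. Rank-deficient
windows (single tissue or constant fractions) fall back to direct
division `m_GM = y/P_GM` where `P_GM ≥ 0.3` (exact in pure-GM regions)
and are counted in QC. With locally constant magnetizations the local
normal equations are exact, which the validation exploits: recovery of
both tissue fields to ~1e-12 on a two-tissue phantom.

## Atlas fusion and ROI extraction

Label fusion is plain voxelwise majority voting over pre-aligned
atlases. Ties are broken deterministically: background (code 0) loses
to any anatomical code, and the lowest code wins among anatomical ties
— favoring anatomy over background and making fusion order-invariant.
ROI means are taken over voxels carrying the ROI code, inside the GM
mask, with finite CBF; empty ROIs are flagged with a zero voxel count
rather than raising. Atlas registration itself is out of scope; the
simulator emulates registered atlases by flipping boundary voxels at a
configurable rate, under which 30-atlas fusion recovers the true labels
on > 99% of ROI voxels at 10% jitter.

## Group statistics

The split-plot ANOVA uses the classical weighted (cell-frequency) sums
of squares. With two within-subject levels and every complete-case
subject contributing both, cell counts are proportional, the strata are
orthogonal, every SS is non-negative, and the stratum SS add exactly to
the total SS (asserted to 1e-8 in tests on arbitrary inputs). Group is
tested against subjects-within-groups; challenge and group×challenge
against challenge×subjects-within-groups. For unbalanced groups this
weighted challenge test differs from SPSS's Type III (unweighted
marginal means) only when a nonzero interaction is present; under the
null and in balanced designs they coincide. Missing post-challenge
scans are handled complete-case per analysis.

Post-hoc pairwise group contrasts use the pooled between-subject error
(variance of a subject mean estimated as MS_subjects/2) with Sidak
adjustment `p_adj = 1 − (1−p)^m`, m = 3 pairwise contrasts. The
baseline one-way ANOVA optionally adjusts for covariates via the
extra-sum-of-squares F test of the group dummies in an OLS model
containing the covariates. χ² tests are Pearson without continuity
correction (three groups, df = 2, so the Yates correction does not
apply); drug use is dichotomized with strict cutoffs (cannabis
> 1×/week; MDMA/cocaine/amphetamine > 10× lifetime). Degenerate
zero-variance inputs raise explicit errors, except that an exactly null
effect against a degenerate error stratum is reported as F = 0 (e.g.
post duplicated from pre gives SS_challenge = 0, F = 0). No
multiple-testing control is applied across ROIs.

## Cohort generator defaults

Group sizes 26/29/26 (EST/LST/STN). Baseline ROI CBF Normal(60, 10)
ml/100 g/min in all three ROIs; the EST group has a −6 offset in the
ACC only. The challenge lowers CBF by 3 ml/100 g/min in striatum and
ACC, 0 in thalamus, with no group×challenge interaction. The
within-subject change SD is 6 ml/100 g/min — back-derived from the
magnitude of challenge F statistics such a design produces at n = 81
with a −3 effect, and the one generator parameter not fixed by the
cohort description. Behavioral scores (ADHD-RS, BDI, BAI) are Normal
with the per-group means/SDs of the cohort characteristics, censored
at zero (the censoring slightly raises means relative to the nominal
values; CBF fields, which drive the primary analyses, are exact
normals). Drug use is generated directly as over-cutoff Bernoulli
indicators with the per-group observed proportions. With probability
`dropout_prob` (default 1) exactly one random subject misses the post
scan, mirroring the single dropout such studies typically see.

## Replication of the study-level pattern

`pattern_replication` scores, per simulated cohort, the joint event:
challenge effect significant in striatum and ACC but not thalamus,
baseline group effect significant in ACC only, interaction
non-significant everywhere (all at α = 0.05). This conjunction contains
six true-null non-rejections, so even with perfect power its expected
rate is bounded by 0.95⁶ ≈ 0.74; with the analytic baseline-ACC power
of ≈ 0.59 at the −6/SD-10/26-29-26 configuration the achievable joint
rate is ≈ 0.43. The function therefore also reports per-component
rates, which are the interpretable quantities: challenge detection
≈ 0.99 in striatum/ACC, false-positive components near their nominal
5% each, baseline-ACC detection near its analytic power. The joint
rate is reported as-is rather than redefining the pattern to make it
look better.

## Problem sizes and determinism

Validation workloads are sized for a desk-scale run: a 32×32×8 phantom
(3×3×7 mm voxels), 75-pair series for preprocessing properties, 50
seeded series for the outlier operating point, 2,000 null cohorts for
type-I error, 1,000 cohorts for power, 100 for pattern replication,
and ~10,000 subjects for moment recovery. All generators draw from
`numpy.random.default_rng` seeded via `SeedSequence`, so every result
is bit-reproducible given the seed; study runs write a manifest with
the seed and a SHA-256 hash of the canonical config.

## Known limitations

- The registration is a local coordinate-descent method adequate for
  the smooth phantom and small displacements; it is not a substitute
  for a production registration tool on real data, and large or
  through-plane motion on 7 mm slices will defeat it.
- The single-compartment model ignores arterial transit time,
  dispersion and background-suppression effects.
- The cohort generator draws scores independently of CBF; correlation
  analyses between scores and CBF response are therefore only
  null-calibrated, not power-tested.
- Only the three analysis ROIs are modeled; a real multi-atlas
  segmentation covers many more structures.
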