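# phasl — pharmacological ASL perfusion pipeline

`phasl` is a tested, reusable implementation of a pharmacological-MRI
(phMRI) analysis for pseudo-continuous arterial spin labeling (pCASL)
data: quantify cerebral blood flow (CBF) before and after an acute
dopaminergic drug challenge (oral methylphenidate, 0.5 mg/kg) and test
how the CBF response differs between patient groups defined by their
stimulant-treatment history — early-treated (EST), late-treated (LST)
and stimulant-treatment-naive (STN).

It is aimed at perfusion-MRI methods researchers who want each stage of
such an analysis available as a library function with a forward
simulator to validate against, since clinical cohort data of this kind
are rarely shareable.

## What it implements

**Preprocessing.** An interleaved control/label series is split into
pairs; each pair's subtraction `M_diff = M_c − M_l` carries the
perfusion signal. Sudden-motion artifacts are rejected with a pairwise
sum-of-squared-differences (SSD) statistic: for images *i*, *j*,
`SSD(i,j) = Σ_v (M_diff,i(v) − M_diff,j(v))²`. A common threshold
`median + 3·SD` is formed over all pairwise SSD values, with the SD
estimated robustly from only the values below the median; a timepoint
is discarded when a strict majority of its SSD values exceeds the
threshold. Rigid motion is estimated by coordinate descent against an
evolving class mean (controls and labels referenced separately), motion
is summarized as Power-style framewise displacement
`FD_t = Σ|Δt| + r·Σ|Δθ|` (head radius r = 50 mm), and the retained,
motion-compensated `M_diff` images are averaged into the
perfusion-weighted image ΔM.

**Quantification.** Single-compartment (Buxton) model for pCASL:

    CBF = 6000 · λ · ΔM · exp(PLD_z / T1) / (2 · α · T1 · M0 · (1 − exp(−τ/T1)))

in ml/100 g/min, with labeling efficiency α = 0.85, gray-matter
T1 = 1.6 s, partition coefficient λ = 0.95 mL/g, label duration
τ = 1.525 s and a per-slice post-labeling delay
`PLD_z = PLD + z·Δt_slice` for the 2D readout (PLD = 1.650 s). M0 is
the mean of the control images. CBF is quantified in gray matter only,
with partial-volume correction by local linear regression: in each
voxel's neighborhood the signal is modeled as
`y = P_GM·m_GM + P_WM·m_WM` and solved by least squares from the local
normal equations.

**ROI extraction.** Multiple pre-aligned atlas label maps are fused by
majority voting (deterministic tie-breaks) and mean GM CBF is extracted
for striatum, thalamus and anterior cingulate cortex (ACC).

**Statistics.** Per ROI: a split-plot (mixed) ANOVA with group
(EST/LST/STN) as the between-subjects factor and challenge (pre/post)
as the within-subjects factor; a baseline one-way ANOVA with optional
covariate adjustment (extra-sum-of-squares F); Sidak post-hoc contrasts
`p_adj = 1 − (1 − p)^m` on the pooled error; Pearson correlations of
the CBF response with age of first exposure; and Pearson χ² tests on
drug use dichotomized at the study cutoffs (cannabis > 1×/week, other
drugs > 10× lifetime).

**Simulation.** A smooth digital brain phantom (CSF core, WM interior,
cortical GM shell, three pure-GM ROI blobs) drives the exact algebraic
forward of the quantification model to produce pCASL series with
configurable rigid motion, bright-slab artifacts and Gaussian noise,
plus jittered atlas copies and a three-group cohort generator
(group sizes 26/29/26, baseline CBF 60 ± 10 ml/100 g/min, EST-only ACC
deficit −6, challenge effect −3 in striatum and ACC, behavioral scores
and drug-use rates) with ground truth returned for recovery tests.

## Worked example

```
phasl simulate --out demo --seed 1
phasl stats --cohort demo/cohort.tsv --out demo/results.json
```

prints

```
striatum: challenge F=25.90 (p=0.0000), group F=0.03 (p=0.9697), interaction F=1.24 (p=0.2944); baseline group F=0.18 (p=0.8322)
thalamus: challenge F=0.02 (p=0.8760), group F=2.02 (p=0.1402), interaction F=0.07 (p=0.9282); baseline group F=2.37 (p=0.1000)
acc: challenge F=19.79 (p=0.0000), group F=8.29 (p=0.0005), interaction F=0.21 (p=0.8151); baseline group F=9.43 (p=0.0002)
cannabis: chi2=2.55 df=2 p=0.2799
mdma: chi2=4.81 df=2 p=0.0902
cocaine: chi2=5.75 df=2 p=0.0564
amphetamine: chi2=2.17 df=2 p=0.3387
```

Reading this: the challenge reduced CBF in striatum and ACC (large
challenge F, tiny p) but not in the thalamus, no group × challenge
interaction anywhere, and in this draw the EST group's ACC baseline
deficit reached significance — the qualitative behavior the cohort
generator is parameterized to produce. The χ² lines test whether the
proportion of drug users differs between the three groups.

The image pipeline is available per stage (`phasl preproc`,
`phasl quantify`, `phasl roi`) and end to end via a YAML study config
(`phasl run-all --config study.yaml`); every run writes a manifest with
the seed and a config hash for reproducibility.

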