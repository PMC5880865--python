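"""Forward simulation of everything the pipeline consumes.

A digital phantom (smooth concentric-ellipsoid brain with a CSF core, a
WM interior, a cortical GM shell and three deep-GM ROI blobs standing in
for striatum, thalamus and anterior cingulate cortex) is pushed through
the exact algebraic forward of the single-compartment model to produce
pCASL control/label series with rigid motion, slab artifacts and
Gaussian noise.  A three-group pharmacological-challenge cohort (early
stimulant treatment EST, late LST, treatment-naive STN) is simulated
with group baseline offsets, pre-to-post challenge effects, behavioral
scores and dichotomized recreational drug use.  Ground truth is
returned alongside for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preproc import AslTimeSeries, RigidTransform, resample_rigid
from .quant import QuantParams, _kinetic_factor

ROI_NAMES = ("striatum", "thalamus", "acc")
ROI_CODES = {"striatum": 1, "thalamus": 2, "acc": 3}
GROUPS = ("EST", "LST", "STN")

#: acquisition defaults of the emulated pCASL protocol
DEFAULT_TR_S = 4.0
DEFAULT_TE_S = 0.014
DEFAULT_PLD_S = 1.650
DEFAULT_TAU_S = 1.525
DEFAULT_N_PAIRS = 75
DEFAULT_SPACING_MM = (3.0, 3.0, 7.0)


@dataclass
class Phantom:
    """Anatomical ground truth on a voxel grid."""

    shape: tuple
    spacing_mm: tuple
    gm_pv: np.ndarray
    wm_pv: np.ndarray
    csf_pv: np.ndarray
    true_cbf: np.ndarray
    m0: np.ndarray
    roi_labels: np.ndarray

    def roi_true_means(self, gm_threshold: float = 0.3) -> dict:
        """Mean true CBF per ROI over GM voxels (the recovery target)."""
        out = {}
        for name, code in ROI_CODES.items():
            sel = (self.roi_labels == code) & (self.gm_pv >= gm_threshold)
            out[name] = float(self.true_cbf[sel].mean()) if sel.any() else float("nan")
        return out


@dataclass
class MotionSpec:
    """Per-dynamic rigid motion, artifact timepoints and noise level.

    One dynamic = one control/label pair; both volumes of a pair share
    the pair's rigid parameters.  Outlier dynamics receive an additive
    bright slab over a contiguous run of slices with amplitude
    ``outlier_amplitude`` times ``noise_sd`` (mimicking a sudden-motion
    subtraction artifact).
    """

    n_dynamics: int = DEFAULT_N_PAIRS
    translations_mm: np.ndarray | None = None
    rotations_rad: np.ndarray | None = None
    outlier_timepoints: frozenset = frozenset()
    outlier_amplitude: float = 20.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_dynamics < 1:
            raise ValueError("n_dynamics must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("translations_mm", "rotations_rad"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != (self.n_dynamics, 3):
                    raise ValueError(f"{name} must have shape (n_dynamics, 3)")
                setattr(self, name, arr)
        self.outlier_timepoints = frozenset(int(i) for i in self.outlier_timepoints)
        if any(i < 0 or i >= self.n_dynamics for i in self.outlier_timepoints):
            raise ValueError("outlier_timepoints must lie in [0, n_dynamics)")


def _soft_inside(rho: np.ndarray, boundary: float, width: float) -> np.ndarray:
    """Fractional 'inside boundary' weight with a linear transition band."""
    return np.clip((boundary - rho) / width + 0.5, 0.0, 1.0)


def make_phantom(shape=(32, 32, 8), spacing_mm=DEFAULT_SPACING_MM,
                 seed: int = 0,
                 cbf_gm: float = 60.0, cbf_wm: float = 20.0) -> Phantom:
    """Build the default smooth digital brain phantom.

    Concentric ellipsoids: CSF core, WM interior, GM shell, plus three
    disjoint pure-GM ROI blobs (deep gray nuclei and a midline frontal
    blob).  Tissue partial volumes have linear transition bands so the
    phantom is smooth enough for gradient-free registration.  True CBF
    defaults: GM 60, WM 20, CSF 0 ml/100 g/min.  Deterministic given
    (shape, seed): the seed only jitters ROI centers by half a voxel.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < m for s, m in zip(shape, (16, 16, 4))):
        raise ValueError(
            f"shape {shape} too small to place 3 disjoint ROIs; minimum (16, 16, 4)")
    rng = np.random.default_rng(seed)
    idx = np.indices(shape, dtype=np.float64)
    center = (np.array(shape, dtype=np.float64) - 1.0) / 2.0
    semi = 0.92 * center
    rho = np.sqrt(sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)))

    w = 0.10  # transition-band half width in normalized radius
    in_brain = _soft_inside(rho, 1.0, w)
    in_csf = _soft_inside(rho, 0.22, w)
    in_wm_outer = _soft_inside(rho, 0.68, w)
    csf_pv = in_csf
    wm_pv = np.clip(in_wm_outer - in_csf, 0.0, 1.0)
    gm_pv = np.clip(in_brain - in_wm_outer, 0.0, 1.0)

    # ROI blobs: pure GM, placed in the WM belt, disjoint by construction
    roi_labels = np.zeros(shape, dtype=np.int32)
    rx, ry = 0.14 * shape[0], 0.14 * shape[1]
    rz = max(0.8, 0.18 * shape[2])
    offsets = {
        "striatum": np.array([0.22 * shape[0], 0.0, 0.0]),
        "thalamus": np.array([-0.22 * shape[0], 0.0, 0.0]),
        "acc": np.array([0.0, 0.26 * shape[1], 0.0]),
    }
    for name in ROI_NAMES:
        c = center + offsets[name] + rng.uniform(-0.5, 0.5, size=3)
        d = np.sqrt(((idx[0] - c[0]) / rx) ** 2 + ((idx[1] - c[1]) / ry) ** 2
                    + ((idx[2] - c[2]) / rz) ** 2)
        blob = d <= 1.0
        if not blob.any():
            raise ValueError(f"shape {shape} too small to place ROI {name!r}; "
                             "minimum (16, 16, 4)")
        roi_labels[blob] = ROI_CODES[name]
        gm_pv[blob], wm_pv[blob], csf_pv[blob] = 1.0, 0.0, 0.0

    total = gm_pv + wm_pv + csf_pv
    over = total > 1.0
    if over.any():  # guard: renormalize any accumulation above the simplex
        gm_pv[over] /= total[over]
        wm_pv[over] /= total[over]
        csf_pv[over] /= total[over]

    true_cbf = cbf_gm * gm_pv + cbf_wm * wm_pv
    m0 = 100.0 * gm_pv + 80.0 * wm_pv + 120.0 * csf_pv
    return Phantom(shape=shape, spacing_mm=tuple(spacing_mm), gm_pv=gm_pv,
                   wm_pv=wm_pv, csf_pv=csf_pv, true_cbf=true_cbf, m0=m0,
                   roi_labels=roi_labels)


def forward_delta_m(phantom: Phantom, params: QuantParams,
                    slice_axis: int = 2) -> np.ndarray:
    """Exact forward of the single-compartment model.

    ΔM(v) = CBF(v) * 2 α T1 M0(v) (1 - e^{-τ/T1}) e^{-PLD(v)/T1} / (6000 λ)
    with the per-slice post-labeling delay PLD(v) = pld_s + z(v)*slice_dt_s.
    The quantification step inverts this identically.
    """
    return phantom.true_cbf * _kinetic_factor(phantom.m0, params, slice_axis)


def default_quant_params(n_slices: int | None = None,
                         tr_s: float = DEFAULT_TR_S) -> QuantParams:
    """Protocol defaults; slice_dt_s = (TR - τ - PLD) / n_slices when known."""
    slice_dt = 0.0
    if n_slices:
        slice_dt = (tr_s - DEFAULT_TAU_S - DEFAULT_PLD_S) / n_slices
    return QuantParams(pld_s=DEFAULT_PLD_S, tau_s=DEFAULT_TAU_S, slice_dt_s=slice_dt)


def simulate_asl_series(phantom: Phantom, params: QuantParams,
                        motion: MotionSpec | None = None,
                        label_order: str = "control_first",
                        slice_axis: int = 2):
    """Simulate an interleaved pCASL series from the phantom.

    Control volumes are M0 plus noise; label volumes are M0 - ΔM plus
    noise; each dynamic's underlying volumes are rigidly resampled under
    its motion parameters before noise is added; outlier dynamics
    receive the bright-slab artifact on their control volume.  Returns
    (AslTimeSeries, sidecar) where the sidecar carries the ground truth
    (motion, outlier indices, true ROI means).
    """
    motion = motion or MotionSpec()
    n = motion.n_dynamics
    rng = np.random.default_rng(motion.seed)
    dm = forward_delta_m(phantom, params, slice_axis)
    shape = phantom.shape
    data = np.empty(shape + (2 * n,), dtype=np.float64)

    zeros = np.zeros((n, 3))
    trans = motion.translations_mm if motion.translations_mm is not None else zeros
    rots = motion.rotations_rad if motion.rotations_rad is not None else zeros

    nz = shape[slice_axis]
    slab_of = {}
    for k in sorted(motion.outlier_timepoints):
        n_slices = int(rng.integers(2, max(3, nz // 2) + 1))
        z0 = int(rng.integers(0, nz - n_slices + 1))
        slab_of[k] = (z0, z0 + n_slices)

    for k in range(n):
        tr = RigidTransform(trans[k], rots[k])
        control = resample_rigid(phantom.m0, tr, phantom.spacing_mm)
        label = resample_rigid(phantom.m0 - dm, tr, phantom.spacing_mm)
        if motion.noise_sd > 0:
            control = control + rng.normal(0.0, motion.noise_sd, size=shape)
            label = label + rng.normal(0.0, motion.noise_sd, size=shape)
        if k in slab_of:
            z0, z1 = slab_of[k]
            sl = [slice(None)] * 3
            sl[slice_axis] = slice(z0, z1)
            control[tuple(sl)] += motion.outlier_amplitude * motion.noise_sd
        if label_order == "control_first":
            data[..., 2 * k], data[..., 2 * k + 1] = control, label
        else:
            data[..., 2 * k], data[..., 2 * k + 1] = label, control

    series = AslTimeSeries(data=data, tr_s=DEFAULT_TR_S, te_s=DEFAULT_TE_S,
                           pld_s=params.pld_s, tau_s=params.tau_s,
                           slice_dt_s=params.slice_dt_s, label_order=label_order,
                           spacing_mm=phantom.spacing_mm)
    sidecar = {
        "translations_mm": np.asarray(trans).tolist(),
        "rotations_rad": np.asarray(rots).tolist(),
        "outlier_timepoints": sorted(motion.outlier_timepoints),
        "noise_sd": motion.noise_sd,
        "outlier_amplitude": motion.outlier_amplitude,
        "true_roi_means": phantom.roi_true_means(),
    }
    return series, sidecar


def simulate_atlases(phantom: Phantom, n_atlases: int = 30,
                     jitter: float = 0.1, seed: int = 0) -> list[np.ndarray]:
    """Perturbed copies of the phantom ROI labels for label-fusion input.

    Each atlas flips boundary voxels (voxels with a 6-neighbor of a
    different code) at rate ``jitter`` to a randomly chosen differing
    neighbor code.  jitter=0 returns exact copies.
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    if not (0.0 <= jitter <= 0.5):
        raise ValueError(f"jitter must be in [0, 0.5], got {jitter}")
    labels = phantom.roi_labels
    rng = np.random.default_rng(seed)

    # boundary voxels and their candidate replacement codes
    boundary = []
    shape = labels.shape
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    it = np.argwhere(np.ones(shape, dtype=bool))
    for x, y, z in it:
        c = labels[x, y, z]
        cands = set()
        for dx, dy, dz in offs:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]:
                if labels[u, v, w] != c:
                    cands.add(int(labels[u, v, w]))
        if cands:
            boundary.append(((x, y, z), sorted(cands)))

    atlases = []
    for _ in range(n_atlases):
        a = labels.copy()
        if jitter > 0:
            for (pos, cands) in boundary:
                if rng.random() < jitter:
                    a[pos] = cands[rng.integers(0, len(cands))]
        atlases.append(a)
    return atlases


@dataclass
class CohortSpec:
    """Three-group pre/post-challenge cohort generator settings.

    Defaults are the study conditions: group sizes 26/29/26
    (EST/LST/STN), per-ROI baseline CBF 60 +- 10 ml/100 g/min, an EST-only
    ACC baseline deficit of -6, a challenge-induced CBF decrease of
    -3 ml/100 g/min in striatum and ACC (0 in thalamus), no
    group-by-challenge interaction, within-subject change SD 6, Table-1
    behavioral score means/SDs, and per-group probabilities of exceeding
    the drug-use cutoffs.  ``dropout_prob`` is the probability that the
    cohort contains exactly one subject missing the post scan.
    """

    group_sizes: dict = field(default_factory=lambda: {"EST": 26, "LST": 29, "STN": 26})
    rois: tuple = ROI_NAMES
    baseline_roi_means: dict = field(
        default_factory=lambda: {r: 60.0 for r in ROI_NAMES})
    baseline_roi_sds: dict = field(
        default_factory=lambda: {r: 10.0 for r in ROI_NAMES})
    group_baseline_offsets: dict = field(
        default_factory=lambda: {("EST", "acc"): -6.0})
    challenge_effects: dict = field(
        default_factory=lambda: {"striatum": -3.0, "thalamus": 0.0, "acc": -3.0})
    interaction_effects: dict = field(default_factory=dict)
    change_sds: dict = field(default_factory=lambda: {r: 6.0 for r in ROI_NAMES})
    score_means: dict = field(default_factory=lambda: {
        "EST": {"adhd_rs": 23.2, "bdi": 10.7, "bai": 8.5},
        "LST": {"adhd_rs": 21.8, "bdi": 5.3, "bai": 6.3},
        "STN": {"adhd_rs": 30.4, "bdi": 8.0, "bai": 9.4},
    })
    score_sds: dict = field(default_factory=lambda: {
        "EST": {"adhd_rs": 10.0, "bdi": 8.9, "bai": 8.7},
        "LST": {"adhd_rs": 7.6, "bdi": 4.1, "bai": 4.9},
        "STN": {"adhd_rs": 10.3, "bdi": 6.1, "bai": 7.7},
    })
    druguse_probs: dict = field(default_factory=lambda: {
        "EST": {"cannabis": 0.25, "mdma": 0.13, "cocaine": 0.00, "amphetamine": 0.00},
        "LST": {"cannabis": 0.55, "mdma": 0.24, "cocaine": 0.24, "amphetamine": 0.07},
        "STN": {"cannabis": 0.60, "mdma": 0.31, "cocaine": 0.19, "amphetamine": 0.08},
    })
    age_means: dict = field(default_factory=lambda: {"EST": 26.0, "LST": 28.5, "STN": 29.0})
    age_sds: dict = field(default_factory=lambda: {"EST": 2.8, "LST": 4.9, "STN": 4.7})
    dropout_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if any(sd <= 0 for sd in self.baseline_roi_sds.values()):
            raise ValueError("baseline SDs must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        for g, probs in self.druguse_probs.items():
            if any(not (0.0 <= p <= 1.0) for p in probs.values()):
                raise ValueError(f"drug-use probabilities for {g} must be in [0, 1]")


def null_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec with all group, challenge and interaction effects zero."""
    return CohortSpec(group_baseline_offsets={},
                      challenge_effects={r: 0.0 for r in ROI_NAMES},
                      interaction_effects={}, seed=seed)


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw one cohort table from the generative model.

    Per subject: pre-challenge ROI CBF ~ Normal(baseline + group offset,
    baseline SD); post = pre + challenge effect + group interaction +
    Normal(0, change SD); behavioral scores ~ Normal(group mean, SD)
    censored at 0; drug-use booleans ~ Bernoulli(group probability).
    With probability ``dropout_prob`` one random subject's post-scan
    values are set missing.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for g, n_g in spec.group_sizes.items():
        for _ in range(n_g):
            sid += 1
            row = {"subject_id": f"sub-{sid:03d}", "group": g}
            row["age"] = float(np.clip(rng.normal(spec.age_means[g], spec.age_sds[g]),
                                       23.0, 40.0))
            for sc in ("adhd_rs", "bdi", "bai"):
                row[sc] = float(max(0.0, rng.normal(spec.score_means[g][sc],
                                                    spec.score_sds[g][sc])))
            for drug, p in spec.druguse_probs[g].items():
                row[f"{drug}_user"] = bool(rng.random() < p)
            if g == "EST":
                row["age_first_treatment"] = float(np.clip(rng.normal(9.5, 3.0), 4.0, 15.9))
                row["treatment_duration_months"] = float(max(4.0, rng.normal(94.9, 56.0)))
                row["time_since_last_months"] = float(max(0.0, rng.normal(84.0, 57.0)))
            elif g == "LST":
                row["age_first_treatment"] = float(max(23.0, rng.normal(26.0, 4.5)))
                row["treatment_duration_months"] = float(max(4.0, rng.normal(11.8, 8.0)))
                row["time_since_last_months"] = float(max(0.0, rng.normal(0.8, 1.3)))
            else:
                row["age_first_treatment"] = np.nan
                row["treatment_duration_months"] = np.nan
                row["time_since_last_months"] = np.nan
            for roi in spec.rois:
                mu = spec.baseline_roi_means[roi] \
                    + spec.group_baseline_offsets.get((g, roi), 0.0)
                pre = rng.normal(mu, spec.baseline_roi_sds[roi])
                post = (pre + spec.challenge_effects.get(roi, 0.0)
                        + spec.interaction_effects.get((g, roi), 0.0)
                        + rng.normal(0.0, spec.change_sds[roi]))
                row[f"cbf_pre_{roi}"] = float(pre)
                row[f"cbf_post_{roi}"] = float(post)
            rows.append(row)
    df = pd.DataFrame(rows)
    if spec.dropout_prob > 0 and rng.random() < spec.dropout_prob:
        drop = int(rng.integers(0, len(df)))
        for roi in spec.rois:
            df.loc[drop, f"cbf_post_{roi}"] = np.nan
    front = ["subject_id", "group", "age", "adhd_rs", "bdi", "bai",
             "cannabis_user", "mdma_user", "cocaine_user", "amphetamine_user",
             "age_first_treatment", "treatment_duration_months",
             "time_since_last_months"]
    cbf_cols = [f"cbf_pre_{r}" for r in spec.rois] + [f"cbf_post_{r}" for r in spec.rois]
    return df[front + cbf_cols]
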