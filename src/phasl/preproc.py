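"""pCASL preprocessing: pair splitting, control-label subtraction,
SSD-based outlier rejection, rigid motion estimation and correction,
framewise displacement, and the perfusion-weighted image.

The outlier statistic operates on the pairwise sum of squared
differences (SSD) between M_diff images: SSD(i, j) = sum over voxels of
(M_diff,i - M_diff,j)^2.  A timepoint is rejected when a strict majority
of its SSD values to all other timepoints exceeds median + 3*SD, where
the median is taken over all pairwise SSD values and the SD is a robust
estimate computed from only the values below that median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class RigidTransform:
    """6-parameter rigid transform (pull-back convention).

    Resampling a volume with this transform samples the input at
    R (x - c) + t + c for world coordinate x and rotation center c, so
    composing two pure translations adds their parameters.  The identity
    is all zeros.
    """

    translations_mm: np.ndarray
    rotations_rad: np.ndarray
    center_mm: np.ndarray | None = None

    def __post_init__(self):
        self.translations_mm = np.asarray(self.translations_mm, dtype=np.float64)
        self.rotations_rad = np.asarray(self.rotations_rad, dtype=np.float64)
        if self.translations_mm.shape != (3,) or self.rotations_rad.shape != (3,):
            raise ValueError("translations and rotations must be 3-vectors")
        if not (np.isfinite(self.translations_mm).all()
                and np.isfinite(self.rotations_rad).all()):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return not (self.translations_mm.any() or self.rotations_rad.any())

    def as_params(self) -> np.ndarray:
        return np.concatenate([self.translations_mm, self.rotations_rad])


@dataclass
class AslTimeSeries:
    """4D pCASL acquisition with its timing metadata.

    ``data`` is (x, y, z, t) in acquisition order with control and label
    volumes interleaved according to ``label_order``; timings in seconds.
    """

    data: np.ndarray
    tr_s: float = 4.0
    te_s: float = 0.014
    pld_s: float = 1.650
    tau_s: float = 1.525
    slice_dt_s: float = 0.0
    label_order: str = "control_first"
    spacing_mm: tuple = (3.0, 3.0, 7.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] % 2 != 0:
            raise ValueError(f"number of timepoints must be even, got {self.data.shape[3]}")
        if self.label_order not in ("control_first", "label_first"):
            raise ValueError(f"unknown label_order {self.label_order!r}")
        if min(self.tr_s, self.te_s, self.pld_s, self.tau_s) <= 0:
            raise ValueError("all timings must be positive")
        if self.tr_s <= self.pld_s + self.tau_s:
            raise ValueError("tr_s must exceed pld_s + tau_s")

    @property
    def n_pairs(self) -> int:
        return self.data.shape[3] // 2


@dataclass
class DiffSeries:
    """Control-label subtraction series with its outlier bookkeeping."""

    mdiff: np.ndarray
    ssd_matrix: np.ndarray | None = None
    keep_mask: np.ndarray | None = None


def split_pairs(series: AslTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Split the interleaved series into (controls, labels), each (x,y,z,t/2).

    Pairing is (2k, 2k+1); ``label_order`` designates which member of
    each pair is the control.
    """
    t = series.data.shape[3]
    if t % 2 != 0:
        raise ValueError("odd number of timepoints")
    even = series.data[..., 0::2]
    odd = series.data[..., 1::2]
    if series.label_order == "control_first":
        return even, odd
    return odd, even


def control_label_diff(series: AslTimeSeries) -> np.ndarray:
    """M_diff images: control minus label, one volume per pair."""
    controls, labels = split_pairs(series)
    return controls - labels


def compute_ssd_matrix(mdiff: np.ndarray) -> np.ndarray:
    """Pairwise sum of squared voxelwise differences between M_diff images.

    Returns the symmetric (n_pairs, n_pairs) matrix with zero diagonal.
    Computed by direct summation (no norm expansion) so identical images
    give exactly zero.
    """
    mdiff = np.asarray(mdiff, dtype=np.float64)
    if mdiff.ndim != 4:
        raise ValueError("mdiff must be 4D (x, y, z, n_pairs)")
    n = mdiff.shape[3]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    flat = mdiff.reshape(-1, n).T  # (n, V)
    ssd = np.zeros((n, n))
    for i in range(n - 1):
        d = flat[i + 1:] - flat[i]
        ssd[i, i + 1:] = np.einsum("ij,ij->i", d, d)
    ssd += ssd.T
    return ssd


def reject_outliers(ssd_matrix: np.ndarray, n_sd: float = 3.0,
                    scope: str = "global") -> np.ndarray:
    """Flag outlier timepoints from the pairwise SSD matrix.

    A common threshold median + ``n_sd`` * SD is formed, the SD being a
    robust estimate from only the SSD values strictly below the median
    (population form, denominator n); a timepoint is an outlier iff a
    strict majority of its n-1 SSD values exceeds the threshold.
    Returns ``keep_mask`` (True = retained).

    ``scope`` selects where the median/SD are computed: ``"global"``
    (default) pools all off-diagonal SSD values; ``"per_timepoint"``
    uses each timepoint's own n-1 values (kept for sensitivity analysis;
    note that at most half of a row's values can exceed the row's own
    median, so this variant flags essentially nothing).

    Degenerate cases (below-median subset smaller than 2, or zero SD)
    collapse the threshold to the median itself, and the strict ">"
    comparison then leaves all-identical series unflagged.
    """
    ssd = np.asarray(ssd_matrix, dtype=np.float64)
    n = ssd.shape[0]
    if ssd.ndim != 2 or ssd.shape[1] != n:
        raise ValueError("ssd_matrix must be square")
    if n < 3:
        raise ValueError("need at least 3 pairs for outlier rejection")
    if (ssd < 0).any() or np.abs(np.diag(ssd)).max() > 0:
        raise ValueError("ssd_matrix must be non-negative with zero diagonal")
    off = ~np.eye(n, dtype=bool)

    def _threshold(values: np.ndarray) -> float:
        med = float(np.median(values))
        below = values[values < med]
        sd = float(below.std()) if below.size >= 2 else 0.0
        return med + n_sd * sd

    keep = np.ones(n, dtype=bool)
    if scope == "global":
        thr = _threshold(ssd[np.triu_indices(n, k=1)])
        for i in range(n):
            frac = float(np.mean(ssd[i, off[i]] > thr))
            keep[i] = not (frac > 0.5)
    elif scope == "per_timepoint":
        for i in range(n):
            row = ssd[i, off[i]]
            frac = float(np.mean(row > _threshold(row)))
            keep[i] = not (frac > 0.5)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return keep


def _rotation_matrix(rotations_rad: np.ndarray) -> np.ndarray:
    rx, ry, rz = rotations_rad
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def resample_rigid(vol: np.ndarray, transform: RigidTransform,
                   spacing_mm=(3.0, 3.0, 7.0), order: int = 1) -> np.ndarray:
    """Trilinear pull-back resampling of ``vol`` under a rigid transform.

    output(v) = vol at index coordinates S^-1 (R (S v - S c) + t) + c
    where S is the voxel spacing and c the grid-center index.  Exact
    identity transforms short-circuit to a copy so that noiseless
    pipelines stay bit-exact.
    """
    if transform.is_identity:
        return np.array(vol, dtype=np.float64, copy=True)
    vol = np.asarray(vol, dtype=np.float64)
    s = np.asarray(spacing_mm, dtype=np.float64)
    R = _rotation_matrix(transform.rotations_rad)
    center = (np.array(vol.shape, dtype=np.float64) - 1.0) / 2.0
    if transform.center_mm is not None:
        center = np.asarray(transform.center_mm, dtype=np.float64) / s
    # index-space matrix and offset for scipy's pull-back convention
    M = (R * s[np.newaxis, :]) / s[:, np.newaxis]
    offset = (transform.translations_mm / s) + center - M @ center
    return ndimage.affine_transform(vol, M, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def _cost_ssd(vol, ref):
    d = vol - ref
    return float(np.dot(d.ravel(), d.ravel()))


class _PcaCost:
    """Groupwise cost: residual eigenvalue mass of the timepoint Gram matrix.

    The stack is centered voxelwise; the cost is the sum of all
    eigenvalues minus the largest, so a stack that is well aligned (one
    dominant mode) scores low.
    """

    def __init__(self, stack: list[np.ndarray]):
        self.stack = [v.ravel() for v in stack]

    def cost(self, index: int, candidate: np.ndarray) -> float:
        mats = list(self.stack)
        mats[index] = candidate.ravel()
        X = np.stack(mats)
        X = X - X.mean(axis=0, keepdims=True)
        gram = X @ X.T
        eig = np.linalg.eigvalsh(gram)
        return float(eig.sum() - eig.max())


def _coordinate_descent(eval_cost, init_params, max_evals=400, tol=1e-30):
    """Derivative-free local search over the 6 rigid parameters.

    Steps start at 1 mm / 0.02 rad and halve whenever a full sweep
    yields no improvement; terminates below 0.01 mm / 0.0005 rad or at
    the evaluation cap.  Returns (params, cost, converged).
    """
    params = np.asarray(init_params, dtype=np.float64).copy()
    steps = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
    min_steps = np.array([0.01, 0.01, 0.01, 0.0005, 0.0005, 0.0005])
    best = eval_cost(params)
    evals = 1
    while evals < max_evals:
        if best <= tol:
            return params, best, True
        improved = False
        for p in range(6):
            if steps[p] < min_steps[p]:
                continue
            for sign in (1.0, -1.0):
                trial = params.copy()
                trial[p] += sign * steps[p]
                c = eval_cost(trial)
                evals += 1
                if c < best:
                    best, params = c, trial
                    improved = True
                    break
                if evals >= max_evals:
                    break
            if evals >= max_evals:
                break
        if not improved:
            if (steps < min_steps).all():
                return params, best, True
            steps /= 2.0
    return params, best, (steps < min_steps).all()


def estimate_motion(series, reference: np.ndarray | None = None,
                    spacing_mm=None, metric: str = "ssd", n_passes: int = 2,
                    max_evals: int = 400, return_qc: bool = False):
    """Rigid motion estimation, one transform per timepoint.

    The default reference is the evolving mean: transforms are estimated
    against the current mean, the mean is rebuilt from the corrected
    volumes, and the estimate is refined (``n_passes`` total).  When an
    ``AslTimeSeries`` is given, controls and labels are referenced to
    their own class means (the label volumes differ from the controls by
    the perfusion signal, which would otherwise bias the registration).
    ``metric`` is ``"ssd"`` (pairwise to the mean, default) or ``"pca"``
    (groupwise residual-eigenvalue cost).  Non-convergence is flagged in
    the QC log (``return_qc=True``), never fatal.
    """
    if isinstance(series, AslTimeSeries):
        data = series.data
        spacing_mm = series.spacing_mm if spacing_mm is None else spacing_mm
        even_is_control = series.label_order == "control_first"
        classes = np.array([0 if ((t % 2 == 0) == even_is_control) else 1
                            for t in range(data.shape[3])])
    else:
        data = np.asarray(series, dtype=np.float64)
        spacing_mm = (3.0, 3.0, 7.0) if spacing_mm is None else spacing_mm
        classes = np.zeros(data.shape[3], dtype=int)
    if data.ndim != 4 or data.shape[3] < 2:
        raise ValueError("need a 4D series with at least 2 timepoints")
    nt = data.shape[3]
    vols = [data[..., t] for t in range(nt)]
    fixed_ref = reference is not None
    if fixed_ref:
        ref_of = {c: np.asarray(reference, dtype=np.float64)
                  for c in np.unique(classes)}
    else:
        ref_of = {c: data[..., classes == c].mean(axis=3)
                  for c in np.unique(classes)}

    transforms = [RigidTransform.identity() for _ in range(nt)]
    qc = [{"converged": True, "cost": 0.0} for _ in range(nt)]
    passes = 1 if fixed_ref else max(1, n_passes)
    for p in range(passes):
        if metric == "pca":
            corrected = [resample_rigid(vols[t], transforms[t], spacing_mm)
                         for t in range(nt)]
            group = _PcaCost(corrected)
        for t in range(nt):
            ref = ref_of[classes[t]]
            if metric == "ssd":
                def eval_cost(params, _t=t, _ref=ref):
                    tr = RigidTransform(params[:3], params[3:])
                    return _cost_ssd(resample_rigid(vols[_t], tr, spacing_mm), _ref)
            elif metric == "pca":
                def eval_cost(params, _t=t):
                    tr = RigidTransform(params[:3], params[3:])
                    return group.cost(_t, resample_rigid(vols[_t], tr, spacing_mm))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            # registration is numerically converged once the residual is at
            # rounding level relative to the reference energy
            tol = 1e-24 * float((ref.ravel() ** 2).sum())
            params, cost, converged = _coordinate_descent(
                eval_cost, transforms[t].as_params(), max_evals=max_evals,
                tol=tol)
            transforms[t] = RigidTransform(params[:3], params[3:])
            qc[t] = {"converged": bool(converged), "cost": float(cost)}
        if not fixed_ref and p + 1 < passes:
            for c in ref_of:
                sel = np.flatnonzero(classes == c)
                ref_of[c] = np.mean([resample_rigid(vols[t], transforms[t],
                                                    spacing_mm) for t in sel],
                                    axis=0)
    if return_qc:
        return transforms, qc
    return transforms


def framewise_displacement(transforms, head_radius_mm: float = 50.0):
    """Power-style framewise displacement from consecutive rigid parameters.

    FD_t = sum |Delta translations| + head_radius * sum |Delta rotations|,
    with FD of the first timepoint defined as 0.  Returns (fd, mean_fd).
    """
    if len(transforms) < 2:
        raise ValueError("need at least 2 transforms")
    params = np.stack([tr.as_params() for tr in transforms])
    d = np.abs(np.diff(params, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1)
                         + head_radius_mm * d[:, 3:].sum(axis=1)])
    return fd, float(fd.mean())


def perfusion_weighted_image(mdiff: np.ndarray, keep_mask: np.ndarray,
                             transforms=None, spacing_mm=(3.0, 3.0, 7.0)) -> np.ndarray:
    """Average the retained, motion-compensated M_diff images into ΔM.

    ``transforms`` holds one rigid transform per pair (None = no
    correction); rejected pairs are excluded before averaging.
    """
    mdiff = np.asarray(mdiff, dtype=np.float64)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    n = mdiff.shape[3]
    if keep_mask.shape != (n,):
        raise ValueError("keep_mask length must equal the number of pairs")
    if not keep_mask.any():
        raise ValueError("all timepoints rejected")
    if transforms is not None and len(transforms) != n:
        raise ValueError("need one transform per pair")
    kept = np.flatnonzero(keep_mask)
    vols = []
    for i in kept:
        v = mdiff[..., i]
        if transforms is not None:
            v = resample_rigid(v, transforms[i], spacing_mm)
        vols.append(v)
    return np.mean(vols, axis=0)


@dataclass
class PreprocResult:
    """Bundle of one session's preprocessing outputs."""

    delta_m: np.ndarray
    m0: np.ndarray
    diff: DiffSeries
    transforms: list = field(default_factory=list)
    fd: np.ndarray | None = None
    qc: dict = field(default_factory=dict)


def preprocess(series: AslTimeSeries, estimate_motion_flag: bool = True,
               motion_kwargs: dict | None = None) -> PreprocResult:
    """Full session preprocessing in the canonical order.

    Motion is estimated first (for QC and later correction), outlier
    rejection runs on M_diff images computed from uncorrected volumes,
    then the retained pairs are motion-compensated and averaged into ΔM.
    M0 is the mean of the (uncorrected) control volumes.
    """
    from .quant import compute_m0

    controls, _ = split_pairs(series)
    mdiff = control_label_diff(series)
    ssd = compute_ssd_matrix(mdiff)
    keep = reject_outliers(ssd)
    pair_tr = None
    fd = None
    mean_fd = 0.0
    transforms = []
    if estimate_motion_flag:
        transforms = estimate_motion(series, **(motion_kwargs or {}))
        fd, mean_fd = framewise_displacement(transforms)
        # one transform per pair: the control timepoint's estimate
        ctrl_idx = range(0, series.data.shape[3], 2) \
            if series.label_order == "control_first" \
            else range(1, series.data.shape[3], 2)
        pair_tr = [transforms[i] for i in ctrl_idx]
    delta_m = perfusion_weighted_image(mdiff, keep, pair_tr, series.spacing_mm)
    m0 = compute_m0(controls)
    qc = {"n_rejected": int((~keep).sum()), "n_pairs": int(series.n_pairs),
          "mean_fd": float(mean_fd)}
    return PreprocResult(delta_m=delta_m, m0=m0,
                         diff=DiffSeries(mdiff=mdiff, ssd_matrix=ssd, keep_mask=keep),
                         transforms=transforms, fd=fd, qc=qc)
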