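"""Seeded Monte-Carlo experiments that validate the pipeline.

Each function regenerates its inputs from the package's own forward
models and measures a recovery, error-rate or replication property of
the analysis chain: quantification round-trip error, outlier-rejection
operating characteristics, ANOVA type-I error and power, cohort moment
recovery, partial-volume-correction exactness, and replication of the
study-level significance pattern.  All randomness flows from a single
integer seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .atlas import majority_vote, roi_means
from .preproc import (compute_ssd_matrix, control_label_diff,
                      perfusion_weighted_image, preprocess, reject_outliers,
                      split_pairs)
from .quant import QuantParams, compute_m0, pv_fit, quantify_cbf
from .stats import mixed_anova, oneway_anova
from .synthetic import (CohortSpec, MotionSpec, ROI_NAMES, default_quant_params,
                        forward_delta_m, make_phantom, null_cohort_spec,
                        simulate_asl_series, simulate_cohort)

ALPHA = 0.05


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


def roundtrip_error(seed: int = 0, n_pairs: int = 75) -> float:
    """Max relative CBF error on GM voxels for a noiseless, motionless
    simulated series pushed through the full preprocessing +
    quantification chain (including motion estimation, which must
    return exact identities here)."""
    phantom = make_phantom(seed=seed)
    params = default_quant_params(n_slices=phantom.shape[2])
    motion = MotionSpec(n_dynamics=n_pairs, noise_sd=0.0, seed=seed)
    series, _ = simulate_asl_series(phantom, params, motion)
    res = preprocess(series, estimate_motion_flag=True)
    cbf = quantify_cbf(res.delta_m, res.m0, params, gm_pv=phantom.gm_pv)
    sel = cbf.gm_mask & (phantom.true_cbf > 0)
    rel = np.abs(cbf.cbf[sel] - phantom.true_cbf[sel]) / phantom.true_cbf[sel]
    return float(rel.max())


def outlier_performance(n_runs: int = 50, seed: int = 0,
                        amplitude: float = 20.0, n_pairs: int = 75):
    """Sensitivity and specificity of the SSD outlier rule.

    Each run injects 1-10 artifact dynamics (bright slab at ``amplitude``
    times the noise SD) into a 75-pair series and compares the rejected
    set against the injected set.  Returns a dict with pooled
    sensitivity and specificity in percent.
    """
    phantom = make_phantom(seed=seed)
    params = default_quant_params(n_slices=phantom.shape[2])
    seeds = _child_seeds(seed, n_runs)
    tp = fp = fn = tn = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        k = int(rng.integers(1, 11))
        outliers = frozenset(int(i) for i in
                             rng.choice(n_pairs, size=k, replace=False))
        motion = MotionSpec(n_dynamics=n_pairs, outlier_timepoints=outliers,
                            outlier_amplitude=amplitude, noise_sd=1.0, seed=s)
        series, _ = simulate_asl_series(phantom, params, motion)
        ssd = compute_ssd_matrix(control_label_diff(series))
        keep = reject_outliers(ssd)
        flagged = set(np.flatnonzero(~keep))
        tp += len(flagged & outliers)
        fp += len(flagged - outliers)
        fn += len(outliers - flagged)
        tn += n_pairs - len(flagged | outliers)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return {"sensitivity_pct": sens, "specificity_pct": spec,
            "n_runs": n_runs}


def anova_type1_rates(n_reps: int = 2000, seed: int = 0, roi: str = "striatum"):
    """Empirical rejection rates of the mixed ANOVA under the null cohort
    (no group, challenge or interaction effects; n = 26/29/26)."""
    seeds = _child_seeds(seed, n_reps)
    rej = {"group": 0, "challenge": 0, "interaction": 0}
    for s in seeds:
        table = simulate_cohort(null_cohort_spec(seed=s))
        res = mixed_anova(table, roi)
        for e in rej:
            rej[e] += int(res[e].p < ALPHA)
    return {e: rej[e] / n_reps for e in rej}


def baseline_power(n_reps: int = 1000, seed: int = 0, roi: str = "acc"):
    """Empirical vs analytic power of the baseline one-way ANOVA under
    the default cohort (EST ACC deficit -6, SD 10, n 26/29/26).

    The analytic value is the noncentral-F power for the same
    configuration; returns a dict with both and the replicate count.
    """
    spec = CohortSpec()
    n_g = np.array(list(spec.group_sizes.values()), dtype=float)
    mu = np.array([spec.baseline_roi_means[roi]
                   + spec.group_baseline_offsets.get((g, roi), 0.0)
                   for g in spec.group_sizes])
    sd = spec.baseline_roi_sds[roi]
    grand = (n_g * mu).sum() / n_g.sum()
    lam = float((n_g * (mu - grand) ** 2).sum() / sd ** 2)
    df1, df2 = len(n_g) - 1, int(n_g.sum()) - len(n_g)
    crit = sps.f.isf(ALPHA, df1, df2)
    analytic = float(sps.ncf.sf(crit, df1, df2, lam))

    hits = 0
    for s in _child_seeds(seed, n_reps):
        spec_s = CohortSpec(seed=s)
        table = simulate_cohort(spec_s)
        res = oneway_anova(table[f"cbf_pre_{roi}"].to_numpy(),
                           table["group"].to_numpy())
        hits += int(res["group"].p < ALPHA)
    return {"empirical": hits / n_reps, "analytic": analytic,
            "noncentrality": lam, "n_reps": n_reps}


def cohort_moment_recovery(n_total: int = 10000, seed: int = 0):
    """Recovery of the generator's baseline ROI means at large n.

    Scales the default group sizes to about ``n_total`` subjects,
    simulates one cohort, and returns the maximum absolute z-score
    (|empirical - specified| / SE) over group x ROI baseline CBF means.
    """
    base = CohortSpec()
    factor = max(1, round(n_total / sum(base.group_sizes.values())))
    spec = CohortSpec(group_sizes={g: n * factor for g, n in base.group_sizes.items()},
                      seed=seed, dropout_prob=0.0)
    table = simulate_cohort(spec)
    worst = 0.0
    for g in spec.group_sizes:
        sub = table[table["group"] == g]
        for roi in ROI_NAMES:
            target = spec.baseline_roi_means[roi] \
                + spec.group_baseline_offsets.get((g, roi), 0.0)
            se = spec.baseline_roi_sds[roi] / np.sqrt(len(sub))
            z = abs(sub[f"cbf_pre_{roi}"].mean() - target) / se
            worst = max(worst, float(z))
    return {"max_abs_z": worst, "n_subjects": int(len(table))}


def pattern_replication(n_reps: int = 100, seed: int = 0):
    """Replication rate of the study-level significance pattern.

    Pattern (all at alpha = 0.05): challenge effect significant in
    striatum and ACC but not thalamus; baseline group effect significant
    in ACC only; no group x challenge interaction in any ROI.  Returns
    the joint replication rate and per-component rates.
    """
    comps = ["challenge_striatum_sig", "challenge_acc_sig",
             "challenge_thalamus_ns", "baseline_acc_sig",
             "baseline_striatum_ns", "baseline_thalamus_ns",
             "interaction_all_ns"]
    counts = {c: 0 for c in comps}
    joint = 0
    for s in _child_seeds(seed, n_reps):
        table = simulate_cohort(CohortSpec(seed=s))
        sig = {}
        inter_ns = True
        for roi in ROI_NAMES:
            mx = mixed_anova(table, roi)
            base = oneway_anova(table[f"cbf_pre_{roi}"].to_numpy(),
                                table["group"].to_numpy())
            sig[f"challenge_{roi}"] = mx["challenge"].p < ALPHA
            sig[f"baseline_{roi}"] = base["group"].p < ALPHA
            inter_ns &= not (mx["interaction"].p < ALPHA)
        flags = {
            "challenge_striatum_sig": sig["challenge_striatum"],
            "challenge_acc_sig": sig["challenge_acc"],
            "challenge_thalamus_ns": not sig["challenge_thalamus"],
            "baseline_acc_sig": sig["baseline_acc"],
            "baseline_striatum_ns": not sig["baseline_striatum"],
            "baseline_thalamus_ns": not sig["baseline_thalamus"],
            "interaction_all_ns": inter_ns,
        }
        for c in comps:
            counts[c] += int(flags[c])
        joint += int(all(flags.values()))
    out = {"joint_rate": joint / n_reps, "n_reps": n_reps}
    out.update({c: counts[c] / n_reps for c in comps})
    return out


def pvc_exactness(seed: int = 0, shape=(24, 24, 4),
                  m_gm: float = 60.0, m_wm: float = 20.0) -> float:
    """Max absolute recovery error of the PVC local regression on a
    two-tissue phantom with spatially constant magnetizations and
    smoothly varying fractions (the local normal equations are exact
    here, so the error should be at numerical precision)."""
    rng = np.random.default_rng(seed)
    idx = np.indices(shape, dtype=np.float64)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    gm = 0.5 + 0.35 * np.sin(2 * np.pi * idx[0] / shape[0] + phase[0]) \
        * np.cos(2 * np.pi * idx[1] / shape[1] + phase[1])
    gm = np.clip(gm, 0.05, 0.95)
    wm = 1.0 - gm
    y = gm * m_gm + wm * m_wm
    params = QuantParams(pv_kernel=(5, 5, 1))
    got_gm, got_wm, qc = pv_fit(y, gm, wm, params)
    ok = np.isfinite(got_gm) & np.isfinite(got_wm)
    err = max(float(np.abs(got_gm[ok] - m_gm).max()),
              float(np.abs(got_wm[ok] - m_wm).max()))
    return err


def end_to_end_roi_recovery(seed: int = 0, n_pairs: int = 20):
    """Noiseless end-to-end run (simulate -> preprocess -> PVC ->
    quantify -> atlas fusion -> ROI means) returning the max relative
    ROI-mean error against the phantom ground truth."""
    phantom = make_phantom(seed=seed)
    params = default_quant_params(n_slices=phantom.shape[2])
    series, sidecar = simulate_asl_series(
        phantom, params, MotionSpec(n_dynamics=n_pairs, noise_sd=0.0, seed=seed))
    res = preprocess(series, estimate_motion_flag=False)
    from .quant import pv_correct

    gm_dm, gm_m0, _ = pv_correct(res.delta_m, res.m0, phantom.gm_pv,
                                 phantom.wm_pv, params)
    cbf = quantify_cbf(gm_dm, gm_m0, params, gm_pv=phantom.gm_pv)
    from .synthetic import simulate_atlases

    fused = majority_vote(simulate_atlases(phantom, n_atlases=5, jitter=0.0,
                                           seed=seed))
    table = roi_means(cbf, fused)
    worst = 0.0
    for _, row in table.iterrows():
        truth = sidecar["true_roi_means"][row["roi"]]
        worst = max(worst, abs(row["mean_cbf"] - truth) / truth)
    return {"max_rel_error": float(worst)}
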