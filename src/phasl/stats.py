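"""Group-level statistics for the pre/post-challenge cohort.

The battery mirrors a classical pharmacological-challenge analysis: a
split-plot (mixed) ANOVA per ROI with group as the between-subjects
factor and challenge (pre/post) as the within-subjects factor, a
baseline one-way ANOVA with optional covariate adjustment, Sidak
post-hoc pairwise contrasts on the pooled error term, Pearson
correlations, and Pearson chi-square tests on dichotomized recreational
drug use.

The mixed ANOVA uses the classical weighted (cell-frequency) sums of
squares.  Because every complete-case subject contributes both
within-subject levels, cell counts are proportional, the strata are
orthogonal, every SS is non-negative, and the stratum SS add up exactly
to the total SS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_ORDER = ("EST", "LST", "STN")


@dataclass
class Effect:
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class Contrast:
    pair: tuple
    diff: float
    t: float
    p_unadjusted: float
    p_sidak: float


@dataclass
class AnovaResult:
    """Effect table plus Sidak-adjusted pairwise group contrasts."""

    effects: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=list)
    n_per_group: dict = field(default_factory=dict)
    ss_total: float = 0.0

    def __getitem__(self, key: str) -> Effect:
        return self.effects[key]


def sidak_adjust(p, m: int):
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)
    return float(adj) if adj.ndim == 0 else adj


def _complete_cases(table: pd.DataFrame, roi: str):
    pre = table[f"cbf_pre_{roi}"]
    post = table[f"cbf_post_{roi}"]
    ok = pre.notna() & post.notna() & table["group"].notna()
    sub = table.loc[ok]
    return (sub["group"].to_numpy(), pre[ok].to_numpy(dtype=np.float64),
            post[ok].to_numpy(dtype=np.float64))


def mixed_anova(table: pd.DataFrame, roi: str) -> AnovaResult:
    """Split-plot ANOVA of ROI CBF: group (between) x challenge (within).

    Complete cases only (subjects missing either scan are dropped, as in
    a per-analysis complete-case design).  Effects reported: ``group``
    (error: subjects within groups), ``challenge`` and ``interaction``
    (error: challenge x subjects within groups), plus the two error
    strata under ``subjects_within`` and ``residual``.
    """
    groups, pre, post = _complete_cases(table, roi)
    return mixed_anova_arrays(pre, post, groups)


def mixed_anova_arrays(pre: np.ndarray, post: np.ndarray,
                       groups: np.ndarray) -> AnovaResult:
    """Array-level core of :func:`mixed_anova` (q = 2 within levels)."""
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n_g = np.bincount(gidx)
    for lab, n in zip(labels, n_g):
        if n < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 complete cases")
    N = len(pre)
    q = 2
    y = np.stack([pre, post], axis=1)  # (N, 2)

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = np.array([subj_mean[gidx == g].mean() for g in range(k)])
    time_mean = y.mean(axis=0)
    cell_mean = np.stack([y[gidx == g].mean(axis=0) for g in range(k)])  # (k, 2)

    ss_total = float(((y - grand) ** 2).sum())
    ss_bsubj = q * float(((subj_mean - grand) ** 2).sum())
    ss_group = q * float((n_g * (group_mean - grand) ** 2).sum())
    ss_subj = ss_bsubj - ss_group
    ss_time = N * float(((time_mean - grand) ** 2).sum())
    ss_cells = float((n_g[:, None] * (cell_mean - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_cells - ss_subj

    df_group, df_subj = k - 1, N - k
    df_time, df_inter, df_error = q - 1, (k - 1) * (q - 1), (N - k) * (q - 1)
    ms_subj = ss_subj / df_subj
    ms_error = ss_error / df_error

    def eff(ss, df, ms_err, df_err):
        # an exactly-null effect is F = 0 even against a degenerate error
        # stratum; a positive SS with zero error variance is undefined
        if ms_err <= 0:
            if ss <= 0:
                return Effect(ss=0.0, df=df, ms=0.0, f=0.0, p=1.0)
            raise ValueError("zero-variance error stratum; ANOVA undefined")
        f = (ss / df) / ms_err
        return Effect(ss=ss, df=df, ms=ss / df, f=f,
                      p=float(sps.f.sf(f, df, df_err)))

    res = AnovaResult(
        effects={
            "group": eff(ss_group, df_group, ms_subj, df_subj),
            "challenge": eff(ss_time, df_time, ms_error, df_error),
            "interaction": eff(ss_inter, df_inter, ms_error, df_error),
            "subjects_within": Effect(ss=ss_subj, df=df_subj, ms=ms_subj,
                                      f=float("nan"), p=float("nan")),
            "residual": Effect(ss=ss_error, df=df_error, ms=ms_error,
                               f=float("nan"), p=float("nan")),
        },
        n_per_group={str(lab): int(n) for lab, n in zip(labels, n_g)},
        ss_total=ss_total,
    )

    # Sidak post-hocs on group means of the subject averages, pooled
    # between-subject error: Var(subject mean) = MS_subj / q
    pairs = list(combinations(range(k), 2)) if ms_subj > 0 else []
    m = max(1, len(pairs))
    for a, b in pairs:
        diff = float(group_mean[a] - group_mean[b])
        se = float(np.sqrt((ms_subj / q) * (1.0 / n_g[a] + 1.0 / n_g[b])))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_subj))
        res.contrasts.append(Contrast(pair=(str(labels[a]), str(labels[b])),
                                      diff=diff, t=t, p_unadjusted=p,
                                      p_sidak=float(sidak_adjust(p, m))))
    return res


def oneway_anova(values, groups, covariates=None) -> AnovaResult:
    """One-way (between-subjects) ANOVA with optional covariate adjustment.

    Without covariates this is the textbook F = MSB/MSW.  With a
    covariate matrix (n x c) the group effect is the extra-sum-of-squares
    F test of the group dummies in a linear model already containing an
    intercept and the covariates.
    """
    y = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    ok = np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != len(y):
            raise ValueError("covariates must have one row per observation")
        ok &= np.isfinite(covariates).all(axis=1)
        covariates = covariates[ok]
    y, groups = y[ok], groups[ok]
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    n_g = np.bincount(gidx)
    if k < 2 or (n_g < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    N = len(y)

    if covariates is None:
        grand = y.mean()
        gm = np.array([y[gidx == g].mean() for g in range(k)])
        ssb = float((n_g * (gm - grand) ** 2).sum())
        ssw = float(sum(((y[gidx == g] - gm[g]) ** 2).sum() for g in range(k)))
        df1, df2 = k - 1, N - k
        if ssw <= 0:
            raise ValueError("zero within-group variance; F undefined")
        msb, msw = ssb / df1, ssw / df2
        f = msb / msw
        res = AnovaResult(effects={
            "group": Effect(ss=ssb, df=df1, ms=msb, f=f,
                            p=float(sps.f.sf(f, df1, df2))),
            "residual": Effect(ss=ssw, df=df2, ms=msw, f=float("nan"),
                               p=float("nan")),
        }, n_per_group={str(lab): int(n) for lab, n in zip(labels, n_g)},
            ss_total=ssb + ssw)
        pairs = list(combinations(range(k), 2))
        for a, b in pairs:
            diff = float(gm[a] - gm[b])
            se = float(np.sqrt(msw * (1.0 / n_g[a] + 1.0 / n_g[b])))
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df2))
            res.contrasts.append(Contrast(pair=(str(labels[a]), str(labels[b])),
                                          diff=diff, t=t, p_unadjusted=p,
                                          p_sidak=float(sidak_adjust(p, len(pairs)))))
        return res

    # covariate-adjusted: extra SS of group dummies given the covariates
    X_red = np.column_stack([np.ones(N), covariates])
    dummies = np.zeros((N, k - 1))
    for g in range(1, k):
        dummies[gidx == g, g - 1] = 1.0
    X_full = np.column_stack([X_red, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular covariate design")

    import statsmodels.api as sm

    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    rss_red, rss_full = float(fit_red.ssr), float(fit_full.ssr)
    df1 = k - 1
    df2 = N - X_full.shape[1]
    if rss_full <= 0 or df2 <= 0:
        raise ValueError("degenerate adjusted model; F undefined")
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return AnovaResult(effects={
        "group": Effect(ss=rss_red - rss_full, df=df1,
                        ms=(rss_red - rss_full) / df1, f=f,
                        p=float(sps.f.sf(f, df1, df2))),
        "residual": Effect(ss=rss_full, df=df2, ms=rss_full / df2,
                           f=float("nan"), p=float("nan")),
    }, n_per_group={str(lab): int(n) for lab, n in zip(labels, n_g)},
        ss_total=rss_red)


def pearson_r(x, y):
    """Product-moment correlation with its t-based two-sided p (n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def dichotomize_drug_use(records: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize lifetime drug use into user / non-user booleans.

    Cutoffs (strict inequalities): cannabis more than once per week
    (``cannabis_per_week > 1``); MDMA, cocaine and amphetamine more than
    10 times lifetime (``<drug>_lifetime > 10``).  Subjects missing a
    drug's field get a missing value for that drug (excluded from its
    contingency table downstream).
    """
    out = pd.DataFrame(index=records.index)
    specs = [("cannabis", "cannabis_per_week", 1.0),
             ("mdma", "mdma_lifetime", 10.0),
             ("cocaine", "cocaine_lifetime", 10.0),
             ("amphetamine", "amphetamine_lifetime", 10.0)]
    for drug, col, cutoff in specs:
        if col in records.columns:
            vals = pd.to_numeric(records[col], errors="coerce")
            flags = pd.Series(vals > cutoff, dtype="boolean")
            flags[vals.isna()] = pd.NA
            out[f"{drug}_user"] = flags
        else:
            out[f"{drug}_user"] = pd.Series(pd.NA, index=records.index,
                                            dtype="boolean")
    return out


def chi_square(contingency):
    """Pearson chi-square test of independence, no continuity correction.

    ``contingency`` is a (k groups x 2) table of non-negative integer
    counts (users / non-users).  Returns (chi2, df, p).
    """
    obs = np.asarray(contingency, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[1] < 2:
        raise ValueError("contingency must be a 2D table with >= 2 columns")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def drug_use_table(table: pd.DataFrame, drug: str,
                   groups=GROUP_ORDER) -> np.ndarray:
    """(k x 2) users/non-users counts for one drug from *_user booleans."""
    col = f"{drug}_user"
    rows = []
    for g in groups:
        sub = table.loc[table["group"] == g, col].dropna()
        users = int(sub.astype(bool).sum())
        rows.append([users, int(len(sub) - users)])
    return np.asarray(rows)


def run_battery(table: pd.DataFrame, rois=("striatum", "thalamus", "acc"),
                drugs=("cannabis", "mdma", "cocaine", "amphetamine"),
                covariates: list | None = None) -> dict:
    """The full per-study analysis: mixed ANOVA and baseline ANOVA per
    ROI (optionally covariate-adjusted), correlations of the CBF
    response and mood scores with age of first exposure (treated groups
    only), and a chi-square test per drug.
    Returns a plain nested dict suitable for JSON serialization.
    """
    out = {"rois": {}, "drug_use": {}, "correlations": {}}
    for roi in rois:
        mx = mixed_anova(table, roi)
        base = oneway_anova(table[f"cbf_pre_{roi}"].to_numpy(),
                            table["group"].to_numpy())
        roi_out = {
            "mixed_anova": _anova_dict(mx),
            "baseline_anova": _anova_dict(base),
        }
        if covariates:
            cov = table[covariates].to_numpy(dtype=np.float64)
            adj = oneway_anova(table[f"cbf_pre_{roi}"].to_numpy(),
                               table["group"].to_numpy(), covariates=cov)
            roi_out["baseline_anova_adjusted"] = _anova_dict(adj)
        out["rois"][roi] = roi_out

        treated = table[table["group"].isin(["EST", "LST"])]
        delta = (treated[f"cbf_post_{roi}"] - treated[f"cbf_pre_{roi}"]).to_numpy()
        age_first = treated["age_first_treatment"].to_numpy(dtype=np.float64)
        try:
            r, p = pearson_r(age_first, delta)
            out["correlations"][f"age_first_vs_dcbf_{roi}"] = {"r": r, "p": p}
        except ValueError:
            out["correlations"][f"age_first_vs_dcbf_{roi}"] = None
    for score in ("bdi", "bai"):
        treated = table[table["group"].isin(["EST", "LST"])]
        try:
            r, p = pearson_r(treated["age_first_treatment"].to_numpy(dtype=np.float64),
                             treated[score].to_numpy(dtype=np.float64))
            out["correlations"][f"age_first_vs_{score}"] = {"r": r, "p": p}
        except ValueError:
            out["correlations"][f"age_first_vs_{score}"] = None
    for drug in drugs:
        try:
            tab = drug_use_table(table, drug)
            chi2, df, p = chi_square(tab)
            out["drug_use"][drug] = {"table": tab.tolist(), "chi2": chi2,
                                     "df": df, "p": p}
        except ValueError as e:
            out["drug_use"][drug] = {"error": str(e)}
    return out


def _anova_dict(res: AnovaResult) -> dict:
    d = {"effects": {}, "contrasts": [], "n_per_group": res.n_per_group,
         "ss_total": res.ss_total}
    for name, e in res.effects.items():
        d["effects"][name] = {"ss": e.ss, "df": e.df, "ms": e.ms,
                              "F": e.f, "p": e.p}
    for c in res.contrasts:
        d["contrasts"].append({"pair": list(c.pair), "diff": c.diff, "t": c.t,
                               "p_unadjusted": c.p_unadjusted,
                               "p_sidak": c.p_sidak})
    return d
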