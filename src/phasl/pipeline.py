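"""Study orchestration: simulate -> preprocess -> quantify -> ROI -> stats.

A study run is driven by a single validated configuration (YAML or
dict) and writes a reproducibility manifest (config hash, seed,
package version) next to its outputs.  Two modes are supported:

``cohort``
    simulate the per-subject ROI CBF table directly from the cohort
    generative model and run the statistics battery (fast; used for
    Monte-Carlo replication of the group-level analysis);
``imaging``
    simulate a pCASL series per subject and session, run the full image
    pipeline to ROI means, assemble the cohort table from those
    measurements, then run the battery (desk-scale subject counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import LabelMap, majority_vote, roi_means
from .preproc import AslTimeSeries, preprocess
from .quant import QuantParams, pv_correct, quantify_cbf
from .stats import run_battery
from .synthetic import (CohortSpec, MotionSpec, ROI_CODES, ROI_NAMES,
                        default_quant_params, make_phantom, simulate_asl_series,
                        simulate_atlases, simulate_cohort)

_ALLOWED = {
    "top": {"mode", "seed", "out_dir", "simulate", "acquisition",
            "quantification", "roi", "stats"},
    "simulate": {"shape", "spacing_mm", "n_pairs", "noise_sd", "n_atlases",
                 "jitter", "group_sizes", "cohort"},
    "acquisition": {"tr_s", "te_s", "pld_s", "tau_s", "label_order"},
    "quantification": {"alpha", "t1_s", "lambda_ml_g", "gm_threshold",
                       "pv_kernel", "pvc", "slice_dt_s"},
    "roi": {"codes"},
    "stats": {"covariates", "drugs"},
}


@dataclass
class StudyConfig:
    """Validated study configuration; unknown keys are rejected."""

    mode: str = "cohort"
    seed: int = 0
    out_dir: str = "phasl_out"
    simulate: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    quantification: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("cohort", "imaging"):
            raise ValueError(f"mode must be 'cohort' or 'imaging', got {self.mode!r}")
        for section in ("simulate", "acquisition", "quantification", "roi", "stats"):
            d = getattr(self, section)
            unknown = set(d) - _ALLOWED[section]
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        unknown = set(d) - _ALLOWED["top"]
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def quant_params(self, n_slices: int | None = None) -> QuantParams:
        q = dict(self.quantification)
        q.pop("pvc", None)
        base = default_quant_params(n_slices=n_slices)
        defaults = {"alpha": base.alpha, "t1_s": base.t1_s,
                    "lambda_ml_g": base.lambda_ml_g, "pld_s": base.pld_s,
                    "tau_s": base.tau_s, "slice_dt_s": base.slice_dt_s,
                    "gm_threshold": base.gm_threshold, "pv_kernel": base.pv_kernel}
        defaults.update(q)
        return QuantParams(**defaults)

    def canonical_hash(self) -> str:
        blob = json.dumps({
            "mode": self.mode, "seed": self.seed, "simulate": self.simulate,
            "acquisition": self.acquisition,
            "quantification": self.quantification, "roi": self.roi,
            "stats": self.stats}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class SubjectResult:
    """Per-subject imaging-pipeline outputs (one or two sessions)."""

    subject_id: str
    group: str
    sessions: dict = field(default_factory=dict)  # tag -> {roi means, qc}

    def __post_init__(self):
        tags = set(self.sessions)
        if not tags <= {"pre", "post"}:
            raise ValueError("session tags must be 'pre' and/or 'post'")
        if "post" in tags and "pre" not in tags:
            raise ValueError("post session requires a pre session")


def run_subject(series_by_session: dict, phantom, config: StudyConfig,
                label_map: LabelMap, subject_id: str = "sub-001",
                group: str = "STN") -> SubjectResult:
    """Run preprocess -> (PVC) -> quantify -> ROI means for each session.

    ``series_by_session`` maps 'pre'/'post' to AslTimeSeries.  Stage
    failures propagate annotated with the stage name and subject id.
    """
    use_pvc = bool(config.quantification.get("pvc", True))
    result = SubjectResult(subject_id=subject_id, group=group,
                           sessions={t: {} for t in series_by_session})
    for tag, series in series_by_session.items():
        try:
            params = config.quant_params(n_slices=series.data.shape[2])
            pp = preprocess(series, estimate_motion_flag=False)
            dm, m0 = pp.delta_m, pp.m0
            if use_pvc:
                dm, m0, _ = pv_correct(dm, m0, phantom.gm_pv, phantom.wm_pv, params)
            cbf = quantify_cbf(dm, m0, params, gm_pv=phantom.gm_pv)
            table = roi_means(cbf, label_map)
            result.sessions[tag] = {
                "roi_means": {row["roi"]: row["mean_cbf"]
                              for _, row in table.iterrows()},
                "qc": pp.qc,
            }
        except Exception as e:
            raise RuntimeError(
                f"subject {subject_id}, session {tag}: pipeline stage failed: {e}"
            ) from e
    return result


def _simulate_imaging_cohort(config: StudyConfig, out: Path) -> pd.DataFrame:
    """Full imaging-mode cohort: per-subject series, pipeline, ROI means."""
    sim = config.simulate
    seed = config.seed
    ss = np.random.SeedSequence(seed)
    shape = tuple(sim.get("shape", (32, 32, 8)))
    n_pairs = int(sim.get("n_pairs", 10))
    noise_sd = float(sim.get("noise_sd", 0.2))
    phantom = make_phantom(shape=shape, seed=seed)
    atlases = simulate_atlases(phantom, n_atlases=int(sim.get("n_atlases", 5)),
                               jitter=float(sim.get("jitter", 0.05)), seed=seed)
    fused = majority_vote(atlases)

    cohort_kwargs = dict(sim.get("cohort", {}))
    if "group_sizes" in sim:
        cohort_kwargs["group_sizes"] = dict(sim["group_sizes"])
    cohort_kwargs.setdefault("seed", seed)
    spec = CohortSpec(**cohort_kwargs)
    behav = simulate_cohort(spec)

    params = config.quant_params(n_slices=shape[2])
    rows = []
    child = ss.spawn(len(behav))
    for (idx, brow), cs in zip(behav.iterrows(), child):
        sub_seed = int(cs.generate_state(1)[0]) % (2 ** 31 - 1)
        series = {}
        for tag in ("pre", "post"):
            if not np.isfinite(brow[f"cbf_{tag}_{ROI_NAMES[0]}"]):
                continue
            sub_phantom = make_phantom(shape=shape, seed=seed)
            for roi, code in ROI_CODES.items():
                target = brow[f"cbf_{tag}_{roi}"]
                blob = sub_phantom.roi_labels == code
                sub_phantom.true_cbf[blob] = target
            motion = MotionSpec(n_dynamics=n_pairs, noise_sd=noise_sd,
                                seed=sub_seed + (0 if tag == "pre" else 1))
            series[tag], _ = simulate_asl_series(sub_phantom, params, motion)
        res = run_subject(series, phantom, config, fused,
                          subject_id=brow["subject_id"], group=brow["group"])
        row = brow.to_dict()
        for tag in ("pre", "post"):
            for roi in ROI_NAMES:
                row[f"cbf_{tag}_{roi}"] = (
                    res.sessions.get(tag, {}).get("roi_means", {}).get(roi, np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict:
    """Execute the configured study and write its results bundle.

    Outputs under ``config.out_dir``: ``cohort.tsv`` (per-subject
    table), ``stats/results.json`` (ANOVA tables, post-hocs,
    correlations, chi-square tests) and ``manifest.json``.
    Returns the results dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "cohort":
        kwargs = dict(config.simulate.get("cohort", {}))
        if "group_sizes" in config.simulate:
            kwargs["group_sizes"] = dict(config.simulate["group_sizes"])
        kwargs.setdefault("seed", config.seed)
        table = simulate_cohort(CohortSpec(**kwargs))
    else:
        table = _simulate_imaging_cohort(config, out)
    if table["group"].nunique() < 2:
        raise ValueError("study requires at least 2 groups")

    from .io import save_json, save_tsv

    save_tsv(out / "cohort.tsv", table)
    results = run_battery(table, rois=ROI_NAMES,
                          drugs=tuple(config.stats.get(
                              "drugs", ("cannabis", "mdma", "cocaine",
                                        "amphetamine"))),
                          covariates=config.stats.get("covariates"))
    save_json(out / "stats" / "results.json", results)
    manifest = {
        "phasl_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config_hash": config.canonical_hash(),
        "n_subjects": int(len(table)),
        "outputs": ["cohort.tsv", "stats/results.json"],
    }
    save_json(out / "manifest.json", manifest)
    return results
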