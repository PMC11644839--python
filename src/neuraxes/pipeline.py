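"""End-to-end orchestration: simulate -> behavior -> connectivity -> axes
-> expression -> spin, with every stage reading and writing declared files.

Each stage is independently invocable (see ``neuraxes.cli``) and
communicates with the others only through TSV/JSON artifacts under the
run directory.  All randomness derives from the single master seed in
the configuration; rerunning with the same config produces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuraxes import io
from neuraxes.axes import (alignment_axis, axis_expression, build_axes,
                           cross_task_correlation, AxisMap)
from neuraxes.geometry import center_cohort, ledoit_wolf_cov, seed_connectivity
from neuraxes.reward import (SigmoidPriors, define_epochs, fit_sigmoid_bayes,
                             learning_rate)
from neuraxes.spatial import spin_permutation_test
from neuraxes.synth import EPOCHS, CohortSpec, make_cohort
from neuraxes.vmr import compute_vmr_measures, filter_vmr_trials

log = logging.getLogger("neuraxes")

VMR_EPOCHS = ("rest", "baseline", "vmr_early")
REWARD_EPOCHS = ("reward_pre", "reward_learn", "reward_post")
# the two tasks were scanned in separate sessions, so covariances are
# centered per task (rest anchors both sessions)
CENTERING_SETS = {
    "vmr": ("rest", "baseline", "vmr_early"),
    "reward": ("rest", "reward_pre", "reward_learn", "reward_post"),
}


@dataclass
class PipelineConfig:
    """Everything a run needs: paths, analysis parameters, seeds."""
    out_dir: str = "neuraxes_run"
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 36
    n_rois: int = 120
    n_volumes_per_epoch: int = 100
    n_vmr_trials: int = 200
    n_reward_trials: int = 270
    # behavior analysis
    rt_floor_ms: float = 100.0
    tail_frac: float = 0.0005
    n_report_discard: int = 8
    n_report_use: int = 8
    early_window: int = 32
    # sigmoid MCMC
    mcmc_chains: int = 3
    mcmc_samples: int = 5000
    mcmc_burnin: int = 1500
    q_pre: float = 0.025
    q_learn: float = 0.05
    q_post: float = 0.975
    # ridge
    ridge_iter: int = 10
    ridge_grid: int = 25
    # spin test
    n_perm: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_subjects=self.n_subjects, n_rois=self.n_rois,
                          n_volumes_per_epoch=self.n_volumes_per_epoch,
                          n_vmr_trials=self.n_vmr_trials,
                          n_reward_trials=self.n_reward_trials,
                          seed=self.seed)


def _out(cfg) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ------------------------------------------------------------------ stages

def stage_simulate(cfg: PipelineConfig):
    """Generate a synthetic cohort and write all raw inputs."""
    out = _out(cfg)
    cohort = make_cohort(cfg.cohort_spec())
    for subj, tbl in cohort.vmr_tables.items():
        io.write_table(tbl, out / "vmr_trials" / f"{subj}.tsv")
    for subj, rs in cohort.reward_subjects.items():
        io.write_table(rs.trials, out / "reward_trials" / f"{subj}.tsv")
    for subj, eps in cohort.timecourses.items():
        for ep, tc in eps.items():
            io.write_timecourse(tc, out / "timecourses" / f"{subj}_{ep}.tsv")
    io.write_table(cohort.parcel_meta, out / "parcel_meta.tsv")
    io.write_table(pd.DataFrame({
        "parcel": cohort.parcel_meta["parcel"],
        "value": cohort.reference_map}), out / "reference_map.tsv")
    io.write_json({
        "subjects": cohort.truth.subjects.to_dict(orient="records"),
        "seed": cfg.seed,
    }, out / "ground_truth.json")
    log.info("simulated cohort: %d subjects, %d ROIs",
             cfg.n_subjects, cfg.n_rois)
    return cohort


def _subjects(cfg) -> list:
    out = _out(cfg)
    return sorted(p.stem for p in (out / "vmr_trials").glob("*.tsv"))


def stage_behavior(cfg: PipelineConfig):
    """Filter VMR trials, decompose learning, fit reward sigmoids."""
    out = _out(cfg)
    subjects = _subjects(cfg)
    tables = {s: io.read_table(out / "vmr_trials" / f"{s}.tsv")
              for s in subjects}
    # the RT/MT tail threshold is defined across all subjects
    pooled = pd.concat([t.assign(subject=s) for s, t in tables.items()],
                       ignore_index=True)
    filtered, counts = filter_vmr_trials(pooled, cfg.rt_floor_ms, cfg.tail_frac)
    io.write_json(counts, out / "vmr_exclusions.json")

    rows = []
    for s in subjects:
        tbl = filtered[filtered["subject"] == s]
        m = compute_vmr_measures(tbl, early_window=(0, cfg.early_window),
                                 n_discard=cfg.n_report_discard,
                                 n_use=cfg.n_report_use)
        rows.append({"subject": s, **asdict(m)})
    vmr_df = pd.DataFrame(rows)
    io.write_table(vmr_df, out / "behavior_vmr.tsv")

    ss = np.random.SeedSequence([cfg.seed, 17])
    fits = {}
    rrows = []
    for s, child in zip(subjects, ss.spawn(len(subjects))):
        trials = io.read_table(out / "reward_trials" / f"{s}.tsv")
        scores = trials["lateral_score"].to_numpy(dtype=float)
        fit = fit_sigmoid_bayes(scores, priors=SigmoidPriors(),
                                n_chains=cfg.mcmc_chains,
                                n_samples=cfg.mcmc_samples,
                                n_burnin=cfg.mcmc_burnin,
                                rng=np.random.default_rng(child))
        ep = define_epochs(fit, cfg.q_pre, cfg.q_learn, cfg.q_post,
                           n_trials=len(scores))
        rate = learning_rate(fit, scores, ep)
        fits[s] = {"summary": fit.summary, "rhat": fit.rhat,
                   "near_flat": fit.near_flat,
                   "fallback_used": fit.fallback_used,
                   "accept_rates": fit.accept_rates}
        rrows.append({"subject": s, "learning_rate": rate,
                      "end_pre": ep.end_pre,
                      "start_learning": ep.start_learning,
                      "start_post": ep.start_post,
                      "near_flat": fit.near_flat,
                      "max_rhat": max(fit.rhat.values())})
    io.write_json(fits, out / "sigmoid_fits.json")
    io.write_table(pd.DataFrame(rrows), out / "behavior_reward.tsv")
    log.info("behavior stage complete (%d subjects)", len(subjects))


def stage_connectivity(cfg: PipelineConfig):
    """Covariance estimation, Riemannian centering, seed connectivity."""
    out = _out(cfg)
    subjects = _subjects(cfg)
    meta = io.read_table(out / "parcel_meta.tsv")
    seed_idx = np.where(meta["is_seed"].to_numpy())[0]
    covs = {}
    for s in subjects:
        covs[s] = {}
        for ep in EPOCHS:
            path = out / "timecourses" / f"{s}_{ep}.tsv"
            if not path.exists():
                continue
            tc = io.read_timecourse(path)
            covs[s][ep] = ledoit_wolf_cov(tc)
    nonseed = np.setdiff1d(np.arange(len(meta)), seed_idx)
    labels = meta["parcel"].to_numpy()[nonseed]
    written = set()
    for task, eps in CENTERING_SETS.items():
        sub_covs = {s: {ep: covs[s][ep] for ep in eps if ep in covs[s]}
                    for s in subjects}
        sub_covs = {s: c for s, c in sub_covs.items() if c}
        if not sub_covs:
            continue
        centered = center_cohort(sub_covs)
        for ep in eps:
            if ep in written:
                continue   # rest anchors both sessions; write it once
            rows = {}
            for s in subjects:
                if s in centered and ep in centered[s]:
                    rows[s] = seed_connectivity(centered[s][ep], seed_idx)
            if not rows:
                continue
            df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
            df.insert(0, "subject", df.index)
            io.write_table(df.reset_index(drop=True),
                           out / "connectivity" / f"{ep}.tsv")
            written.add(ep)
    log.info("connectivity stage complete")


def _load_connectivity(cfg, epoch):
    out = _out(cfg)
    df = io.read_table(out / "connectivity" / f"{epoch}.tsv")
    subjects = df["subject"].tolist()
    X = df.drop(columns=["subject"]).to_numpy(dtype=float)
    labels = [c for c in df.columns if c != "subject"]
    return subjects, X, labels


def stage_axes(cfg: PipelineConfig):
    """Fit the explicit / performance / implicit neural axes."""
    out = _out(cfg)
    subjects, X, labels = _load_connectivity(cfg, "vmr_early")
    behavior = io.read_table(out / "behavior_vmr.tsv").set_index("subject") \
        .loc[subjects]
    meta = io.read_table(out / "parcel_meta.tsv").set_index("parcel")
    groups = meta.loc[labels, "network"].to_numpy()
    axes = build_axes(X, behavior, groups, roi_labels=labels,
                      n_iter=cfg.ridge_iter, n_grid=cfg.ridge_grid)
    df = pd.DataFrame({"roi": labels, "network": groups})
    for name, ax in axes.items():
        df[f"beta_{name}"] = ax.beta
    df["alignment"] = alignment_axis(axes["explicit"], axes["implicit"])
    io.write_table(df, out / "axes.tsv")
    io.write_json({name: {"network_penalties": ax.network_penalties,
                          "cv_r2": ax.cv_r2,
                          "residualized_on": ax.residualized_on}
                   for name, ax in axes.items()}, out / "axes_meta.json")
    log.info("axes stage complete (cv R2: %s)",
             {k: round(v.cv_r2, 3) for k, v in axes.items()})


def _load_axes(cfg):
    out = _out(cfg)
    df = io.read_table(out / "axes.tsv")
    meta = io.read_json(out / "axes_meta.json")
    axes = {}
    for name in ("explicit", "performance", "implicit"):
        axes[name] = AxisMap(beta=df[f"beta_{name}"].to_numpy(dtype=float),
                             roi_labels=df["roi"].tolist(),
                             groups=df["network"].to_numpy(),
                             network_penalties=meta[name]["network_penalties"],
                             cv_r2=meta[name]["cv_r2"],
                             outcome_label=name,
                             residualized_on=meta[name]["residualized_on"])
    return axes, df


def stage_express(cfg: PipelineConfig):
    """Score axis expression in the reward-task epochs; cross-task stats."""
    out = _out(cfg)
    axes, _ = _load_axes(cfg)
    rates = io.read_table(out / "behavior_reward.tsv").set_index("subject")
    rows = []
    learn_scores = {name: {} for name in axes}
    for ep in REWARD_EPOCHS:
        subjects, X, labels = _load_connectivity(cfg, ep)
        for name, ax in axes.items():
            if list(labels) != list(ax.roi_labels):
                raise ValueError("ROI order mismatch between axes and "
                                 f"connectivity for epoch {ep}")
            for s, row in zip(subjects, X):
                sc = axis_expression(ax, row, subject=s, epoch=ep)
                rows.append({"subject": s, "epoch": ep, "axis": name,
                             "score": sc.value})
                if ep == "reward_learn":
                    learn_scores[name][s] = sc.value
    io.write_table(pd.DataFrame(rows), out / "axis_scores.tsv")

    stats = {}
    for name, scores in learn_scores.items():
        subs = sorted(scores)
        r, t, p = cross_task_correlation(
            [scores[s] for s in subs],
            rates.loc[subs, "learning_rate"].to_numpy(dtype=float))
        stats[name] = {"r": r, "t": t, "p": p, "n": len(subs)}
    io.write_json(stats, out / "cross_task.json")
    log.info("expression stage complete: %s",
             {k: round(v["r"], 3) for k, v in stats.items()})


def stage_spin(cfg: PipelineConfig):
    """Spin test: explicit-alignment axis vs the reference spatial map."""
    out = _out(cfg)
    _, axes_df = _load_axes(cfg)
    meta = io.read_table(out / "parcel_meta.tsv").set_index("parcel")
    ref = io.read_table(out / "reference_map.tsv").set_index("parcel")
    rois = axes_df["roi"].tolist()
    sub_meta = meta.loc[rois].reset_index()
    seed_int = int(np.random.SeedSequence([cfg.seed, 29]).generate_state(1)[0]
                   % (2**31))
    res = spin_permutation_test(
        axes_df["alignment"].to_numpy(dtype=float),
        ref.loc[rois, "value"].to_numpy(dtype=float),
        sub_meta, n_perm=cfg.n_perm, rng=seed_int)
    io.write_json({"observed_r": res.observed, "p": res.p,
                   "n_perm": res.n_perm, "seed": seed_int,
                   "null_mean": float(res.null.mean()),
                   "null_sd": float(res.null.std())},
                  out / "spin_result.json")
    log.info("spin stage complete: r=%.3f p=%.4f", res.observed, res.p)


# ---------------------------------------------------------------- validate

def validate_inputs(cfg: PipelineConfig) -> dict:
    """Schema and sanity checks on every input table; returns a report."""
    out = _out(cfg)
    failures = []
    vmr_req = {"trial_index", "task_phase", "target_angle", "hand_angle",
               "cursor_angle", "rt", "mt"}
    subjects = _subjects(cfg)
    if not subjects:
        failures.append("no VMR trial tables found")
    for s in subjects:
        tbl = io.read_table(out / "vmr_trials" / f"{s}.tsv")
        missing = vmr_req - set(tbl.columns)
        if missing:
            failures.append(f"{s}: trial table missing columns {sorted(missing)}")
            continue
        for col in ("target_angle", "hand_angle", "cursor_angle"):
            v = tbl[col].to_numpy(dtype=float)
            if np.any((v <= -180) | (v > 180)):
                failures.append(f"{s}: {col} outside (-180, 180]")
        if np.any(tbl["rt"].to_numpy(dtype=float) < 0):
            failures.append(f"{s}: negative reaction times")
    tc_dir = out / "timecourses"
    if tc_dir.exists():
        for path in sorted(tc_dir.glob("*.tsv")):
            tc = io.read_timecourse(path)
            if tc.shape[0] < 2:
                failures.append(
                    f"{path.name}: insufficient volumes for covariance")
    meta_path = out / "parcel_meta.tsv"
    if meta_path.exists():
        meta = io.read_table(meta_path)
        from neuraxes.spatial import validate_parcel_meta
        try:
            validate_parcel_meta(meta.rename(columns=str))
        except ValueError as e:
            failures.append(str(e))
    return {"n_subjects": len(subjects), "failures": failures,
            "ok": not failures}


# ---------------------------------------------------------------- manifest

def write_manifest(cfg: PipelineConfig) -> Path:
    """List every artifact under the run directory with a content hash."""
    out = _out(cfg)
    entries = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            h = hashlib.sha256(path.read_bytes()).hexdigest()
            entries[str(path.relative_to(out))] = h
    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "files": entries,
    }
    io.write_json(manifest, out / "manifest.json")
    return out / "manifest.json"


STAGES = ("simulate", "behavior", "connectivity", "axes", "express", "spin")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write the manifest.

    Returns a small result bundle (cross-task stats, spin result, cv R2)
    read back from the written artifacts.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    stage_simulate(cfg)
    report = validate_inputs(cfg)
    if not report["ok"]:
        raise RuntimeError(f"input validation failed: {report['failures']}")
    stage_behavior(cfg)
    stage_connectivity(cfg)
    stage_axes(cfg)
    stage_express(cfg)
    stage_spin(cfg)
    manifest = write_manifest(cfg)
    out = _out(cfg)
    return {
        "cross_task": io.read_json(out / "cross_task.json"),
        "spin": io.read_json(out / "spin_result.json"),
        "axes_meta": io.read_json(out / "axes_meta.json"),
        "manifest": str(manifest),
    }
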