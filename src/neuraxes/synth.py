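"""Seeded synthetic cohorts with planted behavioral and connectivity truth.

The generator emulates the study design end to end so that every
analysis stage has a recovery test against known ground truth:

* VMR behavior: per-subject explicit/implicit re-aiming angles generate
  trial tables (baseline, learning under a 45-degree clockwise cursor
  rotation, and 16 end-of-block report trials).  Hand direction is
  target + explicit + implicit + noise; reported aim is
  target + explicit + report noise.  When an early-error target is
  supplied, compensation follows an exponential approach whose time
  constant is solved so that the mean error over the early window equals
  the planted value.
* Reward behavior: trajectories are half-sine paths whose lateral
  movement scores follow the generalized sigmoid (plus Gaussian noise),
  realizing each trial's intended score exactly in the noise-free case.
* Timecourses: each subject receives a random correlation-like base
  covariance (stable across epochs, mimicking the static subject-level
  differences that Riemannian centering must remove) plus epoch-specific
  increments to the seed-ROI covariance equal to the per-ROI effect map
  times the z-scored behavioral covariates.  The reward-task learning
  epoch is additionally modulated by the explicit effect pattern scaled
  by the z-scored learning rate, planting the cross-task coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from neuraxes.reward import (SigmoidParams, Trajectory, reward_score,
                             sigmoid_predict)
from neuraxes.vmr import wrap_angle

ROTATION_DEG = -45.0            # 45-degree clockwise cursor rotation
TARGET_ANGLES = np.arange(0.0, 360.0, 45.0)

EPOCHS = ("rest", "baseline", "vmr_early",
          "reward_pre", "reward_learn", "reward_post")


@dataclass
class BehaviorSpec:
    """Cohort-level distributions (mean, SD) of the behavioral truth."""
    explicit: tuple = (20.0, 12.0)       # deg
    implicit: tuple = (12.0, 6.0)        # deg
    early_error: tuple = (-25.0, 8.0)    # deg (signed; unlearned = -45)
    L: tuple = (-0.10, 0.03)             # lateral-score units (of D)
    U: tuple = (0.08, 0.03)
    m: tuple = (1.7, 0.3)                # scaled trials
    k: tuple = (7.0, 2.0)                # per scaled trial
    sigma: float = 0.05                  # residual score SD
    vmr_noise_sd: float = 3.0            # deg, motor noise per trial


@dataclass
class NoiseSpec:
    """Timecourse noise: subject base-covariance dispersion and obs noise."""
    base_df_factor: float = 3.0          # Wishart df = factor * n_rois
    obs_noise_sd: float = 0.2            # added white observation noise SD


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort (all randomness via seed)."""
    n_subjects: int = 36
    n_rois: int = 120
    network_labels: np.ndarray | None = None
    seed_rois: tuple = (0, 1, 2, 3)
    n_volumes_per_epoch: int = 100
    effect_map: np.ndarray | None = None     # (n_rois, 3): explicit, implicit, performance
    behavior_spec: BehaviorSpec = field(default_factory=BehaviorSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    cross_task_gain: float = 1.0
    n_vmr_trials: int = 200
    n_reward_trials: int = 270
    volumes_per_trial: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        seeds = set(int(s) for s in self.seed_rois)
        if not seeds or not seeds < set(range(self.n_rois)):
            raise ValueError("seed_rois must be a nonempty strict subset of ROIs")
        if self.n_volumes_per_epoch < 2:
            raise ValueError("epochs need at least 2 volumes")
        bs = self.behavior_spec
        for name in ("explicit", "implicit", "early_error", "L", "U", "m", "k"):
            if getattr(bs, name)[1] <= 0:
                raise ValueError(f"behavior_spec.{name} SD must be > 0")
        if self.network_labels is None:
            self.network_labels = default_network_labels(
                self.n_rois, self.seed_rois)
        self.network_labels = np.asarray(self.network_labels)
        if len(self.network_labels) != self.n_rois:
            raise ValueError("network_labels must label every ROI")
        if self.effect_map is None:
            self.effect_map = default_effect_map(
                self.network_labels, self.seed_rois)
        self.effect_map = np.asarray(self.effect_map, dtype=float)
        if self.effect_map.shape != (self.n_rois, 3):
            raise ValueError("effect_map must be (n_rois, 3)")


NONSEED_NETWORKS = ("Vis", "SomMotB", "DorsAttnA", "DorsAttnB",
                    "SalVentAttn", "ControlA", "ControlC", "DMNB")
SEED_NETWORK = "SomMotA"
# networks carrying the default planted effects (disjoint sets)
EFFECT_NETWORKS = {"explicit": "DMNB", "implicit": "DorsAttnB",
                   "performance": "ControlA"}
DEFAULT_EFFECT_SIZE = 0.12
DEFAULT_EFFECT_ROIS = 8
# graded within-network profile: effects in real networks are hub-weighted,
# not uniform
DEFAULT_EFFECT_TAPER = (1.6, 1.3, 1.15, 1.0, 0.9, 0.8, 0.7, 0.6)


def default_network_labels(n_rois, seed_rois):
    """Seed ROIs in the somatomotor seed network; the rest split evenly."""
    labels = np.empty(n_rois, dtype=object)
    seed_rois = sorted(set(int(s) for s in seed_rois))
    labels[seed_rois] = SEED_NETWORK
    rest = [i for i in range(n_rois) if i not in seed_rois]
    chunks = np.array_split(np.array(rest), len(NONSEED_NETWORKS))
    for net, idx in zip(NONSEED_NETWORKS, chunks):
        labels[idx] = net
    return labels


def default_effect_map(network_labels, seed_rois,
                       effect_size=DEFAULT_EFFECT_SIZE,
                       n_effect_rois=DEFAULT_EFFECT_ROIS,
                       taper=DEFAULT_EFFECT_TAPER):
    """Disjoint planted ROI sets: one network per behavioral covariate.

    Within each planted set the effect is graded by ``taper`` (strongest
    first), emulating hub-weighted network involvement.
    """
    labels = np.asarray(network_labels)
    p = len(labels)
    E = np.zeros((p, 3))
    weights = np.resize(np.asarray(taper, dtype=float), n_effect_rois)
    for c, cov in enumerate(("explicit", "implicit", "performance")):
        idx = np.where(labels == EFFECT_NETWORKS[cov])[0][:n_effect_rois]
        E[idx, c] = effect_size * weights[:len(idx)]
    E[list(seed_rois), :] = 0.0
    return E


@dataclass
class GroundTruth:
    """Planted per-subject behavior and per-epoch seed-connectivity truth."""
    subjects: pd.DataFrame
    true_seed_conn: dict = field(default_factory=dict)
    base_cov: dict = field(default_factory=dict)

    def planted_rois(self, spec: CohortSpec, covariate: str) -> np.ndarray:
        c = ("explicit", "implicit", "performance").index(covariate)
        return np.where(spec.effect_map[:, c] != 0)[0]


# ---------------------------------------------------------------- behavior

def _target_sequence(n_trials, rng):
    """Targets drawn in pseudorandom bins of 8 (each bin a permutation)."""
    n_bins = int(np.ceil(n_trials / 8))
    seq = np.concatenate([rng.permutation(TARGET_ANGLES) for _ in range(n_bins)])
    return seq[:n_trials]


def _solve_time_constant(total_adaptation, early_error, window=32):
    """Time constant of exponential compensation matching an early error.

    Solves mean_{t=1..window} A (1 - exp(-t/tau)) = early_error + 45.
    Returns (tau, clipped flag).
    """
    t = np.arange(1, window + 1, dtype=float)
    f = (early_error - ROTATION_DEG) / total_adaptation
    clipped = False
    if not (0.02 <= f <= 0.995):
        f = float(np.clip(f, 0.02, 0.995))
        clipped = True

    def g(tau):
        return np.mean(1.0 - np.exp(-t / tau)) - f

    tau = brentq(g, 1e-3, 5e3)
    return tau, clipped


def realized_early_error(explicit_deg, implicit_deg, early_error,
                         window=32):
    """Noise-free mean early error the generator can actually realize.

    With total adaptation A = explicit + implicit, the achievable early
    error lies in (-45, A - 45); targets outside this range are clipped.
    Cohort generation records the realized value as ground truth so the
    planted connectivity covariates stay consistent with behavior.
    """
    A = explicit_deg + implicit_deg
    if A <= 0:
        return ROTATION_DEG
    t = np.arange(1, window + 1, dtype=float)
    tau, _ = _solve_time_constant(A, early_error, window)
    return float(A * np.mean(1.0 - np.exp(-t / tau)) + ROTATION_DEG)


def gen_vmr_subject(explicit_deg, implicit_deg, noise_sd, n_trials, rng,
                    early_error=None, n_baseline=40, n_report=16,
                    early_window=32) -> pd.DataFrame:
    """Simulate one subject's VMR trial table.

    Layout: ``n_baseline`` veridical trials, a learning block under the
    45-degree clockwise rotation, and ``n_report`` report trials at the
    end (still rotated, fully adapted).  Without an ``early_error``
    target, compensation is constant at explicit + implicit from the
    first learning trial; with one, it follows an exponential approach
    whose time constant is solved so the mean noise-free error over the
    first ``early_window`` learning trials equals the target.
    """
    if n_trials <= 0:
        raise ValueError("non-positive trial count")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_trials < n_baseline + n_report + 8:
        raise ValueError(
            f"n_trials={n_trials} leaves no room for {n_baseline} baseline "
            f"+ {n_report} report + 8 learning trials")
    rng = np.random.default_rng(rng)
    A = explicit_deg + implicit_deg
    n_learn = n_trials - n_baseline  # includes the trailing report trials

    targets = _target_sequence(n_trials, rng)
    phase = np.array(["baseline"] * n_baseline
                     + ["learning"] * (n_learn - n_report)
                     + ["report"] * n_report, dtype=object)

    t_learn = np.arange(1, n_learn + 1, dtype=float)
    if early_error is None or A <= 0:
        ramp = np.ones(n_learn)
    else:
        tau, clipped = _solve_time_constant(A, early_error, early_window)
        if clipped:
            warnings.warn("early-error target outside feasible range; clipped")
        ramp = 1.0 - np.exp(-t_learn / tau)
    # report trials: fully adapted
    ramp[n_learn - n_report:] = 1.0

    noise = rng.normal(0.0, noise_sd, size=n_trials)
    hand = np.empty(n_trials)
    cursor = np.empty(n_trials)
    reported = np.full(n_trials, np.nan)

    base = slice(0, n_baseline)
    hand[base] = targets[base] + noise[base]
    cursor[base] = hand[base]
    learn = slice(n_baseline, n_trials)
    hand[learn] = targets[learn] + A * ramp + noise[learn]
    cursor[learn] = hand[learn] + ROTATION_DEG
    rep = slice(n_trials - n_report, n_trials)
    hand[rep] = targets[rep] + explicit_deg + implicit_deg \
        + noise[rep]
    cursor[rep] = hand[rep] + ROTATION_DEG
    reported[rep] = targets[rep] + explicit_deg \
        + rng.normal(0.0, noise_sd, size=n_report)

    rt = 100.0 + rng.lognormal(np.log(500.0), 0.3, size=n_trials)
    mt = 50.0 + rng.lognormal(np.log(250.0), 0.25, size=n_trials)

    return pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "task_phase": phase,
        "target_angle": wrap_angle(targets),
        "hand_angle": wrap_angle(hand),
        "cursor_angle": wrap_angle(cursor),
        "reported_aim": [wrap_angle(v) if np.isfinite(v) else np.nan
                         for v in reported],
        "rt": rt,
        "mt": mt,
        "valid": True,
        "exclusion_reason": "",
        "too_early": False,
        "timeout": False,
        "cursor_jump": False,
    })


@dataclass
class RewardSubject:
    """One subject's reward-task data: trial table plus raw trajectories."""
    trials: pd.DataFrame
    trajectories: np.ndarray     # (n_trials, n_samples, 2)
    params: SigmoidParams


def gen_reward_subject(params: SigmoidParams, noise_sd, n_trials, rng,
                       n_baseline=70, target_distance=60.0,
                       n_path_samples=61) -> RewardSubject:
    """Simulate one subject's reward-task trajectories and scores.

    Each trial's lateral movement score is the sigmoid value at the
    scaled trial index plus Gaussian noise; the trajectory is realized as
    a half-sine path whose amplitude reproduces that score exactly on the
    lateral-score grid.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    if not np.isfinite(params.k):
        raise ValueError("k must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params.k < 0:
        warnings.warn("negative learning rate k (unlearning subject)")
    rng = np.random.default_rng(rng)
    d = target_distance
    x = np.arange(1, n_trials + 1, dtype=float) / 100.0
    scores = sigmoid_predict(params, x) + rng.normal(0.0, noise_sd, n_trials)

    y = np.linspace(0.0, d, n_path_samples)
    s = np.sin(np.pi * y / d)
    mean_sin = np.mean(s)
    trajs = np.empty((n_trials, n_path_samples, 2))
    points = np.empty(n_trials)
    for i in range(n_trials):
        amp = -scores[i] * d / mean_sin
        trajs[i, :, 0] = amp * s
        trajs[i, :, 1] = y
        points[i] = reward_score(Trajectory(trajs[i], d))

    phase = np.array(["baseline"] * min(n_baseline, n_trials)
                     + ["learning"] * max(0, n_trials - n_baseline),
                     dtype=object)
    trials = pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "task_phase": phase,
        "lateral_score": scores,
        "reward_points": points,
        "valid": True,
        "exclusion_reason": "",
    })
    return RewardSubject(trials, trajs, params)


# ------------------------------------------------------------- timecourses

def _zscore(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _base_covariance(p, df, obs_noise_sd, rng):
    """Correlation-like subject base covariance via a Wishart draw."""
    G = rng.standard_normal((df, p)) / np.sqrt(df)
    S = G.T @ G
    dinv = 1.0 / np.sqrt(np.diag(S))
    C = S * np.outer(dinv, dinv)
    return C + obs_noise_sd**2 * np.eye(p)


def _epoch_increments(spec: CohortSpec, truth: GroundTruth) -> dict:
    """Per-subject, per-epoch seed-connectivity increment vectors."""
    df = truth.subjects
    z = {
        "explicit": _zscore(df["explicit"]),
        "implicit": _zscore(df["implicit"]),
        "performance": _zscore(-df["early_error"]),
        "rate": _zscore(df["k"]),
    }
    E = spec.effect_map
    inc = {}
    for i, subj in enumerate(df["subject"]):
        delta = {ep: np.zeros(spec.n_rois) for ep in EPOCHS}
        delta["vmr_early"] = (E[:, 0] * z["explicit"][i]
                              + E[:, 1] * z["implicit"][i]
                              + E[:, 2] * z["performance"][i])
        delta["reward_learn"] = spec.cross_task_gain * E[:, 0] * z["rate"][i]
        inc[subj] = delta
    return inc


def gen_cohort_timecourses(spec: CohortSpec, truth: GroundTruth,
                           rng=None) -> dict:
    """Multivariate-normal timecourses encoding the planted covariates.

    Returns subject -> {epoch -> (n_volumes x n_rois) array}.  Each
    subject's epochs share a base covariance; epochs with planted effects
    add the increment to the covariance between seed ROIs and the
    affected ROIs.  Increments that break positive definiteness are
    damped by halving, with a warning.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    p = spec.n_rois
    seeds = sorted(set(int(s) for s in spec.seed_rois))
    nonseed = np.setdiff1d(np.arange(p), seeds)
    df = int(round(spec.noise_spec.base_df_factor * p))
    increments = _epoch_increments(spec, truth)

    out = {}
    for subj in truth.subjects["subject"]:
        C = _base_covariance(p, df, spec.noise_spec.obs_noise_sd, rng)
        truth.base_cov[subj] = C
        out[subj] = {}
        for ep in EPOCHS:
            delta = increments[subj][ep].copy()

            def _with_delta(d):
                Sigma = C.copy()
                for s in seeds:
                    Sigma[s, nonseed] += d[nonseed]
                    Sigma[nonseed, s] += d[nonseed]
                return Sigma

            Sigma = _with_delta(delta)
            margin = 0.02
            if np.linalg.eigvalsh(Sigma)[0] <= margin:
                # damp the increment by the smallest factor restoring
                # positive definiteness (with margin), to preserve the
                # planted linear relation as far as possible
                warnings.warn("planted increment broke positive "
                              "definiteness; damping")
                lo_g, hi_g = 0.0, 1.0
                for _ in range(20):
                    mid = 0.5 * (lo_g + hi_g)
                    if np.linalg.eigvalsh(_with_delta(mid * delta))[0] > margin:
                        lo_g = mid
                    else:
                        hi_g = mid
                delta *= lo_g
                Sigma = _with_delta(delta)
                if np.linalg.eigvalsh(Sigma)[0] <= 0:
                    raise RuntimeError("could not make epoch covariance PD")
            truth.true_seed_conn[(subj, ep)] = delta[nonseed]
            L = np.linalg.cholesky(Sigma)
            Z = rng.standard_normal((spec.n_volumes_per_epoch, p))
            out[subj][ep] = Z @ L.T
    return out


# ------------------------------------------------------------------ cohort

@dataclass
class Cohort:
    """A fully realized synthetic cohort."""
    spec: CohortSpec
    truth: GroundTruth
    vmr_tables: dict
    reward_subjects: dict
    timecourses: dict
    parcel_meta: pd.DataFrame
    reference_map: np.ndarray


def _fibonacci_sphere(n, rng=None):
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def make_parcel_meta(spec: CohortSpec, rng) -> tuple:
    """Spherical parcel centroids (mirrored hemispheres) + a reference map.

    The reference map emulates a smooth principal-gradient-like value:
    the projection of each centroid on a fixed axis plus small noise.
    """
    p = spec.n_rois
    n_left = (p + 1) // 2
    left = _fibonacci_sphere(n_left)
    right = left[:p - n_left] * np.array([-1.0, 1.0, 1.0])
    xyz = np.vstack([left, right])
    hemi = np.array(["L"] * n_left + ["R"] * (p - n_left))
    order = rng.permutation(p)          # decouple ROI index from position
    xyz, hemi = xyz[order], hemi[order]
    meta = pd.DataFrame({
        "parcel": [f"roi{i:03d}" for i in range(p)],
        "hemi": hemi,
        "network": spec.network_labels,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "is_seed": [i in set(spec.seed_rois) for i in range(p)],
    })
    axis = np.array([0.2, 0.5, 0.84])
    axis /= np.linalg.norm(axis)
    ref = xyz @ axis + 0.1 * rng.standard_normal(p)
    return meta, ref


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate behavior, timecourses and parcel metadata for a cohort."""
    ss = np.random.SeedSequence(spec.seed)
    r_behav, r_vmr, r_reward, r_tc, r_meta = [
        np.random.default_rng(s) for s in ss.spawn(5)]
    bs = spec.behavior_spec
    n = spec.n_subjects

    rows = []
    for i in range(n):
        explicit = r_behav.normal(*bs.explicit)
        implicit = r_behav.normal(*bs.implicit)
        # record the early error the generator can realize (targets outside
        # the feasible range (-45, explicit+implicit-45) are clipped)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            early = realized_early_error(explicit, implicit,
                                         r_behav.normal(*bs.early_error))
        rows.append({
            "subject": f"sub{i:02d}",
            "explicit": explicit,
            "implicit": implicit,
            "early_error": early,
            "L": r_behav.normal(*bs.L),
            "U": r_behav.normal(*bs.U),
            "m": r_behav.normal(*bs.m),
            "k": max(0.5, r_behav.normal(*bs.k)),
            "sigma": bs.sigma,
        })
    df = pd.DataFrame(rows)
    df["learning_rate"] = df["k"]
    truth = GroundTruth(subjects=df)

    vmr_tables, reward_subjects = {}, {}
    for _, row in df.iterrows():
        subj = row["subject"]
        vmr_tables[subj] = gen_vmr_subject(
            row["explicit"], row["implicit"], bs.vmr_noise_sd,
            spec.n_vmr_trials, r_vmr, early_error=row["early_error"])
        params = SigmoidParams(row["L"], row["U"], row["m"], row["k"],
                               row["sigma"])
        reward_subjects[subj] = gen_reward_subject(
            params, bs.sigma, spec.n_reward_trials, r_reward)

    timecourses = gen_cohort_timecourses(spec, truth, r_tc)
    meta, ref = make_parcel_meta(spec, r_meta)
    return Cohort(spec, truth, vmr_tables, reward_subjects, timecourses,
                  meta, ref)
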