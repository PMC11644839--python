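"""Reward-based path-tracing task: scoring, sigmoid learning curves, epochs.

Subjects trace a subtly curved path (a half sine of amplitude 0.15 x the
60 mm target distance) without cursor feedback, but are secretly rewarded
for tracing its mirror image.  Two trial-level summaries are computed:

* ``reward_score`` — the 0-100 points shown to the subject, based on the
  absolute deviation from the mirror path at each cm of forward travel,
  normalized by the deviation of a half-sine of amplitude 0.5 x target
  distance (so a perfect trace of the *visible* path scores 40, and a
  perfect trace of the mirror path scores 100);
* ``lateral_movement_score`` — the average lateral (x) position of the
  trajectory in units of the target distance, sign-flipped so positive
  values point toward the rewarded (mirror) side.

Learning curves of the lateral movement score across trials are modelled
with a generalized sigmoid

    f(x) = L + (U - L) / (1 + exp(-k (x - m)))

where x is the trial number scaled by 100, L and U are the lower and
upper asymptotes, m the midpoint and k the learning rate.  The model is
fit by MCMC under weakly informative priors (see ``SigmoidPriors``), and
the posterior-mean curve's 2.5% / 5% / 97.5% quantile crossings define
the pre-learning / learning / post-learning epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from neuraxes.mcmc import adaptive_metropolis, split_rhat

TARGET_DISTANCE_MM = 60.0
PARAM_NAMES = ("L", "U", "m", "k", "sigma")


@dataclass
class Trajectory:
    """A single movement path: ordered (x, y) samples in mm from the start."""
    samples: np.ndarray              # (n, 2)
    target_distance: float = TARGET_DISTANCE_MM

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array")


def half_sine_path(amplitude: float, d: float = TARGET_DISTANCE_MM,
                   n: int = 61) -> Trajectory:
    """A half-sine path x(y) = amplitude * sin(pi y / d), y in [0, d]."""
    y = np.linspace(0.0, d, n)
    x = amplitude * np.sin(np.pi * y / d)
    return Trajectory(np.column_stack([x, y]), d)


def _interp_x(traj: Trajectory, y_query) -> np.ndarray:
    """Interpolate lateral position at forward displacements ``y_query``.

    Uses the running maximum of y (first crossing) so that small
    non-monotonicities are tolerated; rejects trajectories that never
    reach the queried displacement.
    """
    x, y = traj.samples[:, 0], traj.samples[:, 1]
    ycm = np.maximum.accumulate(y)
    yq = np.atleast_1d(np.asarray(y_query, dtype=float))
    if np.any(yq > ycm[-1] + 1e-9):
        raise ValueError("trajectory does not reach the target distance")
    if ycm[-1] - ycm[0] <= 0:
        raise ValueError("degenerate trajectory (no forward travel)")
    return np.interp(yq, ycm, x)


def reward_score(traj: Trajectory, visible_amplitude_frac: float = 0.15,
                 ref_amplitude_frac: float = 0.5) -> float:
    """The 0-100 point score shown to the subject on each learning trial.

    The lateral position is interpolated at each cm of forward travel
    (10, 20, ..., 60 mm for the 60 mm target distance); the summed
    absolute deviation from the mirror path (amplitude
    -visible_amplitude_frac * D) is divided by the corresponding sum for
    a half-sine of amplitude ref_amplitude_frac * D, and mapped to
    100 * (1 - ratio), clamped to [0, 100].
    """
    d = traj.target_distance
    if d <= 0:
        raise ValueError("target distance must be positive")
    ys = np.arange(10.0, d + 1e-9, 10.0)
    xs = _interp_x(traj, ys)
    s = np.sin(np.pi * ys / d)
    mirror = -visible_amplitude_frac * d * s
    err = np.sum(np.abs(xs - mirror))
    ref = np.sum(ref_amplitude_frac * d * s)
    return float(np.clip(100.0 * (1.0 - err / ref), 0.0, 100.0))


def lateral_movement_score(traj: Trajectory, n_grid: int = 61) -> float:
    """Average lateral position in units of the target distance.

    Positive values indicate movement toward the rewarded (mirror-image)
    side; a straight vertical trace scores 0.  Expressing the score in
    units of the target distance keeps it on the scale assumed by the
    sigmoid priors (a perfect mirror trace scores about +0.096).
    """
    d = traj.target_distance
    ys = np.linspace(0.0, d, n_grid)
    xs = _interp_x(traj, ys)
    return float(-np.mean(xs) / d)


@dataclass
class SigmoidParams:
    """Generalized-sigmoid parameters in lateral-movement-score units."""
    L: float = -0.2
    U: float = 0.1
    m: float = 1.7
    k: float = 7.0
    sigma: float = 0.05

    def as_array(self):
        return np.array([self.L, self.U, self.m, self.k, self.sigma])


def sigmoid_predict(params, x):
    """Value of the generalized sigmoid at scaled trial(s) x."""
    if isinstance(params, SigmoidParams):
        L, U, m, k = params.L, params.U, params.m, params.k
    else:
        L, U, m, k = params[:4]
    x = np.asarray(x, dtype=float)
    return L + (U - L) / (1.0 + np.exp(-k * (x - m)))


@dataclass
class SigmoidPriors:
    """Prior means/SDs for (L, U, m, k) normals and the half-normal sigma."""
    L: tuple = (-0.2, 0.25)
    U: tuple = (0.0, 0.25)
    m: tuple = (1.7, 0.5)
    k: tuple = (7.0, 2.0)
    sigma_scale: float = 0.25


@dataclass
class SigmoidFit:
    """Posterior summary of a Bayesian sigmoid fit.

    ``summary`` maps parameter name -> dict with mean, sd and the
    2.5/50/97.5% posterior quantiles; ``rhat`` holds the split-chain
    potential scale reduction factor per parameter.
    """
    summary: dict
    rhat: dict
    n_chains: int
    n_samples: int
    n_burnin: int
    accept_rates: list
    near_flat: bool = False
    fallback_used: bool = False
    end_pre: float | None = None
    start_learning: float | None = None
    start_post: float | None = None
    draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def posterior_mean(self) -> SigmoidParams:
        return SigmoidParams(*(self.summary[p]["mean"] for p in PARAM_NAMES))


def _log_posterior_factory(x, y, priors: SigmoidPriors):
    pm = np.array([priors.L[0], priors.U[0], priors.m[0], priors.k[0]])
    ps = np.array([priors.L[1], priors.U[1], priors.m[1], priors.k[1]])
    ssc = priors.sigma_scale

    def log_post(theta):
        L, U, m, k, sigma = theta
        if sigma <= 0:
            return -np.inf
        mu = L + (U - L) / (1.0 + np.exp(-k * (x - m)))
        resid = y - mu
        n = y.size
        loglik = -n * np.log(sigma) - 0.5 * np.sum(resid * resid) / sigma**2
        lp = -0.5 * np.sum(((theta[:4] - pm) / ps) ** 2)
        lp += -0.5 * (sigma / ssc) ** 2
        return loglik + lp

    return log_post


def fit_sigmoid_bayes(scores, x=None, priors: SigmoidPriors | None = None,
                      n_chains: int = 3, n_samples: int = 5000,
                      n_burnin: int = 1500, rng=None, thin: int = 5,
                      near_flat_range: float = 0.05,
                      keep_draws: bool = False) -> SigmoidFit:
    """Fit the sigmoid learning-curve model by adaptive Metropolis MCMC.

    Parameters
    ----------
    scores : array (n,)
        Per-trial lateral movement scores.
    x : array (n,), optional
        Scaled trial index; defaults to (1..n)/100.
    priors : SigmoidPriors
        Weakly informative priors regularizing slow learners.
    n_chains, n_samples, n_burnin : int
        Chain budget (retained draws); summaries use the post-burn-in
        draws of each chain.
    thin : int
        Random-walk proposal updates per retained draw (the random-walk
        analogue of one gradient-based sampling step).
    near_flat_range : float
        If the posterior-mean learning range |U - L| falls below this
        value the fit is flagged near-flat (an "extremely low learning
        rate" subject), not errored.
    """
    y = np.asarray(scores, dtype=float)
    if y.size < 20:
        raise ValueError("need at least 20 trials to fit the sigmoid")
    if x is None:
        x = np.arange(1, y.size + 1, dtype=float) / 100.0
    else:
        x = np.asarray(x, dtype=float)
    priors = priors or SigmoidPriors()
    rng = np.random.default_rng(rng)
    log_post = _log_posterior_factory(x, y, priors)

    chains, acc = [], []
    for _ in range(n_chains):
        for attempt in range(5):
            x0 = np.array([
                rng.normal(priors.L[0], 0.3 * priors.L[1]),
                rng.normal(priors.U[0], 0.3 * priors.U[1]),
                rng.normal(priors.m[0], 0.3 * priors.m[1]),
                rng.normal(priors.k[0], 0.3 * priors.k[1]),
                abs(rng.normal(0.1, 0.02)) + 1e-3,
            ])
            if np.isfinite(log_post(x0)):
                break
        else:
            raise RuntimeError("could not initialize chain in prior bulk")
        chain, a = adaptive_metropolis(
            log_post, x0, n_samples, n_burnin, rng, thin=thin,
            init_scale=np.array([0.02, 0.02, 0.05, 0.2, 0.01]))
        chains.append(chain[n_burnin:])
        acc.append(a)
    draws = np.stack(chains)                      # (chains, kept, 5)

    summary, rhat = {}, {}
    flat = draws.reshape(-1, 5)
    for j, name in enumerate(PARAM_NAMES):
        col = flat[:, j]
        summary[name] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)),
            "q2.5": float(np.quantile(col, 0.025)),
            "q50": float(np.quantile(col, 0.5)),
            "q97.5": float(np.quantile(col, 0.975)),
        }
        rhat[name] = split_rhat(draws[:, :, j])

    near_flat = abs(summary["U"]["mean"] - summary["L"]["mean"]) < near_flat_range
    if near_flat:
        warnings.warn("near-flat sigmoid fit: subject recorded as having an "
                      "extremely low learning rate")
    return SigmoidFit(summary=summary, rhat=rhat, n_chains=n_chains,
                      n_samples=n_samples, n_burnin=n_burnin,
                      accept_rates=acc, near_flat=near_flat,
                      draws=draws if keep_draws else None)


@dataclass
class EpochWindows:
    """Epoch boundaries in trial units plus volume windows for covariance."""
    end_pre: float
    start_learning: float
    start_post: float
    pre_volumes: tuple
    learning_volumes: tuple
    post_volumes: tuple
    fallback_used: bool = False


def sigmoid_quantile_crossing(params, q: float) -> float:
    """Scaled trial at which the sigmoid reaches L + q (U - L).

    Closed form x_q = m - ln((1 - q) / q) / k.
    """
    if isinstance(params, SigmoidParams):
        m, k = params.m, params.k
    else:
        m, k = params[2], params[3]
    if k == 0:
        raise ValueError("flat curve has no quantile crossings")
    return m - np.log((1.0 - q) / q) / k


def define_epochs(fit, q_pre: float = 0.025, q_learn: float = 0.05,
                  q_post: float = 0.975, epoch_len: int = 100,
                  volumes_per_trial: float = 3.0,
                  n_trials: int | None = None) -> EpochWindows:
    """Derive pre-learning / learning / post-learning epochs from a fit.

    Boundaries are the posterior-mean curve's quantile crossings (in trial
    units, i.e. scaled x times 100).  The pre-learning window is
    ``epoch_len`` volumes ending at the q_pre crossing; the learning and
    post-learning windows start at the q_learn and q_post crossings.  If
    ``n_trials`` is given, windows are clipped to the scan extent with a
    warning.  A non-positive posterior-mean k triggers the fallback
    (thirds-based) segmentation, flagged for manual review.
    """
    params = fit.posterior_mean if isinstance(fit, SigmoidFit) else fit
    fallback = params.k <= 0
    if fallback:
        warnings.warn("non-positive learning rate in posterior mean; "
                      "falling back to flagged thirds-based segmentation")
        n = n_trials if n_trials is not None else 300
        end_pre, start_learning, start_post = n / 3.0, n / 3.0, 2 * n / 3.0
    else:
        end_pre = 100.0 * sigmoid_quantile_crossing(params, q_pre)
        start_learning = 100.0 * sigmoid_quantile_crossing(params, q_learn)
        start_post = 100.0 * sigmoid_quantile_crossing(params, q_post)

    def vol(t):
        return t * volumes_per_trial

    windows = [
        (vol(end_pre) - epoch_len, vol(end_pre)),
        (vol(start_learning), vol(start_learning) + epoch_len),
        (vol(start_post), vol(start_post) + epoch_len),
    ]
    n_vol = None if n_trials is None else n_trials * volumes_per_trial
    clipped = []
    for lo, hi in windows:
        lo2 = max(0.0, lo)
        hi2 = hi if n_vol is None else min(float(n_vol), hi)
        if (lo2, hi2) != (lo, hi):
            warnings.warn("epoch window clipped to scan extent")
        lo2 = min(lo2, hi2 - 1.0) if hi2 >= 1 else lo2
        clipped.append((int(round(lo2)), int(round(hi2))))

    ep = EpochWindows(end_pre, start_learning, start_post,
                      *clipped, fallback_used=fallback)
    if isinstance(fit, SigmoidFit):
        fit.end_pre, fit.start_learning, fit.start_post = \
            end_pre, start_learning, start_post
        fit.fallback_used = fit.fallback_used or fallback
    return ep


def learning_rate(fit: SigmoidFit, scores=None,
                  epochs: EpochWindows | None = None) -> float:
    """Subject learning rate: posterior-mean k, or a fallback slope.

    For subjects poorly characterized by the sigmoid (``fallback_used``),
    the rate is the least-squares slope (score units per trial) over the
    trials of their learning epoch.
    """
    if not fit.fallback_used:
        return fit.summary["k"]["mean"]
    if scores is None or epochs is None:
        raise ValueError("fallback learning rate needs scores and epochs")
    y = np.asarray(scores, dtype=float)
    lo = int(np.floor(max(0.0, epochs.start_learning)))
    hi = int(np.ceil(min(y.size, epochs.start_post)))
    if hi - lo < 3:
        raise ValueError("learning epoch shorter than 3 trials")
    t = np.arange(lo, hi, dtype=float)
    slope = np.polyfit(t, y[lo:hi], 1)[0]
    return float(slope)
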