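"""Behavioral analysis of the visuomotor rotation (VMR) task.

In the VMR task subjects make center-out reaches toward one of 8 targets
while the cursor is rotated 45 degrees clockwise relative to the hand.
Explicit learning is measured from end-of-block "report" trials (reported
aim vs. target), implicit learning as the difference between the actual
and reported aim, and performance as the mean signed error over an early
learning window.

Sign convention: angles are degrees, counter-clockwise positive, wrapped
to (-180, 180].  The clockwise rotation is -45, so full compensation
corresponds to explicit + implicit = +45 and the unlearned error is -45.

Trial tables are pandas DataFrames with columns::

    trial_index, task_phase (baseline|learning|report), target_angle,
    hand_angle, cursor_angle, reported_aim, rt, mt, valid, exclusion_reason

plus optional boolean event columns ``too_early``, ``timeout``,
``cursor_jump`` recording online violations, and an optional ``subject``
column when tables from several subjects are concatenated (the RT/MT tail
filter is defined across all rows present, i.e. across subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRIAL_COLUMNS = [
    "trial_index", "task_phase", "target_angle", "hand_angle",
    "cursor_angle", "reported_aim", "rt", "mt", "valid", "exclusion_reason",
]

_EVENT_REASONS = ("too_early", "timeout", "cursor_jump")


def wrap_angle(a):
    """Wrap an angle (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    # mod can return exactly 180 -> already in range; -180 never produced
    if w.ndim == 0:
        return float(w)
    return w


def angular_error(movement, target):
    """Signed angular error movement - target, CCW positive, in (-180, 180]."""
    return wrap_angle(np.asarray(movement, dtype=float) - np.asarray(target, dtype=float))


def circular_mean(angles):
    """Mean direction (degrees) of a set of angles.

    Raises if the resultant vector is (numerically) zero, in which case
    the mean direction is undefined.
    """
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circular_mean of empty sequence")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) < 1e-12:
        raise ValueError("undefined mean direction (zero resultant)")
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def filter_vmr_trials(table: pd.DataFrame, rt_floor: float = 100.0,
                      tail_frac: float = 0.0005):
    """Mark invalid VMR trials and return (table, exclusion counts).

    Exclusions, in order of precedence: online events (too-early starts,
    timeouts, cursor jumps to the touchpad default position), RT or MT
    above the cross-subject (1 - tail_frac) quantile, and RT below
    ``rt_floor`` ms.  Counts report the first reason that applied to each
    trial.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    if not (0.0 <= tail_frac < 1.0):
        raise ValueError("tail_frac must be in [0, 1)")
    out = table.copy()
    if "valid" not in out.columns:
        out["valid"] = True
    if "exclusion_reason" not in out.columns:
        out["exclusion_reason"] = ""
    reason = np.array([""] * len(out), dtype=object)

    for ev in _EVENT_REASONS:
        if ev in out.columns:
            hit = out[ev].fillna(False).to_numpy(dtype=bool) & (reason == "")
            reason[hit] = ev

    rt = out["rt"].to_numpy(dtype=float)
    mt = out["mt"].to_numpy(dtype=float)
    if tail_frac > 0:
        q = 1.0 - tail_frac
        rt_hi = np.nanquantile(rt, q)
        mt_hi = np.nanquantile(mt, q)
        hit = ((rt > rt_hi) | (mt > mt_hi)) & (reason == "")
        reason[hit] = "rt_mt_tail"
    hit = (rt < rt_floor) & (reason == "")
    reason[hit] = "rt_floor"

    excluded = reason != ""
    out.loc[excluded, "valid"] = False
    out.loc[excluded, "exclusion_reason"] = reason[excluded]
    counts = {r: int(np.sum(reason == r))
              for r in (*_EVENT_REASONS, "rt_mt_tail", "rt_floor")}
    counts["n_excluded"] = int(excluded.sum())
    counts["n_valid"] = int(out["valid"].sum())
    if counts["n_valid"] == 0:
        raise ValueError("empty after filtering: all trials excluded")
    return out, counts


def estimate_explicit_implicit(report_rows: pd.DataFrame, n_discard: int = 8,
                               n_use: int = 8):
    """Explicit/implicit decomposition from report trials.

    The first ``n_discard`` report trials are dropped (subjects often
    misunderstand the reporting procedure at first) and the circular means
    are taken over the following ``n_use`` trials:

    * explicit  = circular mean of (reported aim - target)
    * implicit  = circular mean of (hand angle - reported aim)
    """
    rep = report_rows[report_rows["task_phase"] == "report"] \
        if "task_phase" in report_rows.columns else report_rows
    if len(rep) < n_discard + n_use:
        raise ValueError(
            f"insufficient report trials: have {len(rep)}, "
            f"need {n_discard + n_use}")
    used = rep.iloc[n_discard:n_discard + n_use]
    explicit = circular_mean(angular_error(used["reported_aim"], used["target_angle"]))
    implicit = circular_mean(angular_error(used["hand_angle"], used["reported_aim"]))
    return explicit, implicit


def epoch_mean_error(table: pd.DataFrame, window=(0, 32)) -> float:
    """Mean signed cursor error over a window of valid learning trials.

    ``window`` is a half-open (start, stop) range indexing learning-phase
    trials (0-based, in presentation order, counted before exclusion).
    """
    learn = table[table["task_phase"] == "learning"]
    start, stop = window
    sel = learn.iloc[start:stop]
    sel = sel[sel["valid"].astype(bool)]
    if len(sel) == 0:
        raise ValueError("empty window after filtering")
    err = angular_error(sel["cursor_angle"], sel["target_angle"])
    return float(np.mean(err))


@dataclass
class RtBinResult:
    """Per-RT-bin error summary for one subject."""
    bin_mean_rt: np.ndarray
    bin_mean_error: np.ndarray
    bin_mean_abs_error: np.ndarray
    n_per_bin: np.ndarray
    rho: float
    rho_defined: bool


def rt_bin_error_analysis(table: pd.DataFrame, n_bins: int = 5) -> RtBinResult:
    """Mean error in RT-quantile bins and the Spearman RT-|error| correlation.

    Valid learning trials are split at the subject's 20/40/60/80% RT
    percentiles (for the default 5 bins); the Spearman correlation is
    computed between per-bin mean RT and per-bin mean absolute error.
    A constant-error (or otherwise undefined) correlation is returned as
    0 with ``rho_defined=False``.
    """
    learn = table[(table["task_phase"] == "learning") & table["valid"].astype(bool)]
    if len(learn) < n_bins:
        raise ValueError(f"need at least {n_bins} valid learning trials")
    rt = learn["rt"].to_numpy(dtype=float)
    err = angular_error(learn["cursor_angle"], learn["target_angle"])
    edges = np.quantile(rt, np.linspace(0, 1, n_bins + 1))
    # ties in RT can collapse edges -> merge the affected (empty) bins
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn("tied RT quantiles: merging adjacent empty bins")
        edges = uniq
    idx = np.clip(np.searchsorted(edges, rt, side="right") - 1, 0, len(edges) - 2)
    k = len(edges) - 1
    mean_rt = np.array([rt[idx == b].mean() for b in range(k)])
    mean_err = np.array([err[idx == b].mean() for b in range(k)])
    mean_abs = np.array([np.abs(err[idx == b]).mean() for b in range(k)])
    n_per = np.array([int(np.sum(idx == b)) for b in range(k)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(mean_rt, mean_abs).statistic
    defined = bool(np.isfinite(rho))
    return RtBinResult(mean_rt, mean_err, mean_abs, n_per,
                       float(rho) if defined else 0.0, defined)


@dataclass
class VmrMeasures:
    """Subject-level behavioral summary of the VMR task (degrees / ms)."""
    explicit: float
    implicit: float
    early_error: float
    late_error: float
    mean_rt_early: float
    mean_rt_late: float
    rt_bin_rho: float


def compute_vmr_measures(table: pd.DataFrame, early_window=(0, 32),
                         late_window=(-32, None), n_discard: int = 8,
                         n_use: int = 8) -> VmrMeasures:
    """Assemble the full per-subject VMR summary from a filtered table."""
    explicit, implicit = estimate_explicit_implicit(table, n_discard, n_use)
    learn = table[table["task_phase"] == "learning"]
    n_learn = len(learn)
    early = early_window
    lw = late_window
    late = (n_learn + lw[0] if lw[0] is not None and lw[0] < 0 else lw[0],
            n_learn if lw[1] is None else lw[1])
    early_error = epoch_mean_error(table, early)
    late_error = epoch_mean_error(table, late)

    def _mean_rt(win):
        sel = learn.iloc[win[0]:win[1]]
        sel = sel[sel["valid"].astype(bool)]
        return float(sel["rt"].mean())

    rtb = rt_bin_error_analysis(table)
    return VmrMeasures(explicit, implicit, early_error, late_error,
                       _mean_rt(early), _mean_rt(late), rtb.rho)
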