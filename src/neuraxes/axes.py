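"""Neural axes: network-penalized ridge maps of learning behavior.

An "axis" is the coefficient vector beta of a ridge regression of a
behavioral measure (explicit report, implicit adaptation, or
sign-inverted early error) on subjects' seed-connectivity profiles, with
a separate penalty multiplier per brain network tuned by leave-one-out
cross-validation.  Networks that contribute little to prediction are
shrunk harshly; predictively useful networks keep large coefficients.

Axis "expression" in new data is the Pearson correlation between beta
and an observed connectivity profile, and the explicit-alignment summary
axis is the difference in rank loadings between the explicit and
implicit axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AxisMap:
    """Per-ROI coefficient map defining a neural axis."""
    beta: np.ndarray
    roi_labels: list
    groups: np.ndarray
    network_penalties: dict
    cv_r2: float
    outcome_label: str = ""
    residualized_on: str | None = None


@dataclass
class AxisScore:
    """Expression of an axis in one subject/epoch connectivity profile."""
    subject: object
    epoch: str
    value: float
    degenerate: bool = False


def residualize(y, covariate):
    """Residuals of a simple linear regression of y on covariate (+intercept).

    A zero-variance covariate yields the demeaned y with a warning.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if y.shape != c.shape or y.ndim != 1:
        raise ValueError("y and covariate must be 1-D of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    cc = c - c.mean()
    denom = np.dot(cc, cc)
    if denom < 1e-12 * max(1.0, np.dot(c, c)):
        warnings.warn("zero-variance covariate: returning demeaned y")
        return y - y.mean()
    yc = y - y.mean()
    slope = np.dot(cc, yc) / denom
    return yc - slope * cc


def _loo_residuals(X, y, penalties):
    """Closed-form leave-one-out residuals for ridge with per-feature penalties.

    Uses the dual (n x n) formulation: with K = X diag(1/lambda) X',
    M = K + I, the LOO residual is (M^{-1} y)_i / (M^{-1})_ii.
    """
    n, p = X.shape
    Xs = X / np.sqrt(penalties)
    M = Xs @ Xs.T + np.eye(n)
    Minv = np.linalg.inv(M)
    alpha = Minv @ y
    diag = np.diag(Minv)
    return alpha / diag


def _ridge_beta(X, y, penalties):
    n, p = X.shape
    if p <= n:
        A = X.T @ X + np.diag(penalties)
        return np.linalg.solve(A, X.T @ y)
    Xs = X / penalties
    alpha = np.linalg.solve(X @ Xs.T + np.eye(n), y)
    return Xs.T @ alpha


def group_ridge_fit(X, y, groups, n_iter: int = 10, n_grid: int = 25,
                    grid_range=(1e-3, 1e3), global_grid=None,
                    se_factor: float = 1.0,
                    roi_labels=None, outcome_label: str = "",
                    residualized_on: str | None = None,
                    rng=None) -> AxisMap:
    """Ridge regression with network-level penalties tuned by LOO CV.

    The penalty of feature j is lambda0 * mult[g(j)].  The global scale
    lambda0 and the per-group multipliers (initialized at 1) are tuned by
    alternately minimizing the closed-form leave-one-out squared error:
    each outer pass retunes lambda0 on ``global_grid`` and then scans each
    group's multiplier over ``n_grid`` log-spaced points in
    ``grid_range``.  Candidate penalties whose LOO error lies within
    ``se_factor`` standard errors of the minimum are treated as ties, and
    ties break toward stronger shrinkage (the one-standard-error rule;
    this curbs the selection bias of minimizing the same LOO error that
    is later reported).  The procedure is deterministic (``rng`` is
    accepted for interface symmetry).

    ``cv_r2`` is 1 - SS_LOO / SS_tot at the final penalties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one entry per row of X")
    groups = np.asarray(groups)
    if groups.shape != (p,):
        raise ValueError("groups must label every column of X")
    labels = list(dict.fromkeys(groups.tolist()))
    if global_grid is None:
        global_grid = np.logspace(-2, 5, 30)
    mult_grid = np.logspace(np.log10(grid_range[0]),
                            np.log10(grid_range[1]), n_grid)
    mult = {g: 1.0 for g in labels}
    group_idx = {g: np.where(groups == g)[0] for g in labels}

    def penalties(lam0, mult):
        pen = np.empty(p)
        for g, idx in group_idx.items():
            pen[idx] = lam0 * mult[g]
        return np.maximum(pen, 1e-10)

    def loo(lam0, mult):
        return _loo_residuals(X, y, penalties(lam0, mult))

    def _select_strong(values, residuals):
        """Strongest shrinkage whose LOO error is within se_factor
        standard errors of the minimum (ties -> stronger shrinkage)."""
        press = np.array([float(np.sum(r * r)) for r in residuals])
        i_min = int(np.argmin(press))
        e2 = residuals[i_min] ** 2
        se = np.sqrt(n * np.var(e2, ddof=1)) if n > 1 else 0.0
        cutoff = press[i_min] + se_factor * se + 1e-12
        ok = [v for v, p_ in zip(values, press) if p_ <= cutoff]
        return max(ok)

    lam0 = _select_strong(global_grid,
                          [loo(l0, mult) for l0 in global_grid])
    for _ in range(n_iter):
        for g in labels:
            res = []
            for mval in mult_grid:
                trial = dict(mult)
                trial[g] = mval
                res.append(loo(lam0, trial))
            mult[g] = _select_strong(mult_grid, res)
        lam0 = _select_strong(global_grid,
                              [loo(l0, mult) for l0 in global_grid])

    pen = penalties(lam0, mult)
    try:
        beta = _ridge_beta(X, y, pen)
    except np.linalg.LinAlgError:
        warnings.warn("singular ridge solve: applying penalty floor")
        beta = _ridge_beta(X, y, pen + 1e-6)
    loo = _loo_residuals(X, y, pen)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cv_r2 = 1.0 - float(np.sum(loo**2)) / ss_tot if ss_tot > 0 else 0.0
    pens = {g: float(lam0 * mult[g]) for g in labels}
    if roi_labels is None:
        roi_labels = list(range(p))
    return AxisMap(beta=beta, roi_labels=list(roi_labels), groups=groups,
                   network_penalties=pens, cv_r2=cv_r2,
                   outcome_label=outcome_label,
                   residualized_on=residualized_on)


def _standardize(a):
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (a - a.mean(axis=0)) / sd


def build_axes(connectivity, behavior, groups, roi_labels=None,
               **ridge_kwargs) -> dict:
    """Fit the Explicit, Performance and Implicit neural axes.

    Parameters
    ----------
    connectivity : array (subjects x non-seed ROIs)
        Seed-connectivity profiles from the early-learning epoch.
    behavior : mapping or DataFrame
        Must provide per-subject ``explicit``, ``implicit`` and
        ``early_error`` vectors (complete cases only).
    groups : array (ROIs,)
        Network label per ROI (the penalty groups).

    The explicit and implicit axes are fit on outcomes and predictors
    residualized on early error (removing performance-related variance);
    the performance axis is fit on sign-inverted early error with no
    residualization (greater loading = better performance).  Predictors
    and outcomes are standardized after residualization.
    """
    X = np.asarray(connectivity, dtype=float)
    explicit = np.asarray(behavior["explicit"], dtype=float)
    implicit = np.asarray(behavior["implicit"], dtype=float)
    error = np.asarray(behavior["early_error"], dtype=float)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(explicit) \
        & np.isfinite(implicit) & np.isfinite(error)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} subject(s) with "
                      "missing behavior or connectivity")
        X, explicit, implicit, error = X[ok], explicit[ok], implicit[ok], error[ok]

    Xres = np.column_stack([residualize(X[:, j], error)
                            for j in range(X.shape[1])])
    axes = {}
    for name, yraw, Xuse, resid_on in (
            ("explicit", residualize(explicit, error), Xres, "early_error"),
            ("performance", -error, X, None),
            ("implicit", residualize(implicit, error), Xres, "early_error")):
        ys = _standardize(yraw)
        Xs = _standardize(Xuse)
        axes[name] = group_ridge_fit(Xs, ys, groups, roi_labels=roi_labels,
                                     outcome_label=name,
                                     residualized_on=resid_on,
                                     **ridge_kwargs)
    return axes


def axis_expression(axis: AxisMap, conn, subject=None, epoch="") -> AxisScore:
    """Pearson correlation between an axis map and a connectivity profile."""
    beta = np.asarray(axis.beta, dtype=float)
    v = np.asarray(conn, dtype=float)
    if beta.shape != v.shape:
        raise ValueError("ROI order/length mismatch between axis and profile")
    if beta.std() == 0 or v.std() == 0:
        warnings.warn("zero-variance vector in axis expression: score 0")
        return AxisScore(subject, epoch, 0.0, degenerate=True)
    r = float(np.corrcoef(beta, v)[0, 1])
    return AxisScore(subject, epoch, r)


def alignment_axis(explicit: AxisMap, implicit: AxisMap) -> np.ndarray:
    """Explicit-alignment summary axis: rank(beta_exp) - rank(beta_imp).

    Average ranks on ties; positive values mark ROIs loading relatively
    more on the explicit than the implicit axis.
    """
    if list(explicit.roi_labels) != list(implicit.roi_labels):
        raise ValueError("axes are defined on different ROI sets")
    re = stats.rankdata(explicit.beta, method="average")
    ri = stats.rankdata(implicit.beta, method="average")
    return re - ri


def cross_task_correlation(scores, rates):
    """Pearson correlation between axis-expression scores and learning rates.

    Returns (r, t, p) with t = r sqrt((n-2)/(1-r^2)) and a two-sided p
    from the t distribution with n-2 degrees of freedom.
    """
    s = np.asarray(scores, dtype=float)
    k = np.asarray(rates, dtype=float)
    if s.shape != k.shape or s.ndim != 1:
        raise ValueError("scores and rates must be 1-D of equal length")
    n = s.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if s.std() == 0 or k.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(s, k)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p)
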