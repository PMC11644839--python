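"""Covariance estimation and Riemannian centering of SPD matrices.

Functional connectivity is dominated by stable subject-level differences
in covariance that can swamp task-related modulation.  The remedy used
here treats covariance matrices as points on the manifold of symmetric
positive-definite (SPD) matrices under the affine-invariant metric:
each subject's epoch covariances S_ij are projected onto the tangent
space at the subject's own Karcher mean S̄_i,

    T_ij = S̄_i^{1/2} log(S̄_i^{-1/2} S_ij S̄_i^{-1/2}) S̄_i^{1/2},

and the tangent vectors are then parallel-transported to the grand mean
S̄ via T_ij^c = G T_ij G' with G = S̄^{1/2} S̄_i^{-1/2}.  The centered
tangent vectors encode within-subject covariance differences expressed
at a common base point, from which seed-connectivity profiles are read
out row-wise.

Epoch covariances are estimated with the Ledoit-Wolf shrinkage
estimator (sample covariance blended with a scaled identity at the
analytically optimal intensity), which is well-conditioned even when
the number of regions exceeds the number of volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

SYM_TOL = 1e-10


def _as_values(S):
    return S.values if isinstance(S, (SpdMatrix, TangentVector)) else np.asarray(S, dtype=float)


def _check_symmetric(a, tol=SYM_TOL, what="matrix"):
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(a, a.T, atol=tol * max(1.0, np.abs(a).max())):
        raise ValueError(f"{what} is not symmetric")


@dataclass
class SpdMatrix:
    """A symmetric positive-definite matrix with optional ROI labels."""
    values: np.ndarray
    labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_symmetric(self.values, what="SpdMatrix")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TangentVector:
    """A symmetric matrix living in the tangent space at ``base``."""
    values: np.ndarray
    base: str = "grand_mean"
    labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_symmetric(self.values, what="TangentVector")
        self.values = 0.5 * (self.values + self.values.T)


def ledoit_wolf_cov(epoch, labels=None, return_shrinkage: bool = False):
    """Ledoit-Wolf shrinkage covariance of a (volumes x regions) matrix.

    Implements the optimal shrinkage toward the scaled identity mu*I
    directly: with S the (biased, /n) sample covariance of the demeaned
    data, mu = tr(S)/p,

        d^2 = ||S - mu I||_F^2 / p
        b̄^2 = (sum_k ||x_k||^4 - n ||S||_F^2) / (n^2 p)
        shrinkage = min(b̄^2, d^2) / d^2

    and the estimate is shrinkage*mu*I + (1-shrinkage)*S.
    """
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 volumes")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    var = Xc.var(axis=0)
    if np.any(var <= 0):
        warnings.warn("constant column(s) in timecourse: jitter applied")
        jit = 1e-6 * max(1.0, np.sqrt(var.max()))
        rng = np.random.default_rng(0)
        Xc = Xc + jit * rng.standard_normal(Xc.shape)
    S = (Xc.T @ Xc) / n
    mu = np.trace(S) / p
    d2 = np.sum((S - mu * np.eye(p)) ** 2) / p
    if d2 <= 0:
        shrinkage = 0.0
        est = S + 1e-12 * np.eye(p)
    else:
        sq_norms = np.sum(Xc**2, axis=1)
        b2_bar = (np.sum(sq_norms**2) - n * np.sum(S**2)) / (n**2 * p)
        b2 = min(b2_bar, d2)
        shrinkage = b2 / d2
        est = shrinkage * mu * np.eye(p) + (1.0 - shrinkage) * S
    out = SpdMatrix(est, labels)
    return (out, float(shrinkage)) if return_shrinkage else out


def _eigh_checked(S, floor=1e-12, require_pd=True):
    vals, vecs = np.linalg.eigh(S)
    if require_pd and vals.min() <= floor:
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {vals.min():.3g}); "
            "upstream covariance estimation likely failed")
    return vals, vecs


def _spd_fun(S, fun, require_pd=True):
    a = _as_values(S)
    _check_symmetric(a)
    vals, vecs = _eigh_checked(a, require_pd=require_pd)
    out = (vecs * fun(vals)) @ vecs.T
    return 0.5 * (out + out.T)


def spd_sqrt(S):
    """Principal matrix square root of an SPD matrix."""
    return _spd_fun(S, np.sqrt)


def spd_invsqrt(S):
    """Inverse principal square root of an SPD matrix."""
    return _spd_fun(S, lambda v: 1.0 / np.sqrt(v))


def spd_log(S):
    """Principal matrix logarithm of an SPD matrix."""
    return _spd_fun(S, np.log)


def spd_exp(S):
    """Matrix exponential of a symmetric matrix (always SPD)."""
    return _spd_fun(S, np.exp, require_pd=False)


def _batched_log(mats):
    """Matrix logarithm of a stack (k, p, p) of SPD matrices."""
    vals, vecs = np.linalg.eigh(mats)
    if vals.min() <= 1e-12:
        raise ValueError("non-PD matrix in batch (min eigenvalue "
                         f"{vals.min():.3g})")
    return (vecs * np.log(vals)[:, None, :]) @ np.transpose(vecs, (0, 2, 1))


def karcher_mean(mats, tol: float = 1e-8, max_iter: int = 100) -> SpdMatrix:
    """Karcher (Fréchet) mean of SPD matrices under the affine metric.

    Fixed-point iteration M <- M^{1/2} exp(mean_i log(M^{-1/2} S_i
    M^{-1/2})) M^{1/2}; converged when the Frobenius norm of the mean
    tangent residual falls below ``tol``.
    """
    arrs = [_as_values(m) for m in mats]
    if len(arrs) == 0:
        raise ValueError("karcher_mean of empty collection")
    p = arrs[0].shape[0]
    if any(a.shape != (p, p) for a in arrs):
        raise ValueError("matrices must share a common dimension")
    stack = np.stack(arrs)
    labels = getattr(mats[0], "labels", None)
    if len(arrs) == 1:
        return SpdMatrix(arrs[0], labels)
    M = stack.mean(axis=0)
    residual = np.inf
    for _ in range(max_iter):
        Ms = spd_sqrt(M)
        Mis = spd_invsqrt(M)
        whitened = Mis @ stack @ Mis
        whitened = 0.5 * (whitened + np.transpose(whitened, (0, 2, 1)))
        W = _batched_log(whitened).mean(axis=0)
        W = 0.5 * (W + W.T)
        residual = float(np.linalg.norm(W))
        if residual < tol:
            return SpdMatrix(M, labels)
        M = Ms @ spd_exp(W) @ Ms
        M = 0.5 * (M + M.T)
    raise RuntimeError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(residual {residual:.3g})")


def tangent_project(S, base) -> TangentVector:
    """Project an SPD matrix onto the tangent space at ``base``.

    T = base^{1/2} log(base^{-1/2} S base^{-1/2}) base^{1/2}.
    """
    a, b = _as_values(S), _as_values(base)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch between matrix and base")
    Bs, Bis = spd_sqrt(b), spd_invsqrt(b)
    T = Bs @ spd_log(Bis @ a @ Bis) @ Bs
    return TangentVector(0.5 * (T + T.T),
                         labels=getattr(S, "labels", None))


def tangent_retract(T, base) -> SpdMatrix:
    """Inverse of ``tangent_project``: map a tangent vector back to the manifold."""
    t, b = _as_values(T), _as_values(base)
    Bs, Bis = spd_sqrt(b), spd_invsqrt(b)
    S = Bs @ spd_exp(Bis @ t @ Bis) @ Bs
    return SpdMatrix(0.5 * (S + S.T), getattr(T, "labels", None))


def parallel_transport(T, from_base, to_base) -> TangentVector:
    """Transport a tangent vector between base points: G T G' with
    G = to_base^{1/2} from_base^{-1/2}."""
    t = _as_values(T)
    f, g = _as_values(from_base), _as_values(to_base)
    if t.shape != f.shape or t.shape != g.shape:
        raise ValueError("dimension mismatch in parallel transport")
    G = spd_sqrt(g) @ spd_invsqrt(f)
    out = G @ t @ G.T
    return TangentVector(0.5 * (out + out.T),
                         labels=getattr(T, "labels", None))


def center_cohort(covs: dict, tol: float = 1e-8, max_iter: int = 100) -> dict:
    """Center per-subject, per-condition covariances at the grand mean.

    ``covs`` maps subject -> {condition -> SpdMatrix}.  For each subject
    the Karcher mean S̄_i over that subject's conditions is computed, and
    the grand mean S̄ over all matrices; each S_ij is projected onto the
    tangent space at S̄_i and transported to S̄.  Returns the same nested
    mapping with ``TangentVector`` values (base = grand mean).  The grand
    mean is returned under the key ``"_grand_mean"``.
    """
    if not covs:
        raise ValueError("empty cohort")
    all_mats = [m for conds in covs.values() for m in conds.values()]
    try:
        grand = karcher_mean(all_mats, tol=tol, max_iter=max_iter)
    except Exception as e:
        raise RuntimeError(f"grand-mean estimation failed: {e}") from e
    out = {"_grand_mean": grand}
    for subj, conds in covs.items():
        if len(conds) == 0:
            raise ValueError(f"subject {subj!r} has no conditions")
        try:
            subj_mean = karcher_mean(list(conds.values()),
                                     tol=tol, max_iter=max_iter)
            centered = {}
            for cond, S in conds.items():
                T = tangent_project(S, subj_mean)
                centered[cond] = parallel_transport(T, subj_mean, grand)
        except Exception as e:
            raise RuntimeError(
                f"centering failed for subject {subj!r}, "
                f"condition {cond!r}: {e}") from e
        out[subj] = centered
    return out


def average_seed_signal(epoch, seed) -> np.ndarray:
    """Collapse the seed parcels of a timecourse into one averaged column.

    Variant of the seed readout in which the seed node is the averaged
    parcel signal computed *before* covariance estimation (the default
    pipeline instead row-averages the centered tangent matrix over the
    seed parcels; see ``seed_connectivity``).  Returns a (volumes x
    (p - |seed| + 1)) matrix with the averaged seed signal as the first
    column, followed by the non-seed columns in order.
    """
    X = np.asarray(epoch, dtype=float)
    p = X.shape[1]
    seed = np.asarray(sorted(set(int(s) for s in seed)), dtype=int)
    if seed.size == 0 or seed.size >= p:
        raise ValueError("seed must be a nonempty strict subset of columns")
    rest = np.setdiff1d(np.arange(p), seed)
    return np.column_stack([X[:, seed].mean(axis=1), X[:, rest]])


def equally_spaced_volumes(n_total: int, n_pick: int) -> np.ndarray:
    """Indices of ``n_pick`` volumes spread evenly over a scan.

    Rounded linear indexing, used to draw a fixed-length baseline epoch
    that covers the whole baseline scan.
    """
    if not (0 < n_pick <= n_total):
        raise ValueError("need 0 < n_pick <= n_total")
    idx = np.round(np.linspace(0, n_total - 1, n_pick)).astype(int)
    return idx


def seed_connectivity(T, seed) -> np.ndarray:
    """Mean tangent covariance between the seed rows and every other ROI.

    For each non-seed ROI r the entry is mean over s in ``seed`` of
    T[s, r]; seed ROIs themselves are excluded from the output.
    """
    t = _as_values(T)
    p = t.shape[0]
    seed = np.asarray(sorted(set(int(s) for s in seed)), dtype=int)
    if seed.size == 0:
        raise ValueError("seed set is empty")
    if seed.min() < 0 or seed.max() >= p:
        raise ValueError("seed index out of range")
    rest = np.setdiff1d(np.arange(p), seed)
    if rest.size == 0:
        raise ValueError("seed set covers all ROIs")
    return t[np.ix_(seed, rest)].mean(axis=0)
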