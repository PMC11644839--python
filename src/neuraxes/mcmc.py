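"""Random-walk MCMC with Haario-style adaptation, and split-chain R-hat.

The sampler is a plain multivariate Gaussian random-walk Metropolis
algorithm whose proposal covariance is adapted during burn-in (empirical
posterior covariance scaled by 2.38^2/d, plus a Robbins-Monro global
scale steering acceptance toward ~0.28).  After burn-in the proposal is
frozen, so the retained draws form a valid Markov chain.
"""

from __future__ import annotations

import numpy as np

TARGET_ACCEPT = 0.28


def adaptive_metropolis(log_prob, x0, n_samples, n_burnin, rng,
                        init_scale=0.1, thin=1):
    """Run one adaptive random-walk Metropolis chain.

    Parameters
    ----------
    log_prob : callable
        Unnormalized log posterior density; may return -inf.
    x0 : array (d,)
        Initial state (must have finite log probability).
    n_samples : int
        Retained draws, including burn-in.
    n_burnin : int
        Number of initial retained draws during which the proposal adapts.
    rng : numpy.random.Generator
    thin : int
        Proposal updates per retained draw.  A random-walk proposal moves
        less per update than a gradient-based sampler, so several updates
        constitute one effective "sample" of comparable quality.

    Returns
    -------
    chain : array (n_samples, d)
    accept_rate : float  (proposal acceptance over the post-burn-in phase)
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = float(log_prob(x))
    if not np.isfinite(lp):
        raise ValueError("initial state has non-finite log probability")

    scale = np.asarray(init_scale, dtype=float) * np.ones(d)
    prop_chol = np.diag(scale)
    log_global = 0.0
    chain = np.empty((n_samples, d))
    n_acc_post = 0
    window_acc = 0
    window_prop = 0

    for i in range(n_samples):
        for _ in range(max(1, int(thin))):
            step = prop_chol @ rng.standard_normal(d)
            prop = x + np.exp(log_global) * step
            lp_prop = float(log_prob(prop))
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                window_acc += 1
                if i >= n_burnin:
                    n_acc_post += 1
            window_prop += 1
        chain[i] = x

        if i < n_burnin:
            # adapt every 50 retained draws once some history exists
            if (i + 1) % 50 == 0:
                rate = window_acc / max(1, window_prop)
                window_acc = window_prop = 0
                log_global += 0.5 * (rate - TARGET_ACCEPT)
                if i + 1 >= 150:
                    hist = chain[max(0, i - 1000):i + 1]
                    cov = np.cov(hist.T) + 1e-10 * np.eye(d)
                    try:
                        prop_chol = np.linalg.cholesky((2.38**2 / d) * cov)
                    except np.linalg.LinAlgError:
                        pass
        elif i == n_burnin:
            window_acc = window_prop = 0

    n_post = max(1, (n_samples - n_burnin) * max(1, int(thin)))
    return chain, n_acc_post / n_post


def split_rhat(chains):
    """Classic split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws) for one scalar parameter.
    Each chain is split in half, and the Gelman-Rubin statistic
    sqrt(((N-1)/N + B/(N*W)) ) is computed over the 2*m half-chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    m, n = chains.shape
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    nn = half
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = nn * means.var(ddof=1)
    if w <= 0:
        return 1.0  # all half-chains constant
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))
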