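"""Phylogenetic signal in continuous traits: Pagel's lambda by maximum likelihood.

Lambda multiplies the off-diagonal entries of the Brownian covariance matrix:
0 means the trait is independent of phylogeny, 1 means it fits Brownian
motion, and values slightly above 1 (up to the interpretability bound
``lam_max``) indicate trait similarity exceeding the Brownian expectation.
The mean and rate are profiled out analytically by GLS at each candidate
lambda, leaving a one-dimensional bounded likelihood search; significance is
a likelihood-ratio test against lambda = 0 on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance, lam_max, vcv

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class LambdaResult:
    lam_hat: float
    loglik_hat: float
    loglik0: float
    lr_stat: float
    p_value: float
    lam_bound: float

    def __str__(self) -> str:
        return (f"lambda = {self.lam_hat:.6f}  "
                f"LR = {self.lr_stat:.3f}  p = {self.p_value:.3g}")


def profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood of y ~ N(mu * 1, sigma2 * V) with mu, sigma2 profiled out.

    mu-hat and sigma2-hat have closed GLS forms at fixed V; sigma2 uses the
    ML divisor n.  Returns -inf when V is not positive definite.
    """
    n = len(y)
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ones = np.ones(n)
    Vi_y = linalg.cho_solve(cho, y, check_finite=False)
    Vi_1 = linalg.cho_solve(cho, ones, check_finite=False)
    mu = (ones @ Vi_y) / (ones @ Vi_1)
    r = y - mu
    sigma2 = r @ linalg.cho_solve(cho, r, check_finite=False) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * (_LOG_2PI + np.log(sigma2) + 1.0) + logdet)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return V


def lambda_ml(tree_or_cov, trait, tol: float = 1e-8) -> LambdaResult:
    """ML estimate of Pagel's lambda for one continuous trait.

    Parameters
    ----------
    tree_or_cov
        A rooted ``dendropy.Tree`` with branch lengths, or a precomputed
        :class:`PhyloCovariance`.
    trait
        Per-taxon values: a mapping/Series keyed by taxon label, or an array
        already in covariance taxon order.

    The search is a deterministic bounded scalar optimization on
    ``[0, lam_max]``; boundary candidates (0, 1, the bound) are always
    evaluated so a boundary optimum is never missed.
    """
    C = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) else vcv(tree_or_cov)
    if isinstance(trait, Mapping):
        y = np.asarray([trait[t] for t in C.taxa], dtype=float)
    elif hasattr(trait, "index") and hasattr(trait, "loc"):  # pandas Series
        y = np.asarray([trait.loc[t] for t in C.taxa], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != C.n:
            raise ValueError("trait length does not match covariance")
    if C.n < 4:
        raise ValueError("need at least 4 taxa to estimate lambda")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; lambda likelihood is degenerate")

    M = C.matrix
    bound = lam_max(C)
    hi = 2.0 if not np.isfinite(bound) else bound

    def nll(lam: float) -> float:
        return -profile_loglik(y, _lambda_cov(M, lam))

    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": tol})
    candidates = [0.0, min(1.0, hi), hi * (1.0 - 1e-12), float(res.x)]
    lls = [-nll(c) for c in candidates]
    best = int(np.argmax(lls))
    lam_hat, loglik_hat = candidates[best], lls[best]
    loglik0 = -nll(0.0)
    if not np.isfinite(loglik_hat) or not np.isfinite(loglik0):
        raise ValueError("singular covariance; cannot evaluate likelihood")
    lr = max(0.0, 2.0 * (loglik_hat - loglik0))
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaResult(lam_hat=float(lam_hat), loglik_hat=float(loglik_hat),
                        loglik0=float(loglik0), lr_stat=float(lr),
                        p_value=p, lam_bound=float(bound))
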