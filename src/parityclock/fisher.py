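"""Fisher information and the Cramer-Rao lower bound for p.

The information matrix of the Poisson-parity model is block structured:
the rate block is diagonal (sites are independent), with one cross term
per site coupling ``lambda_i`` to ``p``.  Profiling the rates out via the
Schur complement yields a closed-form lower bound on the variance of any
unbiased estimator of p, which the benchmark suite plots against the
empirical error of each estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .model import as_rate_array

__all__ = ["FisherBlocks", "fisher_information", "crb_p"]

_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class FisherBlocks:
    """Non-zero blocks of the (n+1) x (n+1) Fisher information matrix.

    Index convention: entries 0..n-1 are the site rates, entry n is p.
    ``diag_lambda[i]`` holds I[i, i]; ``cross[i]`` holds I[i, p] = I[p, i];
    ``info_pp`` holds I[p, p].  All remaining rate-rate off-diagonals are
    identically zero.
    """

    diag_lambda: np.ndarray
    cross: np.ndarray
    info_pp: float
    n: int

    def to_matrix(self) -> np.ndarray:
        """Assemble the dense (n+1) x (n+1) matrix (for small n)."""
        m = np.zeros((self.n + 1, self.n + 1))
        idx = np.arange(self.n)
        m[idx, idx] = self.diag_lambda
        m[idx, self.n] = self.cross
        m[self.n, idx] = self.cross
        m[self.n, self.n] = self.info_pp
        return m


def _validated(rates, p: float) -> np.ndarray:
    lam = as_rate_array(rates)
    if np.any(lam == 0):
        raise ContractError("Fisher information requires strictly positive rates")
    if not (np.isfinite(p) and p > 0):
        raise ContractError("p must be positive and finite")
    return lam


def fisher_information(rates, p: float) -> FisherBlocks:
    """Exact Fisher information blocks at (lambda, p).

    I[i, i] = 1/lambda_i + 4 p^2 / (e^{4 lambda_i p} - 1)
    I[i, p] = 4 p lambda_i / (e^{4 lambda_i p} - 1)
    I[p, p] = 4 sum_i lambda_i^2 / (e^{4 lambda_i p} - 1)

    ``e^{4 lambda p} - 1`` is evaluated with expm1 so that information is
    not lost at small lambda * p.
    """
    lam = _validated(rates, p)
    em = np.expm1(np.minimum(4.0 * lam * p, _EXP_CLAMP))
    diag = 1.0 / lam + 4.0 * p * p / em
    cross = 4.0 * p * lam / em
    ipp = 4.0 * float(np.sum(lam * lam / em))
    return FisherBlocks(diag_lambda=diag, cross=cross, info_pp=ipp, n=lam.size)


def crb_p(rates, p: float) -> float:
    """Cramer-Rao lower bound on Var(p_hat) for unbiased p_hat.

    Schur complement of the rate block:

        CRB = [ 4 sum_i lambda_i^2 / (e^{4 lambda_i p} - 1 + 4 p^2 lambda_i) ]^{-1}

    For equal rates lambda this reduces to
    ``(e^{4 lambda p} - 1 + 4 p^2 lambda) / (4 n lambda^2)``.
    """
    lam = _validated(rates, p)
    em = np.expm1(np.minimum(4.0 * lam * p, _EXP_CLAMP))
    denom = 4.0 * float(np.sum(lam * lam / (em + 4.0 * p * p * lam)))
    return 1.0 / denom
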