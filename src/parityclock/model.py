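"""Poisson-parity model of site-wise transition counts.

The model underlying every estimator in this package is the following.
Each alignment site ``i`` carries an unknown transition rate ``lambda_i``,
expressed in expected transitions per site per unit of total phylogeny edge
length (all tree edges normalised to sum to one).  Two observations exist
per site:

* ``X_i ~ Poisson(lambda_i)`` — the number of transitions annotated at the
  site across the entire reference phylogeny;
* ``Z_i`` — the parity of the latent count ``Y_i ~ Poisson(lambda_i * p)``
  of transitions separating two target sequences at scaled distance ``p``.
  Only the parity is observable, because a pairwise comparison cannot
  distinguish ``A -> G`` from ``A -> G -> A -> G``.

The parity of a Poisson variable with mean ``L`` is Bernoulli with success
probability ``(1 - exp(-2 L)) / 2``, which is what :func:`parity_prob`
computes.  The joint log-likelihood of ``(p, lambda)`` given ``(X, Z)`` is

    sum_i [ -lambda_i + X_i log lambda_i
            + log(1 + (-1)^{Z_i} exp(-2 lambda_i p)) ]

up to an additive constant ``-sum_i log X_i! - n log 2`` that does not
depend on the parameters and is omitted by :func:`log_likelihood`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

__all__ = [
    "SiteRates",
    "ParityProblem",
    "ModelParams",
    "parity_prob",
    "log_likelihood",
]


def as_rate_array(rates) -> np.ndarray:
    """Coerce ``rates`` (SiteRates or array-like) to a validated float array."""
    if isinstance(rates, SiteRates):
        return rates.values
    arr = np.asarray(rates, dtype=float)
    _check_rates(arr)
    return arr


def _check_rates(arr: np.ndarray) -> None:
    if arr.ndim != 1 or arr.size == 0:
        raise ContractError("rates must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ContractError("rates must be finite and non-negative")


@dataclass(frozen=True)
class SiteRates:
    """Vector of per-site Poisson transition rates.

    Units: expected transitions per site per unit of total phylogeny edge
    length.  Zero entries are permitted — they arise naturally from count
    tables with transition-free sites — but make any site with a positive
    count impossible.
    """

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        _check_rates(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class ParityProblem:
    """Paired per-site observations ``(X, Z)`` after any masking.

    ``counts`` are the phylogeny-wide transition counts X (non-negative
    integers); ``parity`` is the 0/1 mismatch indicator Z between the two
    target sequences.  ``site_index`` optionally retains the original
    1-based alignment coordinates of the surviving sites.
    """

    counts: np.ndarray
    parity: np.ndarray
    site_index: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.counts)
        z = np.asarray(self.parity)
        if x.ndim != 1 or z.ndim != 1 or x.size != z.size or x.size == 0:
            raise ContractError("counts and parity must be non-empty vectors of equal length")
        if not np.issubdtype(x.dtype, np.integer):
            xf = np.asarray(x, dtype=float)
            if np.any(xf != np.floor(xf)):
                raise ContractError("counts must be integers")
            x = xf.astype(np.int64)
        if np.any(x < 0):
            raise ContractError("counts must be non-negative")
        z = np.asarray(z, dtype=np.int8)
        if not np.all((z == 0) | (z == 1)):
            raise ContractError("parity entries must be 0 or 1")
        x = np.ascontiguousarray(x, dtype=np.int64)
        x.setflags(write=False)
        z.setflags(write=False)
        object.__setattr__(self, "counts", x)
        object.__setattr__(self, "parity", z)
        if self.site_index is not None:
            si = np.asarray(self.site_index, dtype=np.int64)
            if si.size != x.size:
                raise ContractError("site_index length must match counts")
            si.setflags(write=False)
            object.__setattr__(self, "site_index", si)

    @property
    def n(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class ModelParams:
    """A point ``(p, lambda)`` in parameter space."""

    p: float
    rates: SiteRates = field(repr=False)

    def __post_init__(self):
        if not np.isfinite(self.p) or self.p < 0:
            raise ContractError("p must be finite and non-negative")
        if not isinstance(self.rates, SiteRates):
            object.__setattr__(self, "rates", SiteRates(self.rates))


def parity_prob(lam_times_p):
    """P(Z = 1) for the parity Z of a Poisson variable with mean ``lam_times_p``.

    Equals ``(1 - exp(-2 * lam_times_p)) / 2``; strictly increasing, with
    range [0, 1/2).  Accepts scalars or arrays.
    """
    arr = np.asarray(lam_times_p, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
        raise ContractError("lam_times_p must be finite and non-negative")
    out = -0.5 * np.expm1(-2.0 * arr)
    if np.ndim(lam_times_p) == 0:
        return float(out)
    return out


def _site_loglik_terms(x: np.ndarray, z: np.ndarray, lam: np.ndarray, p: float) -> np.ndarray:
    """Per-site log-likelihood terms, constants dropped.

    Vectorised over sites; ``-inf`` is produced for impossible
    configurations (``lambda_i = 0`` with ``X_i > 0``, or odd parity with
    ``lambda_i * p = 0``).
    """
    lam = np.asarray(lam, dtype=float)
    x = np.asarray(x)
    z = np.asarray(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        count_term = -lam + np.where(x > 0, x * np.log(lam), 0.0)
    lp = lam * p
    even = np.log1p(np.exp(-2.0 * lp))
    with np.errstate(divide="ignore"):
        odd = np.where(lp > 0, np.log(np.maximum(-np.expm1(-2.0 * lp), 0.0)), -np.inf)
    return count_term + np.where(z == 1, odd, even)


def log_likelihood(problem: ParityProblem, params: ModelParams) -> float:
    """Joint log-likelihood of ``(p, lambda)`` given ``(X, Z)``.

    The additive constant ``-sum_i log X_i! - n log 2`` is omitted: all
    comparisons in this package are over a fixed observed X, so rankings
    (and hence all estimators) are unaffected.  Returns ``-inf`` for
    zero-likelihood configurations.
    """
    lam = as_rate_array(params.rates)
    if lam.size != problem.n:
        raise ContractError(
            f"rates have length {lam.size} but problem has {problem.n} sites"
        )
    terms = _site_loglik_terms(problem.counts, problem.parity, lam, params.p)
    if np.any(np.isneginf(terms)):
        return float("-inf")
    return float(np.sum(terms))
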