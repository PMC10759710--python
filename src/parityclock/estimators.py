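"""Three estimators of the scaled distance ``p`` from ``(X, Z)``.

* :func:`fit_mle` — joint maximum likelihood over ``(p, lambda)``.  A grid
  sweep over ``p`` profiles out the site rates: at each candidate ``p`` the
  per-site stationarity equation is solved numerically for ``lambda_i``,
  and the profiled log-likelihood is maximised with one local refinement
  pass around the best grid point.
* :func:`fit_conditional` — estimates each ``lambda_i`` from ``X_i`` alone
  and treats the transitions along the target pair as a binomial
  sub-sample of the phylogeny's: ``Y_i | X_i ~ Bin(X_i, p)``.  The
  aggregated score equation ``sum_i (1 - 2p)^{X_i} = n - 2 sum_i Z_i`` is
  solved by bracketed root finding on [0, 1/2).  The aggregation (a
  Poisson approximation to the sum of per-site Bernoullis, per Le Cam's
  theorem) removes the need to special-case sites with ``X_i = 0``,
  ``Z_i = 1``.
* :func:`fit_gamma_map` — places a conjugate Gamma(alpha, beta) prior on
  the rates (rate convention: mean alpha/beta), integrates them out, and
  maximises the marginal log-posterior of ``p`` under a flat prior on p.
  Hyperparameters are fitted from the counts by intercept-only
  Negative-Binomial maximum likelihood (:func:`fit_nb_prior`), since the
  Gamma-Poisson mixture of the counts is exactly Negative Binomial.

All estimators return a :class:`DistanceEstimate`; the scaled distance is
a fraction of the total phylogeny edge length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import ContractError, ConvergenceError, EstimationError
from .model import ParityProblem, _site_loglik_terms

__all__ = [
    "DistanceEstimate",
    "GammaPrior",
    "GridSpec",
    "solve_site_rate",
    "fit_mle",
    "fit_conditional",
    "fit_nb_prior",
    "fit_gamma_map",
    "estimate",
]

#: clamp applied to exponents before exponentiation to avoid overflow
_EXP_CLAMP = 700.0


@dataclass
class DistanceEstimate:
    """Result of a distance estimation.

    ``p_hat`` is the scaled distance (fraction of total phylogeny edge
    length); ``objective`` is the final log-likelihood (mle, conditional)
    or marginal log-posterior (gamma_map) at ``p_hat``, additive constants
    dropped.  ``boundary_hit`` flags an estimate clamped to the edge of
    its admissible range, in which case ``converged`` is False.
    """

    p_hat: float
    method: str
    converged: bool
    objective: float
    lambda_hat: np.ndarray | None = None
    boundary_hit: bool = False
    sd_boot: float | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior on site rates, rate convention (mean = alpha / beta)."""

    alpha: float
    beta: float
    underdispersed: bool = False

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ContractError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the joint MLE sweep over p.

    The default covers [1e-4, 1] on a log scale with 200 points; observed
    uncalibrated distances for hominin mtDNA pairs fall around 0.008-0.12,
    comfortably interior to this range.
    """

    p_min: float = 1e-4
    p_max: float = 1.0
    n_points: int = 200
    scale: str = "log"

    def __post_init__(self):
        if not (0 < self.p_min < self.p_max):
            raise ContractError("require 0 < p_min < p_max")
        if self.n_points < 2:
            raise ContractError("n_points must be >= 2")
        if self.scale not in ("log", "linear"):
            raise ContractError("scale must be 'log' or 'linear'")

    def points(self) -> np.ndarray:
        if self.scale == "log":
            return np.geomspace(self.p_min, self.p_max, self.n_points)
        return np.linspace(self.p_min, self.p_max, self.n_points)


# ---------------------------------------------------------------------------
# Method 1: joint maximum likelihood


def _stationarity_gap(lam, x, z, p):
    """g(lam) = lam + 2 p lam / ((-1)^z e^{2 lam p} + 1) - x, vectorised.

    Zeros of g are stationary points of the per-site log-likelihood in
    lambda at fixed p.  Stable at lam -> 0 (the odd-parity branch tends to
    -1 - x) and at large lam * p (the correction term vanishes).
    """
    lam = np.asarray(lam, dtype=float)
    lp = 2.0 * p * lam
    em1 = np.expm1(np.minimum(lp, _EXP_CLAMP))
    even = 2.0 * p * lam / (em1 + 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        odd = np.where(lam > 0, -2.0 * p * lam / np.where(em1 > 0, em1, np.nan), -1.0)
    return lam + np.where(np.asarray(z) == 1, odd, even) - np.asarray(x, dtype=float)


def _solve_rates(x, z, p, iters: int = 72) -> np.ndarray:
    """Vectorised bisection for the per-site rate MLE at fixed p.

    Brackets: even parity roots lie in [x / (1 + 2p), x] (the correction
    term is at most p * lam); odd parity roots lie in (x, x + 1] because
    2 p lam / (e^{2 lam p} - 1) is in (0, 1).  ``p`` may be an array
    broadcasting against ``x`` (e.g. a grid column vector), in which case
    all grid points are solved simultaneously.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z)
    lo, hi = np.broadcast_arrays(
        np.where(z == 1, np.maximum(x, 1e-12), x / (1.0 + 2.0 * np.asarray(p))),
        np.where(z == 1, x + 1.0, x),
    )
    lo, hi = lo.copy(), hi.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        up = _stationarity_gap(mid, x, z, p) > 0.0
        hi = np.where(up, mid, hi)
        lo = np.where(up, lo, mid)
    out = 0.5 * (lo + hi)
    # even-parity sites with x == 0 have their maximum at lambda = 0
    return np.where((z == 0) & (x == 0), 0.0, out)


def solve_site_rate(x: int, z: int, p: float) -> float:
    """Rate MLE for one site at fixed p (stationary point in lambda).

    Solves ``x = lam + 2 p lam / ((-1)^z e^{2 lam p} + 1)``.  For
    ``x = 0, z = 1`` the solution has the closed form
    ``log(1 + 2p) / (2p)``.  ``x = 0, z = 0`` returns 0 (boundary maximum).
    """
    if not p > 0:
        raise ContractError("p must be positive")
    if x < 0 or z not in (0, 1):
        raise ContractError("x must be a non-negative integer and z in {0, 1}")
    lam = float(_solve_rates(np.array([x]), np.array([z]), p)[0])
    if not (x == 0 and z == 0):
        gap = float(_stationarity_gap(np.array([lam]), np.array([x]), np.array([z]), p)[0])
        if not abs(gap) < 1e-6 * max(1.0, x):
            raise ConvergenceError(
                f"site-rate solve failed: x={x} z={z} p={p} lam={lam} residual={gap}"
            )
    return lam


def _unique_pairs(problem: ParityProblem):
    """Collapse sites to unique (x, z) pairs with multiplicities.

    Counts are small integers, so the number of distinct pairs is tiny
    compared with n; every per-grid-point solve then costs O(#pairs).
    """
    key = np.stack([problem.counts, problem.parity.astype(np.int64)])
    uniq, inverse, mult = np.unique(key, axis=1, return_inverse=True, return_counts=True)
    return uniq[0], uniq[1], mult, inverse


def fit_mle(problem: ParityProblem, grid: GridSpec | None = None) -> DistanceEstimate:
    """Joint MLE of (p, lambda) by profile grid search plus local refinement.

    At the returned optimum the rate estimates satisfy
    ``sum_i lambda_hat_i ~= sum_i X_i`` and, when p_hat is interior, the
    score in p vanishes; both residuals are reported in ``diagnostics``.
    """
    if grid is None:
        grid = GridSpec()
    if not np.any(problem.counts > 0):
        raise EstimationError("all counts are zero: site rates are unidentifiable")
    xu, zu, mult, inverse = _unique_pairs(problem)

    def profile(p: float):
        lam_u = _solve_rates(xu, zu, p)
        ll = float(np.sum(mult * _site_loglik_terms(xu, zu, lam_u, p)))
        return ll, lam_u

    ps = grid.points()
    # solve all grid points simultaneously: shape (n_grid, n_unique_pairs)
    lam_grid = _solve_rates(xu, zu, ps[:, None])
    lls = np.sum(mult * _site_loglik_terms(xu, zu, lam_grid, ps[:, None]), axis=-1)
    i = int(np.argmax(lls))
    lo, hi = ps[max(i - 1, 0)], ps[min(i + 1, len(ps) - 1)]
    best_p, best_ll = ps[i], lls[i]
    refined = False
    if hi > lo:
        res = minimize_scalar(
            lambda q: -profile(q)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and -res.fun >= best_ll:
            best_p, best_ll = float(res.x), float(-res.fun)
            refined = True
    lam_u = _solve_rates(xu, zu, best_p)
    lam_hat = lam_u[inverse]
    boundary = bool(best_p <= ps[0] * (1 + 1e-6) or best_p >= ps[-1] * (1 - 1e-6))
    total_x = float(problem.counts.sum())
    rate_gap = float(abs(lam_hat.sum() - total_x)) / max(total_x, 1.0)
    lp = 2.0 * best_p * lam_u
    em1 = np.expm1(np.minimum(lp, _EXP_CLAMP))
    sgn = 1.0 - 2.0 * zu.astype(float)
    with np.errstate(divide="ignore"):
        score_terms = np.where(lam_u > 0, lam_u / (sgn * (em1 + 1.0) + 1.0), 0.0)
    score = float(np.sum(mult * score_terms))
    return DistanceEstimate(
        p_hat=float(best_p),
        method="mle",
        converged=bool(refined and not boundary),
        objective=best_ll,
        lambda_hat=lam_hat,
        boundary_hit=boundary,
        diagnostics={"rate_sum_gap": rate_gap, "p_score": score},
    )


# ---------------------------------------------------------------------------
# Method 2: rate-conditional estimation


def fit_conditional(problem: ParityProblem) -> DistanceEstimate:
    """Parity-conditional estimator of p on [0, 1/2).

    Solves ``sum_i (1 - 2p)^{X_i} = n - 2 sum_i Z_i`` by bisection; the
    left side is non-increasing in p, which guarantees a bracket.  The
    binomial-thinning construction is only a valid probability model for
    p < 1/2, so estimates that would exceed it are clamped just inside the
    boundary with ``boundary_hit`` set (and a warning).
    """
    x = problem.counts
    z = problem.parity
    n = problem.n
    total_z = int(z.sum())
    xu, mult = np.unique(x, return_counts=True)
    target = float(n - 2 * total_z)

    def lhs(p: float) -> float:
        return float(np.sum(mult * np.power(1.0 - 2.0 * p, xu)))

    hi = 0.5 - 1e-9
    if total_z == 0:
        p_hat, boundary = 0.0, False
    else:
        f0, fhi = lhs(0.0) - target, lhs(hi) - target
        assert f0 >= fhi - 1e-9, "conditional score must be non-increasing in p"
        if fhi > 0:
            warnings.warn(
                "parity fraction too high for the conditional model; "
                "estimate clamped below 1/2",
                RuntimeWarning,
                stacklevel=2,
            )
            p_hat, boundary = hi, True
        else:
            p_hat = float(brentq(lambda p: lhs(p) - target, 0.0, hi, xtol=1e-12))
            boundary = False
    # conditional log-likelihood of Z given X at p_hat (for diagnostics)
    prob1 = 0.5 * (1.0 - np.power(1.0 - 2.0 * min(p_hat, hi), x))
    with np.errstate(divide="ignore"):
        obj = float(np.sum(np.where(z == 1, np.log(prob1), np.log1p(-prob1))))
    return DistanceEstimate(
        p_hat=p_hat,
        method="conditional",
        converged=not boundary,
        objective=obj,
        boundary_hit=boundary,
    )


# ---------------------------------------------------------------------------
# Method 3: Gamma-prior MAP


def fit_nb_prior(counts, clamp_beta: float = 1e6) -> GammaPrior:
    """Fit Gamma(alpha, beta) rate hyperparameters from phylogeny counts.

    Under the Gamma prior the counts are marginally Negative Binomial with
    size alpha and success probability beta / (beta + 1), i.e.
    ``E X = alpha / beta`` and ``Var X = alpha / beta + alpha / beta**2``.
    The fit is intercept-only NB-2 maximum likelihood via statsmodels;
    underdispersed counts (variance <= mean, outside the NB family) fall
    back to a large-beta clamp preserving the mean, with a warning.
    """
    x = np.asarray(counts)
    if x.ndim != 1 or x.size < 2:
        raise ContractError("counts must be a vector with at least two entries")
    if np.any(x < 0):
        raise ContractError("counts must be non-negative")
    if np.unique(x).size < 2:
        raise ContractError("counts must take at least two distinct values")
    x = x.astype(float)
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if m <= 0:
        raise ContractError("counts must have a positive mean")
    if v <= m:
        warnings.warn(
            "counts are underdispersed relative to Poisson; "
            "returning a near-Poisson prior with clamped beta",
            RuntimeWarning,
            stacklevel=2,
        )
        return GammaPrior(alpha=m * clamp_beta, beta=clamp_beta, underdispersed=True)
    # method-of-moments start: var - mean = alpha / beta**2
    beta0 = m / (v - m)
    alpha0 = m * beta0
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(x, np.ones_like(x)).fit(
                start_params=[np.log(m), 1.0 / alpha0], disp=0, maxiter=200,
                method="bfgs",
            )
        mu = float(np.exp(res.params[0]))
        disp = float(res.params[1])  # Var = mu + disp * mu**2
        if disp <= 0 or not np.isfinite(disp) or not np.isfinite(mu):
            raise FloatingPointError("NB dispersion fit did not converge")
        alpha = 1.0 / disp
        beta = alpha / mu
    except Exception:  # pragma: no cover - exercised only on pathological data
        warnings.warn(
            "Negative-Binomial ML fit failed; falling back to method of moments",
            RuntimeWarning,
            stacklevel=2,
        )
        alpha, beta = alpha0, beta0
    return GammaPrior(alpha=float(alpha), beta=float(beta))


def _map_objective(p, xu, zu, mult, alpha: float, beta: float):
    """Marginal log-posterior of p (constants dropped), aggregated over
    unique (x, z) pairs.

    Integrating lambda_i out against its Gamma(alpha + X_i, beta + 1)
    posterior gives E[e^{-2 lam p} | X_i] = (1 + 2p / (beta + 1))^{-(X_i + alpha)},
    hence l(p) = sum_i log(1 + (-1)^{Z_i} (1 + 2p/(beta+1))^{-(X_i+alpha)}).
    """
    expo = -(xu + alpha) * np.log1p(2.0 * p / (beta + 1.0))
    q = np.exp(np.maximum(expo, -_EXP_CLAMP))
    sgn = 1.0 - 2.0 * zu.astype(float)
    with np.errstate(divide="ignore"):
        vals = np.log1p(sgn * q)
    return float(np.sum(mult * vals))


def _map_score(p, xu, zu, mult, alpha: float, beta: float):
    """Stationarity sum: zero at interior maxima of the marginal posterior.

    Differentiating the marginal objective shows its stationary points
    solve ``sum_i (X_i + alpha) / ((-1)^{Z_i} (1 + 2p/(beta+1))^{X_i+alpha} + 1) = 0``.
    """
    expo = np.minimum((xu + alpha) * np.log1p(2.0 * p / (beta + 1.0)), _EXP_CLAMP)
    grown = np.exp(expo)
    sgn = 1.0 - 2.0 * zu.astype(float)
    return float(np.sum(mult * (xu + alpha) / (sgn * grown + 1.0)))


def fit_gamma_map(
    problem: ParityProblem,
    prior: GammaPrior,
    p_max: float = 20.0,
    n_grid: int = 600,
) -> DistanceEstimate:
    """MAP estimator of p under a Gamma rate prior and flat prior on p.

    Maximises the closed-form marginal objective on [0, p_max] by a coarse
    log-grid sweep plus bounded refinement.  The score equation is
    singular at p = 0 for odd-parity sites, so maximisation (rather than
    root finding) is used; the stationarity residual at the returned
    estimate is reported in ``diagnostics['score']``.
    """
    if p_max <= 0:
        raise ContractError("p_max must be positive")
    xu, zu, mult, _ = _unique_pairs(problem)
    a, b = prior.alpha, prior.beta
    if int(problem.parity.sum()) == 0:
        obj = _map_objective(0.0, xu, zu, mult, a, b)
        return DistanceEstimate(0.0, "gamma_map", True, obj,
                                diagnostics={"score": np.nan})
    ps = np.geomspace(1e-8, p_max, n_grid)
    objs = np.array([_map_objective(p, xu, zu, mult, a, b) for p in ps])
    i = int(np.argmax(objs))
    lo, hi = ps[max(i - 1, 0)], ps[min(i + 1, len(ps) - 1)]
    res = minimize_scalar(
        lambda q: -_map_objective(q, xu, zu, mult, a, b),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-12},
    )
    p_hat, obj = float(res.x), float(-res.fun)
    if objs[i] > obj:
        p_hat, obj = float(ps[i]), float(objs[i])
    boundary = bool(p_hat >= p_max * (1 - 1e-6))
    score = _map_score(p_hat, xu, zu, mult, a, b)
    return DistanceEstimate(
        p_hat=p_hat,
        method="gamma_map",
        converged=bool(res.success and not boundary),
        objective=obj,
        boundary_hit=boundary,
        diagnostics={"score": score, "prior": (a, b)},
    )


# ---------------------------------------------------------------------------
# dispatch

_METHODS = ("mle", "conditional", "gamma_map")


def estimate(problem: ParityProblem, method: str = "conditional", **options) -> DistanceEstimate:
    """Run one of the three estimators by name.

    ``method`` is one of ``'mle'`` (accepts ``grid=``), ``'conditional'``,
    or ``'gamma_map'`` (accepts ``prior=`` and ``p_max=``; the prior is
    fitted from the problem's own counts when not supplied).
    """
    if method == "mle":
        return fit_mle(problem, grid=options.get("grid"))
    if method == "conditional":
        return fit_conditional(problem)
    if method == "gamma_map":
        prior = options.get("prior") or fit_nb_prior(problem.counts)
        kw = {}
        if "p_max" in options:
            kw["p_max"] = options["p_max"]
        return fit_gamma_map(problem, prior, **kw)
    raise ContractError(f"unknown method {method!r}; choose from {_METHODS}")
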