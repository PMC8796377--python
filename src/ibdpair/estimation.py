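"""Maximum-likelihood estimation of (k0, k1, k2, alpha).

The simplex constraint on R = (k0, k1, k2) and the positivity of alpha are
removed by a reparametrisation — two logits for R (softmax with state 0 as
reference) and log(alpha) — after which the log-likelihood is maximised by
BFGS with central-difference gradients.  Because the likelihood surface can
be multimodal near the simplex boundary, the optimiser is restarted from a
panel of canonical relationship configurations and the best optimum kept.

Any of k0, k1, k2 or alpha may be held fixed; the free part of the simplex
is then reparametrised accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ibd_model import PARAM_FLOOR, PairGL, RelatednessParams, SiteTable, emission_matrix
from .hmm_engine import log_likelihood

__all__ = ["FitResult", "transform", "inverse_transform", "fit"]

# Canonical start panel: parent-offspring, full siblings, half siblings,
# first cousins, unrelated — floored into the simplex interior.
START_K = (
    (0.0, 1.0, 0.0),
    (0.25, 0.5, 0.25),
    (0.5, 0.5, 0.0),
    (0.75, 0.25, 0.0),
    (1.0, 0.0, 0.0),
)
START_ALPHA = (0.01, 0.1, 1.0)


@dataclass
class FitResult:
    """Result of a maximum-likelihood fit.

    ``loglik_hat`` is the best log-likelihood across all restarts;
    ``params_hat`` the corresponding parameters.  ``start_points`` records
    the initial parameter sets actually optimised from.
    """

    params_hat: RelatednessParams
    loglik_hat: float
    n_restarts_used: int
    converged: bool
    start_points: list = field(default_factory=list)


def transform(params: RelatednessParams) -> np.ndarray:
    """Map valid parameters to an unconstrained 3-vector.

    Components: (log(k1/k0), log(k2/k0), log(alpha)).  Boundary k values
    are floored to keep the logits finite; the map is a bijection between
    the simplex interior x (0, inf) and R^3.
    """
    p = params.floored()
    return np.array(
        [np.log(p.k1 / p.k0), np.log(p.k2 / p.k0), np.log(p.alpha)]
    )


def inverse_transform(theta: np.ndarray) -> RelatednessParams:
    """Inverse of :func:`transform` (softmax over (0, t1, t2), exp for alpha)."""
    theta = np.asarray(theta, dtype=float)
    z = np.array([0.0, theta[0], theta[1]])
    z -= z.max()
    k = np.exp(z)
    k /= k.sum()
    return RelatednessParams(k[0], k[1], k[2], float(np.exp(theta[2])))


class _Parametrization:
    """Unconstrained coordinates for the free parameters under constraints.

    ``fixed`` maps any of 'k0', 'k1', 'k2', 'alpha' to fixed values.  The
    free k components are softmax-coded relative to the first free one; the
    fixed k mass is removed from the simplex first.
    """

    def __init__(self, fixed: dict[str, float] | None = None):
        fixed = dict(fixed or {})
        for key, val in fixed.items():
            if key not in ("k0", "k1", "k2", "alpha"):
                raise ValueError(f"unknown fixed parameter {key!r}")
            if key == "alpha" and val <= 0:
                raise ValueError("fixed alpha must be positive")
            if key != "alpha" and not 0 <= val <= 1:
                raise ValueError(f"fixed {key} must lie in [0, 1]")
        self.fixed = fixed
        self.free_k = [i for i in range(3) if f"k{i}" not in fixed]
        self.fixed_k_mass = sum(v for k, v in fixed.items() if k != "alpha")
        if self.fixed_k_mass > 1 + 1e-9:
            raise ValueError("fixed k components exceed the simplex")
        if not self.free_k and abs(self.fixed_k_mass - 1.0) > 1e-9:
            raise ValueError("all k fixed but do not sum to 1")
        self.alpha_free = "alpha" not in fixed
        # softmax over free k needs len(free_k) - 1 coordinates
        self.n_free = max(len(self.free_k) - 1, 0) + (1 if self.alpha_free else 0)

    def to_theta(self, params: RelatednessParams) -> np.ndarray:
        p = params.floored()
        k = p.k
        theta = []
        if len(self.free_k) >= 2:
            ref = max(k[self.free_k[0]], PARAM_FLOOR)
            for i in self.free_k[1:]:
                theta.append(np.log(max(k[i], PARAM_FLOOR) / ref))
        if self.alpha_free:
            theta.append(np.log(p.alpha))
        return np.array(theta)

    def from_theta(self, theta: np.ndarray) -> RelatednessParams:
        theta = np.asarray(theta, dtype=float)
        k = np.zeros(3)
        for i in range(3):
            if f"k{i}" in self.fixed:
                k[i] = self.fixed[f"k{i}"]
        free_mass = max(1.0 - self.fixed_k_mass, 0.0)
        nf = len(self.free_k)
        if nf == 1:
            k[self.free_k[0]] = free_mass
        elif nf >= 2:
            z = np.concatenate([[0.0], theta[: nf - 1]])
            z -= z.max()
            w = np.exp(z)
            w *= free_mass / w.sum()
            for i, idx in enumerate(self.free_k):
                k[idx] = w[i]
        alpha = (
            float(np.exp(theta[-1])) if self.alpha_free else self.fixed["alpha"]
        )
        k = np.maximum(k, PARAM_FLOOR)
        k /= k.sum()
        return RelatednessParams(k[0], k[1], k[2], max(alpha, PARAM_FLOOR))


def _central_diff_grad(fun, theta, step=1e-5):
    grad = np.empty_like(theta)
    for i in range(theta.size):
        up = theta.copy()
        dn = theta.copy()
        up[i] += step
        dn[i] -= step
        grad[i] = (fun(up) - fun(dn)) / (2 * step)
    return grad


def fit(
    pair: PairGL,
    sites: SiteTable,
    fixed: dict[str, float] | None = None,
    n_restarts: int = 3,
    n_random_restarts: int = 0,
    min_sites: int = 100,
    seed: int | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of (R, alpha) for one pair.

    The full start panel (five relationship configurations crossed with
    alpha in {0.01, 0.1, 1} per Morgan) is scored once; BFGS is run from
    the ``n_restarts`` best-scoring points (plus ``n_random_restarts``
    random draws) and the best optimum returned.

    Parameters
    ----------
    pair, sites :
        Aligned genotype likelihoods and site table.
    fixed :
        Optional mapping holding any of k0, k1, k2, alpha at fixed values.
    min_sites :
        Minimum number of sites required (ML on fewer is unreliable).
    seed :
        Seed for the random restarts, if any.

    Raises
    ------
    RuntimeError
        If no start point yields a finite likelihood or no restart
        converges to a finite optimum.
    """
    if len(sites) < min_sites:
        raise ValueError(
            f"need at least {min_sites} sites to fit, got {len(sites)}"
        )
    e = emission_matrix(pair, sites)
    par = _Parametrization(fixed)

    def negloglik(theta: np.ndarray) -> float:
        try:
            return -log_likelihood(e, sites, par.from_theta(theta))
        except FloatingPointError:
            return np.inf

    # score the full panel, keep the most promising starts
    panel = []
    for k in START_K:
        for a in START_ALPHA:
            p0 = RelatednessParams.from_k(np.asarray(k), a).floored()
            panel.append(p0)
    if n_random_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_random_restarts):
            k = rng.dirichlet(np.ones(3))
            a = float(np.exp(rng.uniform(np.log(0.01), np.log(30.0))))
            panel.append(RelatednessParams.from_k(k, a).floored())
    thetas = [par.to_theta(p) for p in panel]
    # deduplicate starts that collapse under the constraints
    uniq: dict[tuple, np.ndarray] = {}
    for th in thetas:
        uniq.setdefault(tuple(np.round(th, 10)), th)
    thetas = list(uniq.values())
    scores = np.array([negloglik(th) for th in thetas])
    if not np.any(np.isfinite(scores)):
        raise RuntimeError("likelihood is non-finite at every start point")
    order = np.argsort(scores)
    chosen = [thetas[i] for i in order[: max(n_restarts, 1)] if np.isfinite(scores[i])]

    best_theta = None
    best_val = np.inf
    converged = False
    starts_used = []
    for th0 in chosen:
        starts_used.append(par.from_theta(th0))
        if par.n_free == 0:
            val = negloglik(th0)
            if val < best_val:
                best_val, best_theta, converged = val, th0, True
            continue
        res = minimize(
            negloglik,
            th0,
            jac=lambda t: _central_diff_grad(negloglik, t),
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        start_val = negloglik(th0)
        val, cand = (res.fun, res.x) if res.fun <= start_val else (start_val, th0)
        if val < best_val and np.isfinite(val):
            best_val = val
            best_theta = cand
            converged = bool(res.success)
    if best_theta is None:
        raise RuntimeError(
            "optimisation failed from every start point; "
            f"panel scores: {scores[order][:5]}"
        )
    return FitResult(
        params_hat=par.from_theta(best_theta),
        loglik_hat=-best_val,
        n_restarts_used=len(chosen),
        converged=converged,
        start_points=starts_used,
    )
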