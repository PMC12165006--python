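"""IPW estimation of direct, spillover, total and overall effects.

Estimands are defined under counterfactual Bernoulli allocation strategies:
under coverage ``alpha`` every participant is independently assigned
treatment with probability ``alpha``.  Observed treatment vectors are
standardized to such a policy by weighting each community's outcomes with
the policy probability of its treatment vector divided by the community-level
propensity score f(A_i | X_i):

    direct    DE(a)        = Ybar(1; a) - Ybar(0; a)
    spillover SE(a, a')    = Ybar(0; a) - Ybar(0; a')
    total     TE(a, a')    = Ybar(1; a) - Ybar(0; a')
    overall   OE(a, a')    = Ybar(a) - Ybar(a')

with a > a' for the two-coverage contrasts.  Total = direct + spillover holds
identically by construction.

Standard errors come from an M-estimation sandwich with communities as the
independent units and the propensity-score estimating equations stacked with
the mean equations, so the uncertainty from estimating the weights is
propagated into the effect standard errors.  All probability products are
computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .propensity import (
    PropensityModel,
    _grouped,
    community_loglik,
)

__all__ = [
    "AllocationPolicy",
    "EffectEstimate",
    "CommunityWeight",
    "EffectsResult",
    "policy_prob",
    "policy_prob_excluding",
    "group_ipw_mean",
    "group_ipw_marginal",
    "population_means",
    "estimate_effects",
    "sandwich_variance",
    "community_weights",
    "trim_extreme",
]

Z_95 = 1.96  # Wald multiplier for 95% confidence intervals


@dataclass(frozen=True)
class AllocationPolicy:
    """Bernoulli allocation strategy: treat independently with prob alpha."""

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class EffectEstimate:
    effect: str                     # direct | spillover | total | overall
    alpha: float
    alpha_prime: float | None
    estimate: float
    se: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.ci_low = self.estimate - Z_95 * self.se
        self.ci_high = self.estimate + Z_95 * self.se


@dataclass
class CommunityWeight:
    community: int
    alpha: float
    weight: float


def _as_policy(policy) -> AllocationPolicy:
    return policy if isinstance(policy, AllocationPolicy) else AllocationPolicy(float(policy))


def _log_terms(a: np.ndarray, alpha: float) -> np.ndarray:
    return a * math.log(alpha) + (1.0 - a) * math.log1p(-alpha)


def policy_prob(a_vector: Sequence[int], policy) -> float:
    """Probability of a treatment vector under Bernoulli(alpha) allocation."""
    a = np.asarray(a_vector, float)
    if a.size == 0:
        raise ValueError("treatment vector must be non-empty")
    return float(np.exp(_log_terms(a, _as_policy(policy).alpha).sum()))


def policy_prob_excluding(a_vector: Sequence[int], j: int, policy) -> float:
    """Policy probability of the vector omitting position ``j`` (0-based).

    For a community of size 1 the empty product is 1.
    """
    a = np.asarray(a_vector, float)
    if not 0 <= j < a.size:
        raise IndexError(f"index {j} out of range for vector of length {a.size}")
    terms = _log_terms(a, _as_policy(policy).alpha)
    return float(np.exp(terms.sum() - terms[j]))


def group_ipw_mean(a, y, f_value: float, policy, arm: int) -> float:
    """Community IPW average potential outcome for treatment arm ``arm``.

    sum_j pi(A_{i,-j}; alpha) 1{A_ij = arm} Y_ij / (n_i f(A_i|X_i)).
    Communities with no member in the arm (or all zero outcomes) contribute 0.
    """
    a = np.asarray(a, float)
    y = np.asarray(y, float)
    if np.any(np.isnan(y)):
        raise ValueError("outcomes contain missing values; impute before estimation")
    if not f_value > 0.0:
        raise ValueError("community propensity must be positive")
    terms = _log_terms(a, _as_policy(policy).alpha)
    log_pi_excl = terms.sum() - terms  # leave-one-out policy probabilities
    sel = (a == arm).astype(float)
    return float(np.sum(np.exp(log_pi_excl - math.log(f_value)) * sel * y) / a.size)


def group_ipw_marginal(a, y, f_value: float, policy) -> float:
    """Community IPW marginal average outcome (full-vector policy weight)."""
    a = np.asarray(a, float)
    y = np.asarray(y, float)
    if np.any(np.isnan(y)):
        raise ValueError("outcomes contain missing values; impute before estimation")
    if not f_value > 0.0:
        raise ValueError("community propensity must be positive")
    log_pi = _log_terms(a, _as_policy(policy).alpha).sum()
    return float(np.exp(log_pi - math.log(f_value)) * y.sum() / a.size)


def population_means(group_values: Sequence[float]) -> float:
    """Unweighted average of community-level values across communities."""
    vals = np.asarray(list(group_values), float)
    if vals.size == 0:
        raise ValueError("no communities")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# weights and trimming


def community_weights(a_by_comm: Mapping[int, np.ndarray],
                      f_by_comm: Mapping[int, float],
                      policy) -> list[CommunityWeight]:
    """Community-level inverse probability weights pi(A_i; alpha) / f_i."""
    pol = _as_policy(policy)
    out = []
    for lab in sorted(a_by_comm):
        w = policy_prob(a_by_comm[lab], pol) / f_by_comm[lab]
        out.append(CommunityWeight(community=lab, alpha=pol.alpha, weight=float(w)))
    return out


def trim_extreme(weights: Iterable[CommunityWeight], low: float = 0.001,
                 high: float | None = None) -> set[int]:
    """Communities whose weight is not extreme at any supplied (alpha, weight)."""
    all_labels = {w.community for w in weights}
    flagged = {
        w.community
        for w in weights
        if w.weight < low or (high is not None and w.weight > high)
    }
    return all_labels - flagged


# ---------------------------------------------------------------------------
# sandwich variance


def sandwich_variance(
    psi: np.ndarray,
    scores: np.ndarray | None = None,
    bread_cross: np.ndarray | None = None,
    hessian: np.ndarray | None = None,
) -> np.ndarray:
    """M-estimation covariance of the target means from stacked equations.

    ``psi``: (N, T) mean-equation residuals Yhat_i - mu per community;
    ``scores``: (N, q) propensity-score estimating functions (omit when the
    propensity is known); ``bread_cross``: (T, q) block -mean d psi / d eta;
    ``hessian``: (q, q) second derivative of the total log likelihood.

    Returns the (T, T) covariance matrix of the estimated means.
    """
    n = psi.shape[0]
    if n < 2:
        raise ValueError("sandwich variance needs at least 2 communities")
    if scores is None:
        meat = psi.T @ psi / n
        return meat / n
    g = np.hstack([scores, psi])
    q, t = scores.shape[1], psi.shape[1]
    meat = g.T @ g / n
    bread = np.zeros((q + t, q + t))
    bread[:q, :q] = -hessian / n
    bread[q:, :q] = bread_cross
    bread[q:, q:] = np.eye(t)
    cond = np.linalg.cond(bread)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular bread matrix (condition number {cond:.3g})"
        )
    binv = np.linalg.inv(bread)
    v = binv @ meat @ binv.T / n
    return v[q:, q:]


# ---------------------------------------------------------------------------
# full estimation


@dataclass
class EffectsResult:
    estimates: list[EffectEstimate]
    means: dict                     # (kind, alpha) -> estimate, kind in {1,0,"marg"}
    mean_cov: np.ndarray
    weights: list[CommunityWeight]
    n_communities: int
    n_singletons_excluded: int
    excluded_communities: set = field(default_factory=set)

    def effect(self, name: str, alpha: float, alpha_prime: float | None = None):
        for e in self.estimates:
            if (e.effect == name and math.isclose(e.alpha, alpha)
                    and (alpha_prime is None or math.isclose(e.alpha_prime, alpha_prime))):
                return e
        raise KeyError((name, alpha, alpha_prime))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "alpha": e.alpha,
                    "alpha_prime": e.alpha_prime,
                    "estimate": e.estimate,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                for e in self.estimates
            ]
        )


def _validate_pairs(pairs):
    for alpha, alpha_p in pairs:
        if not alpha > alpha_p:
            raise ValueError(
                f"coverage pair must satisfy alpha > alpha_prime, got ({alpha}, {alpha_p})"
            )


def estimate_effects(
    network,
    structure,
    prop_model: PropensityModel | None,
    alphas: Sequence[float] = (0.20, 0.40, 0.60),
    alpha_pairs: Sequence[tuple[float, float]] = ((0.60, 0.20), (0.40, 0.20), (0.60, 0.40)),
    *,
    known_propensity: Mapping[int, float] | None = None,
    exclude_communities: Iterable[int] = (),
    n_quad: int | None = None,
    compute_se: bool = True,
) -> EffectsResult:
    """Estimate all four effects on the allocation grid with robust SEs.

    Singleton communities are excluded automatically (no spillover is
    possible in a community of one).  ``known_propensity`` maps community
    label to a fixed f value and bypasses the propensity-model uncertainty
    (used for simulations where the true treatment law is known);
    otherwise ``prop_model`` must be a converged fit and its estimating
    equations are stacked into the variance.
    """
    _validate_pairs(alpha_pairs)
    exclude = set(exclude_communities)

    records = [network.records[n] for n in sorted(network.records, key=str)]
    comms = structure.communities()
    keep_labels = sorted(
        lab for lab, members in comms.items() if len(members) > 1 and lab not in exclude
    )
    n_singletons = sum(1 for members in comms.values() if len(members) == 1)
    kept_nodes = {n for lab in keep_labels for n in comms[lab]}
    records = [r for r in records if r.id in kept_nodes]
    if any(r.outcome is None for r in records):
        raise ValueError("outcomes contain missing values; impute before estimation")

    a_by, y_by = {}, {}
    for lab in keep_labels:
        members = sorted(comms[lab], key=str)
        a_by[lab] = np.array([network.records[m].treatment for m in members], float)
        y_by[lab] = np.array([network.records[m].outcome for m in members], float)

    # community propensity scores
    if known_propensity is not None:
        f_by = {lab: float(known_propensity[lab]) for lab in keep_labels}
        data = None
    else:
        if prop_model is None or not prop_model.converged:
            raise ValueError("a converged propensity model (or known_propensity) is required")
        data, _, _ = _grouped(records, structure, prop_model.covariate_spec,
                              coding=prop_model.coding)
        logf = community_loglik(prop_model.theta, prop_model.sigma_b, data,
                                n_quad or prop_model.n_quad)
        f_by = {lab: float(np.exp(logf[i])) for i, lab in enumerate(data.labels)}

    # target means: for each alpha, arm-1, arm-0, marginal group averages
    target_alphas = sorted({*alphas, *(a for p in alpha_pairs for a in p)})
    targets = [(kind, al) for al in target_alphas for kind in (1, 0, "marg")]
    tpos = {t: k for k, t in enumerate(targets)}
    n_comm = len(keep_labels)
    group_vals = np.zeros((n_comm, len(targets)))
    for i, lab in enumerate(keep_labels):
        a, y, f = a_by[lab], y_by[lab], f_by[lab]
        for kind, al in targets:
            k = tpos[(kind, al)]
            if kind == "marg":
                group_vals[i, k] = group_ipw_marginal(a, y, f, al)
            else:
                group_vals[i, k] = group_ipw_mean(a, y, f, al, arm=kind)
    mu = group_vals.mean(axis=0)
    psi = group_vals - mu

    # sandwich pieces
    if not compute_se:
        cov = np.zeros((len(targets), len(targets)))
    elif known_propensity is not None:
        cov = sandwich_variance(psi)
    else:
        q_names, eta, jac_fn = _propensity_eta(prop_model, data)
        scores = jac_fn(eta)                                    # (N, q)
        hess = _total_hessian(jac_fn, eta)                      # (q, q)
        # d psi_t / d eta = -Yhat * d log f / d eta; scores ARE d log f
        bread_cross = (group_vals[:, :, None] * scores[:, None, :]).mean(axis=0)
        cov = sandwich_variance(psi, scores=scores, bread_cross=bread_cross,
                                hessian=hess)

    # assemble effect contrasts
    estimates: list[EffectEstimate] = []

    def _contrast(name, al, al_p, plus, minus):
        c = np.zeros(len(targets))
        c[tpos[plus]] += 1.0
        c[tpos[minus]] -= 1.0
        est = float(c @ mu)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        estimates.append(EffectEstimate(name, al, al_p, est, se))

    for al in alphas:
        _contrast("direct", al, None, (1, al), (0, al))
    for al, al_p in alpha_pairs:
        _contrast("spillover", al, al_p, (0, al), (0, al_p))
        _contrast("total", al, al_p, (1, al), (0, al_p))
        _contrast("overall", al, al_p, ("marg", al), ("marg", al_p))

    weights = []
    for al in target_alphas:
        weights.extend(community_weights(a_by, f_by, al))

    return EffectsResult(
        estimates=estimates,
        means={t: float(mu[tpos[t]]) for t in targets},
        mean_cov=cov,
        weights=weights,
        n_communities=n_comm,
        n_singletons_excluded=n_singletons,
        excluded_communities=exclude,
    )


# ---------------------------------------------------------------------------
# numerical derivatives of the propensity log likelihood


def _propensity_eta(model: PropensityModel, data):
    """Parameter vector and per-community log-likelihood Jacobian function.

    sigma_b is included unless the estimate sits on the boundary at 0, where
    the marginal likelihood is not differentiable in sigma.
    """
    include_sigma = model.sigma_b > 1e-6
    eta = np.concatenate([model.theta, [model.sigma_b]]) if include_sigma else model.theta.copy()
    names = list(model.columns) + (["sigma_b"] if include_sigma else [])
    n_quad = model.n_quad

    def loglik_vec(e):
        if include_sigma:
            return community_loglik(e[:-1], e[-1], data, n_quad)
        return community_loglik(e, model.sigma_b, data, n_quad)

    def jac(e):
        q = e.size
        out = np.empty((data.n_comm, q))
        for k in range(q):
            h = 1e-5 * (1.0 + abs(e[k]))
            ep, em = e.copy(), e.copy()
            ep[k] += h
            em[k] -= h
            if include_sigma and k == q - 1:
                em[k] = max(em[k], 1e-8)
            out[:, k] = (loglik_vec(ep) - loglik_vec(em)) / (ep[k] - em[k])
        return out

    jac.loglik_total = lambda e: float(np.sum(loglik_vec(e)))
    return names, eta, jac


def _total_hessian(jac_fn, eta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of the total log likelihood."""
    f = jac_fn.loglik_total
    q = eta.size
    h = 1e-4 * (1.0 + np.abs(eta))
    hess = np.empty((q, q))
    f0 = f(eta)
    for j in range(q):
        ej = np.zeros(q)
        ej[j] = h[j]
        hess[j, j] = (f(eta + ej) - 2.0 * f0 + f(eta - ej)) / h[j] ** 2
        for k in range(j + 1, q):
            ek = np.zeros(q)
            ek[k] = h[k]
            val = (
                f(eta + ej + ek) - f(eta + ej - ek)
                - f(eta - ej + ek) + f(eta - ej - ek)
            ) / (4.0 * h[j] * h[k])
            hess[j, k] = hess[k, j] = val
    return hess
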