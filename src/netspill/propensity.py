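"""Treatment propensity modeling at the community level.

Treatment (MOUD receipt/prescription) is not randomized, so measured
confounding is adjusted with a propensity model: a mixed-effects logistic
regression of treatment on baseline covariates with a random intercept
``b_i ~ N(0, sigma_b^2)`` shared by all members of community ``i``.  The
community-level propensity score is the probability of the community's whole
observed treatment vector,

    f(A_i | X_i) = Int prod_j h(x_ij, b)^{A_ij} (1 - h(x_ij, b))^{1-A_ij}
                       phi(b; 0, sigma_b^2) db,

with ``h`` the inverse-logit of the linear predictor.  The integral over the
random intercept is evaluated by adaptive Gauss-Hermite quadrature centered
and scaled at the conditional mode of each community's integrand, which keeps
the rule accurate even when the integrand is sharply peaked (large
communities).

Covariate screening mirrors common propensity-model practice: variance
inflation factors first, then pairwise chi-square association among
categorical covariates, then removal of covariates that break model
convergence or create empty treatment-by-level cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2_contingency

from .network import ParticipantRecord, records_to_frame

__all__ = [
    "PropensityModel",
    "CommunityPropensity",
    "ConvergenceError",
    "SeparationError",
    "build_design",
    "fit_mixed_logit",
    "community_propensity",
    "community_propensities",
    "screen_covariates",
]

_SIGMA_FLOOR = 1e-10  # below this the random effect is treated as absent


class ConvergenceError(RuntimeError):
    """Mixed-logit optimization failed to converge."""


class SeparationError(ValueError):
    """A design column perfectly separates treated from untreated."""


@dataclass
class PropensityModel:
    """Fitted mixed-effects logit for treatment."""

    covariate_spec: list[str]
    columns: list[str]              # design column names incl. intercept
    coding: dict                    # categorical covariate -> ordered levels
    theta: np.ndarray               # fixed effects, log-odds units
    sigma_b: float                  # random-intercept SD, log-odds units
    loglik: float
    converged: bool
    n_quad: int = 21

    def summary_frame(self, se: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.columns, "estimate": self.theta})
        if se is not None:
            df["se"] = se
        return pd.concat(
            [df, pd.DataFrame({"term": ["sigma_b"], "estimate": [self.sigma_b]})],
            ignore_index=True,
        )


@dataclass
class CommunityPropensity:
    """Probability of one community's observed treatment vector."""

    community: int
    f_value: float
    n_i: int
    quadrature_nodes: int


# ---------------------------------------------------------------------------
# design matrices


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    if series.dtype == bool:
        return True
    return False


def build_design(
    df: pd.DataFrame,
    covariate_spec: Sequence[str],
    coding: dict | None = None,
) -> tuple[np.ndarray, list[str], dict]:
    """Reference-coded design matrix with intercept.

    Categorical covariates are dummy-coded against their first level with
    levels ordered by sorted label (deterministic); numeric covariates enter
    linearly.  ``coding`` pins the level order of a previously built design
    so that new data are coded compatibly.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["(intercept)"]
    out_coding: dict = {}
    for name in covariate_spec:
        series = df[name]
        if series.isna().any():
            raise ValueError(f"covariate {name!r} has missing values; impute first")
        if (coding is not None and name in coding) or _is_categorical(series):
            levels = (coding or {}).get(name) or sorted(map(str, series.unique()))
            out_coding[name] = list(levels)
            as_str = series.astype(str)
            unknown = set(as_str) - set(levels)
            if unknown:
                raise ValueError(f"covariate {name!r}: unseen levels {unknown!r}")
            for level in levels[1:]:
                cols.append((as_str == level).to_numpy(float))
                names.append(f"{name}[{level}]")
        else:
            cols.append(series.to_numpy(float))
            names.append(name)
    return np.column_stack(cols), names, out_coding


def _check_separation(x: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    for j in range(1, x.shape[1]):  # skip intercept
        x1, x0 = x[y == 1, j], x[y == 0, j]
        if x1.size == 0 or x0.size == 0:
            continue
        if x1.min() > x0.max() or x1.max() < x0.min():
            raise SeparationError(
                f"design column {names[j]!r} perfectly separates treatment"
            )


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature


@dataclass
class _GroupedData:
    x: np.ndarray           # (n_obs, p)
    y: np.ndarray           # (n_obs,)
    comm_idx: np.ndarray    # (n_obs,) 0-based community index
    n_comm: int
    labels: list            # community labels in index order


def _grouped(records: Iterable[ParticipantRecord], structure, covariate_spec,
             coding=None, response: str = "treatment"):
    records = list(records)
    df = records_to_frame(records)
    x, names, out_coding = build_design(df, covariate_spec, coding)
    if response == "treatment":
        y = np.array([r.treatment for r in records], float)
    else:
        y = np.array([r.outcome for r in records], float)
    labels = sorted({structure.assignment[r.id] for r in records})
    pos = {lab: i for i, lab in enumerate(labels)}
    comm_idx = np.array([pos[structure.assignment[r.id]] for r in records])
    return _GroupedData(x, y, comm_idx, len(labels), labels), names, out_coding


def _conditional_mode(eta0, y, comm_idx, n_comm, sigma, max_iter=60):
    """Vectorized Newton search for the mode of each community integrand."""
    b = np.zeros(n_comm)
    inv_var = 1.0 / sigma**2
    for _ in range(max_iter):
        lp = eta0 + b[comm_idx]
        p = expit(lp)
        grad = np.bincount(comm_idx, weights=y - p, minlength=n_comm) - b * inv_var
        hess = -np.bincount(comm_idx, weights=p * (1 - p), minlength=n_comm) - inv_var
        step = grad / hess
        np.clip(step, -5.0, 5.0, out=step)
        b -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    return b, hess


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(n: int):
    if n not in _GH_CACHE:
        _GH_CACHE[n] = np.polynomial.hermite.hermgauss(n)
    return _GH_CACHE[n]


def community_loglik(theta, sigma, data: _GroupedData, n_quad: int = 21) -> np.ndarray:
    """Per-community log marginal likelihood of the observed treatments."""
    eta0 = data.x @ theta
    if sigma < _SIGMA_FLOOR:
        ll = data.y * eta0 - np.logaddexp(0.0, eta0)
        return np.bincount(data.comm_idx, weights=ll, minlength=data.n_comm)
    b_hat, hess = _conditional_mode(eta0, data.y, data.comm_idx, data.n_comm, sigma)
    tau = 1.0 / np.sqrt(-hess)
    z, w = _gh(n_quad)
    # integrand exponent at shifted/scaled nodes, community-by-node matrix
    g = np.empty((data.n_comm, n_quad))
    for k in range(n_quad):
        bk = b_hat + np.sqrt(2.0) * tau * z[k]
        lp = eta0 + bk[data.comm_idx]
        ll = data.y * lp - np.logaddexp(0.0, lp)
        g[:, k] = (
            np.bincount(data.comm_idx, weights=ll, minlength=data.n_comm)
            - bk**2 / (2.0 * sigma**2)
            + z[k] ** 2
            + np.log(w[k])
        )
    return (
        logsumexp(g, axis=1)
        + 0.5 * np.log(2.0) + np.log(tau)
        - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    )


def fit_mixed_logit(
    records: Iterable[ParticipantRecord],
    structure,
    covariate_spec: Sequence[str],
    n_quad: int = 21,
    start: tuple[np.ndarray, float] | None = None,
) -> PropensityModel:
    """Maximum (marginal) likelihood fit of the random-intercept logit.

    The community random intercept is integrated out by adaptive
    Gauss-Hermite quadrature; the estimate of ``sigma_b`` is constrained to
    be nonnegative and may land on the boundary 0 when the data carry no
    community-level heterogeneity.
    """
    records = list(records)
    data, names, coding = _grouped(records, structure, covariate_spec)
    y = data.y
    if y.min() == y.max():
        raise ValueError("treatment is constant; propensity model is not identifiable")
    _check_separation(data.x, y, names)

    p = data.x.shape[1]
    if start is not None:
        theta0, sigma0 = np.asarray(start[0], float), float(start[1])
    else:
        theta0 = _plain_logit_start(data.x, y)
        sigma0 = 0.5

    def nll(params):
        theta, sigma = params[:-1], params[-1]
        return -float(np.sum(community_loglik(theta, sigma, data, n_quad)))

    bounds = [(None, None)] * p + [(0.0, None)]
    res = scipy.optimize.minimize(
        nll,
        np.concatenate([theta0, [sigma0]]),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        # line searches on an FD gradient can terminate "abnormally" at what
        # is numerically the optimum; polish and accept if the gradient is flat
        polish = scipy.optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if polish.fun <= res.fun:
            res = polish
        res.x[-1] = max(res.x[-1], 0.0)
        grad = scipy.optimize.approx_fprime(res.x, nll, 1e-6)
        if res.x[-1] < 1e-6:
            grad = grad[:-1]  # sigma at the boundary: one-sided, not zero
        if np.max(np.abs(grad)) > 1e-2 * (1.0 + abs(res.fun)):
            raise ConvergenceError(f"mixed logit did not converge: {res.message}")
    converged = True
    theta, sigma = res.x[:-1], max(0.0, float(res.x[-1]))
    return PropensityModel(
        covariate_spec=list(covariate_spec),
        columns=names,
        coding=coding,
        theta=theta,
        sigma_b=sigma,
        loglik=-float(res.fun),
        converged=converged,
        n_quad=n_quad,
    )


def _plain_logit_start(x, y, max_iter=50):
    """Newton-fit ordinary logit used as a starting value (ridge-damped)."""
    theta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        p = expit(x @ theta)
        w = np.maximum(p * (1 - p), 1e-6)
        h = (x * w[:, None]).T @ x + 1e-8 * np.eye(x.shape[1])
        step = np.linalg.solve(h, x.T @ (y - p))
        nrm = np.linalg.norm(step)
        if nrm > 10.0:
            step *= 10.0 / nrm
        theta += step
        if nrm < 1e-10:
            break
    return theta


# ---------------------------------------------------------------------------
# community-level propensity scores


def community_propensities(
    model: PropensityModel,
    records: Iterable[ParticipantRecord],
    structure,
    n_quad: int | None = None,
) -> dict[int, CommunityPropensity]:
    """Community-level propensity score f(A_i | X_i) for every community."""
    if not model.converged:
        raise ValueError("propensity model did not converge; refit before use")
    n_quad = n_quad or model.n_quad
    data, _, _ = _grouped(records, structure, model.covariate_spec, coding=model.coding)
    logf = community_loglik(model.theta, model.sigma_b, data, n_quad)
    sizes = np.bincount(data.comm_idx, minlength=data.n_comm)
    out = {}
    for i, lab in enumerate(data.labels):
        f = float(np.exp(logf[i]))
        if f < 1e-300:
            raise FloatingPointError(
                f"community {lab}: propensity underflow; consider smaller "
                "communities or rescaled covariates"
            )
        out[lab] = CommunityPropensity(
            community=lab, f_value=f, n_i=int(sizes[i]), quadrature_nodes=n_quad
        )
    return out


def community_propensity(
    model: PropensityModel,
    records: Iterable[ParticipantRecord],
    n_quad: int | None = None,
) -> CommunityPropensity:
    """Propensity score of a single community's records."""
    records = list(records)

    class _One:
        assignment = {r.id: 1 for r in records}

    return community_propensities(model, records, _One(), n_quad)[1]


# ---------------------------------------------------------------------------
# covariate screening


def screen_covariates(
    records: Iterable[ParticipantRecord],
    candidates: Sequence[str],
    structure=None,
    vif_threshold: float = 10.0,
    chi2_alpha: float = 0.05,
    check_fit: bool = True,
) -> tuple[list[str], list[dict]]:
    """Three-stage covariate screen for the propensity model.

    1. drop covariates with variance inflation factor above ``vif_threshold``
       (largest first, recomputed after each drop);
    2. among categorical pairs associated at chi-square p < ``chi2_alpha``,
       iteratively drop the covariate involved in the most significant pairs
       (ties broken toward the later position in the candidate list);
    3. drop covariates creating an empty treatment-by-level cell, then any
       whose inclusion stops the mixed (or plain, if no community structure
       is supplied) logit from converging.

    Returns the retained list and a report of drops with reasons.
    """
    records = list(records)
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates")
    df = records_to_frame(records)
    report: list[dict] = []
    kept = list(candidates)

    # stage 1: VIF
    while len(kept) >= 2:
        x, names, _ = build_design(df, kept)
        vifs = _vif_by_covariate(x, names, kept)
        top = max(vifs.values())
        if top <= vif_threshold:
            break
        # ties (e.g. exact duplicates, both infinite) drop the later candidate
        tied = [c for c in kept if vifs[c] >= top - 1e-9 or (
            np.isinf(top) and np.isinf(vifs[c]))]
        worst = max(tied, key=candidates.index)
        kept.remove(worst)
        report.append({"covariate": worst, "stage": 1,
                       "reason": f"VIF {vifs[worst]:.1f} > {vif_threshold}"})

    # stage 2: pairwise chi-square among categoricals
    while True:
        cats = [c for c in kept if _is_categorical(df[c])]
        sig_count = {c: 0 for c in cats}
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                table = pd.crosstab(df[a], df[b])
                if table.shape[0] < 2 or table.shape[1] < 2:
                    continue
                pval = chi2_contingency(table.to_numpy())[1]
                if pval < chi2_alpha:
                    sig_count[a] += 1
                    sig_count[b] += 1
        if not sig_count or max(sig_count.values()) == 0:
            break
        worst_n = max(sig_count.values())
        tied = [c for c in cats if sig_count[c] == worst_n]
        drop = max(tied, key=candidates.index)  # later position loses
        kept.remove(drop)
        report.append({"covariate": drop, "stage": 2,
                       "reason": f"chi-square association with {worst_n} covariate(s)"})

    # stage 3: empty cells, then convergence
    for cov in list(kept):
        if _is_categorical(df[cov]):
            table = pd.crosstab(df["treatment"], df[cov])
            if (table.to_numpy() == 0).any():
                kept.remove(cov)
                report.append({"covariate": cov, "stage": 3,
                               "reason": "empty treatment-by-level cell"})
    if check_fit:
        while kept:
            if _fits(records, structure, kept):
                break
            for cov in reversed(kept):  # later candidates dropped first
                if _fits(records, structure, [c for c in kept if c != cov]):
                    kept.remove(cov)
                    report.append({"covariate": cov, "stage": 3,
                                   "reason": "model convergence failure"})
                    break
            else:
                dropped = kept.pop()  # no single removal helps; drop the last
                report.append({"covariate": dropped, "stage": 3,
                               "reason": "model convergence failure"})
    if not kept:
        raise ValueError("all candidate covariates were eliminated by screening")
    return kept, report


def _fits(records, structure, spec) -> bool:
    if not spec:
        return False
    try:
        if structure is None:
            df = records_to_frame(records)
            x, names, _ = build_design(df, spec)
            y = df["treatment"].to_numpy(float)
            _check_separation(x, y, names)
            theta = _plain_logit_start(x, y)
            return bool(np.all(np.isfinite(theta)) and np.max(np.abs(theta)) < 30)
        fit_mixed_logit(records, structure, spec)
        return True
    except (ConvergenceError, SeparationError, np.linalg.LinAlgError):
        return False


def _vif_by_covariate(x: np.ndarray, names: list[str], covariates: list[str]) -> dict:
    """Max VIF over each covariate's design columns (intercept excluded)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    out = {c: 0.0 for c in covariates}
    for j in range(1, x.shape[1]):
        with np.errstate(divide="ignore", invalid="ignore"):
            vif = variance_inflation_factor(x, j)
        if not np.isfinite(vif):
            vif = np.inf
        cov = names[j].split("[")[0]
        if cov in out:
            out[cov] = max(out[cov], vif)
    return out
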