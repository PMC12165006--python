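"""Covariate and outcome imputation, with sensitivity variants.

Missing covariates are imputed with an iterative random-forest scheme
(missForest-style): initialize missing cells with the observed mode or mean,
then cycle over covariates in order of increasing missingness, refitting a
forest of each covariate on all others and overwriting its missing cells,
until the imputation change criterion rises or a cap of 10 iterations.

Missing outcomes are imputed by a single random draw from a Bernoulli whose
probability comes from a mixed-effects logit of the outcome on covariates
with a community random intercept (main analysis); sensitivity variants are
a plain logit without the community term (making imputations identical
whatever community structure is used downstream) and deterministic best- and
worst-case fills keyed to treatment status.  Observed values are never
altered by any imputation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .network import ParticipantRecord, records_to_frame
from .propensity import _grouped, build_design, fit_mixed_logit

__all__ = [
    "ImputationResult",
    "impute_covariates_rf",
    "impute_outcome_mixed",
    "impute_outcome_glm",
    "impute_outcome_extreme",
]


@dataclass
class ImputationResult:
    records: list[ParticipantRecord]
    imputed_outcome_ids: set = field(default_factory=set)
    imputed_covariate_cells: set = field(default_factory=set)
    mode: str = "main"
    seed: int | None = None


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


# ---------------------------------------------------------------------------
# covariates


def impute_covariates_rf(
    records: Iterable[ParticipantRecord],
    rng: np.random.Generator,
    n_trees: int = 100,
    max_iter: int = 10,
) -> ImputationResult:
    """Iterative random-forest imputation of missing covariate cells."""
    records = list(records)
    seed = _seed_from(rng)
    df = records_to_frame(records).drop(columns=["treatment", "outcome"])
    cov_names = list(df.columns)
    miss_mask = df.isna()
    for r in records:
        for c in r.covariate_missing:
            miss_mask.loc[r.id, c] = True
            df.loc[r.id, c] = np.nan

    frac = miss_mask.mean()
    if (frac >= 0.5).any():
        bad = frac[frac >= 0.5].index.tolist()
        raise ValueError(f"covariates with >= 50% missingness: {bad}")
    targets = [c for c in cov_names if miss_mask[c].any()]
    if not targets:
        return ImputationResult(records=list(records), mode="main", seed=seed)
    if any(miss_mask[c].all() for c in targets):
        raise ValueError("a covariate is entirely missing")

    categorical = {c: _is_cat_col(df[c]) for c in cov_names}
    # initialize with mode (categorical) or mean (numeric)
    work = df.copy()
    for c in cov_names:
        if categorical[c]:
            work[c] = work[c].fillna(df[c].mode(dropna=True).iloc[0])
        else:
            work[c] = work[c].fillna(df[c].astype(float).mean())

    order = sorted(targets, key=lambda c: float(miss_mask[c].mean()))
    prev_change = np.inf
    prev_work = None
    for it in range(max_iter):
        before = work.copy()
        for c in order:
            others = [o for o in cov_names if o != c]
            x = pd.get_dummies(work[others], drop_first=False).to_numpy(float)
            obs = ~miss_mask[c].to_numpy()
            if categorical[c]:
                model = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed + it
                )
                model.fit(x[obs], df.loc[obs, c].to_numpy())
            else:
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=seed + it
                )
                model.fit(x[obs], df.loc[obs, c].to_numpy(float))
            pred = model.predict(x[~obs])
            work.loc[~obs, c] = pred
        change = _imputation_change(before, work, targets, miss_mask, categorical)
        if change >= prev_change:
            work = before  # change criterion rose: keep previous round
            break
        prev_change = change
        if change == 0.0:
            break

    cells = set()
    new_records = []
    for r in records:
        covs = dict(r.covariates)
        for c in cov_names:
            if miss_mask.loc[r.id, c]:
                covs[c] = work.loc[r.id, c]
                cells.add((r.id, c))
        new_records.append(r.replace(covariates=covs))
    return ImputationResult(
        records=new_records, imputed_covariate_cells=cells, mode="main", seed=seed
    )


def _is_cat_col(s: pd.Series) -> bool:
    obs = s.dropna()
    if obs.dtype == object or obs.dtype == bool or isinstance(obs.dtype, pd.CategoricalDtype):
        return True
    vals = obs.to_numpy(float)
    return bool(np.all(vals == np.round(vals)) and obs.nunique() <= 10)


def _imputation_change(before, after, targets, miss_mask, categorical) -> float:
    total = 0.0
    for c in targets:
        mask = miss_mask[c].to_numpy()
        if categorical[c]:
            total += float(np.mean(
                before.loc[mask, c].astype(str).to_numpy()
                != after.loc[mask, c].astype(str).to_numpy()
            ))
        else:
            b = before.loc[mask, c].astype(float).to_numpy()
            a = after.loc[mask, c].astype(float).to_numpy()
            denom = float(np.sum(a**2)) or 1.0
            total += float(np.sum((a - b) ** 2) / denom)
    return total


# ---------------------------------------------------------------------------
# outcomes


def _missing_outcome_ids(records) -> list[str]:
    return [r.id for r in records if r.outcome is None]


def impute_outcome_mixed(
    records: Iterable[ParticipantRecord],
    structure,
    covariate_spec: Sequence[str],
    rng: np.random.Generator,
) -> ImputationResult:
    """Draw missing outcomes from a community-random-intercept logit.

    The model is fit on rows with observed outcomes; each missing outcome is
    drawn Bernoulli at the fitted probability evaluated with the community's
    empirical-Bayes random-effect mode (communities with no observed
    outcomes use the prior mode 0).
    """
    records = list(records)
    seed = _seed_from(rng)
    missing_ids = set(_missing_outcome_ids(records))
    if not missing_ids:
        return ImputationResult(records=records, mode="main", seed=seed)
    observed = [r for r in records if r.outcome is not None]
    model = fit_mixed_logit(
        [r.replace(treatment=r.outcome) for r in observed],
        structure, covariate_spec,
    )
    b_modes = _eb_modes(model, observed, structure)
    draw_rng = np.random.default_rng(seed)
    df = records_to_frame(records)
    x, _, _ = build_design(df, model.covariate_spec, coding=model.coding)
    eta = x @ model.theta
    new_records = []
    for i, r in enumerate(records):
        if r.id in missing_ids:
            b = b_modes.get(structure.assignment[r.id], 0.0)
            p = expit(eta[i] + b)
            new_records.append(r.replace(outcome=int(draw_rng.random() < p)))
        else:
            new_records.append(r)
    return ImputationResult(
        records=new_records, imputed_outcome_ids=missing_ids, mode="main", seed=seed
    )


def _eb_modes(model, observed_records, structure) -> dict[int, float]:
    """Empirical-Bayes mode of the community random intercept."""
    from .propensity import _conditional_mode

    if model.sigma_b < 1e-10:
        return {}
    data, _, _ = _grouped(
        [r.replace(treatment=r.outcome) for r in observed_records],
        structure, model.covariate_spec, coding=model.coding,
    )
    eta0 = data.x @ model.theta
    b, _ = _conditional_mode(eta0, data.y, data.comm_idx, data.n_comm, model.sigma_b)
    return {lab: float(b[i]) for i, lab in enumerate(data.labels)}


def impute_outcome_glm(
    records: Iterable[ParticipantRecord],
    covariate_spec: Sequence[str],
    rng: np.random.Generator,
) -> ImputationResult:
    """Draw missing outcomes from a plain logit (no community term).

    Because nothing community-specific enters, the imputations are identical
    regardless of which community structure is used downstream.
    """
    records = list(records)
    seed = _seed_from(rng)
    missing_ids = set(_missing_outcome_ids(records))
    if not missing_ids:
        return ImputationResult(records=records, mode="no_random_effect", seed=seed)
    observed = [r for r in records if r.outcome is not None]
    df_obs = records_to_frame(observed)
    x_obs, _, coding = build_design(df_obs, covariate_spec)
    y_obs = np.array([r.outcome for r in observed], float)
    import statsmodels.api as sm

    theta = sm.GLM(y_obs, x_obs, family=sm.families.Binomial()).fit().params
    df_all = records_to_frame(records)
    x_all, _, _ = build_design(df_all, covariate_spec, coding=coding)
    p_all = expit(x_all @ theta)
    draw_rng = np.random.default_rng(seed)
    new_records = []
    for i, r in enumerate(records):
        if r.id in missing_ids:
            new_records.append(r.replace(outcome=int(draw_rng.random() < p_all[i])))
        else:
            new_records.append(r)
    return ImputationResult(
        records=new_records, imputed_outcome_ids=missing_ids,
        mode="no_random_effect", seed=seed,
    )


def impute_outcome_extreme(
    records: Iterable[ParticipantRecord], scenario: str
) -> ImputationResult:
    """Deterministic best/worst-case outcome fills.

    best: treated participants with a missing outcome are assumed not to
    have engaged in risk behavior (Y=0) and untreated to have engaged (Y=1);
    worst: the reverse.  These bound the effect sizes compatible with the
    observed data.
    """
    if scenario not in ("best", "worst"):
        raise ValueError("scenario must be 'best' or 'worst'")
    new_records = []
    imputed = set()
    for r in records:
        if r.outcome is None:
            if scenario == "best":
                y = 0 if r.treatment == 1 else 1
            else:
                y = 1 if r.treatment == 1 else 0
            new_records.append(r.replace(outcome=y))
            imputed.add(r.id)
        else:
            new_records.append(r)
    return ImputationResult(
        records=new_records, imputed_outcome_ids=imputed, mode=f"{scenario}_case"
    )
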