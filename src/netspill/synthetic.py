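"""Synthetic network studies with known ground truth.

The generator emulates the structure of a sociometric risk-network study of
people who inject drugs: roughly 24 planted communities of heterogeneous
size totalling about 277 participants, sparse between-community connections,
about 22% treated, confounded treatment assignment with a community-level
random intercept, a common binary outcome whose probability depends on own
treatment and on the treatment coverage among the *other* community members
(stratified interference), and missing-at-random outcome missingness around
20% driven by treatment and the binary confounder (never by the outcome).

Every planted community is internally connected (a uniform random spanning
tree is laid down before Bernoulli within-community edges), so generated
networks have no degree-0 nodes and the planted assignment is a valid
partition of the realized graph.

True counterfactual effects under Bernoulli allocation policies are computed
either by exact enumeration (a binomial sum over the number of treated
neighbors — exact at any community size because the outcome law depends on
others' treatments only through their count) or by Monte-Carlo draws of
treatment vectors; the two must agree within Monte-Carlo error.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.special import expit
from scipy.stats import binom

from .communities import CommunityStructure
from .network import ParticipantRecord, RiskNetwork

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "TrueEffects",
    "generate_study",
    "true_effects_mc",
    "true_community_propensities",
    "write_study",
]


@dataclass
class SyntheticStudyConfig:
    """Generating law for a synthetic study; defaults emulate the target study."""

    n_communities: int = 24
    sizes: Sequence[int] | None = None       # explicit sizes override the draw
    size_min: int = 3
    size_max: int = 40
    size_log_mean: float = math.log(10.0)    # lognormal size draw, right-skewed
    size_log_sd: float = 0.55
    p_within: float = 0.30
    p_between: float = 0.004
    # treatment model: logit P(A=1) = t0 + t_risk*x + t_age*z + b_i
    treat_intercept: float = -1.80
    treat_coef_risk: float = 0.80
    treat_coef_age: float = 0.30
    sigma_b: float = 0.50
    # outcome model: logit P(Y=1) = o0 + bd*A + bs*coverage_others + ...
    out_intercept: float = 1.10
    beta_direct: float = -1.00
    beta_spill: float = -1.00
    out_coef_risk: float = 1.00
    out_coef_age: float = 0.20
    # outcome missingness (MAR: depends on treatment and x only)
    outcome_missing_rate: float = 0.20
    miss_intercept: float = -1.65
    miss_coef_treat: float = 0.30
    miss_coef_risk: float = 0.40
    p_risk: float = 0.50                     # prevalence of the binary confounder
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_within, self.p_between, self.p_risk):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sizes is not None and any(s < 1 for s in self.sizes):
            raise ValueError("community sizes must be >= 1")
        if self.p_within <= self.p_between:
            raise ValueError("planted structure needs p_within > p_between")

    def replace(self, **kw) -> "SyntheticStudyConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrueEffects:
    direct: dict
    spillover: dict
    total: dict
    overall: dict
    mc_se: float
    means: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    network: RiskNetwork
    true_structure: CommunityStructure
    config: SyntheticStudyConfig

    @property
    def records(self) -> list[ParticipantRecord]:
        return [self.network.records[n] for n in sorted(self.network.records)]


def _draw_sizes(config: SyntheticStudyConfig, rng: np.random.Generator) -> np.ndarray:
    if config.sizes is not None:
        return np.asarray(config.sizes, int)
    raw = rng.lognormal(config.size_log_mean, config.size_log_sd, config.n_communities)
    return np.clip(np.round(raw).astype(int), config.size_min, config.size_max)


def _random_spanning_tree(members: list, rng: np.random.Generator) -> list[tuple]:
    """Uniform-ish random tree via a random permutation attachment."""
    order = list(rng.permutation(members))
    return [
        (order[i], order[rng.integers(i)]) for i in range(1, len(order))
    ]


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate one study (graph, covariates, treatment, outcome, missingness)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = _draw_sizes(config, rng)
    n_total = int(sizes.sum())
    width = len(str(n_total))
    ids = [f"p{i:0{width}d}" for i in range(1, n_total + 1)]

    assignment: dict[str, int] = {}
    start = 0
    community_members: dict[int, list[str]] = {}
    for c, size in enumerate(sizes, start=1):
        members = ids[start:start + size]
        community_members[c] = members
        for node in members:
            assignment[node] = c
        start += size

    g = nx.Graph()
    g.add_nodes_from(ids)
    for c, members in community_members.items():
        if len(members) >= 2:
            g.add_edges_from(_random_spanning_tree(members, rng))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if not g.has_edge(members[i], members[j]) and rng.random() < config.p_within:
                        g.add_edge(members[i], members[j])
    labels = sorted(community_members)
    for ci in range(len(labels)):
        for cj in range(ci + 1, len(labels)):
            for u in community_members[labels[ci]]:
                for v in community_members[labels[cj]]:
                    if rng.random() < config.p_between:
                        g.add_edge(u, v)

    # covariates, treatment, outcome
    x_risk = (rng.random(n_total) < config.p_risk).astype(int)
    age = rng.standard_normal(n_total)
    b = rng.normal(0.0, config.sigma_b, len(labels))
    comm_idx = np.array([assignment[i] - 1 for i in ids])
    lp_a = (
        config.treat_intercept
        + config.treat_coef_risk * x_risk
        + config.treat_coef_age * age
        + b[comm_idx]
    )
    a = (rng.random(n_total) < expit(lp_a)).astype(int)

    id_pos = {node: k for k, node in enumerate(ids)}
    coverage_others = np.zeros(n_total)
    for c, members in community_members.items():
        idxs = [id_pos[m] for m in members]
        if len(idxs) > 1:
            tot = a[idxs].sum()
            for k in idxs:
                coverage_others[k] = (tot - a[k]) / (len(idxs) - 1)
    lp_y = (
        config.out_intercept
        + config.beta_direct * a
        + config.beta_spill * coverage_others
        + config.out_coef_risk * x_risk
        + config.out_coef_age * age
    )
    y = (rng.random(n_total) < expit(lp_y)).astype(int)

    if config.outcome_missing_rate > 0:
        lp_m = (
            config.miss_intercept
            + config.miss_coef_treat * a
            + config.miss_coef_risk * x_risk
        )
        missing = rng.random(n_total) < expit(lp_m)
    else:
        missing = np.zeros(n_total, bool)

    records = {}
    for k, node in enumerate(ids):
        records[node] = ParticipantRecord(
            id=node,
            treatment=int(a[k]),
            outcome=None if missing[k] else int(y[k]),
            covariates={"risk_base": int(x_risk[k]), "age": float(age[k])},
        )
    network = RiskNetwork(graph=g, records=records)
    network.validate()
    structure = CommunityStructure(dict(assignment), method="given")
    return SyntheticStudy(network=network, true_structure=structure, config=config)


# ---------------------------------------------------------------------------
# true counterfactual effects


def _participant_truth_exact(config, a_val, alpha, n_i, xlp):
    """E over others' Bernoulli(alpha) treatments of P(Y=1 | a, coverage)."""
    base = config.out_intercept + config.beta_direct * a_val + xlp
    if n_i == 1:
        return expit(base)
    k = np.arange(n_i)
    pmf = binom.pmf(k, n_i - 1, alpha)
    return float(np.sum(pmf * expit(base + config.beta_spill * k / (n_i - 1))))


def true_effects_mc(
    config: SyntheticStudyConfig,
    alphas: Sequence[float],
    pairs: Sequence[tuple[float, float]],
    reps: int = 20000,
    method: str = "exact",
    mc_draws: int = 200,
    rng: np.random.Generator | None = None,
) -> TrueEffects:
    """Population-level true effects under the configured outcome law.

    Averages participant average potential outcomes over ``reps`` freshly
    drawn communities (sizes and covariates from the config).  ``method``
    'exact' evaluates the expectation over others' treatments by a binomial
    sum; 'mc' draws ``mc_draws`` counterfactual treatment vectors per
    community.  The Monte-Carlo standard error reported is the replicate SE
    of the community-level means.
    """
    rng = rng or np.random.default_rng(config.seed + 777)
    all_alphas = sorted({*alphas, *(a for p in pairs for a in p)})
    per_comm = {al: {"y1": [], "y0": [], "ym": []} for al in all_alphas}
    for _ in range(reps):
        size = int(_draw_sizes(config.replace(n_communities=1), rng)[0])
        x_risk = (rng.random(size) < config.p_risk).astype(int)
        age = rng.standard_normal(size)
        xlp = config.out_coef_risk * x_risk + config.out_coef_age * age
        for al in all_alphas:
            if method == "exact":
                y1 = np.array([_participant_truth_exact(config, 1, al, size, v) for v in xlp])
                y0 = np.array([_participant_truth_exact(config, 0, al, size, v) for v in xlp])
            elif method == "mc":
                draws = (rng.random((mc_draws, size)) < al).astype(float)
                if size > 1:
                    cov_others = (draws.sum(axis=1, keepdims=True) - draws) / (size - 1)
                else:
                    cov_others = np.zeros_like(draws)
                base = config.out_intercept + xlp[None, :]
                y1 = expit(base + config.beta_direct + config.beta_spill * cov_others).mean(axis=0)
                y0 = expit(base + config.beta_spill * cov_others).mean(axis=0)
            else:
                raise ValueError(f"unknown method {method!r}")
            per_comm[al]["y1"].append(float(y1.mean()))
            per_comm[al]["y0"].append(float(y0.mean()))
            per_comm[al]["ym"].append(float(al * y1.mean() + (1 - al) * y0.mean()))

    means = {}
    se_parts = []
    for al in all_alphas:
        for kind in ("y1", "y0", "ym"):
            vals = np.asarray(per_comm[al][kind])
            means[(kind, al)] = float(vals.mean())
            se_parts.append(vals.std(ddof=1) / math.sqrt(reps))
    mc_se = float(max(se_parts))

    direct = {al: means[("y1", al)] - means[("y0", al)] for al in alphas}
    spill = {p: means[("y0", p[0])] - means[("y0", p[1])] for p in pairs}
    total = {p: means[("y1", p[0])] - means[("y0", p[1])] for p in pairs}
    overall = {p: means[("ym", p[0])] - means[("ym", p[1])] for p in pairs}
    return TrueEffects(direct=direct, spillover=spill, total=total,
                       overall=overall, mc_se=mc_se, means=means)


def true_community_propensities(study: SyntheticStudy, n_quad: int = 41) -> dict[int, float]:
    """f(A_i | X_i) under the TRUE treatment-generating law (by quadrature)."""
    from .propensity import _GroupedData, community_loglik

    cfg = study.config
    records = study.records
    x = np.column_stack([
        np.ones(len(records)),
        [r.covariates["risk_base"] for r in records],
        [r.covariates["age"] for r in records],
    ])
    y = np.array([r.treatment for r in records], float)
    labels = sorted({study.true_structure.assignment[r.id] for r in records})
    pos = {lab: i for i, lab in enumerate(labels)}
    comm_idx = np.array([pos[study.true_structure.assignment[r.id]] for r in records])
    data = _GroupedData(x, y, comm_idx, len(labels), labels)
    theta = np.array([cfg.treat_intercept, cfg.treat_coef_risk, cfg.treat_coef_age])
    logf = community_loglik(theta, cfg.sigma_b, data, n_quad)
    return {lab: float(np.exp(logf[i])) for i, lab in enumerate(labels)}


def write_study(study: SyntheticStudy, outdir, delimiter: str = ",") -> None:
    """Emit edge list, attribute table and a truth file in plain text."""
    import os

    from .network import records_to_frame, write_table

    os.makedirs(outdir, exist_ok=True)
    meta = {"seed": study.config.seed, "generator": "netspill.synthetic"}
    import pandas as pd

    edges = pd.DataFrame(study.network.edges, columns=["id1", "id2"])
    write_table(edges, os.path.join(outdir, "edges.csv"), metadata=meta)
    df = records_to_frame(study.records).reset_index()
    df["community"] = [study.true_structure.assignment[i] for i in df["id"]]
    write_table(df, os.path.join(outdir, "attributes.csv"), metadata=meta)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2, default=list)
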