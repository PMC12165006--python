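"""End-to-end analysis orchestration.

Per detection method the pipeline runs: covariate imputation -> community
detection -> singleton exclusion -> outcome imputation -> covariate
screening -> propensity fit -> effect estimation (plus an extreme-weight
trimmed variant) -> perturbation significance, writing delimited result
tables, weight diagnostics, perturbation curves, an imputation audit and a
structured log.  All stage seeds derive from the master seed by fixed
offsets so a single stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
import numpy as np
import yaml

from . import __version__
from .communities import detect_greedy_agglomerative, detect_leading_eigenvector
from .effects import estimate_effects, trim_extreme
from .missing import (
    impute_covariates_rf,
    impute_outcome_extreme,
    impute_outcome_glm,
    impute_outcome_mixed,
)
from .network import (
    RiskNetwork,
    build_network,
    read_attributes,
    read_edge_list,
    summarize_partition_edges,
    write_table,
)
from .propensity import fit_mixed_logit, screen_covariates
from .significance import (
    crossing_gamma,
    node_reassignment_reference,
    null_network,
    perturbation_curve,
)

__all__ = ["RunConfig", "run_pipeline", "DETECTORS"]

DETECTORS = {
    "cfg": detect_greedy_agglomerative,
    "le": detect_leading_eigenvector,
}

# fixed child-seed offsets (master seed + offset), per stage
_SEED_COVARIATE_IMPUTE = 11
_SEED_OUTCOME_IMPUTE = 101      # + method index
_SEED_CURVE = 201               # + method index
_SEED_NULL = 301                # + method index
_SEED_REFERENCE = 401


@dataclass
class RunConfig:
    edges: str
    attributes: str
    covariates: list[str]
    id_col: str = "id"
    treatment_col: str = "treatment"
    outcome_col: str = "outcome"
    delimiter: str = ","
    methods: list[str] = field(default_factory=lambda: ["cfg", "le"])
    alphas: list[float] = field(default_factory=lambda: [0.20, 0.40, 0.60])
    pairs: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.60, 0.20), (0.40, 0.20), (0.60, 0.40)]
    )
    imputation: str = "main"        # main | best_case | worst_case | no_random_effect
    trim_low: float = 0.001
    trim_high: float | None = None
    gamma_max: float = 1.0
    gamma_step: float = 0.02
    curve_reps: int = 30
    run_significance: bool = True
    seed: int = 0
    outdir: str = "netspill_out"

    def validate(self) -> None:
        for m in self.methods:
            if m not in DETECTORS:
                raise ValueError(f"unknown detection method {m!r}")
        for a in self.alphas:
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha {a} outside (0, 1)")
        for a, ap in self.pairs:
            if not a > ap:
                raise ValueError(f"pair ({a}, {ap}) must satisfy alpha > alpha_prime")
        if self.imputation not in ("main", "best_case", "worst_case", "no_random_effect"):
            raise ValueError(f"unknown imputation mode {self.imputation!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["pairs"] = [tuple(p) for p in raw.get("pairs", [])] or None
        raw = {k: v for k, v in raw.items() if v is not None}
        return cls(**raw)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _load_network(config: RunConfig) -> RiskNetwork:
    edge_rows = read_edge_list(config.edges, delimiter=config.delimiter, header=True)
    records = read_attributes(
        config.attributes,
        id_col=config.id_col,
        treatment_col=config.treatment_col,
        outcome_col=config.outcome_col,
        covariate_cols=config.covariates,
        delimiter=config.delimiter,
    )
    return build_network(edge_rows, records, drop_isolates=True)


def run_pipeline(config: RunConfig, network: RiskNetwork | None = None) -> dict:
    """Run the full analysis; returns a report dict and writes all outputs."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "version": __version__,
        "imputation": config.imputation,
        "stages": [],
        "methods": {},
    }
    meta = {"seed": config.seed, "netspill": __version__}

    def stage(name):
        log["stages"].append(name)

    try:
        stage("load")
        if network is None:
            network = _load_network(config)
        log["n_nodes"] = network.n_nodes
        log["n_edges"] = network.n_edges
        log["n_isolates_removed"] = network.n_isolates_removed
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("load", exc) from exc

    try:
        stage("covariate_imputation")
        rng = np.random.default_rng(config.seed + _SEED_COVARIATE_IMPUTE)
        cov_result = impute_covariates_rf(network.records.values(), rng)
        records = {r.id: r for r in cov_result.records}
        network = RiskNetwork(graph=network.graph, records=records,
                              n_isolates_removed=network.n_isolates_removed)
        audit_rows = [
            {"id": i, "field": c, "mode": "covariate_rf", "seed": cov_result.seed}
            for i, c in sorted(cov_result.imputed_covariate_cells)
        ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("covariate_imputation", exc) from exc

    for mi, method in enumerate(config.methods):
        mlog: dict = {}
        try:
            stage(f"detect[{method}]")
            structure = DETECTORS[method](network)
            within, between = summarize_partition_edges(network, structure)
            mlog.update(
                n_communities=structure.n_communities,
                modularity=structure.modularity,
                edges_within=within,
                edges_between=between,
            )

            stage(f"singleton_exclusion[{method}]")
            comms = structure.communities()
            singleton_nodes = {
                n for lab, members in comms.items() if len(members) == 1 for n in members
            }
            mlog["n_singletons_excluded"] = len(singleton_nodes)
            kept = [r for r in network.records.values() if r.id not in singleton_nodes]

            stage(f"outcome_imputation[{method}]")
            rng = np.random.default_rng(config.seed + _SEED_OUTCOME_IMPUTE + mi)
            if config.imputation == "main":
                imp = impute_outcome_mixed(kept, structure, config.covariates, rng)
            elif config.imputation == "no_random_effect":
                imp = impute_outcome_glm(kept, config.covariates, rng)
            else:
                imp = impute_outcome_extreme(
                    kept, config.imputation.removesuffix("_case")
                )
            audit_rows += [
                {"id": i, "field": "outcome", "mode": imp.mode, "seed": imp.seed}
                for i in sorted(imp.imputed_outcome_ids)
            ]
            est_network = RiskNetwork(
                graph=network.graph.subgraph([r.id for r in imp.records]).copy(),
                records={r.id: r for r in imp.records},
            )

            stage(f"screening[{method}]")
            selected, screen_report = screen_covariates(
                imp.records, config.covariates, structure=structure
            )
            mlog["covariates_selected"] = selected
            mlog["screening"] = screen_report

            stage(f"propensity[{method}]")
            model = fit_mixed_logit(imp.records, structure, selected)
            mlog["sigma_b"] = model.sigma_b
            mlog["loglik"] = model.loglik

            stage(f"effects[{method}]")
            result = estimate_effects(
                est_network, structure, model,
                alphas=config.alphas, alpha_pairs=config.pairs,
            )
            write_table(result.to_frame().assign(method=method),
                        os.path.join(config.outdir, f"effects_{method}.csv"),
                        metadata=meta)
            import pandas as pd

            write_table(
                pd.DataFrame(
                    [{"community": w.community, "alpha": w.alpha, "weight": w.weight}
                     for w in result.weights]
                ),
                os.path.join(config.outdir, f"weights_{method}.csv"),
                metadata=meta,
            )

            stage(f"trimmed_effects[{method}]")
            retained = trim_extreme(result.weights, low=config.trim_low,
                                    high=config.trim_high)
            all_labels = {w.community for w in result.weights}
            dropped = all_labels - retained
            mlog["trimmed_communities"] = sorted(dropped)
            trimmed = estimate_effects(
                est_network, structure, model,
                alphas=config.alphas, alpha_pairs=config.pairs,
                exclude_communities=dropped,
            )
            write_table(trimmed.to_frame().assign(method=method),
                        os.path.join(config.outdir, f"effects_trimmed_{method}.csv"),
                        metadata=meta)

            if config.run_significance:
                stage(f"significance[{method}]")
                gamma_grid = np.round(
                    np.arange(0.0, config.gamma_max + 1e-9, config.gamma_step), 6
                ).tolist()
                curve = perturbation_curve(
                    network, DETECTORS[method], gamma_grid, reps=config.curve_reps,
                    rng=np.random.default_rng(config.seed + _SEED_CURVE + mi),
                )
                null = null_network(
                    network, np.random.default_rng(config.seed + _SEED_NULL + mi)
                )
                null_curve = perturbation_curve(
                    null, DETECTORS[method], gamma_grid, reps=config.curve_reps,
                    rng=np.random.default_rng(config.seed + _SEED_NULL + mi),
                    network_tag="null",
                )
                ref_rng = np.random.default_rng(config.seed + _SEED_REFERENCE)
                ref10 = node_reassignment_reference(structure, 0.10, reps=500, rng=ref_rng)
                ref20 = node_reassignment_reference(structure, 0.20, reps=500, rng=ref_rng)
                curve.reference_10, curve.reference_20 = ref10, ref20
                frames = pd.concat([curve.to_frame(), null_curve.to_frame()])
                write_table(frames,
                            os.path.join(config.outdir, f"curve_{method}.csv"),
                            metadata=meta)
                with open(os.path.join(config.outdir, f"references_{method}.json"), "w") as fh:
                    json.dump({"reference_10": ref10, "reference_20": ref20,
                               "crossing_10": crossing_gamma(curve, ref10),
                               "crossing_20": crossing_gamma(curve, ref20)}, fh, indent=2)
                mlog["reference_10"] = ref10
                mlog["reference_20"] = ref20
                mlog["crossing_10"] = crossing_gamma(curve, ref10)
                mlog["crossing_20"] = crossing_gamma(curve, ref20)

            log["methods"][method] = mlog
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(log["stages"][-1], exc) from exc

    import pandas as pd

    write_table(pd.DataFrame(audit_rows or [{}]),
                os.path.join(config.outdir, "imputation_audit.csv"), metadata=meta)
    with open(os.path.join(config.outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log
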