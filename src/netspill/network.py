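"""Reading, validation and canonicalization of the participant risk network.

A study network is an undirected simple graph whose nodes are participants
(people who inject drugs and their risk contacts) and whose edges are
risk-relevant contacts (shared drug use, sex, shared venues).  Each node
carries a :class:`ParticipantRecord` with a binary treatment (medication for
opioid use disorder received or prescribed in the six months before
baseline), a binary outcome that may be missing (any injection risk behavior
during follow-up), and baseline covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "RiskNetwork",
    "NetworkDataError",
    "build_network",
    "summarize_partition_edges",
    "read_edge_list",
    "read_attributes",
    "records_to_frame",
    "write_table",
]

#: tokens interpreted as a missing value in delimited input
MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}

TRUE_TOKENS = {"1", "yes", "y", "true"}
FALSE_TOKENS = {"0", "no", "n", "false"}


class NetworkDataError(ValueError):
    """Raised for invalid network or attribute input."""


@dataclass
class ParticipantRecord:
    """One participant: treatment, (possibly missing) outcome, covariates."""

    id: str
    treatment: int
    outcome: int | None
    covariates: dict = field(default_factory=dict)
    covariate_missing: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.treatment not in (0, 1):
            raise NetworkDataError(
                f"participant {self.id!r}: treatment must be 0/1, got {self.treatment!r}"
            )
        if self.outcome not in (0, 1, None):
            raise NetworkDataError(
                f"participant {self.id!r}: outcome must be 0/1/missing, got {self.outcome!r}"
            )

    def replace(self, **kwargs) -> "ParticipantRecord":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RiskNetwork:
    """Simple undirected graph plus the participant records on its nodes."""

    graph: nx.Graph
    records: dict[str, ParticipantRecord]
    n_isolates_removed: int = 0

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return sorted((canonical_edge(u, v) for u, v in self.graph.edges), key=str)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def record(self, node) -> ParticipantRecord:
        return self.records[node]

    def validate(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise NetworkDataError("self-loop present")
        for node in g.nodes:
            if node not in self.records:
                raise NetworkDataError(f"node {node!r} has no attribute record")

    def subgraph(self, nodes: Iterable) -> "RiskNetwork":
        nodes = list(nodes)
        return RiskNetwork(
            graph=self.graph.subgraph(nodes).copy(),
            records={n: self.records[n] for n in nodes},
        )


def canonical_edge(u, v) -> tuple:
    """Unordered pair canonicalized by sorting the two ids as strings."""
    return (u, v) if str(u) <= str(v) else (v, u)


def coerce_binary(value, *, allow_missing: bool, context: str) -> int | None:
    """Code a raw treatment/outcome value to {0, 1, missing}.

    Accepts 0/1 ints, "0"/"1", yes/no style strings; anything else is an
    error rather than silently coerced.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        token = ""
    elif isinstance(value, (int, float)) and value in (0, 1):
        return int(value)
    else:
        token = str(value).strip().lower()
    if token in MISSING_TOKENS:
        if allow_missing:
            return None
        raise NetworkDataError(f"{context}: missing value not allowed")
    if token in TRUE_TOKENS:
        return 1
    if token in FALSE_TOKENS:
        return 0
    raise NetworkDataError(f"{context}: cannot code {value!r} as binary")


def build_network(
    edge_rows: Iterable[tuple],
    attribute_rows: Iterable[Mapping] | Iterable[ParticipantRecord],
    drop_isolates: bool = True,
    *,
    treatment_key: str = "treatment",
    outcome_key: str = "outcome",
    id_key: str = "id",
    covariate_keys: Sequence[str] | None = None,
) -> RiskNetwork:
    """Assemble a canonical :class:`RiskNetwork` from raw rows.

    Edge direction is ignored; duplicate edges are collapsed; self-loops are
    rejected.  With ``drop_isolates`` (the default, matching the convention
    of analysing only participants who share at least one edge), degree-0
    nodes are removed and counted in ``n_isolates_removed``.

    Raises :class:`NetworkDataError` on a self-loop, an edge endpoint with no
    attribute record, a duplicated participant id, or a missing treatment.
    """
    records: dict[str, ParticipantRecord] = {}
    for row in attribute_rows:
        if isinstance(row, ParticipantRecord):
            rec = row
        else:
            row = dict(row)
            pid = row[id_key]
            if covariate_keys is None:
                cov_keys = [k for k in row if k not in (id_key, treatment_key, outcome_key)]
            else:
                cov_keys = list(covariate_keys)
            covs = {}
            missing = set()
            for k in cov_keys:
                v = row.get(k)
                if v is None or (isinstance(v, float) and pd.isna(v)) or (
                    isinstance(v, str) and v.strip().lower() in MISSING_TOKENS
                ):
                    covs[k] = None
                    missing.add(k)
                else:
                    covs[k] = v
            rec = ParticipantRecord(
                id=str(pid),
                treatment=coerce_binary(
                    row.get(treatment_key), allow_missing=False,
                    context=f"participant {pid!r} treatment",
                ),
                outcome=coerce_binary(
                    row.get(outcome_key), allow_missing=True,
                    context=f"participant {pid!r} outcome",
                ),
                covariates=covs,
                covariate_missing=missing,
            )
        if rec.id in records:
            raise NetworkDataError(f"duplicate participant id {rec.id!r}")
        records[rec.id] = rec

    g = nx.Graph()
    g.add_nodes_from(records)
    for u, v in edge_rows:
        u, v = str(u), str(v)
        if u == v:
            raise NetworkDataError(f"self-loop on id {u!r}")
        for endpoint in (u, v):
            if endpoint not in records:
                raise NetworkDataError(f"edge endpoint {endpoint!r} has no attribute record")
        g.add_edge(*canonical_edge(u, v))

    n_removed = 0
    if drop_isolates:
        isolates = [n for n in g.nodes if g.degree(n) == 0]
        g.remove_nodes_from(isolates)
        n_removed = len(isolates)
        records = {n: records[n] for n in g.nodes}

    net = RiskNetwork(graph=g, records=records, n_isolates_removed=n_removed)
    net.validate()
    return net


def summarize_partition_edges(network: RiskNetwork, structure) -> tuple[int, int]:
    """Count edges within vs between the communities of a partition.

    Returns ``(edges_within, edges_between)``; their sum is ``|E|``.
    """
    assignment = structure.assignment
    for node in network.graph.nodes:
        if node not in assignment:
            raise NetworkDataError(f"node {node!r} absent from the partition")
    within = sum(1 for u, v in network.graph.edges if assignment[u] == assignment[v])
    return within, network.n_edges - within


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_edge_list(path, delimiter: str = ",", header: bool = False) -> list[tuple[str, str]]:
    """Read a two-column edge list; lines starting with '#' are comments."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header and not rows and i == _first_data_index(path):
                pass
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise NetworkDataError(f"{path}: edge line {i + 1} has fewer than 2 columns")
            rows.append((parts[0], parts[1]))
    if header and rows:
        rows = rows[1:]
    return rows


def _first_data_index(path) -> int:  # pragma: no cover - trivial helper
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.strip() and not line.startswith("#"):
                return i
    return 0


def read_attributes(
    path,
    id_col: str,
    treatment_col: str,
    outcome_col: str,
    covariate_cols: Sequence[str],
    delimiter: str = ",",
) -> list[ParticipantRecord]:
    """Read the participant attribute table via pandas with role mapping."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype={id_col: str})
    rows = df.to_dict("records")
    for row in rows:
        row[id_col] = str(row[id_col])
    recs = build_network(
        [], rows, drop_isolates=False,
        id_key=id_col, treatment_key=treatment_col, outcome_key=outcome_col,
        covariate_keys=covariate_cols,
    ).records
    return [recs[str(r[id_col])] for r in rows]


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tabular view of records: id index, treatment, outcome, covariates."""
    rows = []
    for rec in records:
        row = {"id": rec.id, "treatment": rec.treatment, "outcome": rec.outcome}
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def write_table(df: pd.DataFrame, path, *, metadata: Mapping | None = None,
                delimiter: str = ",") -> None:
    """Write a delimited table with a commented run-metadata header."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=delimiter, index=False)
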