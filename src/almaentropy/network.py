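"""Tripartite drug-target-assay networks from observed or predicted links.

Every positive assay outcome (observed L = 1, or predicted p > cutoff)
contributes the directed path drug -> target -> assay plus the shortcut
drug -> assay, so the network has exactly three arc classes. Duplicate
outcomes collapse (set semantics), and nodes are namespaced (``d:``,
``t:``, ``a:``) so a string reused as both target and assay id cannot
collide. Measure and organism are deliberately not represented as nodes:
they would become near-universal hubs and drown the topology.

Node statistics follow the network-information convention used for the
molecular descriptors: arcs are symmetrized, the walk matrix gets uniform
weights and self-loops, and each node's first-order Markov-Shannon entropy
is its term of the one-step distribution's entropy from a uniform start:

    Pi(i, j) = 1 / (deg(i) + 1)   for j in N(i) u {i}
    pi_1     = u . Pi,  u uniform
    Sh_1(i)  = -pi_1(i) log2 pi_1(i)

On an n-node vertex-transitive graph every Sh_1 equals (1/n) log2 n.
"""

from __future__ import annotations

from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .records import EndpointRecord

__all__ = [
    "TripartiteNetwork",
    "build_observed",
    "build_predicted",
    "node_entropy",
    "class_summary",
    "summarize_node_table",
]

NODE_CLASSES = ("drug", "target", "assay")
_PREFIX = {"drug": "d:", "target": "t:", "assay": "a:"}
#: Allowed (source class, destination class) arc pairs.
ARC_CLASSES = (("drug", "target"), ("drug", "assay"), ("target", "assay"))


class TripartiteNetwork:
    """Directed tripartite network over drug, target and assay nodes."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_node(self, kind: str, ident: str) -> str:
        if kind not in NODE_CLASSES:
            raise DataError(f"unknown node class {kind!r}")
        name = _PREFIX[kind] + str(ident)
        self.graph.add_node(name, kind=kind, ident=str(ident))
        return name

    def add_link(self, drug: str, target: str, assay: str,
                 *, path_only: bool = False) -> None:
        """Add one positive outcome's arcs: d->t, d->a, t->a.

        ``path_only`` omits the drug->assay shortcut and keeps only the
        two-arc path through the target.
        """
        if not (str(drug) and str(target) and str(assay)):
            raise DataError("drug, target and assay ids must be non-empty")
        d = self.add_node("drug", drug)
        t = self.add_node("target", target)
        a = self.add_node("assay", assay)
        self.graph.add_edge(d, t, arc_class="drug-target")
        if not path_only:
            self.graph.add_edge(d, a, arc_class="drug-assay")
        self.graph.add_edge(t, a, arc_class="target-assay")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        """Per-node degrees and entropy: node_id, class, deg_in/out, deg, sh1."""
        sh1 = node_entropy(self)
        rows = []
        for name, data in sorted(self.graph.nodes(data=True)):
            din = self.graph.in_degree(name)
            dout = self.graph.out_degree(name)
            rows.append(
                {
                    "node_id": data["ident"],
                    "class": data["kind"],
                    "deg_in": din,
                    "deg_out": dout,
                    "deg": din + dout,
                    "sh1": sh1[name],
                }
            )
        return pd.DataFrame(
            rows, columns=["node_id", "class", "deg_in", "deg_out", "deg", "sh1"]
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "arc_class": d["arc_class"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "arc_class"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_observed(
    records: list[EndpointRecord] | pd.DataFrame, *, path_only: bool = False
) -> TripartiteNetwork:
    """Network of the observed positive outcomes (L = 1) in an endpoint table."""
    net = TripartiteNetwork()
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in records],
                "target_id": [r.target_id for r in records],
                "assay_id": [r.assay_id for r in records],
                "label": [r.label for r in records],
            }
        )
    if frame["label"].isna().any():
        raise DataError("observed network requires a label on every record")
    bad = frame["target_id"].astype(str).eq("") | frame["assay_id"].astype(str).eq("")
    if bad.any():
        raise DataError(
            f"records with missing target/assay ids at rows {list(frame.index[bad])[:10]}"
        )
    for row in frame[frame["label"].astype(int) == 1].itertuples(index=False):
        net.add_link(row.compound_id, row.target_id, row.assay_id,
                     path_only=path_only)
    return net


def build_predicted(
    predictions: pd.DataFrame,
    cutoff: float = 0.5,
    *,
    proba_column: str = "proba",
    path_only: bool = False,
) -> TripartiteNetwork:
    """Network of predicted links: rows with probability strictly above cutoff.

    ``predictions`` must carry compound_id, target_id, assay_id and the
    probability column; a probability exactly at the cutoff is excluded.
    """
    for col in ("compound_id", "target_id", "assay_id", proba_column):
        if col not in predictions.columns:
            raise DataError(f"prediction table lacks column {col!r}")
    net = TripartiteNetwork()
    keep = predictions[predictions[proba_column] > cutoff]
    for row in keep.itertuples(index=False):
        net.add_link(
            getattr(row, "compound_id"),
            getattr(row, "target_id"),
            getattr(row, "assay_id"),
            path_only=path_only,
        )
    return net


def node_entropy(network: TripartiteNetwork) -> dict[str, float]:
    """First-order Markov-Shannon entropy per node, in bits.

    Computed on the symmetrized graph with self-loops and uniform node
    weights; repeated calls give identical results (symmetrization is
    idempotent).
    """
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise DataError("node entropy of an empty network is undefined")
    nodes = sorted(g.nodes())
    index = {name: i for i, name in enumerate(nodes)}
    adj = np.eye(n)
    for u, v in g.edges():
        adj[index[u], index[v]] = adj[index[v], index[u]] = 1.0
    pi = adj / adj.sum(axis=1, keepdims=True)
    p1 = np.full(n, 1.0 / n) @ pi
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p1 > 0, -p1 * np.log2(p1), 0.0)
    return {name: float(terms[index[name]]) for name in nodes}


def summarize_node_table(node_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class topology summary plus a Total row from a node-stats table.

    Expects the :meth:`TripartiteNetwork.node_table` columns (``sh1`` and
    degree columns optional); reports n, mean sh1 and median degrees per
    node class in a fixed class order, then the totals.
    """
    if len(node_table) == 0:
        raise DataError("cannot summarize an empty node table")
    rows = []
    blocks = [
        (cls, node_table[node_table["class"] == cls]) for cls in NODE_CLASSES
    ]
    blocks.append(("Total", node_table))
    for name, block in blocks:
        if len(block) == 0:
            continue
        row: dict[str, object] = {"class": name, "n": int(len(block))}
        row["mean_sh1"] = (
            float(block["sh1"].mean()) if "sh1" in block.columns else np.nan
        )
        for col, out in (("deg", "median_deg"), ("deg_in", "median_deg_in"),
                         ("deg_out", "median_deg_out")):
            row[out] = (
                float(block[col].median()) if col in block.columns else np.nan
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["class", "n", "mean_sh1", "median_deg", "median_deg_in",
                 "median_deg_out"],
    )


def class_summary(network: TripartiteNetwork) -> pd.DataFrame:
    """Topology summary of a network: one row per node class plus Total."""
    if network.n_nodes == 0:
        raise DataError("cannot summarize an empty network")
    return summarize_node_table(network.node_table())
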