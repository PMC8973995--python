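"""Anti-correlated sncRNA-mRNA regulatory networks.

An edge joins a differentially expressed regulator (miRNA or tRF/tiRNA) to a
differentially expressed mRNA when (a) the pair survived target prediction
and (b) their directions are opposite: regulator up with target down, or
regulator down with target up. Networks are bipartite; hubs are regulators
ranked by degree with the DE p-value breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_TYPES = ("miRNA", "tRF/tiRNA")


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    target: str
    regulator_direction: str
    target_direction: str
    score: float

    def __post_init__(self) -> None:
        if self.regulator_direction == self.target_direction:
            raise ValueError(
                f"{self.regulator}->{self.target}: directions must be opposite")


def pair_filter(
    de_sncrna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    predicted_pairs: pd.DataFrame,
) -> list[RegulatoryEdge]:
    """Keep predicted pairs whose regulator and target moved oppositely.

    ``de_*`` are diff_expression result tables indexed by feature;
    ``predicted_pairs`` needs columns (sncrna, mrna, best_score). Pairs whose
    ids are missing from the DE tables are logged and dropped; ``ns``
    features never produce an edge.
    """
    edges = []
    for row in predicted_pairs.itertuples(index=False):
        if row.sncrna not in de_sncrna.index or row.mrna not in de_mrna.index:
            logger.warning("pair (%s, %s) missing from DE tables; dropped",
                           row.sncrna, row.mrna)
            continue
        rdir = de_sncrna.loc[row.sncrna, "direction"]
        tdir = de_mrna.loc[row.mrna, "direction"]
        if {rdir, tdir} == {"up", "down"}:
            edges.append(RegulatoryEdge(row.sncrna, row.mrna, rdir, tdir,
                                        float(row.best_score)))
    return edges


def build_network(
    edges: Sequence[RegulatoryEdge],
    de_sncrna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    tf_list: Iterable[str] = (),
    regulator_type: str = "miRNA",
) -> nx.Graph:
    """Bipartite regulator-mRNA graph with DE and TF node annotations.

    Node attributes: ``node_type``, ``is_tf`` (mRNA nodes only), ``degree``,
    ``p_value`` and ``fold_change`` from the DE tables. Edges carry the best
    target-prediction score and a ``direction`` attribute
    (``regulator_to_target``).
    """
    if regulator_type not in REGULATOR_TYPES:
        raise ValueError(f"regulator_type must be one of {REGULATOR_TYPES}")
    tf_set = set(tf_list)
    g = nx.Graph()
    regulators = {e.regulator for e in edges}
    targets = {e.target for e in edges}
    clash = regulators & targets
    if clash:
        raise ValueError(f"node(s) on both sides of the bipartite graph: "
                         f"{sorted(clash)}")
    for e in edges:
        if e.regulator == e.target:
            raise ValueError(f"self-loop on {e.regulator}")
        for node, df, ntype in ((e.regulator, de_sncrna, regulator_type),
                                (e.target, de_mrna, "mRNA")):
            if node not in g:
                g.add_node(
                    node,
                    node_type=ntype,
                    is_tf=bool(ntype == "mRNA" and node in tf_set),
                    p_value=float(df.loc[node, "p_value"]),
                    fold_change=float(df.loc[node, "fold_change"]),
                )
        g.add_edge(e.regulator, e.target, score=e.score,
                   direction="regulator_to_target")
    _refresh_degrees(g)
    _assert_bipartite(g)
    return g


def _refresh_degrees(g: nx.Graph) -> None:
    for node, deg in g.degree():
        g.nodes[node]["degree"] = int(deg)


def _assert_bipartite(g: nx.Graph) -> None:
    for a, b in g.edges():
        types = {g.nodes[a]["node_type"], g.nodes[b]["node_type"]}
        if "mRNA" not in types or len(types) != 2:
            raise ValueError(f"edge {a}--{b} violates the regulator-mRNA "
                             f"bipartite contract")


def hub_ranking(g: nx.Graph, k: int = 10) -> list[str]:
    """Top-k regulator nodes by (degree desc, p-value asc, id asc)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    regs = [n for n, d in g.nodes(data=True) if d["node_type"] != "mRNA"]
    regs.sort(key=lambda n: (-g.degree(n), g.nodes[n].get("p_value", 1.0), n))
    return regs[:k]


def tf_overlap(graph_a: nx.Graph, graph_b: nx.Graph) -> set[str]:
    """Transcription factors present (as TF-flagged nodes) in both graphs."""
    tfs_a = {n for n, d in graph_a.nodes(data=True) if d.get("is_tf")}
    tfs_b = {n for n, d in graph_b.nodes(data=True) if d.get("is_tf")}
    return tfs_a & tfs_b


def merge_networks(graph_a: nx.Graph, graph_b: nx.Graph) -> nx.Graph:
    """Union of two regulatory networks, merging shared mRNA nodes by id.

    Non-degree attributes of shared nodes must agree; degrees are recomputed
    on the merged graph.
    """
    conflicts = []
    for node in set(graph_a) & set(graph_b):
        a = {k: v for k, v in graph_a.nodes[node].items() if k != "degree"}
        b = {k: v for k, v in graph_b.nodes[node].items() if k != "degree"}
        if a != b:
            conflicts.append(node)
    if conflicts:
        raise ValueError(f"conflicting attributes for shared node(s): "
                         f"{sorted(conflicts)}")
    merged = nx.compose(graph_a, graph_b)
    _refresh_degrees(merged)
    _assert_bipartite(merged)
    return merged


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Cytoscape SIF interchange: ``regulator  targets  mRNA`` per edge."""
    lines = []
    for a, b in sorted(g.edges()):
        reg, tgt = (a, b) if g.nodes[a]["node_type"] != "mRNA" else (b, a)
        lines.append(f"{reg}\ttargets\t{tgt}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def node_table(g: nx.Graph) -> pd.DataFrame:
    rows = [{"id": n, **d} for n, d in sorted(g.nodes(data=True))]
    cols = ["id", "node_type", "is_tf", "degree", "p_value", "fold_change"]
    return pd.DataFrame(rows, columns=cols)


def read_tf_list(path: str | Path) -> set[str]:
    """Transcription-factor symbols, one per line; blank lines ignored."""
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def default_tf_list() -> set[str]:
    """The packaged transcription-factor fixture."""
    text = resources.files("trfnet").joinpath("data/tf_list.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}
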