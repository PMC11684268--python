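"""Joint transcriptome-metabolome pathway evidence and key-driver maps.

Two views of convergence between the omics layers:

* a joint pathway table — per shared pathway name, over-representation of
  the significant genes and of the significant metabolites side by side,
  with a combined flag when both layers pass their cutoff; and
* a key-driver-centered reaction map — a small graph of user-annotated
  biochemical reactions around one called key driver, with every node
  painted up/down/unmeasured from the differential tables (the kind of
  curated gene-metabolite diagram drawn around a gluconeogenic regulator
  and its product sugars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ParameterError
from .genesets import ora
from .ioformats import GeneNetwork, GeneSetCollection, write_graphml

logger = logging.getLogger("kdapipe.integrate")

JOINT_COLUMNS = [
    "pathway", "de_genes", "de_metabolites",
    "gene_k", "gene_K", "gene_fold_enrichment", "gene_p", "gene_adj_p",
    "met_k", "met_K", "met_fold_enrichment", "met_p", "met_adj_p",
    "combined",
]


def _significant(results: pd.DataFrame, cutoff: float, column: str) -> set[str]:
    return set(results.index[results[column].le(cutoff)])


def _directional(results: pd.DataFrame, features) -> str:
    parts = []
    for f in sorted(features):
        fc = results.loc[f, "fold_change"]
        arrow = "up" if fc > 1 else ("down" if fc < 1 else "flat")
        parts.append(f"{f}({arrow})")
    return ",".join(parts)


def joint_pathway_table(
    gene_results: pd.DataFrame,
    metabolite_results: pd.DataFrame,
    gene_sets: GeneSetCollection,
    metabolite_map: GeneSetCollection,
    gene_cutoff: float = 0.05,
    metabolite_cutoff: float = 0.05,
    gene_column: str = "adj_p",
    metabolite_column: str = "q",
) -> pd.DataFrame:
    """Per-pathway enrichment of both omics layers on a shared namespace.

    Pathway names must be shared between ``gene_sets`` and
    ``metabolite_map`` (disjoint namespaces are an error).  Per pathway:
    the ORA counts and fold enrichment of the significant genes and of the
    significant metabolites, the member lists with direction/fold, and a
    combined flag set when both layers reach their ORA BH-adjusted cutoff.
    Rows cover every shared pathway with >= 1 detected member in either
    omics.
    """
    if gene_results.empty or metabolite_results.empty:
        raise ParameterError("both differential tables must be non-empty")
    shared = [n for n in gene_sets.names if n in set(metabolite_map.names)]
    if not shared:
        raise ParameterError("gene and metabolite pathway namespaces share no name")

    genes_detected = set(gene_results.index[gene_results["p"].notna()])
    mets_detected = set(metabolite_results.index[metabolite_results["p"].notna()])
    genes_sig = _significant(gene_results, gene_cutoff, gene_column) & genes_detected
    mets_sig = _significant(metabolite_results, metabolite_cutoff, metabolite_column) & mets_detected

    shared_gene_sets = GeneSetCollection(
        sets={n: gene_sets[n] for n in shared},
        descriptions={n: gene_sets.descriptions.get(n, "") for n in shared},
    )
    shared_met_sets = GeneSetCollection(
        sets={n: metabolite_map[n] for n in shared},
        descriptions={n: metabolite_map.descriptions.get(n, "") for n in shared},
    )
    gene_ora = ora(genes_sig, genes_detected, shared_gene_sets).set_index("set_name")
    met_ora = ora(mets_sig, mets_detected, shared_met_sets).set_index("set_name")

    rows = []
    for name in shared:
        g_members = set(shared_gene_sets[name]) & genes_detected
        m_members = set(shared_met_sets[name]) & mets_detected
        if not g_members and not m_members:
            continue
        g = gene_ora.loc[name] if name in gene_ora.index else None
        m = met_ora.loc[name] if name in met_ora.index else None
        g_sig_members = g_members & genes_sig
        m_sig_members = m_members & mets_sig
        combined = (
            g is not None and m is not None
            and g["adj_p"] <= gene_cutoff and m["adj_p"] <= metabolite_cutoff
        )
        rows.append({
            "pathway": name,
            "de_genes": _directional(gene_results, g_sig_members),
            "de_metabolites": ",".join(
                f"{f}({metabolite_results.loc[f, 'fold_change']:.2f})"
                for f in sorted(m_sig_members)
            ),
            "gene_k": int(g["k"]) if g is not None else 0,
            "gene_K": int(g["K"]) if g is not None else 0,
            "gene_fold_enrichment": float(g["fold_enrichment"]) if g is not None else float("nan"),
            "gene_p": float(g["p_value"]) if g is not None else float("nan"),
            "gene_adj_p": float(g["adj_p"]) if g is not None else float("nan"),
            "met_k": int(m["k"]) if m is not None else 0,
            "met_K": int(m["K"]) if m is not None else 0,
            "met_fold_enrichment": float(m["fold_enrichment"]) if m is not None else float("nan"),
            "met_p": float(m["p_value"]) if m is not None else float("nan"),
            "met_adj_p": float(m["adj_p"]) if m is not None else float("nan"),
            "combined": bool(combined),
        })
    return pd.DataFrame(rows, columns=JOINT_COLUMNS)


@dataclass
class KdMap:
    """A reaction map centered on one key driver, with per-node states."""

    center: str
    graph: nx.DiGraph
    states: dict[str, str] = field(default_factory=dict)

    def to_graphml(self, path) -> None:
        write_graphml(
            GeneNetwork(graph=self.graph.copy()),
            {n: {"state": s, "is_center": n == self.center} for n, s in self.states.items()},
            path,
        )


def kd_map(
    kd: pd.Series | dict,
    reactions: pd.DataFrame,
    gene_results: pd.DataFrame,
    metabolite_results: pd.DataFrame,
    radius: int = 2,
    gene_cutoff: float = 0.05,
    metabolite_cutoff: float = 0.05,
    gene_column: str = "adj_p",
    metabolite_column: str = "q",
) -> KdMap:
    """Assemble the reaction map around one called key driver.

    ``kd`` is a row of the KDA result table (needs ``gene`` and ``is_kd``);
    ``reactions`` has columns ``source``, ``target`` and optional
    ``relation``.  The map is the reaction subgraph within ``radius``
    undirected hops of the center (radius 0: the center alone), each node
    annotated ``up``/``down`` when significant in the matching differential
    table and ``unmeasured`` otherwise — unmeasured is distinct from
    unchanged.
    """
    gene = kd["gene"] if "gene" in kd else kd["gene_id"]
    if not bool(kd["is_kd"]):
        raise ParameterError(f"{gene!r} is not a called key driver")
    for col in ("source", "target"):
        if col not in reactions.columns:
            raise ParameterError(f"reactions table lacks column {col!r}")

    g = nx.DiGraph()
    for _, row in reactions.iterrows():
        g.add_edge(row["source"], row["target"],
                   relation=str(row.get("relation", "reaction")))
    if gene not in g:
        raise ParameterError(f"key driver {gene!r} absent from the reaction annotation")

    ego = nx.ego_graph(g.to_undirected(as_view=True), gene, radius=radius)
    sub = nx.DiGraph(g.subgraph(ego.nodes))
    if radius == 0:
        sub = nx.DiGraph()
        sub.add_node(gene)

    states = {}
    for node in sub.nodes:
        states[node] = _node_state(
            node, gene_results, metabolite_results,
            gene_cutoff, metabolite_cutoff, gene_column, metabolite_column,
        )
    return KdMap(center=gene, graph=sub, states=states)


def _node_state(node, gene_results, metabolite_results,
                gene_cutoff, metabolite_cutoff, gene_column, metabolite_column) -> str:
    for results, cutoff, column in (
        (gene_results, gene_cutoff, gene_column),
        (metabolite_results, metabolite_cutoff, metabolite_column),
    ):
        if node in results.index:
            row = results.loc[node]
            if pd.notna(row[column]) and row[column] <= cutoff:
                return "up" if row["fold_change"] > 1 else "down"
            return "unchanged"
    return "unmeasured"
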