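"""Network key-driver analysis (KDA).

Given a directed gene network and a differential signature, every candidate
gene's local neighborhood (nodes within a hop radius, default 1 hop treating
edges as undirected) is tested for over-representation of signature genes
with a one-sided Fisher's exact test against the rest of the network.
Candidates whose Bonferroni-adjusted p-value falls below alpha are called
key drivers — genes whose network surroundings concentrate the
transcriptomic response and are therefore its likely regulators.

Conventions: the background universe is the network's node set (the test is
about topology, so the signature is intersected with the network first and
the discarded count logged); the Bonferroni divisor is the number of
candidates actually tested; candidates need a minimum neighborhood size
(default 5) for the 2x2 table to be informative.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ioformats import GeneNetwork

logger = logging.getLogger("kdapipe.kda")

KDA_COLUMNS = ["gene", "neighborhood_size", "overlap", "fisher_p", "bonferroni_p", "is_kd"]


def _directed_view(network: GeneNetwork, direction: str):
    g = network.graph
    if direction == "out":
        return g
    if direction == "in":
        return g.reverse(copy=False)
    if direction == "both":
        return g.to_undirected(as_view=True)
    raise ParameterError(f"direction must be 'out', 'in' or 'both', got {direction!r}")


def neighborhood(
    network: GeneNetwork, gene: str, radius: int = 1, direction: str = "both"
) -> set[str]:
    """Genes within ``radius`` hops of ``gene`` (excluding the gene itself)."""
    if gene not in network:
        raise ParameterError(f"gene {gene!r} not in network")
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    view = _directed_view(network, direction)
    reach = nx.single_source_shortest_path_length(view, gene, cutoff=radius)
    reach.pop(gene, None)
    return set(reach)


def extract_subnetwork(
    network: GeneNetwork, seeds, expand: int = 1
) -> tuple[GeneNetwork, pd.DataFrame]:
    """Seed-based subnetwork extraction.

    Takes the induced subgraph on the seeds plus their ``expand``-hop
    neighbors (undirected reach), splits it into weakly connected
    components, ranks components by edge count (ties: node count, then the
    lexicographically smallest member), and returns the top component with
    the full ranking table.  Seeds absent from the network are logged, not
    fatal; zero overlapping seeds is an error.
    """
    seeds = set(seeds)
    present = seeds & network.nodes
    absent = seeds - present
    if absent:
        logger.info("%d seed(s) absent from network", len(absent))
    if not present:
        raise ParameterError("no seed overlaps the network (overlap 0)")

    keep = set(present)
    for s in sorted(present):
        keep |= neighborhood(network, s, radius=expand, direction="both") if expand else set()
    sub = network.graph.subgraph(keep)
    components = sorted(
        nx.weakly_connected_components(sub),
        key=lambda comp: (
            -sub.subgraph(comp).number_of_edges(), -len(comp), min(comp),
        ),
    )
    ranking = pd.DataFrame([
        {
            "rank": i + 1,
            "n_nodes": len(comp),
            "n_edges": sub.subgraph(comp).number_of_edges(),
            "n_seeds": len(comp & present),
            "min_node": min(comp),
        }
        for i, comp in enumerate(components)
    ])
    top = GeneNetwork(graph=nx.DiGraph(sub.subgraph(components[0])))
    return top, ranking


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    P(X >= a) where X is hypergeometric with population a+b+c+d, a+b draws
    and a+c successes — the probability of at least the observed overlap
    given the margins.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ParameterError(f"count {name} must be a nonnegative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def key_driver_analysis(
    network: GeneNetwork,
    signature,
    radius: int = 1,
    direction: str = "both",
    alpha: float = 0.05,
    min_neighborhood: int = 5,
) -> pd.DataFrame:
    """Per-gene neighborhood enrichment of a signature (Fisher + Bonferroni).

    For each candidate (node with neighborhood >= ``min_neighborhood``), a
    2x2 table of neighborhood vs rest-of-network (excluding the candidate)
    against signature membership is tested one-sided for enrichment; the
    Bonferroni correction multiplies by the number of candidates tested.
    Genes with bonferroni_p < alpha are flagged key drivers.  Sorted by
    bonferroni_p ascending, ties by gene id.
    """
    sig_all = set(signature)
    sig = sig_all & network.nodes
    if len(sig) < len(sig_all):
        logger.info("%d signature gene(s) outside the network discarded",
                    len(sig_all) - len(sig))
    if not sig:
        raise ParameterError("signature does not overlap the network")

    nodes = network.nodes
    neighborhoods = {}
    for gene in sorted(nodes):
        nb = neighborhood(network, gene, radius=radius, direction=direction)
        if len(nb) >= min_neighborhood:
            neighborhoods[gene] = nb
    if not neighborhoods:
        raise ParameterError(
            f"no candidate has a neighborhood of size >= {min_neighborhood}; "
            "lower min_neighborhood"
        )
    n_candidates = len(neighborhoods)

    rows = []
    for gene, nb in neighborhoods.items():
        rest = nodes - nb - {gene}
        a = len(nb & sig)
        b = len(nb) - a
        c = len(sig & rest)
        d = len(rest) - c
        p = fisher_one_sided(a, b, c, d)
        bonf = min(1.0, p * n_candidates)
        rows.append({
            "gene": gene, "neighborhood_size": len(nb), "overlap": a,
            "fisher_p": p, "bonferroni_p": bonf, "is_kd": bonf < alpha,
        })
    out = pd.DataFrame(rows, columns=KDA_COLUMNS)
    return out.sort_values(["bonferroni_p", "gene"], kind="stable").reset_index(drop=True)


def kda_node_annotations(
    network: GeneNetwork, signature, kda_results: pd.DataFrame
) -> dict[str, dict[str, object]]:
    """Node attribute map (signature membership, KD flag) for GraphML export."""
    sig = set(signature)
    kd = set(kda_results.loc[kda_results["is_kd"], "gene"])
    return {
        node: {"in_signature": node in sig, "is_kd": node in kd}
        for node in sorted(network.nodes)
    }
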