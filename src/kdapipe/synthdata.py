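"""Synthetic multi-omics benchmark generators with planted, recorded truth.

The generators emulate a two-group inhalation-exposure study design:
transcriptomics at n = 8 animals per group and metabolomics at n = 5 per
group, a directed scale-free gene network harbouring planted key drivers,
and pathway annotations tying genes to metabolites.  Every generator
records exactly what it planted in a :class:`SyntheticTruth`, so each
downstream stage can be scored for recovery without any external data.

Defaults mirror the study conditions being emulated: expression baselines
``Normal(8, 1.5^2)`` on the log2 scale with residual SD 0.25 (plausible for
rank-invariant-normalized bead-array intensities), and a metabolite
fold-change palette spanning 0.35x up to 104x — the range reported for
TCA-cycle intermediates and glycogen-breakdown products (citrate 0.35,
maltohexaose 104.13, maltose 18.13, fructose 9.6, mannose 4.52, glucose
3.26, tagatose 2.46).

Reproducibility: one global seed expands into per-stage child seeds through
:func:`child_seed`, a fixed scheme (``SeedSequence(seed, spawn_key=(code,))``
with a documented code per stage), so each stage is independently
re-runnable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .ioformats import (
    ExpressionMatrix,
    GeneNetwork,
    GeneSetCollection,
    MetaboliteTable,
    MetabolitePathwayMap,
)

logger = logging.getLogger("kdapipe.synthdata")

#: Fixed stage codes for the seed-expansion scheme.
STAGE_CODES = {
    "expression": 1,
    "metabolome": 2,
    "network": 3,
    "pathways": 4,
    "gsea": 5,
    "classify": 6,
}

#: Default planted metabolite fold changes; spans the 0.35-104x scale of the
#: emulated study (see module docstring).
DEFAULT_METABOLITE_EFFECTS = (104.13, 18.13, 9.6, 4.52, 3.26, 2.46, 1.77, 0.35)

CONTROL_GROUP = "FA"
TREATED_GROUP = "DE"


def child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Expand the global seed into the named stage's child seed sequence."""
    if stage not in STAGE_CODES:
        raise ParameterError(f"unknown stage {stage!r}")
    return np.random.SeedSequence(seed, spawn_key=(STAGE_CODES[stage],))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator: what was planted, and how.

    ``planted_degs`` maps gene id -> signed log2 effect; ``planted_metabolites``
    maps metabolite id -> multiplicative fold effect; ``planted_drivers`` is
    the set of planted key-driver genes; ``seeded_pathways`` names pathways
    enriched by construction.  ``generator_params`` holds every distribution
    parameter and the seed used.
    """

    planted_degs: dict[str, float] = field(default_factory=dict)
    planted_metabolites: dict[str, float] = field(default_factory=dict)
    planted_drivers: set[str] = field(default_factory=set)
    seeded_pathways: list[str] = field(default_factory=list)
    generator_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_degs": self.planted_degs,
            "planted_metabolites": self.planted_metabolites,
            "planted_drivers": sorted(self.planted_drivers),
            "seeded_pathways": list(self.seeded_pathways),
            "generator_params": self.generator_params,
        }


def _two_group_samples(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    control = [f"{CONTROL_GROUP}{i + 1}" for i in range(n_per_group)]
    treated = [f"{TREATED_GROUP}{i + 1}" for i in range(n_per_group)]
    groups = {s: CONTROL_GROUP for s in control}
    groups.update({s: TREATED_GROUP for s in treated})
    return control + treated, groups


def simulate_expression(
    n_genes: int = 10_000,
    n_per_group: int = 8,
    frac_de: float = 0.05,
    effect_range: tuple[float, float] = (1.0, 2.0),
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a two-group log2 expression matrix with planted DEGs.

    Exactly ``round(frac_de * n_genes)`` genes receive a signed log2 shift
    drawn uniformly from ``effect_range`` (sign Rademacher) in the treated
    group.  Per-gene baselines are Normal(``baseline_mean``,
    ``baseline_sd``^2); i.i.d. Normal(0, ``noise_sd``^2) residuals on top.

    Returns the matrix (log2 scale, groups FA/DE) and the recorded truth.
    """
    if n_genes < 10:
        raise ParameterError(f"n_genes must be >= 10, got {n_genes}")
    if n_per_group < 2:
        raise ParameterError(f"n_per_group must be >= 2, got {n_per_group}")
    if not (0 <= frac_de < 1):
        raise ParameterError(f"frac_de must be in [0, 1), got {frac_de}")
    lo, hi = effect_range
    if lo <= 0 or hi < lo:
        raise ParameterError(f"effect_range must satisfy 0 < lo <= hi, got {effect_range}")
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be positive, got {noise_sd}")

    rng = np.random.default_rng(child_seed(seed, "expression"))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples, groups = _two_group_samples(n_per_group)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    effects = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    values[de_idx, n_per_group:] += effects[:, None]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )
    truth = SyntheticTruth(
        planted_degs={genes[i]: float(e) for i, e in zip(de_idx, effects)},
        generator_params={
            "stage": "expression", "n_genes": n_genes, "n_per_group": n_per_group,
            "frac_de": frac_de, "effect_range": list(effect_range),
            "noise_sd": noise_sd, "baseline_mean": baseline_mean,
            "baseline_sd": baseline_sd, "seed": seed,
        },
    )
    return matrix, truth


def simulate_metabolome(
    n_metabolites: int = 500,
    n_per_group: int = 5,
    planted_effects: tuple[float, ...] = DEFAULT_METABOLITE_EFFECTS,
    detection_floor: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.25,
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 2.0,
    n_pathway_groups: int = 8,
) -> tuple[MetaboliteTable, SyntheticTruth]:
    """Simulate log-normal metabolite abundances with planted fold changes.

    The first ``len(planted_effects)`` metabolites are multiplied by their
    fold change in the treated group; a fold change of exactly 1.0 is a
    no-op and is omitted from the truth.  Abundances below
    ``detection_floor`` are recorded as missing.  Annotations assign each
    metabolite a ``super_pathway``/``sub_pathway`` label cyclically over
    ``n_pathway_groups`` synthetic pathway names.
    """
    if n_per_group < 2:
        raise ParameterError(f"n_per_group must be >= 2, got {n_per_group}")
    if any(f <= 0 for f in planted_effects):
        raise ParameterError("planted_effects must all be positive fold changes")
    if len(planted_effects) > n_metabolites:
        raise ParameterError("more planted effects than metabolites")

    rng = np.random.default_rng(child_seed(seed, "metabolome"))
    mets = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    samples, groups = _two_group_samples(n_per_group)

    base_log2 = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_metabolites)
    log2_vals = base_log2[:, None] + rng.normal(
        0.0, noise_sd, size=(n_metabolites, 2 * n_per_group)
    )
    effects = np.asarray(planted_effects, dtype=float)
    log2_vals[: len(effects), n_per_group:] += np.log2(effects)[:, None]
    abund = np.power(2.0, log2_vals)

    abund = pd.DataFrame(abund, index=mets, columns=samples)
    if detection_floor > 0:
        below = abund < detection_floor
        n_below = int(below.sum().sum())
        if n_below:
            logger.info("%d value(s) below detection floor -> missing", n_below)
        abund = abund.mask(below)
        if abund.isna().all().all():
            warnings.warn("detection floor exceeds every abundance; table is all-missing")

    sp_names = [f"SP{i + 1}" for i in range(n_pathway_groups)]
    ann = pd.DataFrame(
        {
            "super_pathway": [sp_names[i % n_pathway_groups] for i in range(n_metabolites)],
            "sub_pathway": [
                f"{sp_names[i % n_pathway_groups]}.{i % 3 + 1}" for i in range(n_metabolites)
            ],
        },
        index=mets,
    )
    table = MetaboliteTable(abundances=abund, annotations=ann, groups=groups)
    truth = SyntheticTruth(
        planted_metabolites={
            mets[i]: float(f) for i, f in enumerate(effects) if f != 1.0
        },
        generator_params={
            "stage": "metabolome", "n_metabolites": n_metabolites,
            "n_per_group": n_per_group, "planted_effects": [float(f) for f in effects],
            "detection_floor": detection_floor, "noise_sd": noise_sd,
            "baseline_log2_mean": baseline_log2_mean,
            "baseline_log2_sd": baseline_log2_sd, "seed": seed,
        },
    )
    return table, truth


def simulate_network(
    n_nodes: int = 1000,
    n_drivers: int = 10,
    rho_in: float = 0.7,
    rho_bg: float = 0.05,
    seed: int = 0,
    attachment: int = 3,
) -> tuple[GeneNetwork, set[str], SyntheticTruth]:
    """Simulate a directed scale-free network with planted key drivers.

    A Barabási–Albert graph (``attachment`` edges per new node) is oriented
    by flipping a fair coin per edge.  Drivers are sampled among the top 5%
    of nodes by total degree: a planted driver must have a neighborhood
    large enough that its enrichment is detectable in principle — at
    ``rho_in=0.7`` against a Bonferroni correction over several hundred
    candidates, a median overlap of 0.7 x degree needs degree around 14 or
    more, which the 5% pool guarantees while the decile boundary (degree
    near 10) does not.  The returned signature contains each driver
    neighbor with probability ``rho_in`` and every other node with
    probability ``rho_bg``; truth records the drivers.
    """
    if n_drivers >= n_nodes:
        raise ParameterError("n_drivers must be < n_nodes")
    if n_drivers > 0 and not (0 <= rho_bg < rho_in <= 1):
        raise ParameterError(
            f"need 0 <= rho_bg < rho_in <= 1 (got rho_in={rho_in}, rho_bg={rho_bg}); "
            "otherwise the planted enrichment would be absent"
        )

    ss = child_seed(seed, "network")
    rng = np.random.default_rng(ss)
    # networkx wants an int seed; derive one from the same stream
    base = nx.barabasi_albert_graph(
        n_nodes, attachment, seed=int(rng.integers(2**31 - 1))
    )
    names = {i: f"G{i + 1:05d}" for i in range(n_nodes)}
    g = nx.DiGraph()
    g.add_nodes_from(names.values())
    for u, v in base.edges():
        if rng.random() < 0.5:
            u, v = v, u
        g.add_edge(names[u], names[v])
    network = GeneNetwork(graph=g)

    degree = dict(base.degree())
    order = sorted(degree, key=lambda n: (-degree[n], n))
    pool = order[: max(n_drivers, n_nodes // 20)]
    driver_idx = rng.choice(len(pool), size=n_drivers, replace=False) if n_drivers else []
    drivers = {names[pool[i]] for i in driver_idx}

    neighbor_pool: set[str] = set()
    for d in drivers:
        neighbor_pool |= set(g.successors(d)) | set(g.predecessors(d))

    # every node is eligible, drivers included: a driver adjacent to another
    # driver is itself a driver-neighbor and enters at rho_in
    signature: set[str] = set()
    for node in sorted(names.values()):
        p = rho_in if node in neighbor_pool else rho_bg
        if rng.random() < p:
            signature.add(node)

    truth = SyntheticTruth(
        planted_drivers=drivers,
        generator_params={
            "stage": "network", "n_nodes": n_nodes, "n_drivers": n_drivers,
            "rho_in": rho_in, "rho_bg": rho_bg, "attachment": attachment, "seed": seed,
        },
    )
    return network, signature, truth


def simulate_pathways(
    genes: list[str],
    metabolites: list[str],
    n_pathways: int = 20,
    sizes: tuple[int, int] = (10, 50),
    seed: int = 0,
    planted_genes: set[str] | None = None,
    planted_metabolites: set[str] | None = None,
    n_seeded: int = 3,
    seeded_fraction: float = 0.5,
) -> tuple[GeneSetCollection, MetabolitePathwayMap, SyntheticTruth]:
    """Simulate joint gene/metabolite pathway annotations.

    Pathways share a namespace across the two omics (``PW001``...).  The
    first ``n_seeded`` pathways are enriched by construction: a
    ``seeded_fraction`` of their gene members come from ``planted_genes``
    and of their metabolite members from ``planted_metabolites`` (when
    provided).  Truth flags those pathway names.
    """
    if not genes:
        raise ParameterError("gene universe is empty")
    if not metabolites:
        raise ParameterError("metabolite universe is empty")
    lo, hi = sizes
    if lo < 1 or hi < lo:
        raise ParameterError(f"sizes must satisfy 1 <= lo <= hi, got {sizes}")
    if hi > len(genes):
        raise ParameterError("pathway size range exceeds gene universe")
    n_seeded = min(n_seeded, n_pathways)

    rng = np.random.default_rng(child_seed(seed, "pathways"))
    planted_genes = sorted(planted_genes or ())
    planted_metabolites = sorted(planted_metabolites or ())

    gene_sets: dict[str, list[str]] = {}
    met_sets: dict[str, list[str]] = {}
    seeded: list[str] = []
    for i in range(n_pathways):
        name = f"PW{i + 1:03d}"
        g_size = int(rng.integers(lo, hi + 1))
        m_size = int(rng.integers(max(1, lo // 2), max(2, hi // 2)))
        m_size = min(m_size, len(metabolites))
        seed_this = i < n_seeded and (planted_genes or planted_metabolites)
        if seed_this:
            members = _seeded_sample(rng, genes, planted_genes, g_size, seeded_fraction)
            met_members = _seeded_sample(
                rng, metabolites, planted_metabolites, m_size, seeded_fraction
            )
            seeded.append(name)
        else:
            members = sorted(rng.choice(genes, size=g_size, replace=False).tolist())
            met_members = sorted(rng.choice(metabolites, size=m_size, replace=False).tolist())
        gene_sets[name] = members
        met_sets[name] = met_members

    descs = {n: ("seeded" if n in seeded else "background") for n in gene_sets}
    truth = SyntheticTruth(
        seeded_pathways=seeded,
        generator_params={
            "stage": "pathways", "n_pathways": n_pathways, "sizes": list(sizes),
            "n_seeded": n_seeded, "seeded_fraction": seeded_fraction, "seed": seed,
        },
    )
    return (
        GeneSetCollection(sets=gene_sets, descriptions=descs),
        MetabolitePathwayMap(sets=met_sets, descriptions=dict(descs)),
        truth,
    )


def _seeded_sample(
    rng: np.random.Generator,
    universe: list[str],
    planted: list[str],
    size: int,
    fraction: float,
) -> list[str]:
    n_planted = min(int(round(fraction * size)), len(planted))
    chosen = (
        rng.choice(planted, size=n_planted, replace=False).tolist() if n_planted else []
    )
    rest_pool = [u for u in universe if u not in set(chosen)]
    n_rest = min(size - n_planted, len(rest_pool))
    chosen += rng.choice(rest_pool, size=n_rest, replace=False).tolist()
    return sorted(set(chosen))
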