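"""On-disk formats and the typed containers every stage consumes.

Tabular data travel as UTF-8 tab-separated text: feature-by-sample matrices
with the feature identifier in the first column and sample identifiers in
the header, sample->group maps as two-column TSV, gene sets as GMT, directed
networks as SIF (``source\\trelation\\ttarget``) or two-column TSV, and
annotated networks as GraphML for Cytoscape-style viewers.

Missing-value tokens accepted on read: the empty cell, ``NA`` and ``NaN``
(metabolomics exports vary); occurrences are logged per file. Identifier
matching everywhere is case-sensitive exact string match — silent case
folding hides annotation bugs (mouse Pck1 vs human PCK1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import LoadError, ParameterError

logger = logging.getLogger("kdapipe.ioformats")

MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: Column names treated as metabolite annotations rather than samples.
ANNOTATION_COLUMNS = ("super_pathway", "sub_pathway")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale intensities, features x samples, with a group per sample.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    groups
        Mapping sample id -> group label (e.g. FA, DE, DE+FA).
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise LoadError(f"duplicate feature id(s): {', '.join(map(str, dups[:5]))}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise LoadError(f"duplicate sample id(s): {', '.join(map(str, dups[:5]))}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise LoadError(f"sample(s) absent from group map: {', '.join(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class MetaboliteTable:
    """Original-scale metabolite abundances with pathway annotations.

    ``abundances`` holds nonnegative values with NaN for below-detection or
    unmeasured cells.  ``annotations`` is indexed by metabolite id and has
    ``super_pathway`` / ``sub_pathway`` columns ("unknown" when absent).
    """

    abundances: pd.DataFrame
    annotations: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.abundances.index.has_duplicates:
            dups = self.abundances.index[self.abundances.index.duplicated()].unique()
            raise LoadError(f"duplicate metabolite id(s): {', '.join(map(str, dups[:5]))}")
        missing = [s for s in self.abundances.columns if s not in self.groups]
        if missing:
            raise LoadError(f"sample(s) absent from group map: {', '.join(missing)}")
        unannotated = self.abundances.index.difference(self.annotations.index)
        if len(unannotated):
            raise LoadError(
                f"metabolite(s) without annotation row: {', '.join(map(str, unannotated[:5]))}"
            )
        if (self.abundances < 0).any().any():
            raise LoadError("negative abundance encountered")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.abundances.columns if self.groups[s] == group]


@dataclass
class GeneNetwork:
    """Directed gene-gene network backed by a :class:`networkx.DiGraph`.

    Self-loops are dropped (with a logged count) at construction; the node
    universe may include isolated genes beyond the edge endpoints.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)
            logger.info("dropped %d self-loop(s)", len(loops))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class GeneSetCollection:
    """Named, ordered sets of feature ids with optional descriptions (GMT)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise LoadError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


#: Metabolite pathway annotations share GMT semantics with gene sets.
MetabolitePathwayMap = GeneSetCollection


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_groups(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LoadError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            if parts[0] in ("sample", "sample_id") and lineno == 1:
                continue  # optional header
            groups[parts[0]] = parts[1]
    return groups


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, dtype=str,
    )
    return df


def read_matrix(
    path: str | Path,
    groups_path: str | Path,
    kind: str = "auto",
) -> ExpressionMatrix | MetaboliteTable:
    """Load a feature-by-sample matrix plus its sample->group map.

    ``kind`` is ``"expression"``, ``"metabolite"`` or ``"auto"`` (metabolite
    when annotation columns ``super_pathway``/``sub_pathway`` are present).
    Missing cells stay missing; non-numeric cells and duplicate ids are
    load errors naming the offender.
    """
    groups = _read_groups(groups_path)
    raw = _read_table(path)
    ann_cols = [c for c in ANNOTATION_COLUMNS if c in raw.columns]
    if kind == "auto":
        kind = "metabolite" if ann_cols else "expression"
    if kind not in ("expression", "metabolite"):
        raise ParameterError(f"kind must be expression/metabolite/auto, got {kind!r}")

    data = raw.drop(columns=ann_cols)
    n_missing = int(data.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing cell(s)", path, n_missing)
    numeric = pd.DataFrame(index=data.index)
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna()
        if bad.any():
            row = data.index[bad.argmax()]
            raise LoadError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{data.loc[row, col]!r}"
            )
        numeric[col] = converted

    if kind == "expression":
        return ExpressionMatrix(values=numeric, groups=groups)
    ann = pd.DataFrame(index=raw.index)
    for col in ANNOTATION_COLUMNS:
        ann[col] = raw[col] if col in raw.columns else "unknown"
    ann = ann.fillna("unknown")
    return MetaboliteTable(abundances=numeric, annotations=ann, groups=groups)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...), order-preserving.

    Duplicate members within a set are deduplicated with a logged warning;
    a line with fewer than three fields is a load error with its number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise LoadError(f"{path}: line {lineno}: GMT needs >=3 fields")
            name, desc, *members = parts
            members = [m for m in members if m]
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.warning("%s: set %s: duplicate member %s", path, name, m)
                seen[m] = None
            if name in sets:
                raise LoadError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = list(seen)
            descriptions[name] = desc
    if n_lines == 0:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_network(path: str | Path) -> GeneNetwork:
    """Load a directed network from SIF (3 columns) or 2-column TSV.

    Duplicate edges collapse to one; self-loops are dropped and counted.
    """
    g = nx.DiGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                src, _, tgt = parts
            elif len(parts) == 2:
                src, tgt = parts
            else:
                raise LoadError(f"{path}: line {lineno}: expected 2 or 3 fields")
            if not src or not tgt:
                raise LoadError(f"{path}: line {lineno}: empty node id")
            g.add_edge(src, tgt)
    return GeneNetwork(graph=g)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix | MetaboliteTable, path: str | Path) -> None:
    """Write a matrix as TSV, annotations (if any) as leading columns."""
    if isinstance(matrix, MetaboliteTable):
        out = matrix.annotations.join(matrix.abundances)
        out.index.name = "metabolite"
    else:
        out = matrix.values.copy()
        out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_network(network: GeneNetwork, path: str | Path, fmt: str = "sif") -> None:
    """Write edges as SIF (relation column ``reg``) or 2-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for src, tgt in network.edges:
            if fmt == "sif":
                fh.write(f"{src}\treg\t{tgt}\n")
            else:
                fh.write(f"{src}\t{tgt}\n")


def write_graphml(
    network: GeneNetwork,
    annotations: Mapping[str, Mapping[str, object]],
    path: str | Path,
) -> None:
    """Export the network with node attributes to GraphML.

    ``annotations`` maps node id -> attribute dict (e.g. signature
    membership, key-driver flag); an attribute for an unknown node is an
    error.  Booleans are serialized as 0/1 integers for viewer portability.
    """
    unknown = [n for n in annotations if n not in network.graph]
    if unknown:
        raise ParameterError(f"annotation for unknown node(s): {', '.join(unknown[:5])}")
    g = network.graph.copy()
    for node, attrs in annotations.items():
        for key, val in attrs.items():
            if isinstance(val, bool):
                val = int(val)
            g.nodes[node][key] = val
    nx.write_graphml(g, str(path))


def write_truth_json(truth_dict: dict, path: str | Path) -> None:
    """Serialize ground truth (or any report) deterministically as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth_dict, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
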