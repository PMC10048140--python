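"""File formats and domain containers for the pathway-walk pipeline.

Expression matrices are pandas DataFrames with genes on the rows and
samples on the columns, read from plain TSV or GCT.  Phenotype labels are
an integer Series (0 = normal, 1 = tumor) aligned to the sample axis.
Directed gene-gene networks come from SIF edge lists and pathway
membership from GMT gene sets; both are kept as light dataclasses so the
walk code can attach a sparse transition matrix without dragging a graph
library through every signature.

Gene identifiers are opaque, case-sensitive strings throughout: matching
between expression, networks and gene sets is exact string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "EmptyInputError",
    "DirectedPathwayNetwork",
    "PathwayCollection",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "validate_labels",
    "read_network_sif",
    "write_network_sif",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyInputError(ValueError):
    """An input is syntactically valid but contains no usable data."""


@dataclass
class DirectedPathwayNetwork:
    """A directed gene graph, optionally carrying a row-stochastic transition.

    Parameters
    ----------
    name:
        Label for the network (e.g. ``"KEGG"`` or ``"PID"``), used to tag
        walk results and pathway-activity provenance.
    nodes:
        Ordered, unique gene identifiers.
    edges:
        Ordered ``(source, target)`` pairs; every endpoint must be a node
        and duplicates are rejected.
    transition:
        Optional sparse row-stochastic matrix over ``nodes`` (each row sums
        to 1 within 1e-12), as built by
        :func:`edrw.walk.build_entropy_transition`.
    """

    name: str
    nodes: list[str]
    edges: list[tuple[str, str]]
    transition: sparse.csr_matrix | None = None

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"network {self.name!r}: duplicate node identifiers")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError(f"network {self.name!r}: duplicate edges")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(
                    f"network {self.name!r}: edge ({u!r}, {v!r}) has an "
                    "endpoint outside the node list"
                )
        if self.transition is not None:
            n = len(self.nodes)
            if self.transition.shape != (n, n):
                raise ValueError(
                    f"network {self.name!r}: transition shape "
                    f"{self.transition.shape} does not match {n} nodes"
                )
            rowsums = np.asarray(self.transition.sum(axis=1)).ravel()
            if not np.allclose(rowsums, 1.0, rtol=0.0, atol=1e-12):
                worst = float(np.abs(rowsums - 1.0).max())
                raise ValueError(
                    f"network {self.name!r}: transition rows must sum to 1 "
                    f"(max deviation {worst:.3e})"
                )

    @cached_property
    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self):
        """Export as a :class:`networkx.DiGraph` (topology only)."""
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class PathwayCollection:
    """Ordered pathway gene sets with per-pathway source-network labels."""

    pathway_ids: list[str]
    members: dict[str, frozenset[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway identifiers")
        if set(self.members) != set(self.pathway_ids):
            raise ValueError("members must be keyed exactly by pathway_ids")
        for pid, genes in self.members.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.pathway_ids)

    def sizes(self) -> dict[str, int]:
        return {pid: len(self.members[pid]) for pid in self.pathway_ids}

    def subset_by_source(self, source: str) -> "PathwayCollection":
        ids = [p for p in self.pathway_ids if self.sources.get(p) == source]
        return PathwayCollection(
            pathway_ids=ids,
            members={p: self.members[p] for p in ids},
            sources={p: source for p in ids},
        )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene id, keeping first-occurrence order."""
    if frame.index.duplicated().any():
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene id(s) by mean: %s",
            len(dups), ", ".join(map(str, dups[:10])),
        )
        frame = frame.groupby(level=0, sort=False).mean()
    return frame


def _coerce_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        return frame.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc


def read_expression(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or GCT.

    The first column holds gene identifiers; rows sharing an identifier are
    collapsed by arithmetic mean.  Empty cells become ``NaN`` (missing,
    to be handled by :func:`edrw.preprocess.impute_row_mean`).  File order
    of genes and samples is preserved.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {fmt!r}")

    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().rstrip("\n")
            dims = fh.readline().rstrip("\n").split("\t")
        if not version.startswith("#1."):
            raise FormatError(f"{path}: missing GCT version line (#1.2)")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed GCT dimension line") from exc
        frame = pd.read_csv(
            path, sep="\t", skiprows=2, index_col=0, float_precision="round_trip"
        )
        if frame.shape[1] < 1:
            raise EmptyInputError(f"{path}: GCT body has no sample columns")
        frame = frame.iloc[:, 1:]  # drop the Description column
        if frame.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: declared dimensions ({n_rows}, {n_cols}) disagree "
                f"with body {frame.shape}"
            )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty header line")
        if len(header.split("\t")) < 2:
            raise EmptyInputError(f"{path}: no sample columns")
        frame = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )

    if frame.shape[1] == 0:
        raise EmptyInputError(f"{path}: no sample columns")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame = _coerce_numeric(frame, path)
    return _collapse_duplicate_genes(frame)


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV (round-trips exactly)."""
    frame.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


# ---------------------------------------------------------------------------
# phenotype labels
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (``sample_id``, ``label``) of 0/1 phenotypes."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected columns sample_id<TAB>label")
    sample_ids = frame.iloc[:, 0].astype(str)
    try:
        values = frame.iloc[:, 1].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: labels must be integers 0/1") from exc
    if not set(values.unique()) <= {0, 1}:
        raise FormatError(f"{path}: labels must be 0 (normal) or 1 (tumor)")
    labels = pd.Series(values.to_numpy(), index=sample_ids.to_numpy(), name="label")
    if labels.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def validate_labels(labels: pd.Series, sample_ids: Iterable[str]) -> pd.Series:
    """Check label/sample alignment and that both classes are present."""
    sample_ids = list(sample_ids)
    if list(labels.index) != sample_ids:
        missing = set(sample_ids).symmetric_difference(labels.index)
        raise ValueError(
            "labels and expression sample ids differ "
            f"(symmetric difference: {sorted(missing)[:10]})"
            if missing
            else "labels and expression sample ids are ordered differently"
        )
    present = set(np.unique(labels.to_numpy()))
    if present != {0, 1}:
        raise ValueError(f"both classes must be present, got labels {sorted(present)}")
    return labels


# ---------------------------------------------------------------------------
# SIF networks
# ---------------------------------------------------------------------------

def read_network_sif(path: str | Path, name: str) -> DirectedPathwayNetwork:
    """Read a directed edge list in three-column SIF dialect.

    Each non-blank line is ``source<TAB>relation<TAB>target``; the relation
    token is ignored for topology and direction is taken as written
    (source -> target).  Duplicate edge lines are deduplicated; the node
    list is the lexicographically sorted union of endpoints.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            edge = (fields[0], fields[2])
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    if not edges:
        raise EmptyInputError(f"{path}: no edges (empty network)")
    nodes = sorted({g for e in edges for g in e})
    return DirectedPathwayNetwork(name=name, nodes=nodes, edges=edges)


def write_network_sif(
    net: DirectedPathwayNetwork, path: str | Path, relation: str = "directed"
) -> None:
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{u}\t{relation}\t{v}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str = "") -> PathwayCollection:
    """Read pathway membership from a GMT file.

    Each line is ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``;
    repeated genes within a line count once and pathway order is preserved.
    """
    path = Path(path)
    pathway_ids: list[str] = []
    members: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 fields "
                    "(id, description, genes...)"
                )
            pid = fields[0]
            if pid in members:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} lists no genes")
            pathway_ids.append(pid)
            members[pid] = genes
    if not pathway_ids:
        raise EmptyInputError(f"{path}: no pathways")
    return PathwayCollection(
        pathway_ids=pathway_ids,
        members=members,
        sources={pid: source for pid in pathway_ids},
    )


def write_gmt(
    coll: PathwayCollection,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write a pathway collection as GMT (members sorted for stable bytes)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for pid in coll.pathway_ids:
            desc = descriptions.get(pid, coll.sources.get(pid, "na")) or "na"
            genes = "\t".join(sorted(coll.members[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")
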