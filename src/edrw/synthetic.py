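"""Synthetic two-network cohorts with planted risk-active pathways.

The generator emulates the study setting — two directed pathway
databases over a partially shared gene pool, plus a binary expression
cohort — so every pipeline stage runs without external downloads.
Pathways are directed Erdos-Renyi blocks with sparse cross-pathway
edges; expression is i.i.d. standard normal noise, with tumor samples of
genes in planted pathways shifted by the effect size (a configurable
coherence fraction shifted up, the rest down).  Generation order is
fixed and integer-indexed, so outputs are byte-identical under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DirectedPathwayNetwork, PathwayCollection

__all__ = ["SyntheticSpec", "simulate_networks", "simulate_expression", "simulate"]


@dataclass
class SyntheticSpec:
    """Generator configuration; the defaults are the study conditions
    used throughout the test-bed (two 50-pathway networks of sizes 10-40,
    three planted pathways at effect size 1.5 noise SDs with full
    direction coherence, and a 60 normal + 60 tumor cohort)."""

    n_genes: int = 1000
    n_pathways: int = 50            # per network
    pathway_size: tuple[int, int] = (10, 40)
    within_p: float = 0.3           # edge prob inside a pathway block
    cross_p: float = 5e-4           # edge prob between any other gene pair
    n_planted: int = 3              # planted pathways (first network)
    effect_size: float = 1.5        # tumor shift, in noise-SD units
    coherence: float = 1.0          # fraction of planted genes shifted up
    n_normal: int = 60
    n_tumor: int = 60
    missing_rate: float = 0.0
    shared_fraction: float = 0.3    # gene overlap between the two networks
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_p", "cross_p", "coherence", "missing_rate",
                     "shared_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        lo, hi = self.pathway_size
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid pathway size bounds {self.pathway_size}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted signal."""

    planted_pathways: list[str]
    gene_effects: pd.Series  # signed shift per gene (0 for null genes)
    labels: pd.Series = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_effects.index, "effect": self.gene_effects.to_numpy()}
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _network_pools(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """Two per-network gene pools carved from one pool, overlapping by
    roughly ``shared_fraction`` of each pool."""
    genes = _gene_names(spec.n_genes)
    pool = int(np.rint(spec.n_genes / (2.0 - spec.shared_fraction)))
    pool = min(max(pool, 1), spec.n_genes)
    pool_a = genes[:pool]
    pool_b = genes[spec.n_genes - pool:]
    return pool_a, pool_b


def _simulate_one_network(
    name: str,
    pool: list[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[DirectedPathwayNetwork, list[str], dict[str, frozenset[str]]]:
    lo, hi = spec.pathway_size
    if hi > len(pool):
        raise ValueError(
            f"pathway size bound {hi} exceeds the {len(pool)}-gene pool of {name}"
        )
    pathway_ids: list[str] = []
    members: dict[str, frozenset[str]] = {}
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    pool_arr = np.asarray(pool, dtype=object)
    for k in range(spec.n_pathways):
        pid = f"{prefix}{k:03d}"
        size = int(rng.integers(lo, hi + 1))
        sel = rng.choice(len(pool_arr), size=size, replace=False)
        genes = sorted(pool_arr[np.sort(sel)].tolist())
        pathway_ids.append(pid)
        members[pid] = frozenset(genes)
        for i, u in enumerate(genes):
            for j, v in enumerate(genes):
                if i != j and rng.random() < spec.within_p:
                    edge = (u, v)
                    if edge not in seen:
                        seen.add(edge)
                        edges.append(edge)
    # sparse background edges across the whole pool
    n_pairs = len(pool) * (len(pool) - 1)
    n_cross = int(rng.binomial(n_pairs, spec.cross_p))
    for _ in range(n_cross):
        u, v = rng.choice(len(pool_arr), size=2, replace=False)
        edge = (str(pool_arr[u]), str(pool_arr[v]))
        if edge not in seen:
            seen.add(edge)
            edges.append(edge)
    nodes = sorted({g for e in edges for g in e} | set().union(*members.values()))
    net = DirectedPathwayNetwork(name=name, nodes=nodes, edges=edges)
    return net, pathway_ids, members


def simulate_networks(
    spec: SyntheticSpec,
) -> tuple[DirectedPathwayNetwork, DirectedPathwayNetwork, PathwayCollection]:
    """Build the two directed networks and their combined pathway sets."""
    rng = np.random.default_rng(spec.seed)
    pool_a, pool_b = _network_pools(spec)
    net_a, ids_a, mem_a = _simulate_one_network("KEGG-like", pool_a, spec, rng, "KPW")
    net_b, ids_b, mem_b = _simulate_one_network("PID-like", pool_b, spec, rng, "PPW")
    pathways = PathwayCollection(
        pathway_ids=ids_a + ids_b,
        members={**mem_a, **mem_b},
        sources={**{p: net_a.name for p in ids_a}, **{p: net_b.name for p in ids_b}},
    )
    return net_a, net_b, pathways


def simulate_expression(
    networks,
    pathways: PathwayCollection,
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate the expression cohort with the planted class signal.

    Returns the genes x samples matrix over the full gene pool (missing
    cells masked at ``missing_rate``), the 0/1 phenotype labels, and the
    ground-truth record (planted pathway ids and signed per-gene
    effects).
    """
    if spec.n_normal < 1 or spec.n_tumor < 1:
        raise ValueError("both classes need at least one sample")
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from topology
    genes = _gene_names(spec.n_genes)
    first_net = networks[0] if not isinstance(networks, DirectedPathwayNetwork) else networks
    candidates = [
        p for p in pathways.pathway_ids
        if pathways.sources.get(p) == first_net.name
    ]
    n_planted = min(spec.n_planted, len(candidates))
    planted = sorted(
        rng.choice(np.asarray(candidates, dtype=object), size=n_planted,
                   replace=False).tolist()
    )
    planted_genes = sorted(set().union(*(pathways.members[p] for p in planted))) \
        if planted else []

    samples = [f"N{i:03d}" for i in range(spec.n_normal)] + [
        f"T{i:03d}" for i in range(spec.n_tumor)
    ]
    labels = pd.Series(
        [0] * spec.n_normal + [1] * spec.n_tumor, index=samples, name="label"
    )
    values = rng.standard_normal((spec.n_genes, len(samples)))

    effects = pd.Series(0.0, index=genes, name="effect")
    gene_pos = {g: i for i, g in enumerate(genes)}
    tumor_cols = np.arange(spec.n_normal, len(samples))
    for g in planted_genes:
        sign = 1.0 if rng.random() < spec.coherence else -1.0
        effects[g] = sign * spec.effect_size
        values[gene_pos[g], tumor_cols] += effects[g]

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    frame = pd.DataFrame(values, index=genes, columns=samples)
    truth = GroundTruth(planted_pathways=planted, gene_effects=effects, labels=labels)
    return frame, labels, truth


def simulate(spec: SyntheticSpec | None = None, **overrides):
    """One-call cohort: returns (net_a, net_b, pathways, expr, labels, truth)."""
    spec = replace(spec, **overrides) if spec is not None else SyntheticSpec(**overrides)
    net_a, net_b, pathways = simulate_networks(spec)
    expr, labels, truth = simulate_expression((net_a, net_b), pathways, spec)
    return net_a, net_b, pathways, expr, labels, truth
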