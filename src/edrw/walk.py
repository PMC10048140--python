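"""Gene entropy, entropy weights, and the random walk with restart.

Each gene's expression row, shifted to non-negativity, is treated as a
distribution over samples; its normalised Shannon entropy E lies in
[0, 1] (1 = uniform, 0 = all mass on one sample).  The entropy-weight
criterion ew = (1 - E) / sum(1 - E) favours genes whose expression
concentrates in few samples.  Edge weights of the directed network
allocate each node's outgoing probability proportionally to the entropy
weight of the target gene, keeping every row of the transition matrix
stochastic; with equal weights this reduces to plain out-degree
normalisation.  The walk iterates

    H_{t+1} = (1 - r) * T' H_t + r * H_0

to its stationary vector, once per network (the two networks are walked
independently, with no cross-network coupling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import xlogy

from .io import DirectedPathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "WalkResult",
    "shannon_entropy",
    "gene_entropy",
    "entropy_weights",
    "build_entropy_transition",
    "uniform_transition",
    "walk_with_restart",
    "bi_random_walk",
]


@dataclass
class WalkResult:
    """Stationary vector of one restart walk on one network."""

    network: str
    restart: float
    h_inf: pd.Series  # over network nodes, sums to 1
    iterations: int
    converged: bool
    l1_history: list[float] = field(default_factory=list, repr=False)
    mass_history: list[float] = field(default_factory=list, repr=False)


def shannon_entropy(masses) -> float:
    """Normalised Shannon entropy of a non-negative mass vector, in [0, 1]."""
    p = np.asarray(masses, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-D mass vector of length >= 2")
    if np.any(p < 0):
        raise ValueError("masses must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("masses must not all be zero")
    p = p / total
    return float(-xlogy(p, p).sum() / np.log(p.size))


def gene_entropy(frame: pd.DataFrame, eps: float = 1e-12) -> pd.Series:
    """Normalised Shannon entropy of every gene's sample distribution.

    Computed on the cleaned (pre-z-score) matrix: each row is shifted by
    its minimum plus ``eps`` to non-negativity, normalised to a
    distribution over the m samples, and scored by -sum(p ln p) / ln m.
    """
    if frame.shape[1] < 2:
        raise ValueError("entropy needs at least 2 samples")
    if frame.isna().any().any():
        raise ValueError("entropy requires a complete matrix; impute first")
    x = frame.to_numpy(dtype=float)
    shifted = x - x.min(axis=1, keepdims=True) + eps
    p = shifted / shifted.sum(axis=1, keepdims=True)
    entropy = -xlogy(p, p).sum(axis=1) / np.log(x.shape[1])
    return pd.Series(np.clip(entropy, 0.0, 1.0), index=frame.index, name="entropy")


def entropy_weights(entropy) -> pd.Series | np.ndarray:
    """Entropy-weight-method weights ew = (1 - E) / sum(1 - E)."""
    e = np.asarray(entropy, dtype=float)
    if np.any((e < 0) | (e > 1)):
        raise ValueError("entropies must lie in [0, 1]")
    w = 1.0 - e
    total = w.sum()
    if total <= 0:
        raise ValueError(
            "all gene entropies equal 1: entropy weights are degenerate "
            "(fall back to uniform weights)"
        )
    w = w / total
    if isinstance(entropy, pd.Series):
        return pd.Series(w, index=entropy.index, name="entropy_weight")
    return w


def build_entropy_transition(
    net: DirectedPathwayNetwork, ew
) -> DirectedPathwayNetwork:
    """Attach the entropy edge-weighted row-stochastic transition matrix.

    Row u distributes probability over its out-neighbours v proportionally
    to ew(v).  Genes without an entropy weight (absent from expression)
    get weight 0; a node whose out-neighbours all have zero weight falls
    back to a uniform row (logged), and a dangling node keeps its mass via
    a unit self-loop, so every row sums to exactly 1.
    """
    if isinstance(ew, pd.Series):
        ew_map = ew.to_dict()
    else:
        ew_map = dict(ew)
    idx = net.node_index
    n = net.n_nodes
    out: dict[int, list[int]] = {}
    for u, v in net.edges:
        out.setdefault(idx[u], []).append(idx[v])

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    n_fallback = 0
    node_weight = np.array([float(ew_map.get(g, 0.0)) for g in net.nodes])
    for i in range(n):
        targets = out.get(i)
        if not targets:
            rows.append(i)
            cols.append(i)
            data.append(1.0)
            continue
        w = node_weight[targets]
        total = w.sum()
        if total > 0:
            probs = w / total
        else:
            n_fallback += 1
            probs = np.full(len(targets), 1.0 / len(targets))
        # guard against fp drift so rows sum to 1 exactly enough
        probs = probs / probs.sum()
        rows.extend([i] * len(targets))
        cols.extend(targets)
        data.extend(probs.tolist())
    if n_fallback:
        logger.info(
            "network %s: %d node(s) fell back to uniform out-edge weights "
            "(all out-neighbours had zero entropy weight)",
            net.name, n_fallback,
        )
    transition = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return DirectedPathwayNetwork(
        name=net.name,
        nodes=list(net.nodes),
        edges=list(net.edges),
        transition=transition,
    )


def uniform_transition(net: DirectedPathwayNetwork) -> DirectedPathwayNetwork:
    """Plain out-degree-normalised transition (all entropy weights equal)."""
    return build_entropy_transition(net, {g: 1.0 for g in net.nodes})


def walk_with_restart(
    net: DirectedPathwayNetwork,
    h0,
    r: float,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> WalkResult:
    """Power-iterate H_{t+1} = (1-r) T' H_t + r H_0 to its fixed point.

    ``h0`` must be a probability vector over the network's nodes (a
    pandas Series is reindexed to the node order).  Iteration stops when
    the L1 change drops below ``tol``; the per-iteration L1 change and
    total mass are recorded on the result for conservation checks.
    """
    if net.transition is None:
        raise ValueError(f"network {net.name!r}: transition matrix not built")
    if not (0.0 < r <= 1.0):
        raise ValueError(f"restart probability must lie in (0, 1], got {r}")
    if isinstance(h0, pd.Series):
        h0 = h0.reindex(net.nodes).to_numpy(dtype=float)
        if np.isnan(h0).any():
            raise ValueError("h0 Series is missing entries for some network nodes")
    else:
        h0 = np.asarray(h0, dtype=float)
    if h0.shape != (net.n_nodes,):
        raise ValueError(f"h0 must have length {net.n_nodes}")
    if np.any(h0 < 0) or abs(h0.sum() - 1.0) > 1e-9:
        raise ValueError("h0 must be a probability vector (non-negative, sum 1)")

    transition_t = net.transition.T.tocsr()
    h = h0.copy()
    l1_history: list[float] = []
    mass_history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        h_next = (1.0 - r) * (transition_t @ h) + r * h0
        mass_history.append(float(h_next.sum()))
        delta = float(np.abs(h_next - h).sum())
        l1_history.append(delta)
        h = h_next
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "walk on %s did not converge in %d iterations (last L1 change %.3e)",
            net.name, max_iter, l1_history[-1],
        )
    return WalkResult(
        network=net.name,
        restart=float(r),
        h_inf=pd.Series(h, index=net.nodes, name="h_inf"),
        iterations=iterations,
        converged=converged,
        l1_history=l1_history,
        mass_history=mass_history,
    )


def bi_random_walk(
    nets,
    w0: pd.Series,
    r: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[WalkResult, ...]:
    """Run the restart walk independently on each prepared network.

    The start vector of each network is the initial gene weight W0
    restricted to that network's nodes (genes absent from the expression
    data contribute 0) and renormalised to sum 1.
    """
    results = []
    for net in nets:
        h0 = w0.reindex(net.nodes).fillna(0.0).to_numpy(dtype=float)
        total = h0.sum()
        if total <= 0:
            raise ValueError(
                f"network {net.name!r} shares no weighted genes with the "
                "expression data"
            )
        results.append(walk_with_restart(net, h0 / total, r, tol=tol, max_iter=max_iter))
    return tuple(results)
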