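"""Independent brute-force references used to cross-check the package.

Everything here is deliberately naive — dense matrices, explicit Python
loops, closed-form linear algebra — and shares no code path with the
implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_auc(scores, labels) -> float:
    """AUC as the fraction of concordant (positive, negative) score pairs,
    counting ties as half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def rwr_linear_solve(transition: np.ndarray, h0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form stationary vector r (I - (1-r) T')^{-1} h0."""
    transition = np.asarray(transition, dtype=float)
    n = transition.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * transition.T, np.asarray(h0))


def naive_out_degree_transition(nodes, edges) -> np.ndarray:
    """Dense out-degree-normalised transition with self-loops on dangles."""
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v in edges:
        adj[idx[u], idx[v]] = 1.0
    out = adj.sum(axis=1)
    trans = np.zeros_like(adj)
    for i in range(n):
        if out[i] == 0:
            trans[i, i] = 1.0
        else:
            trans[i] = adj[i] / out[i]
    return trans


def naive_rwr_power(transition: np.ndarray, h0: np.ndarray, r: float,
                    tol: float = 1e-14, max_iter: int = 20000) -> np.ndarray:
    h = np.asarray(h0, dtype=float).copy()
    for _ in range(max_iter):
        h_next = (1.0 - r) * transition.T @ h + r * h0
        if np.abs(h_next - h).sum() < tol:
            return h_next
        h = h_next
    return h


def naive_pathway_activity(member_genes, h_inf, pct, z, ew, sign_t=None):
    """Spreadsheet-style evaluation of the activity formula for one pathway.

    ``h_inf``, ``pct``, ``ew`` and ``sign_t`` are dicts keyed by gene;
    ``z`` maps gene -> list of per-sample standardised values.  Returns
    the per-sample activity list.
    """
    genes = sorted(member_genes)
    n_samples = len(next(iter(z.values())))
    denom = 0.0
    for g in genes:
        denom += ew[g] ** 2
    denom = denom ** 0.5
    activity = []
    for k in range(n_samples):
        total = 0.0
        for g in genes:
            zz = z[g][k]
            if sign_t is not None:
                zz *= sign_t[g]
            total += h_inf[g] * pct[g] * zz
        activity.append(total / denom)
    return activity


def naive_drw_activity(nodes, edges, member_genes, w0, pct, sign_t, z, r,
                       n_weighted: int):
    """Conventional-DRW-style pathway activity with all entropy weights
    equal (1/n_weighted): uniform out-degree walk from w0, then the
    sign-adjusted weighted-z sum normalised by sqrt(sum of equal weights
    squared) over the used genes."""
    trans = naive_out_degree_transition(nodes, edges)
    h0 = np.array([w0.get(g, 0.0) for g in nodes], dtype=float)
    h0 = h0 / h0.sum()
    h_inf = naive_rwr_power(trans, h0, r)
    h_map = dict(zip(nodes, h_inf))
    ew = {g: 1.0 / n_weighted for g in member_genes}
    return naive_pathway_activity(member_genes, h_map, pct, z, ew, sign_t=sign_t)
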