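"""Per-gene differential-expression scoring and initial walk weights.

Each gene receives an equal-variance two-sample t statistic, a
point-biserial correlation with the binary phenotype, the combined PCT
score t^2 + |rho_pb|, and a min-max initial weight W0 used to seed the
random walk.

The point-biserial correlation is computed as the Pearson correlation
between the expression row and the 0/1 phenotype coding (0 = normal,
1 = tumor), so positive values mean higher expression in tumors; this is
numerically identical to (M_tumor - M_normal)/S_pop * sqrt(p*q) with the
population standard deviation, and satisfies the exact link
rho^2 = t^2 / (t^2 + n - 2) with the equal-variance t statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ttest_equal_variance",
    "point_biserial",
    "pct_score",
    "initial_weight_minmax",
    "gene_stats",
]


def _as_2d(values) -> tuple[np.ndarray, bool]:
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise ValueError("expression values must be 1- or 2-dimensional")


def _split_classes(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be coded 0 (normal) / 1 (tumor)")
    return y == 0, y == 1


def ttest_equal_variance(values, labels, epsilon: float = 0.0):
    """Equal-variance two-sample t statistic and two-tailed p-value.

    t = (mean_normal - mean_tumor) / (S_pooled * sqrt(1/N1 + 1/N2)) with
    the classic pooled standard deviation over N1 + N2 - 2 degrees of
    freedom.  ``epsilon`` is an optional stabiliser added to the pooled
    standard deviation; with the default 0, a zero pooled variance raises
    unless the class means are also equal (then t = 0, p = 1).

    Accepts a single row (1-D) or a genes x samples matrix (2-D);
    returns scalars or vectors accordingly.
    """
    x, squeeze = _as_2d(values)
    norm, tum = _split_classes(labels)
    n1, n2 = int(norm.sum()), int(tum.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each class needs at least 2 samples (got {n1} normal, {n2} tumor)"
        )
    a, b = x[:, norm], x[:, tum]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    dof = n1 + n2 - 2
    pooled_sd = np.sqrt(ss / dof)
    denom = (pooled_sd + epsilon) * np.sqrt(1.0 / n1 + 1.0 / n2)
    diff = m1 - m2

    t = np.zeros_like(diff)
    degenerate = denom == 0.0
    if np.any(degenerate & (diff != 0.0)):
        raise ValueError(
            "zero pooled variance with unequal class means; "
            "pass epsilon > 0 to stabilise"
        )
    ok = ~degenerate
    t[ok] = diff[ok] / denom[ok]
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    if squeeze:
        return float(t[0]), float(p[0])
    return t, p


def point_biserial(values, labels):
    """Point-biserial correlation: Pearson r against the 0/1 phenotype."""
    x, squeeze = _as_2d(values)
    _split_classes(labels)  # validates coding
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    if np.any(sx == 0.0):
        raise ValueError("zero-variance expression row: correlation undefined")
    r = (xc @ yc) / (sx * np.sqrt((yc**2).sum()))
    if squeeze:
        return float(r[0])
    return r


def pct_score(t, rho_pb):
    """Combined gene weight: t^2 + |rho_pb| (non-negative, monotone in both)."""
    t = np.asarray(t, dtype=float)
    rho = np.asarray(rho_pb, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(rho))):
        raise ValueError("PCT score requires finite t and rho_pb")
    out = t**2 + np.abs(rho)
    if out.ndim == 0:
        return float(out)
    return out


def initial_weight_minmax(pct, orientation: str = "literal"):
    """Min-max initial walk weights from PCT scores, in [0, 1].

    ``orientation="literal"`` applies |pct - max| / (max - min), so the
    gene with the largest PCT score gets weight 0 and the smallest gets 1.  ``orientation="complement"`` uses
    (pct - min) / (max - min), giving the largest score weight 1.
    """
    p = np.asarray(pct, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 PCT scores")
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        raise ValueError(
            "all PCT scores are equal; min-max weights are undefined "
            "(use uniform initial weights instead)"
        )
    if orientation == "literal":
        w = np.abs(p - hi) / (hi - lo)
    elif orientation == "complement":
        w = (p - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown w0 orientation {orientation!r}")
    return w


def gene_stats(
    frame: pd.DataFrame,
    labels,
    epsilon: float = 1e-12,
    w0_orientation: str = "literal",
) -> pd.DataFrame:
    """Score every gene row of a (normalised) expression matrix.

    Returns a DataFrame indexed by gene with columns ``t``, ``p_value``,
    ``rho_pb``, ``pct`` and ``w0``.  A tiny epsilon stabilises the pooled
    standard deviation so a perfectly separated row scores (very high)
    rather than aborting the whole cohort.
    """
    values = frame.to_numpy(dtype=float)
    t, p = ttest_equal_variance(values, labels, epsilon=epsilon)
    rho = point_biserial(values, labels)
    pct = pct_score(t, rho)
    w0 = initial_weight_minmax(pct, orientation=w0_orientation)
    return pd.DataFrame(
        {"t": t, "p_value": p, "rho_pb": rho, "pct": pct, "w0": w0},
        index=frame.index,
    )
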