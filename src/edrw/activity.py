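"""Entropy-based pathway activity inference and pathway ranking.

For pathway Pj, only member genes that pass the raw t-test filter
p < alpha, appear in the source network, and carry a stationary walk
weight are used.  The activity of Pj in sample k is

    a_k(Pj) = sum_i Hinf(g_i) * PCT(g_i) * z_k(g_i) / sqrt(sum_i ew(g_i)^2)

over the nj used genes, where Hinf is the walk's stationary weight, PCT
the combined t/point-biserial gene score, z the standardised expression,
and ew the entropy weight of the gene.  The denominator's sum runs over
the same used genes.  No sign term appears by default; ``sign_adjust``
optionally multiplies z by sign(t) so coherently deregulated pathways
accumulate rather than cancel.

Profiles from the two networks are concatenated (pathway ids prefixed by
source network), and the top-k pathways are ranked by the absolute
equal-variance t statistic of their activity vector on training samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import DirectedPathwayNetwork, PathwayCollection
from .preprocess import apply_znorm, impute_row_mean, row_moments
from .scoring import gene_stats, ttest_equal_variance
from .walk import (
    WalkResult,
    bi_random_walk,
    build_entropy_transition,
    entropy_weights,
    gene_entropy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayActivityMatrix",
    "infer_pathway_activity",
    "combine_network_profiles",
    "rank_top_pathways",
    "EDRWActivity",
]


@dataclass
class PathwayActivityMatrix:
    """Pathways x samples activity scores with per-pathway provenance."""

    frame: pd.DataFrame
    used_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate pathway ids in activity matrix")
        ids = set(self.frame.index)
        if self.used_genes and set(self.used_genes) != ids:
            raise ValueError("used_genes must be keyed exactly by the pathway ids")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def infer_pathway_activity(
    pathways: PathwayCollection,
    walk: WalkResult,
    stats: pd.DataFrame,
    znorm: pd.DataFrame,
    ew: pd.Series,
    alpha: float = 0.05,
    sign_adjust: bool = False,
) -> PathwayActivityMatrix:
    """Score every pathway in every sample from one network's walk.

    ``stats`` is the gene-stats table (needs ``p_value``, ``pct``, ``t``),
    ``znorm`` the standardised genes x samples matrix, and ``ew`` the
    entropy weights over this network's expression genes.  Pathways whose
    member genes all fail the p < alpha filter (or are absent from the
    network/expression) are dropped with a logged list.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if len(walk.h_inf) == 0:
        raise ValueError("empty walk vector")

    significant = set(stats.index[stats["p_value"] < alpha])
    in_walk = set(walk.h_inf.index[np.isfinite(walk.h_inf.to_numpy())])
    in_z = set(znorm.index)
    in_ew = set(ew.index)
    usable = significant & in_walk & in_z & in_ew

    rows: list[np.ndarray] = []
    kept: list[str] = []
    used_map: dict[str, tuple[str, ...]] = {}
    src_map: dict[str, str] = {}
    dropped: list[str] = []
    for pid in pathways.pathway_ids:
        used = sorted(pathways.members[pid] & usable)
        if not used:
            dropped.append(pid)
            continue
        h = walk.h_inf[used].to_numpy(dtype=float)
        pct = stats.loc[used, "pct"].to_numpy(dtype=float)
        z = znorm.loc[used].to_numpy(dtype=float)
        if sign_adjust:
            z = z * np.sign(stats.loc[used, "t"].to_numpy(dtype=float))[:, None]
        denom = float(np.sqrt((ew[used].to_numpy(dtype=float) ** 2).sum()))
        if denom == 0.0:
            raise ValueError(
                f"pathway {pid!r}: all used genes have zero entropy weight"
            )
        rows.append((h * pct) @ z / denom)
        kept.append(pid)
        used_map[pid] = tuple(used)
        src_map[pid] = pathways.sources.get(pid, walk.network)
    if dropped:
        logger.info(
            "dropped %d pathway(s) with no usable genes: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    frame = pd.DataFrame(
        np.asarray(rows).reshape(len(kept), znorm.shape[1]),
        index=kept,
        columns=znorm.columns,
    )
    return PathwayActivityMatrix(frame=frame, used_genes=used_map, sources=src_map)


def combine_network_profiles(*profiles: PathwayActivityMatrix) -> PathwayActivityMatrix:
    """Concatenate per-network activity profiles over identical samples.

    Pathway ids are prefixed by their source network name
    (``"KEGG:hsa04151"``) so the combined index is unique even when both
    databases define a pathway of the same name.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0].sample_ids
    for prof in profiles[1:]:
        if prof.sample_ids != ref:
            diff = sorted(set(prof.sample_ids).symmetric_difference(ref))
            raise ValueError(
                f"sample ids differ between profiles "
                f"(symmetric difference: {diff[:10]})"
                if diff
                else "profiles list the same samples in different orders"
            )
    frames, used, sources = [], {}, {}
    for prof in profiles:
        renamed = {
            pid: f"{prof.sources.get(pid, 'NA')}:{pid}" for pid in prof.pathway_ids
        }
        frames.append(prof.frame.rename(index=renamed))
        for pid, new in renamed.items():
            if new in sources:
                raise ValueError(f"pathway id collision after prefixing: {new!r}")
            used[new] = prof.used_genes.get(pid, ())
            sources[new] = prof.sources.get(pid, "NA")
    return PathwayActivityMatrix(
        frame=pd.concat(frames, axis=0), used_genes=used, sources=sources
    )


def rank_top_pathways(
    activity: PathwayActivityMatrix | pd.DataFrame,
    labels,
    train_idx=None,
    k: int = 50,
) -> list[str]:
    """Rank pathways by |t| of their activity vector on training samples.

    ``train_idx`` selects sample positions (columns); ``None`` uses all.
    Ties in |t| break lexicographically by pathway id.  Returns at most
    ``k`` pathway ids, best first.
    """
    frame = activity.frame if isinstance(activity, PathwayActivityMatrix) else activity
    y = np.asarray(labels)
    if train_idx is not None:
        train_idx = np.asarray(train_idx)
        frame = frame.iloc[:, train_idx]
        y = y[train_idx]
    if len(set(np.unique(y))) < 2:
        raise ValueError("training subset contains a single class")
    t, _ = ttest_equal_variance(frame.to_numpy(dtype=float), y, epsilon=1e-12)
    order = sorted(zip(frame.index, np.abs(t)), key=lambda item: (-item[1], item[0]))
    return [pid for pid, _ in order[: min(k, len(order))]]


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class EDRWActivity(TransformerMixin, BaseEstimator):
    """Entropy-weighted walk pathway-activity transformer.

    ``fit(X, y)`` takes a samples x genes DataFrame (columns are gene ids)
    plus binary phenotype labels and learns, from those samples only:
    per-gene standardisation moments, differential-expression scores (t,
    point-biserial, PCT, W0), gene entropy weights, and one stationary
    restart-walk vector per directed network.  ``transform(X)`` returns a
    samples x pathways activity DataFrame, restricted to the ``top_k``
    training-ranked pathways when ``top_k`` is set.

    Parameters
    ----------
    networks:
        Sequence of :class:`DirectedPathwayNetwork` (topology only; the
        entropy transition is built during ``fit``).
    pathways:
        Either one :class:`PathwayCollection` whose per-pathway sources
        name the networks, or a sequence of collections aligned with
        ``networks``.
    restart_prob:
        Restart probability r of the walk, in (0, 1].
    alpha:
        Raw t-test p-value threshold for a gene to enter a pathway's
        activity (no multiplicity correction).
    top_k:
        If set, ``transform`` emits only the top-k pathways ranked by |t|
        of the training activity.
    w0_orientation:
        ``"literal"`` (largest PCT score gets initial weight 0) or
        ``"complement"`` (largest gets 1).
    sign_adjust:
        Multiply z by sign(t) inside the activity sum.
    """

    def __init__(
        self,
        networks=None,
        pathways=None,
        restart_prob: float = 0.5,
        alpha: float = 0.05,
        top_k: int | None = None,
        w0_orientation: str = "literal",
        sign_adjust: bool = False,
        walk_tol: float = 1e-10,
        walk_max_iter: int = 1000,
    ):
        self.networks = networks
        self.pathways = pathways
        self.restart_prob = restart_prob
        self.alpha = alpha
        self.top_k = top_k
        self.w0_orientation = w0_orientation
        self.sign_adjust = sign_adjust
        self.walk_tol = walk_tol
        self.walk_max_iter = walk_max_iter

    # -- helpers ----------------------------------------------------------
    def _collections(self) -> list[PathwayCollection]:
        nets = list(self.networks)
        if isinstance(self.pathways, PathwayCollection):
            return [self.pathways.subset_by_source(net.name) for net in nets]
        colls = list(self.pathways)
        if len(colls) != len(nets):
            raise ValueError(
                f"got {len(colls)} pathway collections for {len(nets)} networks"
            )
        return colls

    @staticmethod
    def _check_X(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a samples x genes pandas DataFrame with gene-id columns"
            )
        return X

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X = self._check_X(X)
        if self.networks is None or self.pathways is None:
            raise ValueError("networks and pathways must be provided")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different numbers of samples")

        genes_by_samples = X.T
        if genes_by_samples.isna().any().any():
            genes_by_samples = impute_row_mean(genes_by_samples).frame
        mean, sd = row_moments(genes_by_samples)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
        self.gene_mean_, self.gene_sd_ = mean[keep], sd[keep]
        cleaned = genes_by_samples.loc[keep.index[keep]]
        znorm = apply_znorm(cleaned, self.gene_mean_, self.gene_sd_)

        self.gene_stats_ = gene_stats(
            znorm, y, w0_orientation=self.w0_orientation
        )
        self.entropy_ = gene_entropy(cleaned)
        w0 = self.gene_stats_["w0"]

        nets = list(self.networks)
        colls = self._collections()
        expr_genes = set(znorm.index)
        prepared, self.entropy_weights_ = [], {}
        for net in nets:
            shared = sorted(set(net.nodes) & expr_genes)
            if not shared:
                raise ValueError(
                    f"network {net.name!r} shares no genes with the expression data"
                )
            ew = entropy_weights(self.entropy_[shared])
            self.entropy_weights_[net.name] = ew
            prepared.append(build_entropy_transition(net, ew))
        self.walks_ = bi_random_walk(
            prepared, w0, r=self.restart_prob,
            tol=self.walk_tol, max_iter=self.walk_max_iter,
        )

        per_net = [
            infer_pathway_activity(
                coll, walk, self.gene_stats_, znorm,
                self.entropy_weights_[walk.network],
                alpha=self.alpha, sign_adjust=self.sign_adjust,
            )
            for coll, walk in zip(colls, self.walks_)
        ]
        combined = combine_network_profiles(*per_net)
        self.activity_train_ = combined
        k = self.top_k if self.top_k is not None else len(combined)
        self.ranked_pathways_ = rank_top_pathways(combined, y, k=k)

        # per-pathway linear coefficients over used genes, so transform is
        # a dot product against newly standardised expression
        coefs: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
        walk_by_name = {w.network: w for w in self.walks_}
        for pid in self.ranked_pathways_:
            used = combined.used_genes[pid]
            src = combined.sources[pid]
            walk = walk_by_name[src]
            h = walk.h_inf[list(used)].to_numpy(dtype=float)
            pct = self.gene_stats_.loc[list(used), "pct"].to_numpy(dtype=float)
            ew = self.entropy_weights_[src][list(used)].to_numpy(dtype=float)
            coef = h * pct / np.sqrt((ew**2).sum())
            if self.sign_adjust:
                coef = coef * np.sign(
                    self.gene_stats_.loc[list(used), "t"].to_numpy(dtype=float)
                )
            coefs[pid] = (used, coef)
        self.pathway_coefs_ = coefs
        self.feature_names_ = list(self.ranked_pathways_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "pathway_coefs_")
        X = self._check_X(X)
        znorm = apply_znorm(X.T, self.gene_mean_, self.gene_sd_)
        out = np.empty((X.shape[0], len(self.feature_names_)))
        for j, pid in enumerate(self.feature_names_):
            used, coef = self.pathway_coefs_[pid]
            out[:, j] = coef @ znorm.loc[list(used)].to_numpy(dtype=float)
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)
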