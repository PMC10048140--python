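"""One-command orchestration of the full workflow.

The pipeline reads expression + labels + two directed networks + their
gene sets, persists every intermediate (cleaned and normalised
expression, gene statistics, per-network stationary walk vectors, the
combined activity matrix), runs the repeated split/select/test
experiment — refitting scoring, walk and selection from each repeat's
training samples — and writes a report plus a manifest of versions,
seeds and parameters.  Outputs contain no timestamps, so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import combine_network_profiles, infer_pathway_activity
from .classify import CLASSIFIERS, ExperimentResult, run_repeated_experiment
from .io import (
    read_expression,
    read_gmt,
    read_labels,
    read_network_sif,
    validate_labels,
    write_expression,
)
from .preprocess import impute_row_mean, log2_transform, znormalize
from .scoring import gene_stats
from .walk import bi_random_walk, build_entropy_transition, entropy_weights, gene_entropy

logger = logging.getLogger(__name__)

__all__ = ["NetworkSource", "PipelineConfig", "run_pipeline", "parse_scan"]


@dataclass
class NetworkSource:
    name: str
    sif: str
    gmt: str


@dataclass
class PipelineConfig:
    """Serialised source of truth for a reproducible run."""

    expression: str
    labels: str
    networks: list[NetworkSource]
    outdir: str = "edrw_out"
    log2: bool = False
    restart: float = 0.5
    restart_scan: str | None = None  # e.g. "0.1:0.9:0.1"
    alpha: float = 0.05
    top_k: int = 50
    classifier: str = "knn"
    repeats: int = 10
    cv_folds: int = 10
    seed: int = 0
    w0_orientation: str = "literal"
    sign_adjust: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nets = [NetworkSource(**n) for n in raw.pop("networks", [])]
        cfg = cls(networks=nets, **raw)
        if not cfg.networks:
            raise ValueError(f"{path}: config lists no networks")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def parse_scan(spec: str) -> list[float]:
    """Parse a start:stop:step restart-probability grid, stop inclusive."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"bad scan spec {spec!r}; expected start:stop:step") from exc
    if step <= 0 or stop < start:
        raise ValueError(f"bad scan spec {spec!r}")
    grid = np.arange(start, stop + step / 2, step)
    return [round(float(r), 10) for r in grid]


def _write_report(result: ExperimentResult, path: Path) -> None:
    frame = result.to_frame()
    summary = pd.DataFrame(
        {
            "repeat": ["mean", "sd"],
            "seed": ["", ""],
            "test_auc": [result.mean_auc, result.sd_auc],
            "cv_auc": ["", ""],
            "n_selected": ["", ""],
            "selected_pathways": ["", ""],
        }
    )
    pd.concat([frame, summary], ignore_index=True).to_csv(path, sep="\t", index=False)


def _write_scan_report(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _manifest(cfg: PipelineConfig) -> dict:
    import sklearn
    import scipy

    return {
        "edrw_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "sklearn_version": sklearn.__version__,
        "config": cfg.to_dict(),
    }


def run_pipeline(cfg: PipelineConfig) -> ExperimentResult | list[dict]:
    """Execute the full workflow described by ``cfg``.

    Returns the :class:`ExperimentResult` (or the grid rows when a
    restart scan is configured) and leaves all artifacts in
    ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = read_expression(cfg.expression)
    if cfg.log2:
        expr = log2_transform(expr)
    cleaned = impute_row_mean(expr).frame
    write_expression(cleaned, outdir / "cleaned.tsv")

    labels = validate_labels(read_labels(cfg.labels), cleaned.columns)
    normalized = znormalize(cleaned)
    write_expression(normalized, outdir / "normalized.tsv")

    nets, colls = [], []
    for src in cfg.networks:
        nets.append(read_network_sif(src.sif, name=src.name))
        colls.append(read_gmt(src.gmt, source=src.name))

    # whole-cohort intermediates, for inspection and downstream reuse
    stats = gene_stats(normalized, labels, w0_orientation=cfg.w0_orientation)
    stats.to_csv(outdir / "genestats.tsv", sep="\t", index_label="gene_id")
    entropy = gene_entropy(cleaned)
    prepared, ews = [], {}
    for net in nets:
        shared = sorted(set(net.nodes) & set(normalized.index))
        if not shared:
            raise ValueError(f"network {net.name!r} shares no genes with expression")
        ew = entropy_weights(entropy[shared])
        ews[net.name] = ew
        prepared.append(build_entropy_transition(net, ew))
    walks = bi_random_walk(prepared, stats["w0"], r=cfg.restart)
    for walk in walks:
        walk.h_inf.to_csv(outdir / f"hinf_{walk.network}.tsv", sep="\t",
                          index_label="gene_id")
    profiles = [
        infer_pathway_activity(coll, walk, stats, normalized, ews[walk.network],
                               alpha=cfg.alpha, sign_adjust=cfg.sign_adjust)
        for coll, walk in zip(colls, walks)
    ]
    combined = combine_network_profiles(*profiles)
    combined.frame.to_csv(outdir / "activity.tsv", sep="\t", index_label="pathway_id")

    pathway_list = colls
    if cfg.restart_scan:
        rows = []
        for r in parse_scan(cfg.restart_scan):
            for clf in CLASSIFIERS:
                result = run_repeated_experiment(
                    cleaned, labels, nets, pathway_list,
                    classifier=clf, restart_prob=r, repeats=cfg.repeats,
                    base_seed=cfg.seed, top_k=cfg.top_k, alpha=cfg.alpha,
                    cv_folds=cfg.cv_folds, w0_orientation=cfg.w0_orientation,
                    sign_adjust=cfg.sign_adjust,
                )
                rows.append(
                    {"restart": r, "classifier": clf,
                     "mean_auc": result.mean_auc, "sd_auc": result.sd_auc}
                )
                logger.info("scan r=%.1f %s: mean AUC %.4f", r, clf, result.mean_auc)
        _write_scan_report(rows, outdir / "report.tsv")
        out: ExperimentResult | list[dict] = rows
    else:
        result = run_repeated_experiment(
            cleaned, labels, nets, pathway_list,
            classifier=cfg.classifier, restart_prob=cfg.restart,
            repeats=cfg.repeats, base_seed=cfg.seed, top_k=cfg.top_k,
            alpha=cfg.alpha, cv_folds=cfg.cv_folds,
            w0_orientation=cfg.w0_orientation, sign_adjust=cfg.sign_adjust,
        )
        _write_report(result, outdir / "report.tsv")
        out = result

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_manifest(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
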