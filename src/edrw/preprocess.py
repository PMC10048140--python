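"""Missing-value imputation and per-gene z-scaling.

Expression rows with incomplete values are imputed with the row mean of
the observed entries; each retained gene is then standardised to mean 0
and unit variance across samples.  The sample (n-1) standard-deviation
denominator is used everywhere in the package so the z-scores, t-tests
and correlations stay mutually consistent.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import EmptyInputError

logger = logging.getLogger(__name__)

__all__ = [
    "ImputeResult",
    "log2_transform",
    "impute_row_mean",
    "znormalize",
    "row_moments",
    "apply_znorm",
]


class ImputeResult(NamedTuple):
    frame: pd.DataFrame
    was_imputed: pd.Series  # bool per retained gene


def log2_transform(frame: pd.DataFrame) -> pd.DataFrame:
    """log2-transform intensities; non-positive entries become missing."""
    nonpos = int((frame <= 0).sum().sum())
    if nonpos:
        logger.warning("log2: %d non-positive entries set to missing", nonpos)
    return np.log2(frame.where(frame > 0))


def impute_row_mean(frame: pd.DataFrame) -> ImputeResult:
    """Replace each missing cell by the mean of its gene row.

    Genes with no observed value at all are dropped with a warning.
    """
    if frame.shape[1] == 0:
        raise EmptyInputError("expression matrix has no samples")
    all_missing = frame.isna().all(axis=1)
    if all_missing.any():
        dropped = list(frame.index[all_missing])
        logger.warning(
            "dropping %d gene(s) with no observed values: %s",
            len(dropped), ", ".join(map(str, dropped[:10])),
        )
        frame = frame.loc[~all_missing]
    if frame.shape[0] == 0:
        raise EmptyInputError("no genes left after dropping all-missing rows")
    was_imputed = frame.isna().any(axis=1).rename("was_imputed")
    if was_imputed.any():
        row_means = frame.mean(axis=1)
        frame = frame.T.fillna(row_means).T
    return ImputeResult(frame=frame, was_imputed=was_imputed)


def row_moments(frame: pd.DataFrame, ddof: int = 1) -> tuple[pd.Series, pd.Series]:
    """Per-gene mean and standard deviation (sample denominator by default)."""
    return frame.mean(axis=1), frame.std(axis=1, ddof=ddof)


def apply_znorm(frame: pd.DataFrame, mean: pd.Series, sd: pd.Series) -> pd.DataFrame:
    """Standardise rows with externally supplied moments (e.g. from training)."""
    missing = mean.index.difference(frame.index)
    if len(missing):
        raise ValueError(
            f"expression matrix lacks {len(missing)} gene(s) required for "
            f"normalisation, e.g. {list(missing[:5])}"
        )
    frame = frame.loc[mean.index]
    return frame.sub(mean, axis=0).div(sd, axis=0)


def znormalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Standardise every gene row to mean 0, variance 1 across samples.

    Zero-variance genes carry no class signal and would divide by zero;
    they are dropped with a warning.
    """
    if frame.shape[1] < 2:
        raise ValueError("z-normalisation needs at least 2 samples")
    if frame.isna().any().any():
        raise ValueError("z-normalisation requires a complete matrix; impute first")
    mean, sd = row_moments(frame)
    constant = sd == 0.0
    if constant.any():
        dropped = list(frame.index[constant])
        logger.warning(
            "dropping %d zero-variance gene(s): %s",
            len(dropped), ", ".join(map(str, dropped[:10])),
        )
        frame, mean, sd = frame.loc[~constant], mean[~constant], sd[~constant]
    if frame.shape[0] == 0:
        raise EmptyInputError("no genes left after dropping zero-variance rows")
    return frame.sub(mean, axis=0).div(sd, axis=0)
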