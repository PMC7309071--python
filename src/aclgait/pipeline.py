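"""End-to-end glue: dataset -> aligned signals -> features / stride tables.

These helpers chain the stage modules so examples, tests and scripts do
not repeat the plumbing.  Flagged (undefined) feature values are
replaced by zero when assembling the design matrix for the learning
protocol, which keeps the matrix finite without silently dropping the
registry columns; the replacement is recorded per column.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import features as feats
from . import gait, preprocess
from .core import AlignedRepetition, Repetition
from .synth import Dataset

__all__ = [
    "align",
    "repetition_features",
    "dataset_features",
    "dataset_stride_table",
    "design_matrix",
]


def align(rep: Repetition, target_rate: float = 100.0, **kwargs) -> AlignedRepetition:
    """Preprocess one repetition (resample, squat-sync, shank rotation)."""
    return preprocess.align_repetition(rep, target_rate=target_rate, **kwargs)


def repetition_features(
    rep: Repetition,
    registry: Optional[feats.FeatureRegistry] = None,
    target_rate: float = 100.0,
) -> feats.FeatureVector:
    """Align one repetition and compute its feature vector."""
    return feats.extract_features(align(rep, target_rate), registry)


def dataset_features(
    dataset: Dataset,
    registry: Optional[feats.FeatureRegistry] = None,
    target_rate: float = 100.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix and metadata for every repetition of a dataset.

    Returns ``(X, meta)``: X has one row per repetition and one column
    per registry feature (NaN where flagged); meta carries subject,
    cohort, trial and sidestep direction.
    """
    registry = registry or feats.default_registry()
    rows: List[pd.Series] = []
    meta_rows: List[dict] = []
    for rep in dataset.iter_repetitions():
        fv = repetition_features(rep, registry, target_rate)
        rows.append(fv.values)
        meta_rows.append({
            "subject": rep.subject_id,
            "cohort": rep.cohort,
            "trial": rep.trial_index,
            "direction": rep.direction,
        })
    X = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    return X, meta


def design_matrix(X: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Replace flagged (non-finite) entries by zero for model fitting.

    Returns the finite matrix and the list of columns that contained
    flagged values.
    """
    arr = X.to_numpy(dtype=float)
    bad_cols = [c for c, b in zip(X.columns, ~np.isfinite(arr).all(axis=0)) if b]
    return X.fillna(0.0).replace([np.inf, -np.inf], 0.0), bad_cols


def dataset_stride_table(
    dataset: Dataset,
    target_rate: float = 100.0,
    **gait_kwargs,
) -> pd.DataFrame:
    """Concatenated stride table over all repetitions and both limbs.

    Adds subject/cohort/trial columns so the result feeds directly into
    the group statistics (condition x limb ANOVA, effect sizes).
    """
    import warnings

    tables: List[pd.DataFrame] = []
    for rep in dataset.iter_repetitions():
        aligned = align(rep, target_rate)
        for limb in ("left", "right"):
            gx = aligned.gyro(f"{limb}_shank")[:, 0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = gait.stride_table_for_limb(
                    gx, aligned.rate, limb, t0=float(aligned.t[0]), **gait_kwargs
                )
            if len(tab):
                tab = tab.copy()
                tab["subject"] = rep.subject_id
                tab["cohort"] = rep.cohort
                tab["trial"] = rep.trial_index
                tables.append(tab)
    if not tables:
        from .core import empty_stride_table

        out = empty_stride_table()
        out["subject"] = pd.Series(dtype=object)
        out["cohort"] = pd.Series(dtype=object)
        out["trial"] = pd.Series(dtype=int)
        return out
    return pd.concat(tables, ignore_index=True)
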