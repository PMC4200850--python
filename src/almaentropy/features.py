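"""Box-Jenkins moving-average features over assay-condition subsets.

For each condition class (standard measure s_x, assay a_u, organism o_t,
target t_j) and each condition value c, the active-set moving average is

    ma(c) = p_1(c) * <theta_5(c)>

where p_1(c) = n_1/n is the fraction of active records under c and
<theta_5(c)> averages the descriptor over the *active* compounds only. A
record's feature vector is then

    [ p(c_l) * theta_5,
      theta_5 - ma(s_x), theta_5 - ma(a_u),
      theta_5 - ma(o_t), theta_5 - ma(t_j) ]

i.e. a quality-weighted descriptor plus four deviation terms measuring how
far the compound sits from the average active compound in each slice of
assay space. MA statistics are computed on the training records only and
frozen, so validation/prediction rows never leak labels.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError
from .records import CONDITION_COLUMNS, CURATION_QUALITY

__all__ = [
    "FEATURE_NAMES",
    "condition_stats",
    "ma_features",
    "AlmaFeaturizer",
]

FEATURE_NAMES: tuple[str, ...] = (
    "quality_theta5",
    "dev_measure",
    "dev_assay",
    "dev_organism",
    "dev_target",
)

STATS_COLUMNS = (
    "condition_class",
    "condition_value",
    "n",
    "n1",
    "p1",
    "mean_theta5",
    "ma_value",
)


def condition_stats(
    frame: pd.DataFrame,
    condition_class: str,
    theta_column: str = "theta5",
) -> pd.DataFrame:
    """Per-condition counts, activity prior and active-set moving average.

    Parameters
    ----------
    frame : DataFrame
        Labeled endpoint rows carrying the condition column and
        ``theta_column``; every row needs a 0/1 label.
    condition_class : str
        One of ``measure``, ``assay_id``, ``organism``, ``target_id``.

    Returns
    -------
    DataFrame
        One row per distinct condition value with columns
        ``condition_class, condition_value, n, n1, p1, mean_theta5,
        ma_value`` where ``p1 = n1/n`` and ``ma_value = p1 * mean_theta5``.
        A condition with no active record gets ``mean_theta5 = 0`` and
        ``ma_value = 0``.
    """
    if condition_class not in CONDITION_COLUMNS:
        raise DataError(
            f"condition_class must be one of {CONDITION_COLUMNS}, "
            f"got {condition_class!r}"
        )
    if theta_column not in frame.columns:
        raise DataError(f"frame lacks descriptor column {theta_column!r}")
    theta = pd.to_numeric(frame[theta_column], errors="coerce")
    if theta.isna().any():
        bad = frame.loc[theta.isna(), "compound_id"].astype(str).unique()
        raise DataError(
            "missing theta_5 descriptor for compounds: " + ", ".join(bad[:10])
        )
    labels = frame["label"]
    if labels.isna().any():
        raise DataError("condition statistics require a label on every record")
    labels = labels.astype(int)

    rows = []
    for value, idx in frame.groupby(condition_class, sort=True).groups.items():
        lab = labels.loc[idx]
        n = int(len(idx))
        n1 = int(lab.sum())
        p1 = n1 / n
        mean_theta = float(theta.loc[idx][lab == 1].mean()) if n1 else 0.0
        rows.append(
            {
                "condition_class": condition_class,
                "condition_value": value,
                "n": n,
                "n1": n1,
                "p1": p1,
                "mean_theta5": mean_theta,
                "ma_value": p1 * mean_theta,
            }
        )
    return pd.DataFrame(rows, columns=list(STATS_COLUMNS))


def ma_features(
    quality: float,
    theta5: float,
    ma_values: Mapping[str, float],
) -> np.ndarray:
    """Feature vector of one record from its quality, descriptor and MAs.

    ``ma_values`` maps each of the four condition classes to the matching
    condition's ``ma_value``.
    """
    missing = [c for c in CONDITION_COLUMNS if c not in ma_values]
    if missing:
        raise DataError(f"ma_values lacks condition classes: {missing}")
    return np.array(
        [
            quality * theta5,
            theta5 - ma_values["measure"],
            theta5 - ma_values["assay_id"],
            theta5 - ma_values["organism"],
            theta5 - ma_values["target_id"],
        ]
    )


class AlmaFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from labeled endpoint rows to moving-average features.

    ``fit`` learns, from the training rows, the active-set moving average
    of every condition value in the four condition classes; ``transform``
    builds the five-column feature matrix for any endpoint rows. The input
    is an endpoint DataFrame that additionally carries the descriptor
    column (``theta5`` by default).

    Parameters
    ----------
    strict : bool, default True
        With ``strict``, transforming a row whose condition value was not
        seen during fit raises; otherwise the class's global active-set
        moving average is substituted.
    theta_column : str, default "theta5"
        Name of the descriptor column.

    Attributes
    ----------
    stats_ : DataFrame
        Concatenated :func:`condition_stats` tables of the four classes.
    ma_lookup_ : dict of dict
        ``{condition_class: {condition_value: ma_value}}``.
    global_ma_ : dict
        Per-class fallback moving average over all active training rows.
    """

    def __init__(self, *, strict: bool = True, theta_column: str = "theta5") -> None:
        self.strict = strict
        self.theta_column = theta_column

    def fit(self, X: pd.DataFrame, y: Optional[np.ndarray] = None) -> "AlmaFeaturizer":
        frame = X.copy()
        if y is not None:
            frame = frame.assign(label=np.asarray(y))
        if "label" not in frame.columns:
            raise DataError("fitting the featurizer requires labels")
        tables = [
            condition_stats(frame, cls, theta_column=self.theta_column)
            for cls in CONDITION_COLUMNS
        ]
        self.stats_ = pd.concat(tables, ignore_index=True)
        self.ma_lookup_ = {
            cls: dict(
                zip(tab["condition_value"].astype(str), tab["ma_value"])
            )
            for cls, tab in zip(CONDITION_COLUMNS, tables)
        }
        labels = frame["label"].astype(int)
        theta = pd.to_numeric(frame[self.theta_column])
        active = theta[labels == 1]
        p1_global = float(labels.mean())
        mean_global = float(active.mean()) if len(active) else 0.0
        self.global_ma_ = {
            cls: p1_global * mean_global for cls in CONDITION_COLUMNS
        }
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def _ma_of(self, cls: str, value: str) -> float:
        lookup = self.ma_lookup_[cls]
        if value in lookup:
            return lookup[value]
        if self.strict:
            raise DataError(
                f"unseen condition value {value!r} in class {cls!r}; refit "
                "with this value or use strict=False"
            )
        return self.global_ma_[cls]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Five-column MA feature matrix, rows aligned with the input."""
        check_is_fitted(self, "ma_lookup_")
        theta = pd.to_numeric(X[self.theta_column], errors="coerce")
        if theta.isna().any():
            bad = X.loc[theta.isna(), "compound_id"].astype(str).unique()
            raise DataError(
                "missing theta_5 descriptor for compounds: " + ", ".join(bad[:10])
            )
        quality = X["curation_level"].map(CURATION_QUALITY)
        if quality.isna().any():
            bad = X.loc[quality.isna(), "curation_level"].unique()
            raise DataError(f"unknown curation levels: {list(bad)}")
        out = np.empty((len(X), 5))
        out[:, 0] = quality.to_numpy(dtype=float) * theta.to_numpy()
        for col_idx, cls in enumerate(CONDITION_COLUMNS, start=1):
            ma = np.array(
                [self._ma_of(cls, str(v)) for v in X[cls]]
            )
            out[:, col_idx] = theta.to_numpy() - ma
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(FEATURE_NAMES)
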