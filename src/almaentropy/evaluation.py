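"""Confusion-matrix construction and Sn/Sp/Ac reporting.

Rates are row-wise correct-classification percentages keyed by the
observed class, plus the overall accuracy. The published table layout
pairs the label "Sp" with the observed-link (L = 1) row and "Sn" with the
observed-0 row, which is the reverse of the conventional
sensitivity-on-positives naming; the report reproduces that layout by
default and offers the conventional mapping behind a flag. The underlying
counts and rates are identical either way — only the labels move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ConfusionSummary", "confusion", "report_table"]


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts keyed by observed class.

    ``obs1_pred1`` counts observed-active records predicted active, and so
    on. Rates are computed lazily at full precision; rounding to one
    decimal happens only in reports.
    """

    obs1_pred1: int
    obs1_pred0: int
    obs0_pred1: int
    obs0_pred0: int

    def __post_init__(self) -> None:
        counts = (self.obs1_pred1, self.obs1_pred0, self.obs0_pred1, self.obs0_pred0)
        if any(c < 0 for c in counts):
            raise DataError("confusion counts must be non-negative")
        if sum(counts) == 0:
            raise DataError("confusion matrix must contain at least one record")

    @property
    def total(self) -> int:
        return self.obs1_pred1 + self.obs1_pred0 + self.obs0_pred1 + self.obs0_pred0

    @property
    def rate_obs1(self) -> float:
        """Percent of observed-1 records predicted 1."""
        n = self.obs1_pred1 + self.obs1_pred0
        return 100.0 * self.obs1_pred1 / n if n else float("nan")

    @property
    def rate_obs0(self) -> float:
        """Percent of observed-0 records predicted 0."""
        n = self.obs0_pred1 + self.obs0_pred0
        return 100.0 * self.obs0_pred0 / n if n else float("nan")

    @property
    def accuracy(self) -> float:
        """Overall percent correct."""
        return 100.0 * (self.obs1_pred1 + self.obs0_pred0) / self.total

    def rates(self, *, conventional: bool = False) -> dict[str, float]:
        """Sn/Sp/Ac mapping in the published layout or the conventional one.

        Published layout (default): Sp is the observed-1 row rate, Sn the
        observed-0 row rate. Conventional: Sn on observed-1, Sp on
        observed-0.
        """
        if conventional:
            return {"Sn": self.rate_obs1, "Sp": self.rate_obs0, "Ac": self.accuracy}
        return {"Sp": self.rate_obs1, "Sn": self.rate_obs0, "Ac": self.accuracy}


def confusion(
    observed: Sequence[int], predicted: Sequence[int]
) -> ConfusionSummary:
    """Build the 2x2 confusion summary from paired 0/1 label lists."""
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.size == 0:
        raise DataError("confusion requires at least one record")
    if obs.shape != pred.shape:
        raise DataError(
            f"observed ({obs.size}) and predicted ({pred.size}) lengths differ"
        )
    for name, arr in (("observed", obs), ("predicted", pred)):
        if not np.isin(arr, (0, 1)).all():
            raise DataError(f"{name} labels must all be 0 or 1")
    return ConfusionSummary(
        obs1_pred1=int(((obs == 1) & (pred == 1)).sum()),
        obs1_pred0=int(((obs == 1) & (pred == 0)).sum()),
        obs0_pred1=int(((obs == 0) & (pred == 1)).sum()),
        obs0_pred0=int(((obs == 0) & (pred == 0)).sum()),
    )


def report_table(
    summaries: Mapping[tuple[str, str] | str, ConfusionSummary],
    *,
    conventional: bool = False,
) -> pd.DataFrame:
    """Tidy Sn/Sp/Ac report over named (model, split) confusion blocks.

    Keys are ``(model, split)`` pairs or plain strings (split then defaults
    to ``"all"``). Columns: ``model, split, metric, value_percent,
    numerator, denominator``; one Sp/Sn/Ac triple per block, in the
    published row order.
    """
    if not summaries:
        raise DataError("report_table requires at least one summary")
    rows = []
    for key, cm in summaries.items():
        model, split = key if isinstance(key, tuple) else (key, "all")
        if conventional:
            order = ("Sn", "Sp", "Ac")
        else:
            order = ("Sp", "Sn", "Ac")
        parts = {
            "Sp" if not conventional else "Sn": (
                cm.obs1_pred1, cm.obs1_pred1 + cm.obs1_pred0
            ),
            "Sn" if not conventional else "Sp": (
                cm.obs0_pred0, cm.obs0_pred1 + cm.obs0_pred0
            ),
            "Ac": (cm.obs1_pred1 + cm.obs0_pred0, cm.total),
        }
        rates = cm.rates(conventional=conventional)
        for metric in order:
            num, den = parts[metric]
            rows.append(
                {
                    "model": model,
                    "split": split,
                    "metric": metric,
                    "value_percent": rates[metric],
                    "numerator": num,
                    "denominator": den,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model", "split", "metric", "value_percent", "numerator", "denominator"],
    )


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`report_table`, one line per metric."""
    lines = []
    for (model, split), block in report.groupby(["model", "split"], sort=False):
        lines.append(f"{model} / {split}")
        for row in block.itertuples(index=False):
            lines.append(
                f"  {row.metric:>2} {row.value_percent:5.1f}%  "
                f"({row.numerator}/{row.denominator})"
            )
    return "\n".join(lines)
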