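"""Typed endpoint records: one multi-output assay outcome per row.

Each record pairs a compound with the condition tuple of the assay it was
measured in — curation level c_l, standard measure s_x, assay a_u, organism
o_t and target t_j — plus the binary outcome label L (1 = strong/active
outcome). The curation level maps deterministically to a data-quality
probability p(c_l): expert 1.0, intermediate 0.75, autocuration 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import DataError

CURATION_QUALITY: dict[str, float] = {
    "expert": 1.0,
    "intermediate": 0.75,
    "autocuration": 0.5,
}

#: The four moving-average condition classes, keyed by their column name.
CONDITION_COLUMNS: tuple[str, ...] = ("measure", "assay_id", "organism", "target_id")

#: Exact endpoint CSV header.
ENDPOINT_COLUMNS: tuple[str, ...] = (
    "compound_id",
    "smiles",
    "curation_level",
    "measure",
    "assay_id",
    "organism",
    "target_id",
    "label",
)


@dataclass
class EndpointRecord:
    """One assay endpoint: compound x condition tuple x outcome label."""

    compound_id: str
    smiles: str
    curation_level: str
    measure: str
    assay_id: str
    organism: str
    target_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.curation_level not in CURATION_QUALITY:
            raise DataError(
                f"unknown curation level {self.curation_level!r}; expected one "
                f"of {sorted(CURATION_QUALITY)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise DataError(f"label must be 0, 1 or absent, got {self.label!r}")

    @property
    def quality(self) -> float:
        """Data-quality probability p(c_l) from the curation level."""
        return CURATION_QUALITY[self.curation_level]


def records_to_frame(records: Iterable[EndpointRecord]) -> pd.DataFrame:
    """Endpoint records as a DataFrame in the canonical column order."""
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "curation_level": r.curation_level,
            "measure": r.measure,
            "assay_id": r.assay_id,
            "organism": r.organism,
            "target_id": r.target_id,
            "label": r.label,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(ENDPOINT_COLUMNS))
    frame["label"] = frame["label"].astype("Int64")
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[EndpointRecord]:
    """Typed records from an endpoint DataFrame (labels may be missing)."""
    missing = [c for c in ENDPOINT_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"endpoint table lacks required columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        label = getattr(row, "label")
        label = None if pd.isna(label) else int(label)
        out.append(
            EndpointRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                curation_level=str(row.curation_level),
                measure=str(row.measure),
                assay_id=str(row.assay_id),
                organism=str(row.organism),
                target_id=str(row.target_id),
                label=label,
            )
        )
    return out
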