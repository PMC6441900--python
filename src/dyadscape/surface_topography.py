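"""Scanning-EM surface-topography indices computed from Z-spine annotations.

Two per-cell indices summarize sarcolemmal surface architecture:

* **Z-groove index**: total length of elevated membrane crests (which define
  the grooves) divided by the total Z-spine length of the cell — a
  ratio-of-sums over all annotated spines, bounded in [0, 1].
* **T-tubule opening fraction**: number of Z-spines with a visible t-tubule
  lumen divided by the number of Z-spines analysed.

Manual annotation (spine tracing, crest measurement, lumen calls) is an input,
supplied as a CSV table with columns ``spine_id``, ``spine_length_um``,
``groove_crest_length_um``, ``has_ttubule_lumen``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

__all__ = [
    "ZSpineRecord",
    "TopographyMetrics",
    "read_annotations",
    "z_groove_index",
    "ttubule_opening_fraction",
    "analyze_topography",
]


@dataclass(frozen=True)
class ZSpineRecord:
    """Annotation of one Z-spine: length, crest length along it, lumen call."""

    spine_id: str
    spine_length_um: float
    groove_crest_length_um: float
    has_ttubule_lumen: bool

    def validate(self) -> None:
        if not self.spine_length_um > 0:
            raise ValueError(f"spine {self.spine_id}: spine_length_um must be > 0")
        if self.groove_crest_length_um < 0:
            raise ValueError(
                f"spine {self.spine_id}: groove_crest_length_um must be >= 0")
        if self.groove_crest_length_um > self.spine_length_um:
            raise ValueError(
                f"spine {self.spine_id}: crest length exceeds spine length")


@dataclass(frozen=True)
class TopographyMetrics:
    z_groove_index: float
    ttubule_opening_fraction: float
    n_spines: int


def read_annotations(path: Union[str, os.PathLike]) -> list:
    """Read a per-cell Z-spine annotation CSV into :class:`ZSpineRecord` rows."""
    df = pd.read_csv(path)
    required = {"spine_id", "spine_length_um", "groove_crest_length_um",
                "has_ttubule_lumen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        lumen = row.has_ttubule_lumen
        if isinstance(lumen, str):
            lumen = lumen.strip().lower() in {"true", "1", "yes", "y"}
        records.append(
            ZSpineRecord(
                spine_id=str(row.spine_id),
                spine_length_um=float(row.spine_length_um),
                groove_crest_length_um=float(row.groove_crest_length_um),
                has_ttubule_lumen=bool(lumen),
            )
        )
    return records


def z_groove_index(records: Sequence[ZSpineRecord]) -> float:
    """Cell-level Z-groove index: sum of crest lengths / sum of spine lengths."""
    if len(records) == 0:
        raise ValueError("need at least one Z-spine record")
    for rec in records:
        rec.validate()
    crest = sum(r.groove_crest_length_um for r in records)
    spine = sum(r.spine_length_um for r in records)
    return crest / spine


def ttubule_opening_fraction(records: Sequence[ZSpineRecord]) -> float:
    """Fraction of Z-spines with a visible t-tubule lumen."""
    if len(records) == 0:
        raise ValueError("need at least one Z-spine record")
    return sum(1 for r in records if r.has_ttubule_lumen) / len(records)


def analyze_topography(records: Sequence[ZSpineRecord]) -> TopographyMetrics:
    return TopographyMetrics(
        z_groove_index=z_groove_index(records),
        ttubule_opening_fraction=ttubule_opening_fraction(records),
        n_spines=len(records),
    )
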