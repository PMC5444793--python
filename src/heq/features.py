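"""Classifier feature vectors built from filtration profiles.

Two feature encodings are supported:

- ``laa`` (C_LAA%): the LAA% values at every threshold of a grid, ascending;
  60 values over the full -1000..-700 HU sweep.
- ``heq`` (C_HEQ): the normalized Betti numbers, all nb0 by ascending
  threshold followed by all nb1 by ascending threshold; 120 values over the
  full sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import QuantCurve, ThresholdGrid

KINDS = ("laa", "heq")

#: Candidate limits for the threshold-range sweep (HU).
RANGE_LIMITS = (-1000, -950, -900, -850, -800, -750, -700)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with their (quantity, threshold) schema."""

    values: np.ndarray
    schema: tuple[tuple[str, int], ...]
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.schema):
            raise ValueError("values and schema lengths differ")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def _lookup(curve: QuantCurve, grid: ThresholdGrid) -> list:
    by_t = {r.threshold_hu: r for r in curve.records}
    recs = []
    for t in grid.levels:
        if t not in by_t:
            raise KeyError(
                f"curve for slice {curve.slice_id} lacks threshold {t} HU"
            )
        recs.append(by_t[t])
    return recs


def build_features(
    curve: QuantCurve, grid: ThresholdGrid, kind: str
) -> FeatureVector:
    """Assemble one slice's feature vector for a threshold sub-range.

    ``kind='laa'`` yields one LAA% value per level; ``kind='heq'`` yields
    the nb0 block then the nb1 block, each by ascending threshold.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    recs = _lookup(curve, grid)
    if kind == "laa":
        values = [r.laa_pct for r in recs]
        schema = [("laa_pct", r.threshold_hu) for r in recs]
    else:
        values = [r.nb0 for r in recs] + [r.nb1 for r in recs]
        schema = [("nb0", r.threshold_hu) for r in recs] + [
            ("nb1", r.threshold_hu) for r in recs
        ]
    return FeatureVector(
        values=np.asarray(values), schema=tuple(schema), kind=kind
    )


def range_grid() -> list[ThresholdGrid]:
    """All 21 ordered (lower, upper) threshold ranges of the sweep.

    Lower limits run over -1000..-750 HU, upper limits over -950..-700 HU,
    in 50 HU steps with lower < upper: the lower-triangular layout of the
    range-sweep accuracy tables.
    """
    return [
        ThresholdGrid(lo, hi)
        for lo, hi in combinations(RANGE_LIMITS, 2)
    ]


def feature_frame(
    curves: list[QuantCurve],
    grid: ThresholdGrid,
    kind: str,
    scores: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame, one row per slice.

    Columns are named ``<quantity>_<threshold>`` plus ``patient_id``,
    ``slice_id`` and, when ``scores`` maps slice_id to a score, ``score``.
    """
    rows = []
    for curve in curves:
        fv = build_features(curve, grid, kind)
        row = {f"{q}_{t}": v for (q, t), v in zip(fv.schema, fv.values)}
        row["patient_id"] = curve.patient_id
        row["slice_id"] = curve.slice_id
        if scores is not None:
            row["score"] = scores[curve.slice_id]
        rows.append(row)
    return pd.DataFrame(rows)
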