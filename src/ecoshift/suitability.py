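"""Threshold selection, binary presence/absence maps, equal-interval
suitability classes, and present-vs-future change statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridLayer
from .maxent import MaxentModel, predict

__all__ = [
    "BinaryMap",
    "SuitabilityClassTable",
    "PresenceChangeReport",
    "percentile_threshold",
    "binarize",
    "classify_equal_interval",
    "presence_change",
]

CLASS_LABELS = {
    1: "non-suitable",
    2: "low-suitability",
    3: "regular-suitability",
    4: "medium-suitability",
    5: "high-suitability",
}


@dataclass
class BinaryMap:
    layer: GridLayer  # values in {0, 1, nodata}
    threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        vals = self.layer.values[self.layer.valid_mask]
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary map may only contain 0/1/nodata")

    @property
    def presence_cells(self) -> int:
        return int((self.layer.values[self.layer.valid_mask] == 1).sum())

    @property
    def valid_cells(self) -> int:
        return int(self.layer.valid_mask.sum())

    @property
    def presence_pct(self) -> float:
        return 100.0 * self.presence_cells / self.valid_cells


@dataclass
class SuitabilityClassTable:
    scenario: str
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, float]:
        t = self.total
        return {k: 100.0 * c / t for k, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "label": [CLASS_LABELS[k] for k in self.counts],
                "cells": list(self.counts.values()),
                "pct_area": [pct[k] for k in self.counts],
                "scenario": self.scenario,
            }
        )


def percentile_threshold(
    model: MaxentModel,
    presence_env: pd.DataFrame,
    q: float = 10.0,
    interpolate: bool = False,
) -> float:
    """q-th percentile of the cloglog predictions at training presences.

    Default is the nearest-rank definition — the value at 1-based index
    ``ceil(q/100 * m)`` of the sorted predictions, an attained prediction
    value — so at most q% of training presences fall strictly below it.
    ``interpolate=True`` switches to the linear-interpolation percentile.
    """
    preds = np.sort(predict(model, presence_env, "cloglog"))
    if preds.size == 0:
        raise ValueError("no presences")
    if interpolate:
        return float(np.percentile(preds, q))
    rank = max(int(np.ceil(q / 100.0 * preds.size)), 1)
    return float(preds[rank - 1])


def binarize(suitability: GridLayer, threshold: float) -> BinaryMap:
    """Presence (1) where suitability >= threshold, else absence (0);
    nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    valid = suitability.valid_mask
    out = np.full(suitability.values.shape, suitability.nodata, dtype=np.float64)
    out[valid] = (suitability.values[valid] >= threshold).astype(np.float64)
    layer = GridLayer(
        suitability.spec, f"{suitability.name}_binary", "categorical", out,
        suitability.nodata,
    )
    return BinaryMap(layer=layer, threshold=float(threshold), source=suitability.name)


def classify_equal_interval(
    suitability: GridLayer, scenario: str = "current"
) -> tuple[GridLayer, SuitabilityClassTable]:
    """Five equal-interval suitability classes on [0, 1].

    Class k for value v is ``min(floor(v / 0.2) + 1, 5)`` — half-open bins
    with the top bin closed at 1.0.
    """
    valid = suitability.valid_mask
    vals = suitability.values[valid]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    # searchsorted against explicit edges avoids floor(v / 0.2) float slop
    classes = np.searchsorted([0.2, 0.4, 0.6, 0.8], vals, side="right") + 1
    out = np.full(suitability.values.shape, suitability.nodata, dtype=np.float64)
    out[valid] = classes
    layer = GridLayer(
        suitability.spec, f"{suitability.name}_classes", "categorical", out,
        suitability.nodata,
    )
    counts = {k: int((classes == k).sum()) for k in range(1, 6)}
    return layer, SuitabilityClassTable(scenario=scenario, counts=counts)


@dataclass
class PresenceChangeReport:
    current_pct: float
    future_pct: float
    difference_pp: float        # future - current, percentage points
    relative_change_pct: float  # 100 * (A_future - A_current) / A_current
    stable_presence: int
    gain: int
    loss: int
    stable_absence: int

    @property
    def total(self) -> int:
        return self.stable_presence + self.gain + self.loss + self.stable_absence

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def presence_change(current: BinaryMap, future: BinaryMap) -> PresenceChangeReport:
    """Compare two aligned binary maps: area shares, relative change of the
    presence area, and the 2x2 stable/gain/loss cross-tabulation."""
    if not current.layer.spec.aligned_with(future.layer.spec):
        raise ValueError("binary maps are not aligned")
    valid = current.layer.valid_mask & future.layer.valid_mask
    cur = current.layer.values[valid] == 1
    fut = future.layer.values[valid] == 1
    n_cur = int(cur.sum())
    n_fut = int(fut.sum())
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly valid cells")
    rel = 100.0 * (n_fut - n_cur) / n_cur if n_cur else float("nan")
    return PresenceChangeReport(
        current_pct=100.0 * n_cur / n,
        future_pct=100.0 * n_fut / n,
        difference_pp=100.0 * (n_fut - n_cur) / n,
        relative_change_pct=rel,
        stable_presence=int((cur & fut).sum()),
        gain=int((~cur & fut).sum()),
        loss=int((cur & ~fut).sum()),
        stable_absence=int((~cur & ~fut).sum()),
    )
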