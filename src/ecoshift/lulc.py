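"""Multitemporal categorical land-cover analysis: hierarchical legend
reclassification, per-epoch class-share tables, epoch-to-epoch deltas, and
cross-tabulated transition matrices over an optional polygon mask.

``table_change`` also works directly on typed-in published percentage
tables, so printed per-epoch shares can be differenced without any raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridLayer
from .occurrences import AreaPolygon

__all__ = [
    "LULCLegend",
    "LULCTable",
    "TransitionMatrix",
    "reclass_to_level",
    "class_area_table",
    "table_change",
    "transition_matrix",
]


@dataclass
class LULCLegend:
    """Hierarchical legend: raster code -> level-1 and level-4 class names."""

    table: pd.DataFrame  # columns: code, level1, level4

    def __post_init__(self) -> None:
        required = {"code", "level1", "level4"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"legend is missing columns {sorted(missing)}")
        if self.table["code"].duplicated().any():
            dupes = self.table.loc[self.table["code"].duplicated(), "code"].tolist()
            raise ValueError(f"duplicate legend codes: {dupes}")
        by_l4 = self.table.groupby("level4")["level1"].nunique()
        bad = by_l4[by_l4 > 1].index.tolist()
        if bad:
            raise ValueError(
                f"level-4 classes mapping to multiple level-1 classes: {bad}"
            )

    @classmethod
    def from_csv(cls, path) -> "LULCLegend":
        return cls(pd.read_csv(path))

    @property
    def codes(self) -> np.ndarray:
        return self.table["code"].to_numpy()

    def mapping(self, level) -> dict:
        """code -> class name at the requested level (1, 4, or a custom
        dict / column name for mixed schemes)."""
        if isinstance(level, dict):
            return dict(level)
        if level in (1, 4):
            col = f"level{level}"
        elif isinstance(level, str) and level in self.table.columns:
            col = level
        else:
            raise ValueError(f"unknown legend level {level!r}")
        return dict(zip(self.table["code"], self.table[col]))


@dataclass
class LULCTable:
    """Class shares (% of the masked area) for one epoch."""

    epoch: str
    shares: pd.Series  # index: class label, values: percent
    counts: pd.Series | None = None

    def __post_init__(self) -> None:
        self.shares = self.shares.astype(float)
        total = float(self.shares.sum())
        if self.counts is not None and abs(total - 100.0) > 0.1:
            raise ValueError(f"class shares sum to {total:.3f}, expected 100")

    @property
    def classes(self) -> list:
        return list(self.shares.index)

    @classmethod
    def from_published(cls, epoch: str, shares: dict) -> "LULCTable":
        """Build from a typed-in published percentage table (values may sum
        to 100 only up to printed rounding)."""
        return cls(epoch=epoch, shares=pd.Series(shares))

    @classmethod
    def series_from_csv(cls, path, class_col: str = "class") -> list["LULCTable"]:
        """Read a wide CSV (one class column, one column per epoch) into a
        list of tables, one per epoch column."""
        df = pd.read_csv(path)
        if class_col not in df.columns:
            raise ValueError(f"{path}: missing class column {class_col!r}")
        epochs = [c for c in df.columns if c != class_col]
        return [
            cls(epoch=e, shares=pd.Series(df[e].to_numpy(), index=df[class_col]))
            for e in epochs
        ]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"class": self.shares.index, "pct": self.shares.values})
        if self.counts is not None:
            out["cells"] = self.counts.values
        out.insert(0, "epoch", self.epoch)
        return out


def reclass_to_level(layer: GridLayer, legend: LULCLegend, level) -> GridLayer:
    """Replace raster codes by class identifiers at the requested legend
    level (1, 4, a legend column name, or an explicit code->class dict for
    mixed schemes).  Unknown codes are an error."""
    if layer.kind != "categorical":
        raise ValueError("reclass_to_level expects a categorical layer")
    mapping = legend.mapping(level)
    valid = layer.valid_mask
    codes = layer.values[valid]
    unknown = sorted(set(np.unique(codes)) - set(mapping))
    if unknown:
        raise ValueError(f"codes not present in legend: {unknown}")
    labels = sorted(set(mapping.values()), key=str)
    label_ids = {lab: i + 1 for i, lab in enumerate(labels)}
    code_to_id = {c: label_ids[mapping[c]] for c in mapping}
    lut_codes = np.array(sorted(code_to_id))
    lut_ids = np.array([code_to_id[c] for c in lut_codes])
    out = np.full(layer.values.shape, layer.nodata, dtype=np.float64)
    out[valid] = lut_ids[np.searchsorted(lut_codes, codes)]
    new = GridLayer(layer.spec, f"{layer.name}_L{level}", "categorical", out,
                    layer.nodata)
    new.class_names = {v: k for k, v in label_ids.items()}  # type: ignore[attr-defined]
    return new


def _mask_cells(layer: GridLayer, mask: AreaPolygon | None) -> np.ndarray:
    valid = layer.valid_mask
    if mask is None:
        return valid
    xc, yc = layer.spec.cell_centers()
    inside = mask.covers_points(xc.ravel(), yc.ravel()).reshape(xc.shape)
    out = valid & inside
    if not out.any():
        raise ValueError("mask polygon does not intersect any valid cells")
    return out


def class_area_table(
    layer: GridLayer,
    mask: AreaPolygon | None = None,
    epoch: str | None = None,
    class_names: dict | None = None,
) -> LULCTable:
    """Per-class share of the masked area.

    A cell belongs to the mask iff its center lies inside (or on the
    boundary of) the polygon.
    """
    if layer.kind != "categorical":
        raise ValueError("class_area_table expects a categorical layer")
    cells = _mask_cells(layer, mask)
    vals = layer.values[cells]
    codes, counts = np.unique(vals, return_counts=True)
    names = class_names or getattr(layer, "class_names", None) or {}
    index = [names.get(c, c) for c in codes]
    total = counts.sum()
    return LULCTable(
        epoch=epoch or layer.name,
        shares=pd.Series(100.0 * counts / total, index=index),
        counts=pd.Series(counts, index=index),
    )


def table_change(a: LULCTable, b: LULCTable) -> pd.Series:
    """Per-class signed share difference in percentage points (b - a).

    Works on raster-derived tables and on typed-in published tables alike;
    both tables must cover the same class set.
    """
    if set(a.classes) != set(b.classes):
        only_a = sorted(set(a.classes) - set(b.classes), key=str)
        only_b = sorted(set(b.classes) - set(a.classes), key=str)
        raise ValueError(
            f"class sets differ (only in {a.epoch}: {only_a}; "
            f"only in {b.epoch}: {only_b})"
        )
    delta = b.shares.reindex(a.classes) - a.shares
    delta.name = f"{a.epoch} -> {b.epoch}"
    return delta


@dataclass
class TransitionMatrix:
    """Cross-tabulated cell counts between two epochs of the same grid."""

    epoch_a: str
    epoch_b: str
    counts: pd.DataFrame  # rows: class in A, columns: class in B
    cell_area_m2: float = field(default=0.0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def persistence_pct(self) -> float:
        diag = np.diag(self.counts.to_numpy()).sum()
        return 100.0 * float(diag) / self.total

    def to_percent(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.total

    def row_table(self) -> LULCTable:
        shares = 100.0 * self.counts.sum(axis=1) / self.total
        return LULCTable(self.epoch_a, shares, self.counts.sum(axis=1))

    def col_table(self) -> LULCTable:
        shares = 100.0 * self.counts.sum(axis=0) / self.total
        return LULCTable(self.epoch_b, shares, self.counts.sum(axis=0))

    def gains(self, cls) -> pd.Series:
        """Donor classes feeding a class's gains (cells entering ``cls``),
        largest first."""
        col = self.counts[cls].drop(index=cls)
        return col.sort_values(ascending=False)

    def losses(self, cls) -> pd.Series:
        """Recipient classes of a class's losses (cells leaving ``cls``),
        largest first."""
        row = self.counts.loc[cls].drop(index=cls)
        return row.sort_values(ascending=False)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def transition_matrix(
    map_a: GridLayer,
    map_b: GridLayer,
    mask: AreaPolygon | None = None,
    class_names: dict | None = None,
    epoch_a: str | None = None,
    epoch_b: str | None = None,
) -> TransitionMatrix:
    """Cross-tabulate co-located class pairs of two aligned categorical maps
    inside the mask."""
    if not map_a.spec.aligned_with(map_b.spec):
        raise ValueError("maps are not aligned")
    cells = _mask_cells(map_a, mask) & map_b.valid_mask
    a = map_a.values[cells]
    b = map_b.values[cells]
    names = (
        class_names
        or getattr(map_a, "class_names", None)
        or getattr(map_b, "class_names", None)
        or {}
    )
    labels = sorted(set(np.unique(a)) | set(np.unique(b)))
    idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    mat = np.zeros((k, k), dtype=np.int64)
    ai = np.array([idx[v] for v in a])
    bi = np.array([idx[v] for v in b])
    np.add.at(mat, (ai, bi), 1)
    display = [names.get(c, c) for c in labels]
    counts = pd.DataFrame(mat, index=display, columns=display)
    return TransitionMatrix(
        epoch_a=epoch_a or map_a.name,
        epoch_b=epoch_b or map_b.name,
        counts=counts,
        cell_area_m2=map_a.spec.cell_size ** 2,
    )
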