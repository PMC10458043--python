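"""Occurrence point ingestion, per-cell spatial thinning, and convex-hull
occurrence-area polygons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon

from .grid import GridSpec

__all__ = ["OccurrenceSet", "AreaPolygon", "load_occurrences", "thin_to_grid", "convex_hull"]


@dataclass
class OccurrenceSet:
    """Ordered presence points in projected meters, with per-record source tags."""

    points: list[tuple[float, float]]
    source_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.source_tags:
            self.source_tags = [""] * len(self.points)
        if len(self.source_tags) != len(self.points):
            raise ValueError("source_tags length must match points length")
        arr = self.xy
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("occurrence coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def union(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            self.points + other.points, self.source_tags + other.source_tags
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": [p[0] for p in self.points],
             "y": [p[1] for p in self.points],
             "source": self.source_tags}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AreaPolygon:
    """A closed, convex ring with its shoelace area in square meters."""

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.vertices[0] == self.vertices[-1]:
            self.vertices = self.vertices[:-1]

    @property
    def area(self) -> float:
        """Shoelace area of the ring."""
        v = np.asarray(self.vertices, dtype=float)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(
            float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        )

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def covers_points(self, x, y) -> np.ndarray:
        """Vectorized point-in-polygon test; boundary points count as inside."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.shapely, pts)

    def to_wkt(self) -> str:
        return self.shapely.wkt


def load_occurrences(
    csv_path, x_col: str = "x", y_col: str = "y", source_tag: str | None = None
) -> OccurrenceSet:
    """Read occurrence points from a CSV file.

    Raises ``ValueError`` naming the offending rows (1-based data row
    numbers) if a coordinate fails to parse; an empty file yields an empty
    set with a warning.
    """
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{csv_path}: empty occurrence file", stacklevel=2)
        return OccurrenceSet([])
    if df.empty:
        warnings.warn(f"{csv_path}: no occurrence rows", stacklevel=2)
        return OccurrenceSet([])
    for col in (x_col, y_col):
        if col not in df.columns:
            raise ValueError(
                f"{csv_path}: missing column {col!r} (have {list(df.columns)})"
            )
    xs = pd.to_numeric(df[x_col], errors="coerce")
    ys = pd.to_numeric(df[y_col], errors="coerce")
    bad = df.index[xs.isna() | ys.isna()]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:20])
        raise ValueError(f"{csv_path}: non-numeric coordinates in data rows {rows}")
    tags = (
        df["source"].astype(str).tolist()
        if source_tag is None and "source" in df.columns
        else [source_tag or str(csv_path)] * len(df)
    )
    return OccurrenceSet(list(zip(xs.astype(float), ys.astype(float))), tags)


def thin_to_grid(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Reduce an occurrence set to at most one record per grid cell.

    The first record (input order) in each cell is kept, so the operation
    is deterministic and idempotent.  Points outside the grid extent are an
    error.
    """
    if len(occ) == 0:
        return OccurrenceSet([])
    xy = occ.xy
    row, col = spec.cell_of(xy[:, 0], xy[:, 1])
    inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    if not inside.all():
        offenders = [
            f"#{i + 1} ({xy[i, 0]:g}, {xy[i, 1]:g})"
            for i in np.flatnonzero(~inside)[:20]
        ]
        raise ValueError(
            "occurrence points outside grid extent: " + "; ".join(offenders)
        )
    seen: set[tuple[int, int]] = set()
    keep_points, keep_tags = [], []
    for i, rc in enumerate(zip(row.tolist(), col.tolist())):
        if rc in seen:
            continue
        seen.add(rc)
        keep_points.append(occ.points[i])
        keep_tags.append(occ.source_tags[i])
    return OccurrenceSet(keep_points, keep_tags)


def convex_hull(occ: OccurrenceSet) -> AreaPolygon:
    """Convex hull of the occurrence points as an :class:`AreaPolygon`.

    Requires at least 3 non-collinear points.
    """
    if len(occ) < 3:
        raise ValueError(f"convex hull needs >= 3 points, got {len(occ)}")
    hull = MultiPoint([Point(p) for p in occ.points]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; convex hull is degenerate")
    ring = list(hull.exterior.coords)
    return AreaPolygon([(float(x), float(y)) for x, y in ring])
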