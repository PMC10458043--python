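"""Pearson-correlation screening of environmental layers and collinearity
pruning at a cutoff.

Variables with |r| >= cutoff are linked; groups are the connected
components of that graph (single linkage), and one representative per
group is retained — lexicographically first by default, or a seeded random
pick.  Categorical layers are excluded from the matrix and always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterStack

__all__ = ["CorrelationReport", "correlation_matrix", "remove_collinear"]


@dataclass
class CorrelationReport:
    variables: list[str]
    matrix: pd.DataFrame
    categorical: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)
    cutoff: float | None = None
    groups: list[list[str]] | None = None
    retained: list[str] | None = None

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def correlation_matrix(
    stack: RasterStack, mask: np.ndarray | None = None
) -> CorrelationReport:
    """Pairwise Pearson r between all continuous layers of a stack.

    Each pair is computed over the cells valid in BOTH layers (and inside
    ``mask`` if given).  Zero-variance layers make r undefined; those pairs
    are reported as 0 (uncorrelated) and the layer names recorded.
    """
    cont = [l for l in stack if l.kind == "continuous"]
    cat = [l.name for l in stack if l.kind == "categorical"]
    if len(cont) < 2:
        raise ValueError("correlation matrix needs at least 2 continuous layers")
    names = [l.name for l in cont]
    k = len(cont)
    mat = np.eye(k)
    degenerate: set[str] = set()
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = cont[i], cont[j]
            valid = vi.valid_mask & vj.valid_mask
            if mask is not None:
                valid = valid & mask
            a = vi.values[valid].astype(np.float64)
            b = vj.values[valid].astype(np.float64)
            if a.size < 3:
                raise ValueError(
                    f"layers {vi.name!r}/{vj.name!r}: fewer than 3 jointly valid cells"
                )
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                if sa == 0:
                    degenerate.add(vi.name)
                if sb == 0:
                    degenerate.add(vj.name)
                r = 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            mat[i, j] = mat[j, i] = r
    if degenerate:
        warnings.warn(
            f"zero-variance layers treated as uncorrelated: {sorted(degenerate)}",
            stacklevel=2,
        )
    frame = pd.DataFrame(mat, index=names, columns=names)
    return CorrelationReport(
        variables=names, matrix=frame, categorical=cat,
        degenerate=sorted(degenerate),
    )


def remove_collinear(
    report: CorrelationReport,
    cutoff: float = 0.8,
    rule: str = "lexicographic",
    seed: int | None = None,
) -> list[str]:
    """Prune collinear variables, returning the retained list.

    Groups are connected components of the |r| >= cutoff graph; because
    linkage is transitive, two retained variables from different groups are
    guaranteed below the cutoff, but members within a group need not all be
    pairwise collinear.  Categorical variables are appended unchanged.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    if rule not in ("lexicographic", "random"):
        raise ValueError(f"unknown representative rule {rule!r}")
    names = report.variables
    absr = report.matrix.abs().to_numpy()
    n = len(names)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if absr[i, j] >= cutoff:
                parent[find(i)] = find(j)

    comps: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        comps.setdefault(find(i), []).append(name)
    groups = sorted((sorted(g) for g in comps.values()), key=lambda g: g[0])
    rng = np.random.default_rng(seed)
    if rule == "lexicographic":
        retained = [g[0] for g in groups]
    else:
        retained = [g[int(rng.integers(len(g)))] for g in groups]
    report.cutoff = cutoff
    report.groups = groups
    report.retained = retained + list(report.categorical)
    return report.retained
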