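"""Seeded synthetic-data generators: correlated smooth environmental
fields, a categorical soil layer, a DEM, occurrences sampled from a known
suitability surface, and land-cover epoch sequences driven by a per-pixel
Markov kernel.

Every generator is a pure function of (scenario, seed), so runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import logsumexp

from .grid import GridLayer, GridSpec, RasterStack
from .occurrences import OccurrenceSet

__all__ = [
    "SyntheticScenario",
    "gen_env_stack",
    "gen_occurrences",
    "gen_lulc_series",
    "true_suitability",
]


@dataclass
class SyntheticScenario:
    """Everything needed to fabricate a full study dataset."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 100.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "LOCAL_METERS"
    variables: list[str] = field(
        default_factory=lambda: [f"VAR{i + 1}" for i in range(5)]
    )
    correlation: np.ndarray | None = None  # defaults to identity
    smooth_sigma: float = 5.0  # cells; spatial autocorrelation scale
    soil_levels: int = 4
    true_weights: dict[str, float] = field(default_factory=dict)
    m_presence: int = 200
    lulc_classes: int = 4
    lulc_kernel: np.ndarray | None = None  # defaults to 0.85 persistence
    n_epochs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.origin_y == 0.0:
            self.origin_y = self.n_rows * self.cell_size
        k = len(self.variables)
        if self.correlation is None:
            self.correlation = np.eye(k)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (k, k):
            raise ValueError("correlation matrix shape must match variable count")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        eig = np.linalg.eigvalsh(self.correlation)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        if self.lulc_kernel is None:
            k = self.lulc_classes
            off = 0.15 / max(k - 1, 1)
            self.lulc_kernel = np.full((k, k), off)
            np.fill_diagonal(self.lulc_kernel, 0.85)
        self.lulc_kernel = np.asarray(self.lulc_kernel, dtype=float)
        if self.lulc_kernel.shape != (self.lulc_classes, self.lulc_classes):
            raise ValueError("lulc_kernel shape must match lulc_classes")
        if not np.allclose(self.lulc_kernel.sum(axis=1), 1.0):
            raise ValueError("lulc_kernel rows must sum to 1")
        if self.m_presence < 1:
            raise ValueError("m_presence must be >= 1")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            crs_tag=self.crs_tag,
        )


def _smooth_standard_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, re-standardized to mean 0 / sd 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def gen_env_stack(scenario: SyntheticScenario, seed: int | None = None) -> RasterStack:
    """Correlated continuous fields plus a categorical ``soil`` layer and a
    ``dem`` layer.

    Independent smooth Gaussian fields are mixed through the Cholesky factor
    of the target correlation matrix, so empirical pairwise correlations
    track the requested ones.
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = (scenario.n_rows, scenario.n_cols)
    k = len(scenario.variables)
    base = np.stack(
        [_smooth_standard_field(rng, shape, scenario.smooth_sigma) for _ in range(k)]
    )
    chol = np.linalg.cholesky(
        scenario.correlation + 1e-10 * np.eye(k)
    )
    mixed = np.tensordot(chol, base, axes=(1, 0))
    spec = scenario.spec
    layers = [
        GridLayer(spec, name, "continuous", mixed[i], -9999.0)
        for i, name in enumerate(scenario.variables)
    ]
    # categorical soil from quantile-binned extra smooth field
    soil_field = _smooth_standard_field(rng, shape, scenario.smooth_sigma)
    edges = np.quantile(soil_field, np.linspace(0, 1, scenario.soil_levels + 1)[1:-1])
    soil = (np.searchsorted(edges, soil_field.ravel()) + 1).reshape(shape)
    layers.append(GridLayer(spec, "soil", "categorical", soil.astype(np.int32), -9999))
    # DEM: smooth field rescaled to a mountain-like elevation band
    dem_field = _smooth_standard_field(rng, shape, scenario.smooth_sigma * 2)
    dem = 600.0 + 150.0 * dem_field
    layers.append(GridLayer(spec, "dem", "continuous", dem, -9999.0))
    return RasterStack(layers)


def true_suitability(
    stack: RasterStack, true_weights: dict[str, float]
) -> GridLayer:
    """Cloglog suitability implied by known linear weights on z-scored
    variables (quadratic terms via a ``"var^2"`` key)."""
    if not true_weights:
        raise ValueError("true_weights is empty")
    spec = stack.spec
    eta = np.zeros((spec.n_rows, spec.n_cols))
    for key, w in true_weights.items():
        var, power = (key[:-2], 2) if key.endswith("^2") else (key, 1)
        layer = stack[var]
        z = (layer.values - layer.values.mean()) / layer.values.std()
        eta += w * z**power
    flat = eta.ravel()
    log_z = logsumexp(flat)
    raw = np.exp(flat - log_z)
    entropy = -np.sum(raw * np.log(np.maximum(raw, 1e-300)))
    suit = 1.0 - np.exp(-np.exp(entropy) * raw)
    return GridLayer(
        spec, "true_suitability", "continuous", suit.reshape(eta.shape), -9999.0
    )


def gen_occurrences(
    stack: RasterStack,
    true_weights: dict[str, float],
    m: int,
    seed: int,
    replace: bool = False,
) -> OccurrenceSet:
    """Sample ``m`` presence cells with probability proportional to the true
    suitability surface; one point at each sampled cell center."""
    suit = true_suitability(stack, true_weights)
    probs = suit.values.ravel().astype(np.float64)
    total = probs.sum()
    if total <= 0:
        raise ValueError("suitability surface is identically zero")
    probs = probs / total
    rng = np.random.default_rng(seed)
    n_cells = probs.size
    idx = rng.choice(n_cells, size=m, replace=replace, p=probs)
    rows, cols = np.divmod(idx, stack.spec.n_cols)
    x, y = stack.spec.cell_center(rows, cols)
    pts = list(zip(np.asarray(x, float), np.asarray(y, float)))
    return OccurrenceSet(pts, ["synthetic"] * m)


def gen_lulc_series(
    scenario: SyntheticScenario, seed: int | None = None
) -> list[GridLayer]:
    """Land-cover epoch sequence from a per-pixel Markov kernel.

    Epoch 0 is a patchy map (quantile-binned smooth field); each later
    epoch evolves every cell independently through the kernel.
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = (scenario.n_rows, scenario.n_cols)
    spec = scenario.spec
    k = scenario.lulc_classes
    p_cum = np.cumsum(scenario.lulc_kernel, axis=1)

    base = _smooth_standard_field(rng, shape, scenario.smooth_sigma)
    edges = np.quantile(base, np.linspace(0, 1, k + 1)[1:-1])
    current = (np.searchsorted(edges, base.ravel()) + 1).reshape(shape)

    layers = [
        GridLayer(spec, "epoch0", "categorical", current.astype(np.int32), -9999)
    ]
    for t in range(1, scenario.n_epochs):
        u = rng.random(shape)
        cum = p_cum[current - 1]  # (rows, cols, k)
        nxt = (u[..., None] > cum).sum(axis=2) + 1
        current = nxt
        layers.append(
            GridLayer(spec, f"epoch{t}", "categorical", current.astype(np.int32), -9999)
        )
    return layers
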