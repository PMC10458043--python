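"""Presence-background maximum-entropy habitat model.

Fits the Gibbs distribution over a background sample that maximizes the
L1-regularized training gain

    G(lam) = mean_presence[lam . f(x)] - log Z(lam) + log(n_bg)
             - sum_j beta_j |lam_j|

by cyclic coordinate descent with exact per-coordinate backtracking, so the
gain is non-decreasing by construction and G(0) = 0.  Outputs: raw density,
logistic, and the complementary log-log suitability
``1 - exp(-exp(H) * raw)`` where H is the entropy of the fitted raw
distribution over the background sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid import GridLayer, RasterStack

__all__ = [
    "MaxentSettings",
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "ImportanceReport",
    "BackgroundSample",
    "sample_background",
    "env_at_cells",
    "env_at_points",
    "build_features",
    "fit",
    "predict",
    "auc",
    "auc_scores",
    "importance",
    "response_curve",
    "project",
]

Output = Literal["raw", "logistic", "cloglog"]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")

# Default L1 scale per feature class, interpolated by presence count m.
# beta_j = multiplier * interp(m) * sd_j(presences) / sqrt(m).
_BETA_TABLES = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "hinge": ([0], [0.5]),
}
_MIN_FEATURE_SD = 0.05  # floor keeps every feature penalized


@dataclass
class MaxentSettings:
    """Fitting configuration (defaults follow the emulated software)."""

    n_background: int = 2000
    max_iterations: int = 2000
    convergence_threshold: float = 1e-5
    regularization_multiplier: float = 1.0
    prevalence_tau: float = 0.5
    feature_classes: str | Sequence[str] = "auto"
    hinge_knots: int = 50
    threshold_knots: int = 50
    seed: int = 0
    beta_override: float | None = None  # absolute per-feature L1 weight

    def __post_init__(self) -> None:
        if self.n_background < 1 or self.max_iterations < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.prevalence_tau < 1:
            raise ValueError("prevalence_tau must lie in (0, 1)")
        if self.regularization_multiplier <= 0:
            raise ValueError("regularization_multiplier must be > 0")
        if self.feature_classes != "auto":
            bad = set(self.feature_classes) - set(FEATURE_CLASSES)
            if bad:
                raise ValueError(f"unknown feature classes: {sorted(bad)}")


@dataclass
class Feature:
    """One feature: a map from an environment row to a value in [0, 1]."""

    var: str
    cls: str  # linear | quadratic | product | hinge_fwd | hinge_rev | threshold | categorical
    var2: str | None = None
    knot: float | None = None
    level: float | None = None
    lo: float = 0.0
    hi: float = 1.0

    @property
    def beta_class(self) -> str:
        if self.cls in ("hinge_fwd", "hinge_rev"):
            return "hinge"
        return self.cls

    @property
    def label(self) -> str:
        if self.cls == "product":
            return f"{self.var}*{self.var2}"
        if self.cls in ("hinge_fwd", "hinge_rev", "threshold"):
            return f"{self.cls}({self.var}@{self.knot:.4g})"
        if self.cls == "categorical":
            return f"{self.var}=={self.level:g}"
        return f"{self.cls}({self.var})"


@dataclass
class FeatureSet:
    """Feature definitions plus the normalization constants needed to map an
    environment table to a design matrix with every column in [0, 1]."""

    features: list[Feature]
    variables: list[str]
    categorical: list[str]
    var_range: dict[str, tuple[float, float]]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def source_vars(self, feat: Feature) -> list[str]:
        return [feat.var] if feat.var2 is None else [feat.var, feat.var2]

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        """Design matrix (n_rows x n_features), clamped to [0, 1]."""
        n = len(env)
        out = np.empty((n, len(self.features)), dtype=np.float64)
        cols = {v: env[v].to_numpy(dtype=np.float64) for v in self.variables}
        for j, f in enumerate(self.features):
            x = cols[f.var]
            if f.cls == "linear":
                raw = x
            elif f.cls == "quadratic":
                raw = x * x
            elif f.cls == "product":
                raw = x * cols[f.var2]
            elif f.cls == "threshold":
                out[:, j] = (x >= f.knot).astype(np.float64)
                continue
            elif f.cls == "hinge_fwd":
                out[:, j] = np.clip((x - f.knot) / (f.hi - f.knot), 0.0, 1.0)
                continue
            elif f.cls == "hinge_rev":
                out[:, j] = np.clip((f.knot - x) / (f.knot - f.lo), 0.0, 1.0)
                continue
            elif f.cls == "categorical":
                out[:, j] = (x == f.level).astype(np.float64)
                continue
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {f.cls!r}")
            out[:, j] = np.clip((raw - f.lo) / (f.hi - f.lo), 0.0, 1.0)
        return out


@dataclass
class BackgroundSample:
    """Background cells (row/col indices) with their environment table."""

    rows: np.ndarray
    cols: np.ndarray
    env: pd.DataFrame

    def __len__(self) -> int:
        return len(self.env)


@dataclass
class MaxentModel:
    feature_set: FeatureSet
    weights: np.ndarray
    log_z: float                 # log partition over the background sample
    entropy: float               # H of the fitted raw distribution
    settings: MaxentSettings
    gain: float                  # regularized training gain at the optimum
    n_presence: int
    n_background: int
    iterations: int
    gain_path: list[float] = field(default_factory=list)
    var_contribution: dict[str, float] = field(default_factory=dict)
    background_env: pd.DataFrame | None = None

    @property
    def variables(self) -> list[str]:
        return self.feature_set.variables

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "weights": self.weights.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "iterations": self.iterations,
            "var_contribution": self.var_contribution,
            "settings": asdict(self.settings),
            "feature_set": {
                "variables": self.feature_set.variables,
                "categorical": self.feature_set.categorical,
                "var_range": {k: list(v) for k, v in self.feature_set.var_range.items()},
                "features": [asdict(f) for f in self.feature_set.features],
            },
            "background_env": (
                None
                if self.background_env is None
                else self.background_env.to_dict(orient="list")
            ),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MaxentModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    doc = json.load(fh)
        fs_doc = doc["feature_set"]
        fset = FeatureSet(
            features=[Feature(**f) for f in fs_doc["features"]],
            variables=fs_doc["variables"],
            categorical=fs_doc["categorical"],
            var_range={k: tuple(v) for k, v in fs_doc["var_range"].items()},
        )
        bg = doc.get("background_env")
        return cls(
            feature_set=fset,
            weights=np.asarray(doc["weights"], dtype=np.float64),
            log_z=doc["log_z"],
            entropy=doc["entropy"],
            settings=MaxentSettings(**doc["settings"]),
            gain=doc["gain"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
            iterations=doc["iterations"],
            var_contribution=doc.get("var_contribution", {}),
            background_env=None if bg is None else pd.DataFrame(bg),
        )


@dataclass
class ImportanceReport:
    """Per-variable diagnostics mirroring the standard importance table."""

    variables: list[str]
    percent_contribution: dict[str, float]
    permutation_importance: dict[str, float]
    gain_without: dict[str, float]
    gain_with_only: dict[str, float]
    full_gain: float
    training_auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "percent_contribution": [
                    self.percent_contribution[v] for v in self.variables
                ],
                "permutation_importance": [
                    self.permutation_importance[v] for v in self.variables
                ],
                "gain_without": [self.gain_without[v] for v in self.variables],
                "gain_with_only": [self.gain_with_only[v] for v in self.variables],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Environment extraction and background sampling
# ---------------------------------------------------------------------------

def env_at_cells(stack: RasterStack, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {l.name: l.values[rows, cols].astype(np.float64) for l in stack}
    )


def env_at_points(stack: RasterStack, xy: np.ndarray) -> pd.DataFrame:
    """Environment table at point coordinates; raises if any point falls on
    a nodata or out-of-grid cell."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    spec = stack.spec
    rows, cols = spec.cell_of(xy[:, 0], xy[:, 1])
    inside = (rows >= 0) & (rows < spec.n_rows) & (cols >= 0) & (cols < spec.n_cols)
    if not inside.all():
        raise ValueError(
            f"{int((~inside).sum())} point(s) outside the grid extent"
        )
    valid = stack.joint_valid_mask()[rows, cols]
    if not valid.all():
        raise ValueError(f"{int((~valid).sum())} point(s) fall on nodata cells")
    return env_at_cells(stack, rows, cols)


def sample_background(stack: RasterStack, n: int, seed: int) -> BackgroundSample:
    """Uniform sample, without replacement, of jointly valid cells.

    If fewer than ``n`` valid cells exist, all of them are used (with a
    warning).  Deterministic given ``seed``.
    """
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    n_valid = rows.size
    if n_valid == 0:
        raise ValueError("no valid cells to sample background from")
    if n_valid < n:
        warnings.warn(
            f"only {n_valid} valid cells available; using all of them "
            f"(requested {n})",
            stacklevel=2,
        )
        idx = np.arange(n_valid)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_valid, size=n, replace=False)
    r, c = rows[idx], cols[idx]
    return BackgroundSample(rows=r, cols=c, env=env_at_cells(stack, r, c))


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def auto_feature_classes(m: int) -> list[str]:
    """Default feature classes as a function of presence count."""
    classes = ["linear"]
    if m >= 10:
        classes.append("quadratic")
    if m >= 15:
        classes.append("hinge")
    if m >= 80:
        classes += ["product", "threshold"]
    return classes


def build_features(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    settings: MaxentSettings,
    categorical: Sequence[str] = (),
) -> FeatureSet:
    """Expand environment variables into the normalized feature set.

    Continuous variables are min/max-scaled over presence plus background;
    hinge and threshold knots sit on an even grid strictly inside the
    variable's range.  Categorical variables expand to one indicator per
    observed level.  Constant variables keep only well-defined features.
    """
    if presence_env.shape[1] == 0:
        raise ValueError("at least one environment variable is required")
    if list(presence_env.columns) != list(background_env.columns):
        raise ValueError("presence and background tables must share columns")
    m = len(presence_env)
    categorical = [c for c in categorical if c in presence_env.columns]
    cont = [c for c in presence_env.columns if c not in categorical]
    classes = (
        auto_feature_classes(m)
        if settings.feature_classes == "auto"
        else list(settings.feature_classes)
    )
    both = pd.concat([presence_env, background_env], ignore_index=True)

    var_range: dict[str, tuple[float, float]] = {}
    for v in cont:
        var_range[v] = (float(both[v].min()), float(both[v].max()))

    features: list[Feature] = []
    constant = [v for v in cont if var_range[v][0] == var_range[v][1]]
    if constant:
        warnings.warn(
            f"constant variables, degenerate features skipped: {constant}",
            stacklevel=2,
        )
    usable = [v for v in cont if v not in constant]

    def scaled(cls: str, var: str, var2: str | None = None) -> Feature | None:
        if cls == "linear":
            raw = both[var]
        elif cls == "quadratic":
            raw = both[var] ** 2
        else:
            raw = both[var] * both[var2]
        lo, hi = float(raw.min()), float(raw.max())
        if lo == hi:
            return None
        return Feature(var=var, cls=cls, var2=var2, lo=lo, hi=hi)

    if "linear" in classes:
        for v in usable:
            f = scaled("linear", v)
            if f:
                features.append(f)
    if "quadratic" in classes:
        for v in usable:
            f = scaled("quadratic", v)
            if f:
                features.append(f)
    if "product" in classes:
        for i, v in enumerate(usable):
            for w in usable[i + 1:]:
                f = scaled("product", v, w)
                if f:
                    features.append(f)
    if "hinge" in classes:
        for v in usable:
            lo, hi = var_range[v]
            knots = np.linspace(lo, hi, settings.hinge_knots + 2)[1:-1]
            for k in knots:
                features.append(Feature(v, "hinge_fwd", knot=float(k), lo=lo, hi=hi))
                features.append(Feature(v, "hinge_rev", knot=float(k), lo=lo, hi=hi))
    if "threshold" in classes:
        for v in usable:
            lo, hi = var_range[v]
            knots = np.linspace(lo, hi, settings.threshold_knots + 2)[1:-1]
            for k in knots:
                features.append(Feature(v, "threshold", knot=float(k), lo=lo, hi=hi))
    for v in categorical:
        levels = np.unique(both[v].to_numpy())
        for lev in levels:
            features.append(Feature(v, "categorical", level=float(lev)))
        var_range[v] = (float(levels.min()), float(levels.max()))

    if not features:
        raise ValueError("no usable features could be constructed")
    return FeatureSet(
        features=features,
        variables=list(presence_env.columns),
        categorical=list(categorical),
        var_range=var_range,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _feature_betas(
    fset: FeatureSet, f_presence: np.ndarray, settings: MaxentSettings
) -> np.ndarray:
    if settings.beta_override is not None:
        return np.full(fset.n_features, float(settings.beta_override))
    m = f_presence.shape[0]
    sd = f_presence.std(axis=0)
    sd = np.maximum(sd, _MIN_FEATURE_SD)
    betas = np.empty(fset.n_features)
    for j, feat in enumerate(fset.features):
        xs, ys = _BETA_TABLES[feat.beta_class]
        base = float(np.interp(m, xs, ys))
        betas[j] = settings.regularization_multiplier * base * sd[j] / np.sqrt(m)
    return betas


def fit(
    presence_env: pd.DataFrame,
    background: BackgroundSample | pd.DataFrame,
    settings: MaxentSettings | None = None,
    categorical: Sequence[str] = (),
    feature_set: FeatureSet | None = None,
) -> MaxentModel:
    """Fit the model by cyclic coordinate descent on the regularized gain.

    Each coordinate takes a soft-thresholded Newton step, backtracked
    against the exact penalized-gain change, so the gain increases
    monotonically; iteration stops when a full cycle improves the gain by
    less than ``convergence_threshold``.
    """
    settings = settings or MaxentSettings()
    bg_env = background.env if isinstance(background, BackgroundSample) else background
    m = len(presence_env)
    n = len(bg_env)
    if m < 2:
        raise ValueError(f"need at least 2 presences, got {m}")
    if n < 1:
        raise ValueError("background is empty")
    fset = feature_set or build_features(presence_env, bg_env, settings, categorical)
    f_p = fset.transform(presence_env)
    f_b = fset.transform(bg_env)
    if not (np.isfinite(f_p).all() and np.isfinite(f_b).all()):
        raise ValueError("non-finite feature values; degenerate inputs")
    betas = _feature_betas(fset, f_p, settings)
    pbar = f_p.mean(axis=0)

    J = fset.n_features
    lam = np.zeros(J)
    s_b = np.zeros(n)
    log_z = float(np.log(n))
    gain = 0.0
    gain_path = [0.0]
    credit: dict[str, float] = {v: 0.0 for v in fset.variables}
    n_cycles = 0

    for _cycle in range(settings.max_iterations):
        n_cycles += 1
        gain_start = gain
        for j in range(J):
            fj_b = f_b[:, j]
            q = np.exp(s_b - log_z)
            e_q = float(q @ fj_b)
            e_q2 = float(q @ (fj_b * fj_b))
            h = max(e_q2 - e_q * e_q, 1e-12)
            g0 = pbar[j] - e_q
            b = betas[j]
            lj = lam[j]
            if lj > 0:
                d = (g0 - b) / h
                if lj + d < 0:
                    d = -lj
            elif lj < 0:
                d = (g0 + b) / h
                if lj + d > 0:
                    d = -lj
            else:
                if g0 > b:
                    d = (g0 - b) / h
                elif g0 < -b:
                    d = (g0 + b) / h
                else:
                    continue
            if d == 0.0:
                continue
            # exact penalized-gain change; halve the step until positive
            for _ in range(60):
                new_log_z = float(logsumexp(s_b + d * fj_b))
                delta = (
                    d * pbar[j]
                    - (new_log_z - log_z)
                    - b * (abs(lj + d) - abs(lj))
                )
                if delta > 0:
                    break
                d *= 0.5
                if abs(d) < 1e-15:
                    d = 0.0
                    break
            if d == 0.0 or delta <= 0:
                continue
            lam[j] = lj + d
            s_b += d * fj_b
            log_z = new_log_z
            gain += delta
            srcs = fset.source_vars(fset.features[j])
            for v in srcs:
                credit[v] += delta / len(srcs)
        gain_path.append(gain)
        if gain - gain_start < settings.convergence_threshold:
            break

    if not np.isfinite(gain):
        raise ValueError("non-finite training gain; degenerate features")

    q = np.exp(s_b - log_z)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxentModel(
        feature_set=fset,
        weights=lam,
        log_z=log_z,
        entropy=entropy,
        settings=settings,
        gain=float(gain),
        n_presence=m,
        n_background=n,
        iterations=n_cycles,
        gain_path=gain_path,
        var_contribution=credit,
        background_env=bg_env.copy(),
    )


def regularized_gain(
    model: MaxentModel, presence_env: pd.DataFrame, background_env: pd.DataFrame
) -> float:
    """Recompute the regularized training gain of a model on given data."""
    f_p = model.feature_set.transform(presence_env)
    f_b = model.feature_set.transform(background_env)
    s_p = f_p @ model.weights
    log_z = float(logsumexp(f_b @ model.weights))
    betas = _feature_betas(model.feature_set, f_p, model.settings)
    penalty = float(betas @ np.abs(model.weights))
    return float(s_p.mean() - log_z + np.log(len(background_env)) - penalty)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _scores(model: MaxentModel, env: pd.DataFrame) -> np.ndarray:
    return model.feature_set.transform(env) @ model.weights


def predict(model: MaxentModel, env: pd.DataFrame, output: Output = "cloglog") -> np.ndarray:
    """Predict raw density, logistic, or cloglog suitability for each row."""
    s = _scores(model, env)
    log_raw = s - model.log_z
    if output == "raw":
        return np.exp(log_raw)
    # work in log space; cap the exponent so extreme scores saturate at 1
    eh_r = np.exp(np.minimum(model.entropy + log_raw, 700.0))
    if output == "cloglog":
        return 1.0 - np.exp(-eh_r)
    if output == "logistic":
        tau = model.settings.prevalence_tau
        return np.where(
            np.isinf(eh_r), 1.0, tau * eh_r / (1.0 - tau + tau * eh_r)
        )
    raise ValueError(f"unknown output {output!r}")


def auc_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: probability that a random presence outranks a
    random background point, ties counted half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least one presence and one background score")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def auc(
    model: MaxentModel,
    presence_env: pd.DataFrame,
    background: BackgroundSample | pd.DataFrame,
) -> float:
    bg_env = background.env if isinstance(background, BackgroundSample) else background
    return auc_scores(_scores(model, presence_env), _scores(model, bg_env))


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def _normalize_to_100(raw: dict[str, float]) -> dict[str, float]:
    total = sum(raw.values())
    if total <= 0:
        return {k: 0.0 for k in raw}
    return {k: 100.0 * v / total for k, v in raw.items()}


def importance(
    model: MaxentModel,
    presence_env: pd.DataFrame,
    background: BackgroundSample | pd.DataFrame,
    seed: int = 0,
    replicates: int = 1,
    jackknife: bool = True,
) -> ImportanceReport:
    """Percent contribution, permutation importance, and jackknife gains.

    Contribution credits each coordinate-descent gain increment to the
    updated feature's source variable(s).  Permutation importance permutes a
    variable jointly across presence and background, measures the training
    AUC drop (floored at 0), and normalizes to 100.  The jackknife refits
    with only / without each variable.
    """
    bg_env = background.env if isinstance(background, BackgroundSample) else background
    variables = model.variables
    if len(variables) < 1:
        raise ValueError("model has no variables")

    contribution = _normalize_to_100(dict(model.var_contribution))

    full_auc = auc(model, presence_env, bg_env)
    rng = np.random.default_rng(seed)
    m = len(presence_env)
    drops: dict[str, float] = {}
    for v in variables:
        drop_reps = []
        for _ in range(replicates):
            combined = np.concatenate(
                [presence_env[v].to_numpy(), bg_env[v].to_numpy()]
            )
            perm = rng.permutation(combined)
            p_env = presence_env.copy()
            b_env = bg_env.copy()
            p_env[v] = perm[:m]
            b_env[v] = perm[m:]
            perm_auc = auc_scores(_scores(model, p_env), _scores(model, b_env))
            drop_reps.append(max(0.0, full_auc - perm_auc))
        drops[v] = float(np.mean(drop_reps))
    permutation = _normalize_to_100(drops)

    cat = model.feature_set.categorical
    gain_with_only: dict[str, float] = {v: float("nan") for v in variables}
    gain_without: dict[str, float] = {v: float("nan") for v in variables}
    for v in (variables if jackknife else []):
        only = fit(
            presence_env[[v]], bg_env[[v]], model.settings,
            categorical=[c for c in cat if c == v],
        )
        gain_with_only[v] = only.gain
        rest = [w for w in variables if w != v]
        if rest:
            without = fit(
                presence_env[rest], bg_env[rest], model.settings,
                categorical=[c for c in cat if c != v],
            )
            gain_without[v] = without.gain
        else:
            gain_without[v] = 0.0

    return ImportanceReport(
        variables=list(variables),
        percent_contribution=contribution,
        permutation_importance=permutation,
        gain_without=gain_without,
        gain_with_only=gain_with_only,
        full_gain=model.gain,
        training_auc=full_auc,
    )


# ---------------------------------------------------------------------------
# Response curves and raster projection
# ---------------------------------------------------------------------------

def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal cloglog response: sweep one variable across its observed
    range (its levels, if categorical) with the others held at the
    background mean / modal level."""
    if variable not in model.variables:
        raise KeyError(f"variable {variable!r} not in model")
    if model.background_env is None:
        raise ValueError("model carries no background sample")
    bg = model.background_env
    fixed: dict[str, float] = {}
    for v in model.variables:
        col = bg[v]
        if v in model.feature_set.categorical:
            fixed[v] = float(col.mode().iloc[0])
        else:
            fixed[v] = float(col.mean())
    if variable in model.feature_set.categorical:
        sweep = np.unique(bg[variable].to_numpy())
    else:
        lo, hi = model.feature_set.var_range[variable]
        sweep = np.linspace(lo, hi, n_points)
    env = pd.DataFrame({v: np.full(len(sweep), fixed[v]) for v in model.variables})
    env[variable] = sweep
    return sweep, predict(model, env, "cloglog")


def project(
    model: MaxentModel, stack: RasterStack, output: Output = "cloglog",
    name: str = "suitability",
) -> GridLayer:
    """Predict over every jointly valid cell of a raster stack."""
    missing = [v for v in model.variables if v not in stack]
    if missing:
        raise ValueError(f"stack is missing model variable(s): {missing}")
    sub = stack.subset(model.variables)
    mask = sub.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    env = env_at_cells(sub, rows, cols)
    preds = predict(model, env, output)
    nodata = -9999.0
    values = np.full(mask.shape, nodata, dtype=np.float64)
    values[rows, cols] = preds
    return GridLayer(sub.spec, name, "continuous", values, nodata)
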