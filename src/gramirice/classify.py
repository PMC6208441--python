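"""Paddy-field classification: phenology metrics, PCI, terrain variables, RF + RFE.

Rice paddies are flooded at transplanting (low NDVI, ~DOY 140) and carry a
ripening canopy near harvest (~DOY 270), so the normalised difference of the
two anchor-date NDVI values (the paddy classification index, PCI) separates
paddy from upland vegetation. PCI is combined with curve-shape descriptors of
the smoothed NDVI season (peak value/date, steepest green-up and senescence
rates and their dates) and terrain covariates (elevation, Horn slope,
topographic wetness index), then classified with a random forest whose
features are ranked by recursive feature elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from scipy.signal import savgol_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .stats import ErrorMatrix, error_matrix  # noqa: F401  (re-exported surface)

__all__ = [
    "PhenoMetrics",
    "TerrainVars",
    "paddy_classification_index",
    "median_daily_series",
    "pheno_metrics",
    "pheno_metrics_grid",
    "terrain_variables",
    "rfe_rank",
    "train_classifier",
    "classify_paddy",
    "holdout_accuracy",
    "error_matrix",
    "PHENO_FEATURES",
]

TRANSPLANT_DOY = 140
HARVEST_DOY = 270
ANCHOR_TOL = 8  # days; half-width of the 16-day BRDF retrieval window
SG_WINDOW = 15  # days
SG_ORDER = 2

PHENO_FEATURES = [
    "max_peak_value",
    "max_peak_date",
    "max_growth_rate",
    "max_fading_rate",
    "max_fading_date",
    "pci",
]


@dataclass
class PhenoMetrics:
    max_peak_value: float
    max_peak_date: float
    max_growth_rate: float
    max_fading_rate: float  # magnitude of the steepest decline
    max_fading_date: float
    pci: float


@dataclass
class TerrainVars:
    elevation: np.ndarray
    slope_deg: np.ndarray
    wetness_index: np.ndarray


def median_daily_series(frames) -> pd.DataFrame:
    """Per-DOY median NDVI across multiple years of daily series."""
    cat = pd.concat(frames, ignore_index=True)
    out = cat.groupby("doy", as_index=False)["ndvi"].median()
    return out.sort_values("doy").reset_index(drop=True)


def _nearest_valid(doy, ndvi, anchor, tol):
    ok = np.isfinite(ndvi)
    if not ok.any():
        return np.nan
    d, v = doy[ok], ndvi[ok]
    i = np.argmin(np.abs(d - anchor))
    return v[i] if abs(d[i] - anchor) <= tol else np.nan


def paddy_classification_index(
    doy,
    ndvi,
    transplant_doy: int = TRANSPLANT_DOY,
    harvest_doy: int = HARVEST_DOY,
    tol: int = ANCHOR_TOL,
) -> float:
    """PCI = (NDVI_harvest - NDVI_transplant) / (NDVI_harvest + NDVI_transplant).

    Anchor values are the nearest valid observations within +/- tol days of
    the transplanting (~DOY 140) and harvest (~DOY 270) dates. NaN when an
    anchor is missing or the denominator is non-positive. For multi-year
    input, reduce with :func:`median_daily_series` first.
    """
    doy = np.asarray(doy, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    v_t = _nearest_valid(doy, ndvi, transplant_doy, tol)
    v_h = _nearest_valid(doy, ndvi, harvest_doy, tol)
    denom = v_h + v_t
    if not np.isfinite(denom) or denom <= 0:
        return float("nan")
    return float((v_h - v_t) / denom)


def _smooth_daily(doy, ndvi):
    """Gap-interpolated daily grid + Savitzky-Golay smoothing."""
    ok = np.isfinite(ndvi)
    d, v = doy[ok], ndvi[ok]
    grid = np.arange(int(d.min()), int(d.max()) + 1)
    filled = np.interp(grid, d, v)
    if grid.size >= SG_WINDOW:
        filled = savgol_filter(filled, SG_WINDOW, SG_ORDER)
    return grid, filled


def pheno_metrics(doy, ndvi, min_obs: int = 10, **pci_kwargs) -> PhenoMetrics:
    """Seasonal curve descriptors of one NDVI series.

    The series is linearly interpolated to a daily grid, smoothed with a
    Savitzky-Golay filter (15 d, order 2), and summarised by the peak, the
    steepest rise before the peak, and the steepest decline after it.
    """
    doy = np.asarray(doy, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    if np.isfinite(ndvi).sum() < min_obs:
        nan = float("nan")
        return PhenoMetrics(nan, nan, nan, nan, nan, nan)
    grid, smooth = _smooth_daily(doy, ndvi)
    ipk = int(np.argmax(smooth))
    diffs = np.diff(smooth)
    growth = float(diffs[:ipk].max()) if ipk > 0 else 0.0
    if ipk < diffs.size:
        post = diffs[ipk:]
        ifade = int(np.argmin(post))
        fading = float(-post[ifade])
        fading_date = float(grid[ipk + ifade + 1])
    else:
        fading, fading_date = 0.0, float(grid[ipk])
    pci = paddy_classification_index(grid, smooth, **pci_kwargs)
    return PhenoMetrics(
        max_peak_value=float(smooth[ipk]),
        max_peak_date=float(grid[ipk]),
        max_growth_rate=max(growth, 0.0),
        max_fading_rate=max(fading, 0.0),
        max_fading_date=fading_date,
        pci=pci,
    )


def pheno_metrics_grid(doy, ndvi_stack, **kwargs) -> pd.DataFrame:
    """pheno_metrics applied row-wise to a (n_pixels, n_days) NDVI stack."""
    rows = [pheno_metrics(doy, ndvi_stack[i], **kwargs).__dict__ for i in range(ndvi_stack.shape[0])]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Terrain analysis


def _horn_gradients(dem, cell_size):
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * cell_size)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8.0 * cell_size)
    gx = convolve(dem, kx, mode="nearest")
    gy = convolve(dem, ky, mode="nearest")
    return gx, gy


def _d8_flow_accumulation(dem):
    """D8 flow accumulation in cells: each cell drains to its steepest-descent neighbour."""
    rows, cols = dem.shape
    acc = np.ones_like(dem, dtype=float)
    order = np.argsort(dem, axis=None)[::-1]  # high to low
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dists = [np.sqrt(2), 1, np.sqrt(2), 1, 1, np.sqrt(2), 1, np.sqrt(2)]
    for flat in order:
        r, c = divmod(int(flat), cols)
        best, target = 0.0, None
        for (dr, dc), dist in zip(nbrs, dists):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                drop = (dem[r, c] - dem[rr, cc]) / dist
                if drop > best:
                    best, target = drop, (rr, cc)
        if target is not None:
            acc[target] += acc[r, c]
    return acc


def terrain_variables(dem, cell_size: float) -> TerrainVars:
    """Slope (Horn 3x3) and topographic wetness index from a DEM grid.

    TWI = ln(a / tan(beta)) with specific catchment area a = (D8 accumulated
    cells * cell area) / cell width and tan(beta) floored at 0.001 so flat
    terrain stays finite.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 3:
        raise ValueError("DEM must be at least 3x3")
    if np.isnan(dem).all():
        raise ValueError("DEM is all-NaN")
    gx, gy = _horn_gradients(dem, cell_size)
    tan_beta = np.hypot(gx, gy)
    slope_deg = np.rad2deg(np.arctan(tan_beta))
    acc = _d8_flow_accumulation(dem)
    sca = acc * cell_size  # (cells * cell_size^2) / cell_size
    twi = np.log(sca / np.maximum(tan_beta, 1e-3))
    return TerrainVars(elevation=dem, slope_deg=slope_deg, wetness_index=twi)


# ---------------------------------------------------------------------------
# Random forest + recursive feature elimination


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) aligned with labels")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return X, y


def train_classifier(X, y, feature_names=None, n_trees: int = 1000, seed: int = 0):
    """Fit the paddy/non-paddy random forest (majority-vote of ~1000 trees)."""
    X, y = _check_xy(X, y)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    rf.feature_names_ = list(feature_names) if feature_names is not None else None
    return rf


def classify_paddy(model, features, feature_names=None) -> np.ndarray:
    """Per-pixel binary labels from a trained model.

    `features` is (n_samples, n_features) or a (rows, cols, n_features) grid
    stack; a grid stack returns a (rows, cols) label grid. The feature schema
    must match training.
    """
    feats = np.asarray(features, dtype=float)
    grid_shape = None
    if feats.ndim == 3:
        grid_shape = feats.shape[:2]
        feats = feats.reshape(-1, feats.shape[2])
    if getattr(model, "feature_names_", None) is not None and feature_names is not None:
        if list(feature_names) != model.feature_names_:
            raise ValueError("feature schema does not match the trained model")
    if feats.shape[1] != model.n_features_in_:
        raise ValueError("feature count does not match the trained model")
    labels = model.predict(feats)
    return labels.reshape(grid_shape) if grid_shape else labels


def rfe_rank(
    X,
    y,
    feature_names,
    n_trees: int = 1000,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
    cv_trees: int = 200,
    evaluate_subsets: bool = True,
) -> dict:
    """Recursive feature elimination driven by random-forest importance.

    Each round fits a forest on the surviving features of the full training
    data and removes the least important one; the elimination order (reversed)
    is the ranking. When `evaluate_subsets` is true, every subset size along
    the ranking is scored by repeated stratified k-fold cross-validation
    (n_repeats x n_folds) and the best mean accuracy picks the selected
    subset. Deterministic under `seed`.

    Returns {"ranking": [best..worst], "selected": [...], "cv_accuracy": {size: acc}}.
    """
    X, y = _check_xy(X, y)
    names = list(feature_names)
    if len(names) != X.shape[1] or len(names) < 2:
        raise ValueError("need >= 2 named features matching X columns")

    remaining = list(range(len(names)))
    eliminated: list[int] = []
    rng = np.random.default_rng(seed)
    while len(remaining) > 1:
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(X[:, remaining], y)
        worst_local = int(np.argmin(rf.feature_importances_))
        eliminated.append(remaining.pop(worst_local))
    ranking_idx = remaining + eliminated[::-1]
    ranking = [names[i] for i in ranking_idx]

    cv_accuracy: dict[int, float] = {}
    selected = ranking
    if evaluate_subsets:
        splitter = RepeatedStratifiedKFold(
            n_splits=n_folds, n_repeats=n_repeats, random_state=seed
        )
        for size in range(1, len(names) + 1):
            cols = ranking_idx[:size]
            accs = []
            for tr, te in splitter.split(X, y):
                rf = RandomForestClassifier(n_estimators=cv_trees, random_state=seed, n_jobs=1)
                rf.fit(X[np.ix_(tr, cols)], y[tr])
                accs.append(rf.score(X[np.ix_(te, cols)], y[te]))
            cv_accuracy[size] = float(np.mean(accs))
        best_size = max(cv_accuracy, key=lambda k: (cv_accuracy[k], -k))
        selected = ranking[:best_size]
    return {"ranking": ranking, "selected": selected, "cv_accuracy": cv_accuracy}


def holdout_accuracy(X, y, n_trees: int = 1000, n_folds: int = 10, seed: int = 0) -> float:
    """Mean stratified k-fold held-out overall accuracy of the random forest."""
    X, y = _check_xy(X, y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[tr], y[tr])
        accs.append(rf.score(X[te], y[te]))
    return float(np.mean(accs))
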