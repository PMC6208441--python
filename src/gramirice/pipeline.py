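"""End-to-end helpers tying the stages together on synthetic scenes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, synth
from .grami import DEFAULT_VI_CALIBRATIONS, CropConstants, GramiParams, simulate_season, vi_from_lai

__all__ = ["scene_features", "FEATURE_NAMES", "synth_grid_scene"]

FEATURE_NAMES = ["elevation", "slope_deg", "wetness_index"] + classify.PHENO_FEATURES


def scene_features(scene: synth.SyntheticScene):
    """Feature matrix (terrain + phenology metrics) and labels for a scene.

    Returns (X, feature_names, y) with one row per pixel in row-major order.
    Missing phenology metrics (too few clear observations) are imputed with
    the column median so the forest never sees NaN.
    """
    rows, cols = scene.labels.shape
    stack = scene.ndvi.reshape(rows * cols, -1)
    pheno = classify.pheno_metrics_grid(scene.doys, stack)
    feats = pd.DataFrame(
        {
            "elevation": scene.dem.ravel(),
            "slope_deg": scene.slope_deg.ravel(),
            "wetness_index": scene.wetness_index.ravel(),
        }
    )
    feats = pd.concat([feats, pheno[classify.PHENO_FEATURES]], axis=1)
    feats = feats.fillna(feats.median(numeric_only=True))
    return feats.to_numpy(dtype=float), list(feats.columns), scene.labels.ravel()


def synth_grid_scene(
    rows: int = 20,
    cols: int = 20,
    seed: int = 7,
    paddy_fraction: float = 0.3,
    noise_sd: float = 0.02,
    gap_prob: float = 0.2,
    obs_every: int = 4,
    params: GramiParams = GramiParams(),
    constants: CropConstants = CropConstants(),
    transplant_doy: int = 136,
):
    """Homogeneous-truth grid scene for the per-pixel crop pipeline.

    Every paddy pixel shares the same true crop parameters; its VI series is
    forward-generated by the crop model and degraded with pixel-independent
    noise and gaps (counter-based substreams of `seed`, so generation is
    order-invariant). Returns (vi_obs DataFrame, weather, mask, yield_true).
    """
    weather = synth.synth_weather(seed=seed)
    cal = DEFAULT_VI_CALIBRATIONS["NDVI"]
    traj, yield_true, _ = simulate_season(params, constants, weather, transplant_doy)
    traj = traj.groupby("doy", as_index=False).last()
    sel = traj.iloc[:: max(obs_every, 1)]
    base_doy = sel["doy"].to_numpy(dtype=float)
    base_vi = vi_from_lai(sel["lai"].to_numpy(), cal)

    rng_mask = np.random.default_rng([seed, 888])
    mask = (rng_mask.random((rows, cols)) < paddy_fraction).astype(int)

    frames = []
    for pid in np.flatnonzero(mask.ravel()):
        prng = np.random.default_rng([seed, 999, int(pid)])
        vi = base_vi + prng.normal(0.0, noise_sd, base_vi.shape)
        keep = prng.random(base_doy.shape) >= gap_prob
        if keep.sum() >= 4:
            frames.append(
                pd.DataFrame({"pixel_id": int(pid), "doy": base_doy[keep], "value": vi[keep]})
            )
    vi_obs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pixel_id", "doy", "value"]
    )
    return vi_obs, weather, mask, yield_true
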