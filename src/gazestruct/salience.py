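"""Graph-based salience maps and the moderate-salience screening rule.

The map follows the graph-based visual saliency construction: feature maps
for luminance contrast (center--surround differences across three scales)
and orientation (four oriented band-pass filters) are each turned into a
fully connected Markov chain over map cells, with edge weight

    w(a, b) = |M(a) - M(b)| * exp(-d(a, b)^2 / (2 sigma^2)).

The stationary distribution of the column-normalized chain is the
activation map; a second "concentration" pass runs a chain weighted by the
activation times the same distance kernel.  Activation maps are summed and
the result rescaled to max 1.

Screening: a candidate target is accepted when the mean map value inside
its disk is at least ``theta_target`` (at least moderately salient) AND
some other ring location's disk also reaches ``theta_rival`` (the target
is not the only salient region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .image import GrayImage

__all__ = [
    "SalienceMap",
    "ScreeningResult",
    "salience_map",
    "screen_target",
    "disk_mean",
    "save_heatmap_png",
    "save_raw",
    "load_raw",
]


@dataclass(frozen=True)
class SalienceMap:
    """Salience values on a coarse grid; ``scale`` is stimulus px per cell."""

    values: np.ndarray
    scale: float
    degenerate: bool = False


@dataclass(frozen=True)
class ScreeningResult:
    target_salience: float
    rival_salience: float
    accepted: bool
    thresholds: tuple[float, float]
    reason: str | None = None


def _distance_kernel(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """exp(-d^2 / 2 sigma^2) between all pairs of cells, flattened order."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def stationary_distribution(
    transition: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000
) -> np.ndarray:
    """Stationary distribution of a column-stochastic matrix by power iteration.

    Uniform start; iterates until the L1 change drops below ``tol``.
    """
    n = transition.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = transition @ v
        s = nxt.sum()
        if s > 0:
            nxt = nxt / s
        if np.abs(nxt - v).sum() < tol:
            return nxt
        v = nxt
    return v


def _chain_activation(weights: np.ndarray, kernel: np.ndarray, shape) -> np.ndarray:
    w = weights * kernel
    colsum = w.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return stationary_distribution(w / colsum).reshape(shape)


def _activation(feature: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Activation + one concentration pass for one feature map."""
    f = feature.ravel()
    act = _chain_activation(np.abs(f[:, None] - f[None, :]), kernel, feature.shape)
    # concentration: transition INTO a cell is weighted by its activation
    # (destination = row index under the column-stochastic convention)
    a = act.ravel()
    conc = _chain_activation(np.broadcast_to(a[:, None], kernel.shape).copy(), kernel, feature.shape)
    return conc


def _feature_maps(arr: np.ndarray, grid_shape: tuple[int, int]) -> list[np.ndarray]:
    """Luminance center-surround (3 scales) and orientation (4 angles) maps."""
    maps: list[np.ndarray] = []
    for sc, ss in ((1.0, 4.0), (2.0, 8.0), (4.0, 16.0)):
        cs = np.abs(ndimage.gaussian_filter(arr, sc) - ndimage.gaussian_filter(arr, ss))
        maps.append(resize(cs, grid_shape, anti_aliasing=True))
    smooth = ndimage.gaussian_filter(arr, 1.5)
    for theta in (0.0, 45.0, 90.0, 135.0):
        rad = np.deg2rad(theta)
        gy, gx = np.gradient(smooth)
        o = np.abs(gx * np.cos(rad) + gy * np.sin(rad))
        o = ndimage.gaussian_filter(o, 2.0)
        maps.append(resize(o, grid_shape, anti_aliasing=True))
    return maps


def salience_map(
    img: GrayImage,
    n_cells: int = 32,
    sigma_frac: float = 0.15,
    work_width: int = 256,
) -> SalienceMap:
    """Compute the combined salience map of a grayscale stimulus.

    The stimulus is reduced to a working resolution for feature extraction
    and the chains run on a grid whose longer axis has ``n_cells`` cells.
    The distance-kernel sigma is ``sigma_frac`` times the grid width.
    """
    if min(img.width, img.height) < 128:
        raise ValueError("image must be at least 128 px on each side")
    arr = img.normalized
    scale = img.width / (n_cells if img.width >= img.height else round(n_cells * img.width / img.height))
    if img.width >= img.height:
        grid_shape = (max(2, round(n_cells * img.height / img.width)), n_cells)
    else:
        grid_shape = (n_cells, max(2, round(n_cells * img.width / img.height)))
    scale = img.width / grid_shape[1]

    if img.levels.min() == img.levels.max():
        return SalienceMap(values=np.zeros(grid_shape), scale=scale, degenerate=True)

    work_h = max(64, round(work_width * img.height / img.width))
    work = resize(arr, (work_h, work_width), anti_aliasing=True)
    kernel = _distance_kernel(grid_shape, sigma_frac * grid_shape[1])
    combined = np.zeros(grid_shape)
    for fm in _feature_maps(work, grid_shape):
        if fm.max() - fm.min() < 1e-12:
            continue
        combined += _activation(fm, kernel)
    if combined.max() - combined.min() < 1e-9:
        return SalienceMap(values=combined, scale=scale, degenerate=True)
    return SalienceMap(values=combined / combined.max(), scale=scale)


def disk_mean(smap: SalienceMap, center_xy: tuple[float, float], radius_px: float) -> float:
    """Mean map value inside a disk given in stimulus pixel coordinates."""
    h, w = smap.values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx = center_xy[0] / smap.scale - 0.5
    cy = center_xy[1] / smap.scale - 0.5
    r = radius_px / smap.scale
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if not inside.any():
        return float(smap.values[min(h - 1, max(0, round(cy))), min(w - 1, max(0, round(cx)))])
    return float(smap.values[inside].mean())


def save_heatmap_png(smap: SalienceMap, path) -> None:
    """Write the map as an 8-bit grayscale heatmap PNG."""
    from PIL import Image as _PILImage

    v = smap.values
    rng_v = v.max() - v.min()
    scaled = (v - v.min()) / rng_v if rng_v > 0 else np.zeros_like(v)
    _PILImage.fromarray(np.round(scaled * 255).astype(np.uint8), mode="L").save(path)


def save_raw(smap: SalienceMap, path) -> None:
    """Write the map as flat float32 binary next to a JSON header."""
    import json
    from pathlib import Path

    path = Path(path)
    smap.values.astype("<f4").ravel().tofile(path)
    header = {
        "dtype": "<f4",
        "shape": list(smap.values.shape),
        "scale_px_per_cell": smap.scale,
        "degenerate": smap.degenerate,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def load_raw(path) -> SalienceMap:
    import json
    from pathlib import Path

    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"]).astype(float)
    return SalienceMap(values=values, scale=header["scale_px_per_cell"],
                       degenerate=header["degenerate"])


def screen_target(
    smap: SalienceMap,
    positions: list[tuple[float, float]],
    target_idx: int,
    target_radius_px: float,
    theta_target: float = 0.25,
    theta_rival: float = 0.10,
) -> ScreeningResult:
    """Apply the moderate-salience screening rule at the ring locations."""
    thresholds = (theta_target, theta_rival)
    if smap.degenerate:
        return ScreeningResult(0.0, 0.0, False, thresholds, reason="degenerate salience map")
    means = [disk_mean(smap, pos, target_radius_px) for pos in positions]
    target_sal = means[target_idx]
    rivals = [m for i, m in enumerate(means) if i != target_idx]
    rival_sal = max(rivals) if rivals else 0.0
    accepted = target_sal >= theta_target and rival_sal >= theta_rival
    reason = None
    if not accepted:
        if target_sal < theta_target:
            reason = "target not salient enough"
        else:
            reason = "target is the only salient region"
    return ScreeningResult(target_sal, rival_sal, accepted, thresholds, reason)
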