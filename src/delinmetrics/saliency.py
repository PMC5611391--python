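"""Graph-based visual saliency (GBVS) for masked grayscale slices.

The model treats locations of a coarse feature map as states of a
fully connected Markov chain. The weight of the edge from node (i, j)
to node (p, q) is

    w = |f(i,j) - f(p,q)| * exp(-((i-p)^2 + (j-q)^2) / (2 sigma^2)),

i.e. dissimilar nearby locations exchange mass readily. Column-
normalizing the weights gives a transition operator whose equilibrium
distribution concentrates on conspicuous regions (the *activation*
step). A second chain, with weights proportional to the activation at
the target node times the same distance kernel, further concentrates
the mass (the *normalization* step). Feature channels here are the
grayscale intensity and four directional-derivative orientation maps;
color channels are meaningless for MR data.

Saliency maps are computed per slice, zeroed outside the brain mask
(skull and eyes are never delineated), and rescaled so the maximum is
1. The *contour-saliency score* of a drawn boundary is the sum of
saliency values over its stroke pixels — how much of the drawing lies
on salient structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .datamodel import BinaryMask

__all__ = [
    "SaliencyConfig",
    "mask_non_brain",
    "gbvs_activation",
    "gbvs_normalize",
    "compute_saliency",
    "contour_saliency_score",
]

CHANNELS = ("intensity", "orientation")
_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)  # degrees


@dataclass
class SaliencyConfig:
    """GBVS settings.

    map_resolution : side of the square computation grid (default 32).
    sigma_frac : Gaussian distance-kernel width as a fraction of the
        map width (default 0.15).
    channels : subset of {"intensity", "orientation"}.
    solver_tol : L1 tolerance of the equilibrium power iteration.
    output_resolution : side of the returned saliency map (default 512).
    """

    map_resolution: int = 32
    sigma_frac: float = 0.15
    channels: tuple[str, ...] = CHANNELS
    solver_tol: float = 1e-9
    output_resolution: int = 512

    def __post_init__(self) -> None:
        if self.map_resolution < 4:
            raise ValueError(f"map_resolution must be >= 4, got {self.map_resolution}")
        if not 0 < self.sigma_frac < 1:
            raise ValueError(f"sigma_frac must be in (0, 1), got {self.sigma_frac}")
        bad = set(self.channels) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channels {bad}; valid: {CHANNELS}")
        if not self.channels:
            raise ValueError("at least one channel required")


def mask_non_brain(image: np.ndarray, brain_mask: BinaryMask) -> np.ndarray:
    """Replace pixels outside the brain mask by the within-mask mean.

    Flattening the background to the mean intensity removes the skull
    and eye structures without creating an artificial high-contrast
    edge at the mask border. Saliency outside the mask is zeroed later
    regardless.
    """
    if image.shape != brain_mask.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {brain_mask.shape}")
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    out = np.asarray(image, dtype=float).copy()
    out[~brain_mask] = out[brain_mask].mean()
    return out


@lru_cache(maxsize=8)
def _distance_kernel(height: int, width: int, sigma: float) -> np.ndarray:
    """exp(-d^2 / 2 sigma^2) between all pairs of grid nodes, (N, N)."""
    ii, jj = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _equilibrium(weights: np.ndarray, tol: float, max_iter: int = 10000) -> np.ndarray:
    """Stationary distribution of the column-normalized weight matrix.

    Power iteration on the lazy chain (M + I)/2, which shares the
    stationary vector of M but cannot oscillate. An all-zero weight
    matrix (constant feature map) is a degenerate chain: returns the
    uniform distribution with a warning.
    """
    n = weights.shape[0]
    col_sums = weights.sum(axis=0)
    if np.all(col_sums == 0):
        warnings.warn("constant feature map: uniform equilibrium returned", stacklevel=3)
        return np.full(n, 1.0 / n)
    safe = np.where(col_sums == 0, 1.0, col_sums)
    M = weights / safe
    # a state with no outgoing mass redistributes uniformly
    M[:, col_sums == 0] = 1.0 / n
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = 0.5 * (M @ x + x)
        x_new /= x_new.sum()
        if np.abs(x_new - x).sum() < tol:
            return x_new
        x = x_new
    warnings.warn(f"equilibrium power iteration did not reach tol={tol}", stacklevel=3)
    return x


def gbvs_activation(feature_map: np.ndarray, config: SaliencyConfig | None = None) -> np.ndarray:
    """Activation map: equilibrium of the dissimilarity-weighted chain.

    Edge weight from node a to node b is |f(a) - f(b)| times a Gaussian
    distance kernel of width ``sigma_frac * map width``. The returned
    map has the feature map's shape and sums to 1.
    """
    config = config or SaliencyConfig()
    f = np.asarray(feature_map, dtype=float)
    h, w = f.shape
    sigma = config.sigma_frac * w
    kernel = _distance_kernel(h, w, sigma)
    flat = f.ravel()
    weights = np.abs(flat[None, :] - flat[:, None]) * kernel
    return _equilibrium(weights, config.solver_tol).reshape(h, w)


def gbvs_normalize(activation: np.ndarray, config: SaliencyConfig | None = None) -> np.ndarray:
    """Concentration pass: equilibrium of the chain whose edge weight
    into node b is the activation mass at b times the distance kernel.
    Mass concentrates where activation is already high; a uniform
    activation is a fixed point.
    """
    config = config or SaliencyConfig()
    a = np.asarray(activation, dtype=float)
    h, w = a.shape
    if np.ptp(a) <= 1e-15:
        # uniform activation carries no conspicuity to concentrate; it is
        # the fixed point of the idealized (translation-invariant) chain,
        # which the finite grid only approximates — return it unchanged
        return a.copy()
    sigma = config.sigma_frac * w
    kernel = _distance_kernel(h, w, sigma)
    flat = a.ravel()
    # weights[target, source] = A(target) * kernel
    weights = flat[:, None] * kernel
    return _equilibrium(weights, config.solver_tol).reshape(h, w)


def _feature_maps(small: np.ndarray, channels: tuple[str, ...]) -> dict[str, list[np.ndarray]]:
    """Per-channel feature maps on the computation grid."""
    maps: dict[str, list[np.ndarray]] = {}
    if "intensity" in channels:
        maps["intensity"] = [small]
    if "orientation" in channels:
        dy = ndimage.gaussian_filter(small, sigma=1.0, order=(1, 0))
        dx = ndimage.gaussian_filter(small, sigma=1.0, order=(0, 1))
        omaps = []
        for theta in _ORIENTATIONS:
            t = np.deg2rad(theta)
            omaps.append(np.abs(np.cos(t) * dx + np.sin(t) * dy))
        maps["orientation"] = omaps
    return maps


def compute_saliency(
    image: np.ndarray,
    brain_mask: BinaryMask,
    config: SaliencyConfig | None = None,
) -> np.ndarray:
    """Full GBVS saliency map of one masked grayscale slice.

    Pipeline: flatten non-brain pixels -> downsample to the
    computation grid -> per feature map, activation then concentration
    -> average maps within each channel, then average channels ->
    bilinear upsample to ``output_resolution`` -> zero outside the
    brain mask -> divide by the maximum so the map peaks at exactly 1.
    A constant masked image has no conspicuous structure: an all-zero
    map is returned with a warning.
    """
    config = config or SaliencyConfig()
    masked = mask_non_brain(image, brain_mask)
    lo, hi = masked.min(), masked.max()
    out_res = config.output_resolution
    if hi == lo:
        warnings.warn("constant masked image: all-zero saliency map", stacklevel=2)
        return np.zeros((out_res, out_res))
    # affine-normalize; the equilibria are scale-invariant anyway
    masked = (masked - lo) / (hi - lo)
    res = config.map_resolution
    small = resize(masked, (res, res), order=1, anti_aliasing=True)

    channel_maps = []
    for _, fmaps in _feature_maps(small, config.channels).items():
        per_map = [gbvs_normalize(gbvs_activation(f, config), config) for f in fmaps]
        channel_maps.append(np.mean(per_map, axis=0))
    combined = np.mean(channel_maps, axis=0)

    big = resize(combined, (out_res, out_res), order=1)
    mask_big = (
        brain_mask
        if brain_mask.shape == (out_res, out_res)
        else resize(brain_mask.astype(float), (out_res, out_res), order=0) > 0.5
    )
    big = np.where(mask_big, big, 0.0)
    peak = big.max()
    if peak <= 0:
        warnings.warn("constant masked image: all-zero saliency map", stacklevel=2)
        return np.zeros_like(big)
    return big / peak


def contour_saliency_score(smap: np.ndarray, boundary: BinaryMask) -> float:
    """Sum of saliency values over the stroke pixels of a boundary mask."""
    if smap.shape != boundary.shape:
        raise ValueError(f"shape mismatch: {smap.shape} vs {boundary.shape}")
    return float(smap[boundary].sum())
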