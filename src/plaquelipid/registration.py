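"""Affine registration of IF images to IR grids and plaque region masks.

Immunofluorescence (IF) images of stained amyloid (a fibril-core probe and
an anti-amyloid antibody for the corona) are registered onto the IR pixel
grid with an affine 2-D transform fitted to user-provided point pairs.
Binary plaque masks are derived from the registered channels with Otsu's
method, a surrounding ring mask is built by dilation, and region mean
spectra are extracted for core / corona / surrounding comparisons.

Point coordinates are (x, y) = (column, row); pixel k covers [k, k+1) with
its center at k + 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk

from .ir import SpectralImage

__all__ = [
    "PointPairSet",
    "AffineTransform2D",
    "RegionMasks",
    "fit_affine",
    "otsu_threshold",
    "otsu_mask",
    "make_region_masks",
    "region_mean_spectrum",
]


@dataclass
class PointPairSet:
    """Matched reference coordinates in source and target images."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source and target must be matching (n, 2) arrays")

    def __len__(self) -> int:
        return self.source.shape[0]


@dataclass
class AffineTransform2D:
    """y = A x + t with invertible linear part A."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))


def fit_affine(pairs: PointPairSet) -> AffineTransform2D:
    """Least-squares affine transform from point pairs.

    Minimizes ``sum || A s + t - g ||^2``; exact for three non-collinear
    pairs.  Raises on fewer than three pairs or collinear geometry.
    """
    if len(pairs) < 3:
        raise ValueError("affine fit needs at least 3 point pairs")
    src = pairs.source
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("source points are collinear; affine fit is degenerate")
    X = np.column_stack([src, np.ones(len(pairs))])
    beta, *_ = np.linalg.lstsq(X, pairs.target, rcond=None)
    return AffineTransform2D(beta[:2].T, beta[2])


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance over a histogram.

    Uses ``nbins`` uniform bins over the observed range; the foreground mask
    convention is ``values >= threshold``.  Raises on constant input.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or np.all(v == v[0]):
        raise ValueError("Otsu threshold undefined for constant input")
    hist, edges = np.histogram(v, bins=nbins)
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))  # split after bin k
    return float(edges[k + 1])


def otsu_mask(values: np.ndarray, nbins: int = 256) -> np.ndarray:
    return np.asarray(values, dtype=float) >= otsu_threshold(values, nbins)


@dataclass
class RegionMasks:
    """Disjoint plaque core, corona and surrounding-ring masks on the IR grid."""

    core: np.ndarray
    corona: np.ndarray
    surrounding_ring: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.core & self.corona) or np.any(
                self.surrounding_ring & (self.core | self.corona)):
            raise ValueError("region masks must be pairwise disjoint")


def _resample_to_grid(channel: np.ndarray, transform: AffineTransform2D,
                      ir_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of an IF channel onto the IR grid.

    ``transform`` maps IF (x, y) pixel coordinates into IR coordinates; each
    IR pixel takes the IF pixel its center falls into (center-point rule).
    Out-of-field pixels are set to the channel minimum.
    """
    h, w = ir_shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    centers = np.column_stack([jj.ravel() + 0.5, ii.ravel() + 0.5])
    src = transform.inverse().apply(centers)
    x = np.floor(src[:, 0]).astype(int)
    y = np.floor(src[:, 1]).astype(int)
    inside = (x >= 0) & (x < channel.shape[1]) & (y >= 0) & (y < channel.shape[0])
    out = np.full(h * w, float(np.min(channel)))
    out[inside] = channel[y[inside], x[inside]]
    return out.reshape(h, w)


def make_region_masks(
    core_channel: np.ndarray,
    corona_channel: np.ndarray,
    transform: AffineTransform2D | None = None,
    ring_width_px: int = 9,
    ir_shape: tuple[int, int] | None = None,
) -> RegionMasks:
    """Derive core / corona / surrounding-ring masks from stain channels.

    The core channel (fibril probe) and corona channel (anti-amyloid
    antibody) are registered onto the IR grid (identity if ``transform`` is
    None and the grids coincide), thresholded with Otsu's method, and a ring
    of ``ring_width_px`` pixels is grown outward from the combined plaque
    mask by dilation (inner edge flush with the plaque boundary).
    """
    if transform is None:
        transform = AffineTransform2D.identity()
        core_reg, corona_reg = core_channel, corona_channel
        if ir_shape is not None and tuple(ir_shape) != core_channel.shape:
            core_reg = _resample_to_grid(core_channel, transform, ir_shape)
            corona_reg = _resample_to_grid(corona_channel, transform, ir_shape)
    else:
        if ir_shape is None:
            raise ValueError("ir_shape required when a transform is given")
        core_reg = _resample_to_grid(core_channel, transform, ir_shape)
        corona_reg = _resample_to_grid(corona_channel, transform, ir_shape)

    core = otsu_mask(core_reg)
    corona = otsu_mask(corona_reg) & ~core
    plaque = core | corona
    if not plaque.any():
        warnings.warn("empty plaque mask; surrounding ring is empty", stacklevel=2)
        ring = np.zeros_like(plaque)
    else:
        ring = dilation(plaque, disk(int(ring_width_px))) & ~plaque
    return RegionMasks(core=core, corona=corona, surrounding_ring=ring)


def region_mean_spectrum(
    image: SpectralImage,
    mask: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Arithmetic mean of all (valid) pixel spectra within a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image grid")
    if valid is not None:
        mask = mask & np.asarray(valid, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    return image.absorbance[mask].mean(axis=0)
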