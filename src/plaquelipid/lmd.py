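"""Whole-slide plaque detection and laser-microdissection shape export.

Whole-slide QCL-IR images are scored tile by tile (64 x 64 px windows with
16 px overlap) by a pluggable scorer, reassembled into a per-pixel
activation map using the maximum over overlapping tiles, binarized at 0.9,
and refined with a fixed morphology cascade (area filter, 15 um dilation,
hole filling, 10 um erosion, area and shape criteria) that leaves
plaque-like objects with a net margin for tissue loss.  Object outlines are
traced to polygons, mapped into microscope-stage coordinates with a
4-parameter (similarity) Helmert transform, and exported as WKT/GeoJSON for
laser microdissection.

The trained segmentation network used in the original workflow is not
redistributable; the scorer is therefore an interface, and a reference
spectral-contrast scorer (amide-I beta-sheet shift, the 1630/1655 band
ratio squashed to [0, 1]) is provided so the full chain runs end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box, mapping, shape as shapely_shape
from shapely.ops import unary_union
from shapely import wkt as shapely_wkt
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, erosion

from .ir import AMIDE_I_1630, AMIDE_I_1655, SpectralImage, _band_absorbance_array

__all__ = [
    "TileSpec",
    "Tile",
    "ActivationMap",
    "MorphParams",
    "HelmertTransform2D",
    "ShapeSet",
    "AmideShiftScorer",
    "tile_wsi",
    "score_tiles",
    "assemble_activation",
    "binarize_activation",
    "morphological_refine",
    "shape_metrics",
    "fit_helmert",
    "shapes_from_mask",
    "export_shapes",
    "read_shapes_wkt",
    "read_shapes_geojson",
    "detect_plaques",
]


@dataclass(frozen=True)
class TileSpec:
    """Tiling of a whole-slide image into overlapping square windows."""

    tile_size: int = 64
    overlap: int = 16

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.tile_size):
            raise ValueError("require 0 <= overlap < tile_size")

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap


@dataclass
class Tile:
    row0: int
    col0: int
    data: np.ndarray  # (tile, tile, n_wavenumbers) or (tile, tile)


def _anchors(extent: int, size: int, stride: int) -> list[int]:
    """Tile anchors at the stride, with the last tile flush to the edge."""
    anchors = list(range(0, extent - size + 1, stride))
    if anchors[-1] + size < extent:
        anchors.append(extent - size)
    return anchors


def tile_wsi(image, spec: TileSpec = TileSpec()) -> list[Tile]:
    """Cut a whole-slide image into overlapping tiles covering every pixel.

    Interior tiles are anchored every ``stride = tile_size - overlap``
    pixels; the final row/column is anchored flush to the image edge (extra
    overlap) rather than padding with synthetic border spectra.
    """
    cube = image.absorbance if isinstance(image, SpectralImage) else np.asarray(image)
    h, w = cube.shape[:2]
    if h < spec.tile_size or w < spec.tile_size:
        raise ValueError(
            f"image {h}x{w} smaller than tile size {spec.tile_size}")
    tiles = []
    for r in _anchors(h, spec.tile_size, spec.stride):
        for c in _anchors(w, spec.tile_size, spec.stride):
            tiles.append(Tile(r, c, cube[r:r + spec.tile_size,
                                         c:c + spec.tile_size]))
    return tiles


@dataclass
class AmideShiftScorer:
    """Reference plaque scorer: amide-I beta-sheet shift contrast.

    Scores each pixel by the baseline-corrected 1630 cm^-1 / 1655 cm^-1
    band-height ratio (beta-sheet-rich amyloid shifts amide I towards
    1630 cm^-1), linearly rescaled so tissue-like ratios map near 0 and
    strongly shifted ratios saturate at 1.
    """

    ratio_lo: float = 0.72
    ratio_hi: float = 0.84
    scorer_id: str = "amide-shift-reference"

    def __call__(self, tile: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
        a1630 = _band_absorbance_array(wavenumbers, tile, AMIDE_I_1630)
        a1655 = _band_absorbance_array(wavenumbers, tile, AMIDE_I_1655)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(a1655 > 1e-6, a1630 / np.maximum(a1655, 1e-300), 0.0)
        return np.clip((ratio - self.ratio_lo) / (self.ratio_hi - self.ratio_lo),
                       0.0, 1.0)


def score_tiles(
    tiles: Sequence[Tile],
    scorer: Callable[[np.ndarray, np.ndarray], np.ndarray],
    wavenumbers: np.ndarray,
) -> list[Tile]:
    """Apply a scorer to each tile, yielding per-pixel activation tiles.

    The scorer maps a tile's spectra to scores in [0, 1]; out-of-range or
    mis-shaped outputs violate the scorer contract and raise.
    """
    out = []
    for t in tiles:
        scores = np.asarray(scorer(t.data, wavenumbers), dtype=float)
        if scores.shape != t.data.shape[:2]:
            raise ValueError("scorer returned scores with wrong shape")
        if np.any(scores < 0) or np.any(scores > 1) or not np.all(np.isfinite(scores)):
            raise ValueError("scorer returned scores outside [0, 1]")
        out.append(Tile(t.row0, t.col0, scores))
    return out


@dataclass
class ActivationMap:
    """Per-pixel plaque score in [0, 1] on the whole-slide grid."""

    scores: np.ndarray
    scorer_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("activation scores must lie in [0, 1]")
        self.scores = s


def assemble_activation(
    tile_activations: Sequence[Tile],
    image_shape: tuple[int, int],
    scorer_id: str = "",
) -> ActivationMap:
    """Reassemble tile scores into a whole-slide activation map.

    Each pixel's score is the maximum over all tiles containing it; a pixel
    covered by no tile is an error.
    """
    h, w = image_shape
    scores = np.full((h, w), -np.inf)
    for t in tile_activations:
        th, tw = t.data.shape
        view = scores[t.row0:t.row0 + th, t.col0:t.col0 + tw]
        np.maximum(view, t.data, out=view)
    if np.any(~np.isfinite(scores)):
        raise ValueError("tiles do not cover the full image")
    return ActivationMap(scores=scores, scorer_id=scorer_id)


def binarize_activation(activation, threshold: float = 0.9) -> np.ndarray:
    """Plaque mask: activation scores >= threshold."""
    scores = activation.scores if isinstance(activation, ActivationMap) else np.asarray(activation)
    return scores >= threshold


@dataclass(frozen=True)
class MorphParams:
    """Parameters of the sequential morphology cascade (metric units)."""

    binarize_threshold: float = 0.9
    min_area_pre: float = 100.0    # um^2
    dilate_radius: float = 15.0    # um
    erode_radius: float = 10.0     # um
    min_area_post: float = 300.0   # um^2
    max_eccentricity: float = 0.95
    min_solidity: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must be in (0, 1)")
        if self.dilate_radius < self.erode_radius:
            raise ValueError("net margin (dilate - erode) must be >= 0")
        if not (0 <= self.max_eccentricity <= 1) or not (0 < self.min_solidity <= 1):
            raise ValueError("eccentricity/solidity thresholds out of range")


def _radius_px(radius_um: float, pixel_size: float) -> int:
    return max(1, int(round(radius_um / pixel_size)))


def _remove_small(mask: np.ndarray, min_area_um2: float, pixel_size: float) -> np.ndarray:
    px_area = pixel_size ** 2
    lab = label(mask, connectivity=2)
    out = np.zeros_like(mask)
    for p in regionprops(lab):
        if p.area * px_area >= min_area_um2:
            out[lab == p.label] = True
    return out


def morphological_refine(
    mask: np.ndarray,
    pixel_size_um: float,
    params: MorphParams = MorphParams(),
) -> np.ndarray:
    """Refine a binarized activation mask into LMD-ready plaque objects.

    Applies, in order: removal of objects below ``min_area_pre``; dilation
    by a disc of ``dilate_radius``; hole filling; erosion by a disc of
    ``erode_radius``; removal of objects below ``min_area_post``; and
    removal of objects failing the eccentricity/solidity criteria.  Metric
    radii are converted to pixels by rounding (minimum 1 px), so the nominal
    net margin of dilate - erode applies in whole pixels.  Components use
    8-connectivity; holes use 4-connectivity.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m.copy()
    m = _remove_small(m, params.min_area_pre, pixel_size_um)
    if m.any():
        m = dilation(m, disk(_radius_px(params.dilate_radius, pixel_size_um)))
        m = ndimage.binary_fill_holes(m)  # default 4-connected structure
        m = erosion(m, disk(_radius_px(params.erode_radius, pixel_size_um)))
    m = _remove_small(m, params.min_area_post, pixel_size_um)
    lab = label(m, connectivity=2)
    out = np.zeros_like(m)
    for p in regionprops(lab):
        if p.eccentricity <= params.max_eccentricity and p.solidity >= params.min_solidity:
            out[lab == p.label] = True
    return out


def shape_metrics(component_mask: np.ndarray, pixel_size_um: float) -> tuple[float, float, float]:
    """(area um^2, eccentricity, solidity) of a single connected component.

    Eccentricity comes from the second-central-moment ellipse model;
    solidity is area over convex-hull area.  A single-pixel component has
    eccentricity 0 and solidity 1.
    """
    m = np.asarray(component_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty component")
    lab = label(m, connectivity=2)
    props = regionprops(lab)
    if len(props) != 1:
        raise ValueError("mask must contain exactly one connected component")
    p = props[0]
    return (float(p.area) * pixel_size_um ** 2, float(p.eccentricity),
            float(p.solidity))


@dataclass
class HelmertTransform2D:
    """4-parameter planar similarity: scale, rotation, translation (um)."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def _alpha(self) -> complex:
        return self.scale * np.exp(1j * self.rotation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 0] + 1j * pts[:, 1]
        zt = self._alpha * z + complex(*self.translation)
        return np.column_stack([zt.real, zt.imag])

    def inverse(self) -> "HelmertTransform2D":
        a = 1.0 / self._alpha
        t = -a * complex(*self.translation)
        return HelmertTransform2D(abs(a), float(np.angle(a)), (t.real, t.imag))

    @classmethod
    def identity(cls) -> "HelmertTransform2D":
        return cls(1.0, 0.0, (0.0, 0.0))


def fit_helmert(pairs) -> HelmertTransform2D:
    """Least-squares 4-parameter similarity transform from point pairs.

    Exact for two distinct pairs; least squares otherwise.  Raises when
    fewer than two pairs are given or the source points coincide.
    """
    src = np.atleast_2d(np.asarray(pairs.source, dtype=float))
    tgt = np.atleast_2d(np.asarray(pairs.target, dtype=float))
    if src.shape[0] < 2:
        raise ValueError("Helmert fit needs at least 2 point pairs")
    s = src[:, 0] + 1j * src[:, 1]
    g = tgt[:, 0] + 1j * tgt[:, 1]
    sc = s - s.mean()
    if np.max(np.abs(sc)) < 1e-12:
        raise ValueError("source points coincide; Helmert fit is degenerate")
    alpha = np.vdot(sc, g - g.mean()) / np.vdot(sc, sc)
    beta = g.mean() - alpha * s.mean()
    return HelmertTransform2D(abs(alpha), float(np.angle(alpha)),
                              (beta.real, beta.imag))


@dataclass
class ShapeSet:
    """Closed polygons with areas in stage (um) coordinates for LMD."""

    polygons: list[Polygon]
    areas: np.ndarray
    source_object_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for poly, area in zip(self.polygons, self.areas):
            if not poly.is_valid or poly.area <= 0:
                raise ValueError("shape polygons must be simple with area > 0")
            if abs(poly.area - area) > 1e-6 * max(1.0, area):
                raise ValueError("stored area inconsistent with polygon geometry")

    def __len__(self) -> int:
        return len(self.polygons)


def shapes_from_mask(
    mask: np.ndarray,
    pixel_size_um: float,
    transform: HelmertTransform2D | None = None,
    min_area_um2: float = 0.0,
) -> ShapeSet:
    """Trace mask components to stage-coordinate polygons.

    Each 8-connected component's outer boundary is traced exactly along the
    pixel edges (union of pixel squares), converted to um with pixel (i, j)
    covering [j, j+1) x [i, i+1) * pixel size, and mapped through the
    Helmert transform into stage coordinates.  Components touching the
    image border are excluded with a warning (their outline is truncated).
    """
    if transform is None:
        transform = HelmertTransform2D.identity()
    m = np.asarray(mask, dtype=bool)
    lab = label(m, connectivity=2)
    polygons: list[Polygon] = []
    areas: list[float] = []
    ids: list[int] = []
    h, w = m.shape
    for p in regionprops(lab):
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            warnings.warn(
                f"component {p.label} touches the image border; excluded",
                stacklevel=2)
            continue
        boxes = [box(j * pixel_size_um, i * pixel_size_um,
                     (j + 1) * pixel_size_um, (i + 1) * pixel_size_um)
                 for i, j in p.coords]
        geom = unary_union(boxes).simplify(0)
        if geom.geom_type != "Polygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        ring = np.asarray(geom.exterior.coords)
        staged = Polygon(transform.apply(ring))
        if staged.area < min_area_um2:
            continue
        polygons.append(staged)
        areas.append(staged.area)
        ids.append(int(p.label))
    return ShapeSet(polygons=polygons, areas=np.asarray(areas), source_object_ids=ids)


def export_shapes(shapes: ShapeSet, path, fmt: str = "wkt") -> None:
    """Write shapes as a WKT-polygon CSV or GeoJSON FeatureCollection."""
    if fmt == "wkt":
        with open(path, "w") as f:
            f.write("id,area_um2,wkt\n")
            for oid, area, poly in zip(shapes.source_object_ids, shapes.areas,
                                       shapes.polygons):
                f.write(f'{oid},{float(area):.10f},"{shapely_wkt.dumps(poly)}"\n')
    elif fmt == "geojson":
        features = [
            {"type": "Feature",
             "properties": {"id": oid, "area_um2": float(area)},
             "geometry": mapping(poly)}
            for oid, area, poly in zip(shapes.source_object_ids, shapes.areas,
                                       shapes.polygons)
        ]
        with open(path, "w") as f:
            json.dump({"type": "FeatureCollection", "features": features}, f)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_shapes_wkt(path) -> ShapeSet:
    import csv

    polygons, areas, ids = [], [], []
    with open(path) as f:
        for row in csv.DictReader(f):
            polygons.append(shapely_wkt.loads(row["wkt"]))
            areas.append(float(row["area_um2"]))
            ids.append(int(row["id"]))
    return ShapeSet(polygons=polygons, areas=np.asarray(areas),
                    source_object_ids=ids)


def read_shapes_geojson(path) -> ShapeSet:
    with open(path) as f:
        data = json.load(f)
    polygons, areas, ids = [], [], []
    for feat in data["features"]:
        polygons.append(shapely_shape(feat["geometry"]))
        areas.append(float(feat["properties"]["area_um2"]))
        ids.append(int(feat["properties"]["id"]))
    return ShapeSet(polygons=polygons, areas=np.asarray(areas),
                    source_object_ids=ids)


def detect_plaques(
    image: SpectralImage,
    tile_spec: TileSpec = TileSpec(),
    scorer: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    params: MorphParams = MorphParams(),
) -> tuple[ActivationMap, np.ndarray]:
    """Full detection chain: tile, score, reassemble, binarize, refine."""
    if scorer is None:
        scorer = AmideShiftScorer()
    tiles = tile_wsi(image, tile_spec)
    activations = score_tiles(tiles, scorer, image.wavenumbers)
    amap = assemble_activation(activations, image.shape,
                               scorer_id=getattr(scorer, "scorer_id", ""))
    mask = binarize_activation(amap, params.binarize_threshold)
    refined = morphological_refine(mask, image.pixel_size, params)
    return amap, refined
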