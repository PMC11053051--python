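"""Labeled 2-D arterial cross-section geometry.

The computational domain is a pixel grid in which every pixel carries one
tissue label: LUMEN (0), HT (1), FI (2), FF (3), NC (4), DC (5) or
EXTERIOR (6).  Pixels are square control volumes of side ``pixel_size``
(mm); pixel ``(row, col)`` is centered at ``x = (col + 0.5) h``,
``y = (row + 0.5) h`` with index (0, 0) at the top-left.

This module builds such grids from synthetic phantoms or from color
segmentation of a VH-IVUS-style image, extracts the lumen-tissue (inner)
and adventitial (outer) interface curves, classifies points against a
curve by the normal-projection rule, and computes the RMSND
plaque-position metric (root-mean-square normal distance of dense-calcium
and necrotic-core pixels from the lumen-tissue interface).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .parameters import (DC, DEFAULT_PIXEL_SIZE_MM, EXTERIOR, FF, FI, HT,
                         LABEL_NAMES, LUMEN, NC, TISSUE_LABELS)

__all__ = [
    "TissueLabelGrid", "InterfaceCurve", "PhantomSpec",
    "GeometryError", "ResolutionError", "ConstructionError",
    "UndefinedMetricError", "SegmentationError",
    "make_circular_phantom", "make_heterogeneous_phantom",
    "extract_boundaries", "classify_point", "rmsnd",
    "segment_image", "render_labels", "DEFAULT_PALETTE",
]


class GeometryError(ValueError):
    """A label grid or interface curve violates a structural invariant."""


class ResolutionError(GeometryError):
    """The requested geometry is unresolvable at the given pixel size."""


class ConstructionError(GeometryError):
    """A phantom specification cannot be realised on the grid."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. no target pixels)."""


class SegmentationError(ValueError):
    """Image input unsuitable for color segmentation."""


#: Reference colors of the VH-IVUS display convention (the source prints
#: color names only, so exact RGB values are a documented package choice):
#: gray = healthy, dark green = fibrous, light green = fibrofatty,
#: red = necrotic core, white = dense calcium.  Lumen and perivascular
#: background are dark; they are told apart by flood fill, not by color.
DEFAULT_PALETTE: Dict[int, Tuple[int, int, int]] = {
    LUMEN: (0, 0, 0),
    HT: (128, 128, 128),
    FI: (0, 100, 0),
    FF: (144, 238, 144),
    NC: (255, 0, 0),
    DC: (255, 255, 255),
    EXTERIOR: (26, 26, 26),
}


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class TissueLabelGrid:
    """Integer tissue label per square pixel plus the pixel size (mm)."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GeometryError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("labels must be integer-coded")
        if not (self.pixel_size > 0):
            raise GeometryError("pixel_size must be positive")

    # -- masks and bookkeeping ------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return (self.labels >= HT) & (self.labels <= DC)

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.labels == LUMEN

    @property
    def n_tissue_pixels(self) -> int:
        return int(self.tissue_mask.sum())

    @property
    def pixel_area(self) -> float:
        """Area of one pixel control volume, mm^2."""
        return self.pixel_size ** 2

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel control volume, cm^2."""
        return (self.pixel_size * 0.1) ** 2

    @property
    def tissue_area(self) -> float:
        """Tissue domain area A = (#tissue pixels) * pixel_size^2, mm^2."""
        return self.n_tissue_pixels * self.pixel_area

    def fractions(self) -> Dict[int, float]:
        """Area fraction of each tissue label, over tissue pixels only."""
        n = self.n_tissue_pixels
        if n == 0:
            raise GeometryError("grid has no tissue pixels")
        return {lab: float((self.labels == lab).sum()) / n
                for lab in TISSUE_LABELS}

    def pixel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 2) array of (x, y) centers in mm for pixels in ``mask``."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        rows, cols = np.nonzero(mask)
        h = self.pixel_size
        return np.column_stack(((cols + 0.5) * h, (rows + 0.5) * h))

    def content_hash(self) -> str:
        digest = hashlib.sha256()
        digest.update(np.ascontiguousarray(self.labels).tobytes())
        digest.update(np.float64(self.pixel_size).tobytes())
        return digest.hexdigest()[:16]

    def validate(self) -> None:
        """Check the structural invariants; raise GeometryError on defect."""
        bad = ~np.isin(self.labels, list(LABEL_NAMES))
        if bad.any():
            raise GeometryError("labels contain unknown codes "
                                f"{np.unique(self.labels[bad])}")
        if self.n_tissue_pixels == 0:
            raise GeometryError("grid has no tissue pixels")
        lumen = self.lumen_mask
        if not lumen.any():
            raise GeometryError("grid has no lumen pixels")
        ncomp = ndimage.label(lumen,
                              structure=_FOUR_CONNECTED)[1]
        if ncomp != 1:
            raise GeometryError(f"lumen must be one 4-connected component, "
                                f"found {ncomp}")
        border = np.zeros(self.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (lumen & border).any():
            raise GeometryError("lumen touches the grid border; it must be "
                                "enclosed by tissue")


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class InterfaceCurve:
    """Ordered closed boundary polyline with outward unit normals.

    ``side`` is ``"inner"`` for the lumen-tissue interface or ``"outer"``
    for the adventitial boundary.  Normals point *out of the tissue*: into
    the lumen for the inner curve, into the perivascular space for the
    outer curve.
    """

    points: np.ndarray       # (N, 2) vertices (x, y) in mm, implicit closure
    normals: np.ndarray      # (N, 2) unit outward normals
    side: str
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("points must be (N, 2)")
        if self.points.shape != self.normals.shape:
            raise GeometryError("points/normals shape mismatch")
        if self.side not in ("inner", "outer"):
            raise GeometryError("side must be 'inner' or 'outer'")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise GeometryError("normals must have unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) -
                           np.dot(y, np.roll(x, -1)))

    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic heterogeneous annular phantom.

    ``mode`` is ``"scattered"`` (labels assigned by a seeded shuffle of
    tissue pixels, hitting the target fractions exactly up to integer
    rounding) or ``"clustered"`` (the DC and NC pixels form a band whose
    inner edge sits ``cluster_offset`` pixel layers away from the
    lumen-tissue interface; offset 0 covers the interface).
    """

    mode: str = "scattered"
    target_fractions: Mapping[int, float] = None  # type: ignore[assignment]
    cluster_offset: int = 0
    seed: int = 0
    lumen_radius: float = 1.5
    wall_thickness: float = 0.5
    pixel_size: float = 2.0e-2

    def __post_init__(self) -> None:
        if self.mode not in ("scattered", "clustered"):
            raise ConstructionError(f"unknown phantom mode {self.mode!r}")
        if self.target_fractions is None:
            object.__setattr__(self, "target_fractions", {HT: 1.0})
        fr = dict(self.target_fractions)
        unknown = set(fr) - set(TISSUE_LABELS)
        if unknown:
            raise ConstructionError(f"fractions reference non-tissue "
                                    f"labels {sorted(unknown)}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-6:
            raise ConstructionError(f"tissue fractions must sum to 1 "
                                    f"(got {total})")
        if any(v < 0 for v in fr.values()):
            raise ConstructionError("fractions must be non-negative")
        if self.cluster_offset < 0:
            raise ConstructionError("cluster_offset must be >= 0")
        object.__setattr__(self, "target_fractions", fr)


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------

def make_circular_phantom(lumen_radius: float, wall_thickness: float,
                          pixel_size: float = DEFAULT_PIXEL_SIZE_MM,
                          label: int = HT, margin: int = 2
                          ) -> TissueLabelGrid:
    """Annular single-label vessel cross-section.

    A pixel is tissue iff its center lies at radius
    ``[lumen_radius, lumen_radius + wall_thickness)`` from the grid
    center; closer pixels are lumen, farther ones exterior.
    """
    if lumen_radius <= 0 or wall_thickness <= 0 or pixel_size <= 0:
        raise GeometryError("radii and pixel size must be positive")
    if label not in TISSUE_LABELS:
        raise GeometryError(f"label {label} is not a tissue code")
    if wall_thickness < 3 * pixel_size:
        raise ResolutionError(
            f"wall thickness {wall_thickness} mm spans fewer than 3 pixels "
            f"at pixel size {pixel_size} mm")
    outer = lumen_radius + wall_thickness
    n = int(np.ceil(2 * outer / pixel_size)) + 2 * margin
    h = pixel_size
    c = n * h / 2.0
    jj, ii = np.mgrid[0:n, 0:n]
    r = np.hypot((ii + 0.5) * h - c, (jj + 0.5) * h - c)
    labels = np.full((n, n), EXTERIOR, dtype=np.int16)
    labels[r < lumen_radius] = LUMEN
    labels[(r >= lumen_radius) & (r < outer)] = label
    grid = TissueLabelGrid(labels, pixel_size)
    grid.validate()
    return grid


def _largest_remainder_counts(fractions: Mapping[int, float],
                              total: int) -> Dict[int, int]:
    labels = sorted(fractions)
    raw = {lab: fractions[lab] * total for lab in labels}
    counts = {lab: int(np.floor(raw[lab])) for lab in labels}
    short = total - sum(counts.values())
    # distribute remaining pixels to the largest fractional remainders
    order = sorted(labels, key=lambda lab: (raw[lab] - counts[lab], -lab),
                   reverse=True)
    for lab in order[:short]:
        counts[lab] += 1
    return counts


def make_heterogeneous_phantom(spec: PhantomSpec) -> TissueLabelGrid:
    """Realise a PhantomSpec on an annular vessel cross-section."""
    grid = make_circular_phantom(spec.lumen_radius, spec.wall_thickness,
                                 spec.pixel_size, label=HT)
    labels = grid.labels.copy()
    tissue = grid.tissue_mask
    n_total = int(tissue.sum())
    counts = _largest_remainder_counts(spec.target_fractions, n_total)
    rng = np.random.default_rng(spec.seed)

    rows, cols = np.nonzero(tissue)          # row-major fixed ordering
    if spec.mode == "scattered":
        perm = rng.permutation(n_total)
        assignment = np.empty(n_total, dtype=np.int16)
        pos = 0
        for lab in sorted(counts):
            assignment[perm[pos:pos + counts[lab]]] = lab
            pos += counts[lab]
        labels[rows, cols] = assignment
    else:
        labels = _assign_clustered(labels, grid, counts,
                                   spec.cluster_offset, rng)

    out = TissueLabelGrid(labels, spec.pixel_size)
    out.validate()
    return out


def _assign_clustered(labels: np.ndarray, grid: TissueLabelGrid,
                      counts: Dict[int, int], offset: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Place the DC and NC pixels as a band at a fixed pixel offset from
    the lumen-tissue interface; scatter the remaining labels outside it."""
    tissue = grid.tissue_mask
    # 4-connected layer distance from the lumen: interface-adjacent tissue
    # pixels have d == 1, the next layer d == 2, ...
    d = ndimage.distance_transform_cdt(~grid.lumen_mask, metric="taxicab")
    d = np.where(tissue, d, 0)
    n_band = counts.get(DC, 0) + counts.get(NC, 0)
    if n_band == 0:
        raise ConstructionError("clustered mode needs DC and/or NC pixels")

    eligible = tissue & (d >= offset + 1)
    if int(eligible.sum()) < n_band:
        raise ConstructionError(
            f"cannot place {n_band} DC/NC pixels at offset {offset}: only "
            f"{int(eligible.sum())} eligible pixels")

    # fill complete layers outward from d = offset + 1; break the last,
    # partial layer by angular position from a seeded starting angle so the
    # band stays contiguous.
    band = np.zeros_like(tissue)
    remaining = n_band
    layer_d = offset + 1
    h = grid.pixel_size
    ny, nx = grid.shape
    cx, cy = nx * h / 2.0, ny * h / 2.0
    while remaining > 0:
        layer = eligible & (d == layer_d)
        m = int(layer.sum())
        if m == 0:
            if not (eligible & (d > layer_d)).any():
                raise ConstructionError("ran out of layers while building "
                                        "the clustered DC/NC band")
            layer_d += 1
            continue
        if m <= remaining:
            band |= layer
            remaining -= m
        else:
            rr, cc = np.nonzero(layer)
            ang = np.arctan2((rr + 0.5) * h - cy, (cc + 0.5) * h - cx)
            start = rng.uniform(-np.pi, np.pi)
            order = np.argsort((ang - start) % (2 * np.pi))
            take = order[:remaining]
            band[rr[take], cc[take]] = True
            remaining = 0
        layer_d += 1

    # DC vs NC inside the band, scattered with the seeded generator
    bi, bj = np.nonzero(band)
    perm = rng.permutation(len(bi))
    n_dc = counts.get(DC, 0)
    labels[bi[perm[:n_dc]], bj[perm[:n_dc]]] = DC
    labels[bi[perm[n_dc:]], bj[perm[n_dc:]]] = NC

    # remaining labels scattered over the rest of the tissue
    rest = tissue & ~band
    ri, rj = np.nonzero(rest)
    perm = rng.permutation(len(ri))
    pos = 0
    for lab in sorted(counts):
        if lab in (DC, NC):
            continue
        k = counts[lab]
        labels[ri[perm[pos:pos + k]], rj[perm[pos:pos + k]]] = lab
        pos += k
    if pos != len(ri):
        raise ConstructionError("label counts do not cover the tissue")
    return labels


# ---------------------------------------------------------------------------
# Boundary extraction and point classification
# ---------------------------------------------------------------------------

def _contour_to_curve(contour: np.ndarray, grid: TissueLabelGrid,
                      side: str) -> InterfaceCurve:
    h = grid.pixel_size
    if not np.allclose(contour[0], contour[-1]):
        raise GeometryError(f"{side} contour is not closed")
    pts_idx = contour[:-1]                       # drop duplicate endpoint
    # contour coordinates are (row, col) with integers at pixel centers
    pts = np.column_stack(((pts_idx[:, 1] + 0.5) * h,
                           (pts_idx[:, 0] + 0.5) * h))
    # counter-clockwise vertex order in the stored (x, y) frame
    x, y = pts[:, 0], pts[:, 1]
    if 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) < 0:
        pts = pts[::-1]
    # normals from the central-difference tangent along the polyline,
    # estimated on a lightly smoothed copy so that the half-pixel
    # staircase of the traced contour does not alias into the normals
    n_pts = len(pts)
    win = min(9, max(1, (n_pts // 8) | 1))
    if win > 1:
        kernel = np.ones(win) / win
        sm = np.column_stack([
            np.convolve(np.concatenate([col[-win:], col, col[:win]]),
                        kernel, mode="same")[win:-win]
            for col in (pts[:, 0], pts[:, 1])])
    else:
        sm = pts
    tang = np.roll(sm, -2, axis=0) - np.roll(sm, 2, axis=0)
    tlen = np.linalg.norm(tang, axis=1)
    tlen[tlen == 0] = 1.0
    tang /= tlen[:, None]
    normals = np.column_stack((tang[:, 1], -tang[:, 0]))
    # orient outward from the tissue by probing the label grid
    probe = pts + 0.75 * h * normals
    jj = np.clip((probe[:, 1] / h - 0.5).round().astype(int),
                 0, grid.shape[0] - 1)
    ii = np.clip((probe[:, 0] / h - 0.5).round().astype(int),
                 0, grid.shape[1] - 1)
    into_tissue = grid.tissue_mask[jj, ii]
    normals[into_tissue] *= -1.0
    return InterfaceCurve(pts, normals, side)


def extract_boundaries(grid: TissueLabelGrid
                       ) -> Tuple[InterfaceCurve, InterfaceCurve]:
    """Trace the lumen-tissue (inner) and adventitial (outer) interfaces.

    Returns ``(inner, outer)`` with counter-clockwise vertex order and unit
    normals pointing out of the tissue.
    """
    grid.validate()
    lumen = grid.lumen_mask.astype(float)
    inner_contours = measure.find_contours(lumen, 0.5)
    if len(inner_contours) != 1:
        raise GeometryError(f"expected one lumen contour, found "
                            f"{len(inner_contours)}")
    body = (grid.tissue_mask | grid.lumen_mask).astype(float)
    outer_contours = measure.find_contours(body, 0.5)
    if len(outer_contours) != 1:
        raise GeometryError(f"expected one outer contour, found "
                            f"{len(outer_contours)}")
    inner = _contour_to_curve(inner_contours[0], grid, "inner")
    outer = _contour_to_curve(outer_contours[0], grid, "outer")
    return inner, outer


def classify_point(curve: InterfaceCurve, p_query) -> str:
    """Classify a point against a boundary curve.

    With ``p`` the vector from the nearest curve vertex to the query point
    and ``n`` that vertex's outward (out-of-tissue) normal, the point is
    ``"inside"`` (tissue side) when ``p . n <= 0`` and ``"outside"``
    otherwise.
    """
    p_query = np.asarray(p_query, dtype=float)
    if not np.all(np.isfinite(p_query)):
        raise ValueError("query point must be finite")
    _, idx = curve.tree().query(p_query)
    rel = p_query - curve.points[idx]
    dot = float(np.dot(rel, curve.normals[idx]))
    return "inside" if dot <= 0.0 else "outside"


def rmsnd(grid: TissueLabelGrid,
          target_labels: Iterable[int] = (DC, NC),
          inner: InterfaceCurve | None = None) -> float:
    """Root-mean-square distance of DC/NC pixel centers from the
    lumen-tissue interface, in mm."""
    target_labels = tuple(target_labels)
    mask = np.isin(grid.labels, target_labels)
    if not mask.any():
        names = [LABEL_NAMES[t] for t in target_labels]
        raise UndefinedMetricError(f"no pixels with labels {names}")
    if inner is None:
        inner, _ = extract_boundaries(grid)
    centers = grid.pixel_centers(mask)
    d, _ = inner.tree().query(centers)
    return float(np.sqrt(np.mean(d ** 2)))


# ---------------------------------------------------------------------------
# Color segmentation
# ---------------------------------------------------------------------------

def render_labels(grid: TissueLabelGrid,
                  palette: Mapping[int, Tuple[int, int, int]] | None = None
                  ) -> np.ndarray:
    """Paint a label grid with palette colors; inverse of segmentation on
    noiseless input."""
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    img = np.zeros(grid.shape + (3,), dtype=np.uint8)
    for lab, color in palette.items():
        img[grid.labels == lab] = color
    return img


def segment_image(image: np.ndarray,
                  palette: Mapping[int, Tuple[int, int, int]] | None = None,
                  k: int | None = None,
                  pixel_size: float = DEFAULT_PIXEL_SIZE_MM,
                  seed: int = 0) -> TissueLabelGrid:
    """Segment an RGB cross-section image into tissue labels.

    Pixels are clustered in RGB space by k-means (k-means++ init, 10
    restarts, seeded); each cluster takes the label of the nearest palette
    reference color.  The perivascular background is then identified by
    flood fill from the image border and the lumen as the enclosed
    non-tissue cavity, so dark lumen and dark background need not differ
    in color.
    """
    from sklearn.cluster import KMeans

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SegmentationError("input must be an RGB (H, W, 3) image")
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    if k is None:
        k = len(palette)
    if k < len(palette):
        raise SegmentationError(f"k = {k} is below the palette size "
                                f"{len(palette)}")
    pixels = image.reshape(-1, 3).astype(float)
    n_colors = len(np.unique(pixels, axis=0))
    k_eff = min(k, n_colors)     # k-means cannot split fewer distinct colors
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=10,
                random_state=seed)
    cluster = km.fit_predict(pixels).reshape(image.shape[:2])

    ref_labels = np.array(sorted(palette))
    ref_colors = np.array([palette[lab] for lab in ref_labels], dtype=float)
    cluster_to_label = np.empty(k_eff, dtype=np.int16)
    for c in range(k_eff):
        dist = np.linalg.norm(ref_colors - km.cluster_centers_[c], axis=1)
        best = np.flatnonzero(np.isclose(dist, dist.min()))
        if len(best) > 1:
            warnings.warn(
                f"cluster centroid {km.cluster_centers_[c]} is equidistant "
                f"to palette entries {ref_labels[best].tolist()}; choosing "
                f"the lowest label code", stacklevel=2)
        cluster_to_label[c] = ref_labels[best[0]]
    labels = cluster_to_label[cluster]

    # flood-fill disambiguation of lumen vs perivascular exterior
    non_tissue = ~np.isin(labels, list(TISSUE_LABELS))
    comp, ncomp = ndimage.label(non_tissue, structure=_FOUR_CONNECTED)
    border_ids = np.unique(np.concatenate([
        comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]]))
    border_ids = border_ids[border_ids != 0]
    exterior = np.isin(comp, border_ids)
    labels = labels.astype(np.int16)
    labels[non_tissue & exterior] = EXTERIOR
    labels[non_tissue & ~exterior] = LUMEN
    return TissueLabelGrid(labels, pixel_size)
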