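"""Cell morphology from F-actin staining.

Segmentation of the cell body, spread area / roundness / volume metrics,
podosome quantitation on the ventral plane, and automated filopodia length
measurement by skeletonization of protrusions.

Roundness is reported as a percentage using the circularity formula
100 * 4 pi A / P^2 (100 for a disk); the ellipse axis-ratio definition is
available as an alternative.  Perimeters are measured on the subpixel
0.5-level contour (with light smoothing) to avoid the staircase bias of
pixel-edge counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology as skmorph

__all__ = [
    "CellMorphology",
    "PodosomeSet",
    "FilopodiaSet",
    "segment_cell",
    "shape_metrics",
    "detect_podosomes",
    "filopodia_lengths",
]


@dataclass
class CellMorphology:
    """Spread area (um^2), roundness (%), volume (um^3) and centroid."""

    area: float
    roundness: float
    volume: float
    centroid: tuple

    def __post_init__(self):
        if not 0 < self.roundness <= 102:   # small overshoot from discretization
            raise ValueError("roundness out of range")
        if self.volume < 0:
            raise ValueError("volume must be non-negative")


@dataclass
class PodosomeSet:
    """Podosome count, per-core areas (um^2) and integrated intensities."""

    count: int
    areas: np.ndarray
    integrated_intensities: np.ndarray

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        self.integrated_intensities = np.asarray(self.integrated_intensities, dtype=float)
        if np.any(self.areas <= 0):
            raise ValueError("podosome areas must be positive")


@dataclass
class FilopodiaSet:
    """Lengths (um) of detected filopodia."""

    lengths: np.ndarray

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("filopodia lengths must be positive")


def segment_cell(factin_zstack: np.ndarray, smooth_sigma: float = 2.0,
                 threshold: float | None = None):
    """Segment the cell body from F-actin intensity.

    Gaussian smoothing, Otsu threshold (or a fixed one), largest connected
    component, hole filling.  The 3D mask applies the same threshold per
    slice; the 2D footprint is the union over z.  If two separate blobs are
    present, the larger is kept with a warning.

    Returns ``(footprint_2d, mask_3d)``.
    """
    stack = np.asarray(factin_zstack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    sm = np.stack([ndimage.gaussian_filter(p, smooth_sigma) for p in stack])
    if threshold is None:
        if np.ptp(sm) == 0:
            raise ValueError("blank stack: cannot segment")
        threshold = filters.threshold_otsu(sm)
    mask3d = sm > threshold
    if not mask3d.any():
        raise ValueError("empty mask after thresholding")
    footprint = mask3d.any(axis=0)
    labels, n = ndimage.label(footprint)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        if sorted(sizes)[-2] > 0.05 * max(sizes):
            warnings.warn("multiple blobs found; keeping the largest")
        footprint = labels == keep
        mask3d = mask3d & footprint[None]
    footprint = ndimage.binary_fill_holes(footprint)
    mask3d = np.stack([ndimage.binary_fill_holes(p) for p in mask3d])
    return footprint, mask3d


def _contour_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Perimeter of the largest 0.5-level contour, lightly smoothed.

    A moving-average smoothing of the contour coordinates removes the
    marching-squares staircase, which otherwise inflates the perimeter of
    curved shapes by several percent.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return 0.0
    contour = max(contours, key=len)
    if smooth_window > 1 and len(contour) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        closed = np.vstack([contour[:-1], contour[:smooth_window]])
        ys = np.convolve(closed[:, 0], kernel, mode="valid")
        xs = np.convolve(closed[:, 1], kernel, mode="valid")
        contour = np.column_stack([ys, xs])
        contour = np.vstack([contour, contour[:1]])
    return float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))


def shape_metrics(footprint: np.ndarray, mask3d: np.ndarray | None = None,
                  pixel_size: float = 0.110, z_step: float = 0.5,
                  roundness_def: str = "circularity") -> CellMorphology:
    """Area, roundness and volume of a segmented cell.

    area = footprint pixel count * pixel_size^2; roundness (%) =
    100 * 4 pi A / P^2 by default (or 100 * minor/major ellipse axis ratio);
    volume = 3D voxel count * pixel_size^2 * z_step.
    """
    fp = np.asarray(footprint, dtype=bool)
    if not fp.any():
        raise ValueError("empty footprint")
    n_px = int(fp.sum())
    area = n_px * pixel_size ** 2
    if roundness_def == "circularity":
        perim_px = _contour_perimeter(fp)
        if perim_px == 0:
            raise ValueError("cannot trace a contour")
        roundness = float(100.0 * 4.0 * np.pi * n_px / perim_px ** 2)
    elif roundness_def == "axis_ratio":
        props = measure.regionprops(fp.astype(int))[0]
        major = props.axis_major_length
        roundness = float(100.0 * props.axis_minor_length / major) if major > 0 else 100.0
    else:
        raise ValueError(f"unknown roundness definition {roundness_def!r}")
    roundness = min(roundness, 102.0)
    if mask3d is not None:
        volume = float(np.asarray(mask3d, dtype=bool).sum()) * pixel_size ** 2 * z_step
    else:
        volume = area * z_step
    cy, cx = ndimage.center_of_mass(fp)
    return CellMorphology(area=area, roundness=roundness, volume=volume,
                          centroid=(cx * pixel_size, cy * pixel_size))


def detect_podosomes(ventral_factin: np.ndarray, raw_image: np.ndarray | None = None,
                     pixel_size: float = 0.110, min_area_um2: float = 0.05,
                     max_area_um2: float = 2.0, min_circularity: float = 0.5,
                     threshold: float | None = None) -> PodosomeSet:
    """Detect podosome actin cores on the ventral plane.

    Threshold (Otsu by default), binarize, and measure connected
    components, keeping dot-like cores with area within
    [min_area_um2, max_area_um2] and circularity >= min_circularity;
    integrated intensity is measured on the raw image.
    """
    img = np.asarray(ventral_factin, dtype=float)
    raw = img if raw_image is None else np.asarray(raw_image, dtype=float)
    if np.ptp(img) == 0:
        return PodosomeSet(0, np.empty(0), np.empty(0))
    thr = filters.threshold_otsu(img) if threshold is None else threshold
    mask = img > thr
    labels, n = ndimage.label(mask)
    areas, intens = [], []
    for region in measure.regionprops(labels, intensity_image=raw):
        a_um2 = region.area * pixel_size ** 2
        if not min_area_um2 <= a_um2 <= max_area_um2:
            continue
        circ = 4 * np.pi * region.area / max(region.perimeter, 1e-9) ** 2
        if circ < min_circularity:
            continue
        areas.append(a_um2)
        intens.append(float(region.image_intensity[region.image].sum()))
    return PodosomeSet(len(areas), np.array(areas), np.array(intens))


def filopodia_lengths(footprint: np.ndarray, pixel_size: float = 0.110,
                      body_radius_px: int = 6, min_length_um: float = 0.5) -> FilopodiaSet:
    """Measure filopodia lengths by skeletonizing protrusions.

    The cell body is the morphological opening of the footprint with a disk
    of ``body_radius_px``; whatever sticks out is skeletonized and each
    connected branch's geodesic length (8-connected, diagonal steps weighted
    sqrt(2)) is reported.  Branches shorter than ``min_length_um`` are
    discarded.  This automates a measurement done by hand in typical
    practice; accuracy is validated against phantoms with known protrusion
    lengths.
    """
    fp = np.asarray(footprint, dtype=bool)
    if not fp.any():
        raise ValueError("empty footprint")
    body = skmorph.opening(fp, skmorph.disk(body_radius_px))
    protrusions = fp & ~body
    if not protrusions.any():
        return FilopodiaSet(np.empty(0))
    skel = skmorph.skeletonize(protrusions)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    lengths = []
    for i in range(1, n + 1):
        pts = np.column_stack(np.nonzero(labels == i))
        if len(pts) < 2:
            continue
        lengths.append(_geodesic_diameter(pts) * pixel_size)
    lengths = [ln for ln in lengths if ln >= min_length_um]
    return FilopodiaSet(np.array(lengths))


def _geodesic_diameter(points: np.ndarray) -> float:
    """Longest shortest-path (in px) within an 8-connected skeleton branch."""
    import heapq

    index = {tuple(p): i for i, p in enumerate(points)}
    adj = [[] for _ in points]
    for i, (y, x) in enumerate(points):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None:
                    adj[i].append((j, np.hypot(dy, dx)))

    def dijkstra(src):
        dist = np.full(len(points), np.inf)
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        return dist

    # double sweep: far end from an arbitrary node, then farthest distance
    d0 = dijkstra(0)
    far = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1 = dijkstra(far)
    return float(np.max(d1[np.isfinite(d1)]))
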