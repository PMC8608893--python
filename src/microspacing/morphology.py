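"""Skeleton/distance-map morphometry of 2-D microglia images.

The measurement chain: despeckle + smooth, threshold (chosen just before the
total skeleton length explodes as the threshold drops into the noise floor),
skeletonize, Euclidean distance transform, then

* thickness — mean distance-map value over skeleton pixels (a half-width
  proxy, reported as-is by convention of the original assay);
* process extraction — somata are distance-map blobs thicker than a soma
  radius, the remaining skeleton is cut at junction pixels into segments
  whose geodesic pixel-step lengths (1 axial, √2 diagonal) are the process
  lengths, each assigned to the nearest soma;
* density — somata per mm² of the imaged field;
* soma-pattern regularity via :func:`microspacing.pointstats.hsi`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, median
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, skeletonize

from .pointstats import PointPattern, hsi

__all__ = [
    "GrayImage",
    "BinaryImage",
    "MorphologyMetrics",
    "preprocess",
    "select_threshold",
    "skeleton_and_distance",
    "mean_thickness",
    "extract_processes",
    "measure",
    "project_max",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale image with physical pixel size (µm/px)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D image")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class BinaryImage:
    mask: np.ndarray
    pixel_size: float


@dataclass(frozen=True)
class MorphologyMetrics:
    mean_thickness: float  # µm
    process_lengths: np.ndarray  # µm
    processes_per_cell: np.ndarray  # count per soma
    avg_process_length: float  # µm
    process_length_per_cell: float  # µm
    density: float  # cells / mm²
    soma_pattern: PointPattern
    hsi: float
    threshold: float


def project_max(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D stack")
    return stack.max(axis=0)


def preprocess(img: GrayImage, gaussian_sigma: float = 0.8) -> GrayImage:
    """Despeckle with a 3×3 median filter, then Gaussian-smooth."""
    med = median(img.pixels, footprint=np.ones((3, 3), dtype=bool))
    if gaussian_sigma > 0:
        out = gaussian(med, sigma=gaussian_sigma, preserve_range=True)
    else:
        out = med.astype(float)
    return GrayImage(out, img.pixel_size)


def _skeleton_length_px(mask: np.ndarray) -> float:
    """Total geodesic length of the skeleton of ``mask``, in pixels."""
    if not mask.any():
        return 0.0
    return _geodesic_lengths(skeletonize(mask), np.ones_like(mask, dtype=int))[1]


def _geodesic_lengths(skel: np.ndarray, labels: np.ndarray) -> tuple[dict, float]:
    """Per-label and total pixel-step geodesic length of a skeleton.

    Adjacent skeleton pixels in the same label contribute 1 (axial) or √2
    (diagonal) per adjacency; isolated pixels contribute 1.
    """
    lab = np.where(skel, labels, 0)
    per: dict[int, float] = {}
    for (dr, dc), w in (((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), _SQRT2), ((1, -1), _SQRT2)):
        a = lab[max(dr, 0) or None : lab.shape[0] - max(-dr, 0) or None,
                max(dc, 0) or None : lab.shape[1] - max(-dc, 0) or None]
        b = lab[max(-dr, 0) or None : lab.shape[0] - max(dr, 0) or None,
                max(-dc, 0) or None : lab.shape[1] - max(dc, 0) or None]
        same = (a > 0) & (a == b)
        if same.any():
            ids, counts = np.unique(a[same], return_counts=True)
            for i, cnt in zip(ids, counts):
                per[int(i)] = per.get(int(i), 0.0) + w * cnt
    # isolated single pixels count as one pixel of length
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    for i, cnt in zip(ids, counts):
        per.setdefault(int(i), float(min(cnt, 1)))
    return per, float(sum(per.values()))


def select_threshold(
    img: GrayImage,
    candidate_thresholds: list[float] | np.ndarray,
    knee_factor: float = 2.0,
    plateau_factor: float = 1.2,
) -> float:
    """Threshold chosen just before the skeleton length explodes.

    Candidates are scanned in descending order.  A knee is a candidate whose
    skeleton length is stable relative to the previous (higher) threshold
    (ratio ≤ ``plateau_factor``) but jumps by more than ``knee_factor`` at
    the next (lower) one — the signature of the threshold dropping from the
    foreground plateau into the noise floor; that stable candidate is
    returned.  If every candidate yields essentially the same skeleton
    (a noise-free two-level image) the smallest candidate is returned
    silently; otherwise, with no plateau-then-explosion found (e.g. pure
    noise, where the length grows steadily), the smallest candidate is
    returned with a warning.
    """
    cand = sorted(set(float(t) for t in candidate_thresholds), reverse=True)
    if len(cand) < 2:
        raise ValueError("need at least 2 candidate thresholds")
    lengths = [_skeleton_length_px(img.pixels >= t) for t in cand]
    for i in range(1, len(cand) - 1):
        prev, cur, nxt = lengths[i - 1], lengths[i], lengths[i + 1]
        if prev <= 0.0 or cur <= 0.0:
            continue
        if cur / prev <= plateau_factor and nxt / cur > knee_factor:
            return cand[i]
    nonzero = [ln for ln in lengths if ln > 0]
    if nonzero and max(nonzero) / min(nonzero) <= plateau_factor and len(nonzero) == len(lengths):
        return cand[-1]  # all skeletons identical — any candidate is fine
    warnings.warn("no skeleton-length knee found; returning smallest candidate", stacklevel=2)
    return cand[-1]


def skeleton_and_distance(binary: BinaryImage) -> tuple[np.ndarray, np.ndarray]:
    """Topology-preserving skeleton and exact Euclidean distance map (px)."""
    mask = np.asarray(binary.mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask), np.zeros(mask.shape)
    skel = skeletonize(mask)
    dist = ndimage.distance_transform_edt(mask)
    return skel, dist


def mean_thickness(skeleton: np.ndarray, distmap: np.ndarray, pixel_size: float) -> float:
    """Mean distance-map value over skeleton pixels, in µm (half-width proxy)."""
    if skeleton.shape != distmap.shape:
        raise ValueError("skeleton and distance map shapes differ")
    if not skeleton.any():
        raise ValueError("empty skeleton: no thickness defined")
    return float(distmap[skeleton.astype(bool)].mean() * pixel_size)


def _junction_mask(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with >= 3 skeleton neighbours (8-connectivity)."""
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), k, mode="constant")
    return skel & (nbrs >= 3)


def extract_processes(
    skeleton: np.ndarray,
    distmap: np.ndarray,
    pixel_size: float,
    soma_min_radius: float = 3.0,
) -> tuple[PointPattern, np.ndarray, np.ndarray]:
    """Somata, per-process lengths (µm) and per-soma process counts.

    Somata are connected components of the distance-map core
    ``distmap >= soma_min_radius`` (µm); their centroids, in µm image
    coordinates (x = column, y = row), form the returned soma pattern.  The
    full soma extent is recovered by dilating the core by the same radius
    (a morphological opening of the mask), so the skeleton stub crossing the
    soma rim is not counted as process.  Skeleton pixels outside somata are
    cut at junction pixels; each remaining 8-connected segment is one
    process, its geodesic length in µm, assigned to the soma whose centroid
    is nearest.
    """
    skel = skeleton.astype(bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    r_px = soma_min_radius / pixel_size
    soma_mask = distmap >= r_px
    soma_labels = label(soma_mask, connectivity=2)
    props = regionprops(soma_labels)
    if not props:
        raise ValueError("no cells: no region thicker than soma_min_radius")
    centroids_px = np.array([p.centroid for p in props])  # (row, col)
    centroids_xy = centroids_px[:, ::-1] * pixel_size

    h, w = skel.shape
    window = (0.0, 0.0, w * pixel_size, h * pixel_size)
    somata = PointPattern(np.clip(centroids_xy, 0, [window[2], window[3]]), window)

    soma_extent = dilation(soma_mask, disk(int(np.ceil(r_px))))
    proc_skel = skel & ~soma_extent
    proc_skel = proc_skel & ~_junction_mask(skel)
    seg_labels = label(proc_skel, connectivity=2)
    counts = np.zeros(len(props), dtype=int)
    lengths: list[float] = []
    if seg_labels.max() > 0:
        per, _ = _geodesic_lengths(proc_skel, seg_labels)
        for p in regionprops(seg_labels):
            seg_xy = np.array(p.centroid)[::-1] * pixel_size
            owner = int(np.argmin(np.sum((centroids_xy - seg_xy) ** 2, axis=1)))
            counts[owner] += 1
            lengths.append(per.get(p.label, 1.0) * pixel_size)
    return somata, np.asarray(lengths), counts


def measure(
    img: GrayImage,
    threshold: float | None = None,
    candidate_thresholds: np.ndarray | None = None,
    soma_min_radius: float = 3.0,
    hsi_seed: int = 0,
) -> MorphologyMetrics:
    """Full measurement chain on one image.

    ``threshold=None`` triggers automatic selection over
    ``candidate_thresholds`` (default: descending integer scan over the
    intensity range) using the skeleton-explosion criterion.
    """
    pre = preprocess(img)
    if threshold is None:
        if candidate_thresholds is None:
            lo = max(1.0, float(pre.pixels.min()))
            hi = float(pre.pixels.max())
            candidate_thresholds = np.arange(np.floor(hi), lo - 1, -1.0)
        threshold = select_threshold(pre, candidate_thresholds)
    binary = BinaryImage(pre.pixels >= threshold, img.pixel_size)
    skel, dist = skeleton_and_distance(binary)
    thick = mean_thickness(skel, dist, img.pixel_size)
    somata, lengths, counts = extract_processes(skel, dist, img.pixel_size, soma_min_radius)
    area_mm2 = somata.area / 1e6
    pat_hsi = hsi(somata, seed=hsi_seed).hsi if somata.n >= 2 else float("nan")
    return MorphologyMetrics(
        mean_thickness=thick,
        process_lengths=lengths,
        processes_per_cell=counts,
        avg_process_length=float(lengths.mean()) if lengths.size else 0.0,
        process_length_per_cell=float(lengths.sum() / somata.n),
        density=somata.n / area_mm2,
        soma_pattern=somata,
        hsi=pat_hsi,
        threshold=float(threshold),
    )
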