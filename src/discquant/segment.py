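"""Segmentation of clones, apoptotic regions, puncta and nuclei.

All operators share one scheme: anisotropy-aware Gaussian smoothing (sigma
given in µm, converted to voxels per axis), an automatic Otsu threshold
computed from the voxels inside the analysis ROI only, and 3D connected
components with 26-connectivity.  The threshold method can be overridden
with a fixed absolute value or an intensity percentile, since the automatic
choice is a convention, not a measurement.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .core import ImageStack, LabelMask, SpotSet

logger = logging.getLogger(__name__)

#: fallback cell diameter (µm) when nuclei segmentation finds too few cells
DEFAULT_CELL_DIAMETER = 5.0


def _sigma_voxels(sigma_um: float, voxel_size: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(sigma_um / v for v in voxel_size)


def _threshold_in_roi(
    values: np.ndarray,
    method: str = "otsu",
    fixed: float | None = None,
    percentile: float = 99.0,
) -> float | None:
    """Threshold from ROI voxel intensities; None signals a flat image."""
    if fixed is not None:
        return float(fixed)
    if values.size == 0:
        raise ValueError("ROI is empty: no voxels to threshold")
    if np.ptp(values) == 0:
        return None
    if method == "otsu":
        return float(threshold_otsu(values))
    if method == "percentile":
        return float(np.percentile(values, percentile))
    raise ValueError(f"unknown threshold method {method!r}")


def _segment_channel(
    stack: ImageStack,
    role: str,
    roi: LabelMask,
    smooth_sigma: float,
    threshold: float | None,
    threshold_method: str,
) -> np.ndarray:
    """Smoothed, ROI-thresholded binary mask for one channel."""
    img = stack.channel(role).astype(np.float64)
    roi_mask = roi.foreground
    if roi_mask.shape != img.shape:
        raise ValueError("ROI grid does not match the stack")
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=_sigma_voxels(smooth_sigma, stack.voxel_size))
    thr = _threshold_in_roi(img[roi_mask], method=threshold_method, fixed=threshold)
    if thr is None:  # flat channel: nothing to segment
        return np.zeros(img.shape, dtype=bool)
    logger.info("threshold for %s: %.4g", role, thr)
    return (img > thr) & roi_mask


def segment_patches(
    stack: ImageStack,
    roi: LabelMask,
    min_volume: float = 0.0,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
    threshold_method: str = "otsu",
) -> LabelMask:
    """Segment GFP-positive clone patches inside the pouch ROI.

    Pipeline: Gaussian smoothing (``smooth_sigma`` µm, per-axis), Otsu
    threshold over ROI voxels, 26-connected 3D components, removal of
    components below ``min_volume`` µm³, contiguous relabeling.  Voxels
    outside the ROI are background.
    """
    binary = _segment_channel(stack, "gfp", roi, smooth_sigma, threshold, threshold_method)
    labels = cc_label(binary, connectivity=3)
    if min_volume > 0 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        min_vox = min_volume / stack.voxel_volume
        kill = np.flatnonzero(sizes < min_vox)
        labels[np.isin(labels, kill[kill > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels=labels.astype(np.int32), voxel_size=stack.voxel_size)


def segment_death(
    stack: ImageStack,
    roi: LabelMask,
    smooth_sigma: float = 0.5,
    threshold: float | None = None,
    threshold_method: str = "otsu",
) -> LabelMask:
    """Binary mask of apoptosis-marker-positive (dcp1) voxels in the ROI.

    The default smoothing is finer than for clone patches (0.5 µm vs 1 µm)
    because apoptotic puncta are nuclear-scale objects; heavier smoothing
    systematically inflates their thresholded volume.
    """
    binary = _segment_channel(stack, "death", roi, smooth_sigma, threshold, threshold_method)
    return LabelMask(labels=binary.astype(np.int32), voxel_size=stack.voxel_size)


def detect_speckles(
    stack: ImageStack,
    role: str = "stain2",
    diameter_range: tuple[float, float] = (0.8, 3.0),
    threshold: float = 0.1,
    n_scales: int = 4,
    axial_elongation: float = 3.0,
) -> SpotSet:
    """Detect diffraction-limited puncta (e.g. FK2 ubiquitin speckles).

    Multiscale scale-normalized Laplacian-of-Gaussian detection over the
    physical diameter range, run per z-section; candidate maxima are
    de-duplicated in 3D, discarding the weaker of any two spots closer than
    the minimum diameter (axial distances are divided by ``axial_elongation``
    first, since the confocal point-spread function — and hence one
    physical punctum — extends ~3× further along z than in-plane).
    Intensities are rescaled to [0, 1] before filtering so ``threshold`` is
    a relative response.
    """
    d_min, d_max = diameter_range
    if not (0 < d_min < d_max):
        raise ValueError("diameter_range must be positive with min < max")
    img = stack.channel(role).astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return SpotSet(coords=np.empty((0, 3)), response=np.empty(0))
    img = (img - lo) / (hi - lo)
    dz, dy, dx = stack.voxel_size
    if abs(dy - dx) > 1e-9:
        raise ValueError("speckle detection assumes square in-plane pixels")
    # blob radius r relates to LoG scale as sigma = r / sqrt(2)
    sigmas_um = np.linspace(d_min / 2, d_max / 2, n_scales) / np.sqrt(2.0)
    min_dist_px = max(1, int(round(d_min / dx)))

    cand: list[tuple[float, float, float, float]] = []
    for z in range(img.shape[0]):
        sl = img[z]
        resp = np.zeros(sl.shape)
        for s_um in sigmas_um:
            # sub-pixel LoG kernels are numerically unstable; clamp at 1 px
            s_px = max(s_um / dx, 1.0)
            resp = np.maximum(resp, -(s_px**2) * ndi.gaussian_laplace(sl, s_px))
        peaks = peak_local_max(resp, min_distance=min_dist_px, threshold_abs=threshold)
        for y, x in peaks:
            cand.append((resp[y, x], z * dz, y * dy, x * dx))

    if not cand:
        return SpotSet(coords=np.empty((0, 3)), response=np.empty(0))
    cand.sort(reverse=True)
    pts = np.array([c[1:] for c in cand])
    resp = np.array([c[0] for c in cand])
    # greedy 3D de-duplication, strongest spot wins; compress z for the PSF
    pts_metric = pts / np.array([axial_elongation, 1.0, 1.0])
    tree = cKDTree(pts_metric)
    alive = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        if not alive[i]:
            continue
        for j in tree.query_ball_point(pts_metric[i], d_min):
            if j != i and resp[j] <= resp[i]:
                alive[j] = False
    return SpotSet(coords=pts[alive], response=resp[alive])


def estimate_cell_diameter(
    stack: ImageStack,
    default: float = DEFAULT_CELL_DIAMETER,
    band_halfwidth: int = 2,
    smooth_sigma: float = 0.5,
    min_nuclei: int = 20,
) -> float:
    """Median nuclear cross-section diameter (µm) from the nuclei channel.

    Supplies the physical unit for the two-cell-diameter border band.
    Nuclei are segmented on a central band of z-sections (smooth → Otsu →
    watershed split of touching nuclei); the estimate is the median
    equivalent-circle diameter of the nuclear cross-sections.  When fewer
    than ``min_nuclei`` cross-sections are found, the configured default is
    returned with a warning.
    """
    img = stack.channel("nuclei").astype(np.float64)
    dz, dy, dx = stack.voxel_size
    z0 = img.shape[0] // 2
    zs = range(max(0, z0 - band_halfwidth), min(img.shape[0], z0 + band_halfwidth + 1))
    diameters: list[float] = []
    for z in zs:
        sl = ndi.gaussian_filter(img[z], sigma=smooth_sigma / dx)
        if np.ptp(sl) == 0:
            continue
        binary = sl > threshold_otsu(sl)
        if not binary.any():
            continue
        dist = ndi.distance_transform_edt(binary, sampling=(dy, dx))
        peaks = peak_local_max(
            dist, min_distance=max(1, int(round(1.5 / dx))), labels=binary
        )
        if len(peaks) == 0:
            continue
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        ws = watershed(-dist, markers, mask=binary)
        for rp in regionprops(ws):
            # drop sub-cellular fragments: at least 4 px and 2 µm²
            if rp.area >= 4 and rp.area * dy * dx >= 2.0:
                diameters.append(rp.equivalent_diameter_area * dx)
    if len(diameters) < min_nuclei:
        logger.warning(
            "only %d nuclear cross-sections found (< %d); falling back to "
            "default cell diameter %.2f µm",
            len(diameters),
            min_nuclei,
            default,
        )
        return float(default)
    return float(np.median(diameters))
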