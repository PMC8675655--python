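"""Disc-level readouts: coverage, death density, intensity ratios, speckles.

All metrics are restricted to the pouch region of interest and aggregated
over the full volume (means over all mask voxels across z-sections, not
maximum projections), consistent with the volume-normalized death readout.
No background subtraction is applied by default — intensities are reported
raw — so ratio metrics are sensitive to additive offsets (multiplying a
channel by a positive constant leaves every ratio unchanged; adding a
constant does not).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import CompartmentMasks, ImageStack, LabelMask, SpotSet
from .territories import BORDER, CENTER, TerritoryMap


def pouch_coverage(patches: LabelMask, pouch: LabelMask) -> float:
    """Percentage of pouch volume occupied by GFP-positive clone voxels."""
    if patches.labels.shape != pouch.labels.shape:
        raise ValueError("patch and pouch masks must share one grid")
    pouch_vox = pouch.foreground
    n_pouch = int(pouch_vox.sum())
    if n_pouch == 0:
        raise ValueError("pouch mask is empty")
    n_in = int((patches.foreground & pouch_vox).sum())
    return 100.0 * n_in / n_pouch


def death_density(
    death: LabelMask, tmap: TerritoryMap, roi: LabelMask | None = None
) -> dict[str, float]:
    """Percent of each territory's volume that is apoptosis-marker positive.

    Returns ``{"border": %, "center": %, "exterior_wt": %}``.  The wild-type
    exterior is taken within ``roi`` (the pouch) when given, excluding patch
    voxels.  An empty territory yields NaN — such discs are excluded from
    downstream paired tests.
    """
    if death.labels.shape != tmap.territory.shape:
        raise ValueError("death mask and territory map must share one grid")
    death_vox = death.foreground
    regions = {
        "border": tmap.mask(BORDER),
        "center": tmap.mask(CENTER),
    }
    ext = tmap.territory == 0
    if roi is not None:
        ext = ext & roi.foreground
    regions["exterior_wt"] = ext
    out = {}
    for name, region in regions.items():
        n = int(region.sum())
        out[name] = float("nan") if n == 0 else 100.0 * int((death_vox & region).sum()) / n
    return out


def mean_intensity(stack: ImageStack, role: str, mask: LabelMask | np.ndarray) -> float:
    """Arithmetic mean intensity of one channel over a mask, across all z."""
    img = stack.channel(role)
    m = mask.foreground if isinstance(mask, LabelMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ValueError("mask grid does not match the stack")
    if not m.any():
        raise ValueError("mask is empty")
    return float(img[m].mean())


def pa_ratio(stack: ImageStack, role: str, comps: CompartmentMasks) -> float:
    """Posterior/anterior mean-intensity ratio of one channel."""
    mean_a = mean_intensity(stack, role, comps.anterior)
    mean_p = mean_intensity(stack, role, comps.posterior)
    if mean_a == 0:
        raise ValueError("degenerate anterior signal (mean intensity 0)")
    return mean_p / mean_a


def relative_patch_intensity(
    stack: ImageStack, role: str, patches: LabelMask, roi: LabelMask
) -> float:
    """Mean intensity in clone patches relative to surrounding wild-type ROI."""
    patch_vox = patches.foreground & roi.foreground
    wt_vox = roi.foreground & ~patches.foreground
    if not patch_vox.any():
        raise ValueError("no patch voxels inside the ROI")
    if not wt_vox.any():
        raise ValueError("no wild-type voxels inside the ROI")
    mean_wt = mean_intensity(stack, role, wt_vox)
    if mean_wt == 0:
        raise ValueError("degenerate wild-type signal (mean intensity 0)")
    return mean_intensity(stack, role, patch_vox) / mean_wt


def speckle_density(spots: SpotSet, mask: LabelMask) -> float:
    """Speckle count per 1000 µm³ of mask volume."""
    vol = mask.volume()
    if vol == 0:
        raise ValueError("mask is empty")
    if len(spots) == 0:
        return 0.0
    vs = np.asarray(mask.voxel_size)
    vox = np.round(spots.coords / vs).astype(int)
    shape = np.asarray(mask.labels.shape)
    vox = np.clip(vox, 0, shape - 1)
    inside = mask.labels[vox[:, 0], vox[:, 1], vox[:, 2]] > 0
    return float(inside.sum()) / vol * 1000.0


def subtract_background(stack: ImageStack, role: str, radius_um: float = 10.0) -> ImageStack:
    """Return a stack with a per-slice background estimate removed.

    The background of each z-section is estimated by a grayscale morphological
    opening with a disk of ``radius_um`` (a rolling-ball-style estimate that
    preserves features smaller than the ball) and subtracted.  Off by default
    throughout the pipelines: ratio metrics are offset-sensitive, and the
    raw-intensity convention is the primary readout.
    """
    img = stack.channel(role).astype(np.float64)
    dz, dy, dx = stack.voxel_size
    ry, rx = max(1, int(round(radius_um / dy))), max(1, int(round(radius_um / dx)))
    yy, xx = np.ogrid[-ry : ry + 1, -rx : rx + 1]
    footprint = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        background = ndi.grey_opening(img[z], footprint=footprint)
        out[z] = img[z] - background
    data = stack.data.astype(np.float64).copy()
    data[stack.channel_map[role]] = np.clip(out, 0.0, None)
    return ImageStack(data=data, voxel_size=stack.voxel_size, channel_map=dict(stack.channel_map))


def midline_compartments(pouch: LabelMask) -> CompartmentMasks:
    """Split a pouch ROI into anterior/posterior halves at its x midline.

    Matches the generator's compartment convention (posterior = right half);
    real discs should use user-supplied compartment masks instead.
    """
    fg = pouch.foreground
    if not fg.any():
        raise ValueError("pouch mask is empty")
    xs = np.where(fg.any(axis=(0, 1)))[0]
    x_mid = 0.5 * (xs[0] + xs[-1])
    cols = np.arange(fg.shape[2])
    posterior = fg & (cols >= x_mid)[None, None, :]
    anterior = fg & ~(cols >= x_mid)[None, None, :]
    return CompartmentMasks(anterior=anterior, posterior=posterior)
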