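"""Decompose GFP-marked clone patches into border and center territories.

Cell competition kills loser cells preferentially where they touch winner
neighbors, so every death readout is resolved into two clone territories:
the *border* — all clone voxels within a band of ``n_cell_diameters`` (by
default two) cell diameters of the clone perimeter — and the *center*, the
remainder.  The band width is physical (µm): ``n_cell_diameters ×
cell_diameter``.

The distance to the perimeter is computed per z-section (2D, with the true
in-plane spacing), matching section-wise macro processing and avoiding
anisotropy artifacts at the typical 1 µm z-step; a 3D mode is available via
``mode="3d"``.  Each labeled patch is decomposed independently — adjacent
patches never merge borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import LabelMask

#: territory codes in a TerritoryMap grid
EXTERIOR_WT = 0
BORDER = 1
CENTER = 2

TERRITORY_NAMES = {EXTERIOR_WT: "exterior_wt", BORDER: "border", CENTER: "center"}


@dataclass
class TerritoryMap:
    """Categorical voxel grid partitioning clone voxels into border/center.

    ``territory`` holds 0 (exterior wild-type), 1 (border) or 2 (center);
    border ∪ center equals the source patch voxels exactly.
    """

    territory: np.ndarray
    band_width: float
    voxel_size: tuple[float, float, float]
    patch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.territory = np.asarray(self.territory)
        if self.territory.ndim != 3:
            raise ValueError("territory grid must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def mask(self, code: int) -> np.ndarray:
        return self.territory == code


def decompose_border_center(
    patches: LabelMask,
    cell_diameter: float,
    n_cell_diameters: float = 2.0,
    mode: str = "2d",
) -> TerritoryMap:
    """Split each labeled patch into a perimeter band and a center.

    Parameters
    ----------
    patches
        Labeled clone mask (0 = wild-type background).
    cell_diameter
        Cell diameter in µm; sets the physical unit of the band.
    n_cell_diameters
        Band width in cell diameters (default 2).
    mode
        ``"2d"`` (default): Euclidean distance to the patch perimeter is
        computed within each z-section.  ``"3d"``: full anisotropic 3D
        distance transform.

    Returns
    -------
    TerritoryMap
        Border voxels have in-plane distance to the patch complement
        <= band width; center voxels lie deeper.  Patches thinner than the
        band have empty centers.
    """
    if cell_diameter <= 0:
        raise ValueError("cell_diameter must be positive")
    if mode not in ("2d", "3d"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = patches.labels
    if not (labels > 0).any():
        raise ValueError("no patch to decompose")
    band = float(n_cell_diameters) * float(cell_diameter)
    dz, dy, dx = patches.voxel_size

    territory = np.zeros(labels.shape, dtype=np.int8)
    objects = ndi.find_objects(labels)
    # pad each bounding box by the band so the distance transform sees the
    # surrounding complement (including any touching neighbor patch)
    margins = (
        0 if mode == "2d" else int(np.ceil(band / dz)) + 1,
        int(np.ceil(band / dy)) + 1,
        int(np.ceil(band / dx)) + 1,
    )
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl = tuple(
            slice(max(0, s.start - m), min(dim, s.stop + m))
            for s, m, dim in zip(sl, margins, labels.shape)
        )
        m = labels[sl] == lab
        if mode == "2d":
            dist = np.zeros(m.shape, dtype=np.float64)
            for z in range(m.shape[0]):
                if m[z].any():
                    dist[z] = ndi.distance_transform_edt(m[z], sampling=(dy, dx))
        else:
            dist = ndi.distance_transform_edt(m, sampling=(dz, dy, dx))
        sub = territory[sl]
        sub[m & (dist <= band)] = BORDER
        sub[m & (dist > band)] = CENTER
        territory[sl] = sub

    return TerritoryMap(
        territory=territory,
        band_width=band,
        voxel_size=patches.voxel_size,
        patch_labels=labels,
    )


def territory_volumes(tmap: TerritoryMap) -> dict[str, float]:
    """Border and center volumes in µm³ (voxel counts × voxel volume)."""
    vv = tmap.voxel_volume
    return {
        "border": float(np.count_nonzero(tmap.territory == BORDER)) * vv,
        "center": float(np.count_nonzero(tmap.territory == CENTER)) * vv,
    }
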