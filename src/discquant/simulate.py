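"""Synthetic wing-disc image generator with exact ground truth.

Emulates the image data the quantification pipeline was designed for: an
ellipsoidal pouch inside a confocal z-stack (1 µm z-step), GFP-positive
clone patches grown as unions of overlapping spheres to a target coverage
fraction, apoptosis-marker (dcp1-like) blobs occupying configured volume
fractions of the border, center and wild-type territories, a reporter
channel whose posterior compartment is a configurable fold brighter than
the anterior, diffraction-limited speckles at a configurable density, and a
dense nuclei channel.  Intensities follow ``signal·mask + background +
Gaussian noise`` (clipped at zero) — no point-spread-function optics or
autofluorescence gradients are modeled.

Every realized quantity stored in :class:`GroundTruth` is derived by voxel
counting on the stored masks, so the generator doubles as a recovery oracle
for the full segmentation → territories → quantification chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ImageStack, LabelMask
from .territories import BORDER, CENTER, TerritoryMap, decompose_border_center

ALL_CHANNELS = ("nuclei", "gfp", "stain", "stain2", "death")


@dataclass
class SimConfig:
    """Study-condition parameters of one synthetic disc.

    Geometry is physical (µm): ``pouch_semiaxes``/``pouch_center`` define the
    ellipsoidal pouch, ``voxel_size`` the grid spacing (dz is 1 µm as in the
    acquisition protocol; the in-plane pixel size is a free parameter).
    ``death_rate_*`` are the fractions of each territory's volume that are
    apoptosis-marker positive; ``pa_fold_change`` the true posterior/anterior
    reporter intensity ratio; ``speckle_density`` is per 1000 µm³ of pouch.
    ``channels`` selects which channels are rendered (all by default).
    """

    shape: tuple[int, int, int] = (16, 160, 160)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pouch_semiaxes: tuple[float, float, float] = (7.0, 62.0, 72.0)
    pouch_center: tuple[float, float, float] | None = None  # default: grid center
    n_patches: int = 3
    target_coverage: float = 0.30
    cell_diameter: float = 5.0
    death_rate_border: float = 0.10
    death_rate_center: float = 0.05
    death_rate_wt: float = 0.02
    pa_fold_change: float = 1.8
    speckle_density: float = 5.0
    background_level: float = 20.0
    signal_level: float = 100.0
    noise_sd: float = 5.0
    n_cell_diameters: float = 2.0
    seed: int = 0
    channels: tuple[str, ...] = ("nuclei", "gfp", "stain", "death")

    def __post_init__(self) -> None:
        for name in ("death_rate_border", "death_rate_center", "death_rate_wt", "target_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.pa_fold_change <= 0:
            raise ValueError("pa_fold_change must be > 0")
        if self.speckle_density < 0:
            raise ValueError("speckle_density must be >= 0")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """The generator's true masks and realized parameters.

    Realized quantities are exact voxel counts on the stored masks — the
    oracle every recovery test compares against.
    """

    pouch_mask: LabelMask
    patch_mask: LabelMask
    territory_map: TerritoryMap | None
    death_mask: LabelMask
    speckle_coords: np.ndarray
    realized_coverage: float  # percent of pouch volume
    realized_death_density: dict[str, float]  # percent per territory
    true_pa_ratio: float
    cell_diameter: float
    seed: int = 0
    config: SimConfig | None = None


def _ellipsoid(shape, voxel_size, center_um, semiaxes_um) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(shape, voxel_size)], indexing="ij"
    )
    cz, cy, cx = center_um
    az, ay, ax = semiaxes_um
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _ball_offsets(radius_um: float, voxel_size) -> np.ndarray:
    """Voxel offsets of a physical ball around the origin, sorted inside-out."""
    dz, dy, dx = voxel_size
    nz, ny, nx = (int(np.floor(radius_um / v)) for v in voxel_size)
    oz, oy, ox = np.meshgrid(
        np.arange(-nz, nz + 1), np.arange(-ny, ny + 1), np.arange(-nx, nx + 1), indexing="ij"
    )
    d2 = (oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2
    inside = d2 <= radius_um**2
    offs = np.stack([oz[inside], oy[inside], ox[inside]], axis=1)
    return offs[np.argsort(d2[inside], kind="stable")]


def _stamp_targets(center, offsets, shape) -> np.ndarray:
    pts = offsets + np.asarray(center)
    ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    return pts[ok]


def _disk_offsets(radius_um: float, voxel_size_yx) -> np.ndarray:
    """In-plane pixel offsets of a disk, sorted inside-out."""
    dy, dx = voxel_size_yx
    ny, nx = int(np.floor(radius_um / dy)), int(np.floor(radius_um / dx))
    oy, ox = np.meshgrid(np.arange(-ny, ny + 1), np.arange(-nx, nx + 1), indexing="ij")
    d2 = (oy * dy) ** 2 + (ox * dx) ** 2
    inside = d2 <= radius_um**2
    offs = np.stack([oy[inside], ox[inside]], axis=1)
    return offs[np.argsort(d2[inside], kind="stable")]


def _grow_patch_columns(
    rng: np.random.Generator,
    pouch: np.ndarray,
    target_vox: int,
    n_seeds: int,
    disk_radius_um: float,
    seed_min_sep_um: float,
    voxel_size,
    max_stall: int = 2000,
) -> np.ndarray:
    """Grow clone patches as 2D blobby footprints extruded through the pouch.

    Clones span the full epithelial thickness, so each patch is a union of
    in-plane disks; its 3D mask is the footprint intersected with the pouch.
    Growth stops when the volumetric voxel count reaches ``target_vox`` (the
    final disk is trimmed inside-out, leaving at most one column of
    overshoot).  Returns a 3D int32 label grid.
    """
    shape3d = pouch.shape
    if target_vox <= 0:
        return np.zeros(shape3d, dtype=np.int32)
    depth = pouch.sum(axis=0)  # pouch thickness per (y, x) column
    allowed = depth > 0
    n_avail = int(depth.sum())
    if target_vox > n_avail:
        raise ValueError(
            f"target_coverage unreachable: requested {target_vox} voxels but the "
            f"pouch has {n_avail}"
        )
    if n_seeds < 1:
        raise ValueError("target_coverage > 0 requires n_patches >= 1")
    dy, dx = voxel_size[1], voxel_size[2]
    disk = _disk_offsets(disk_radius_um, (dy, dx))
    allowed_idx = np.argwhere(allowed)
    vs2 = np.array([dy, dx])

    centers: list[np.ndarray] = []
    for _ in range(200 * n_seeds):
        if len(centers) == n_seeds:
            break
        c = allowed_idx[rng.integers(len(allowed_idx))]
        if centers and (np.linalg.norm((np.array(centers) - c) * vs2, axis=1) < seed_min_sep_um).any():
            continue
        centers.append(c)
    while len(centers) < n_seeds:
        centers.append(allowed_idx[rng.integers(len(allowed_idx))])

    fp = np.zeros(depth.shape, dtype=np.int32)
    count = 0
    label_pixels: list[list[np.ndarray]] = [[] for _ in range(n_seeds)]

    def stamp(lab: int, center: np.ndarray) -> int:
        nonlocal count
        pts = disk + center
        ok = np.all((pts >= 0) & (pts < np.asarray(depth.shape)), axis=1)
        pts = pts[ok]
        ok = allowed[pts[:, 0], pts[:, 1]] & (fp[pts[:, 0], pts[:, 1]] == 0)
        pts = pts[ok]  # still inside-out sorted
        if len(pts) == 0:
            return 0
        room = target_vox - count
        cum = np.cumsum(depth[pts[:, 0], pts[:, 1]])
        if cum[-1] > room:
            pts = pts[: int(np.searchsorted(cum, room)) + 1]
        fp[pts[:, 0], pts[:, 1]] = lab
        added = int(depth[pts[:, 0], pts[:, 1]].sum())
        count += added
        label_pixels[lab - 1].append(pts)
        return added

    for i, c in enumerate(centers):
        if count >= target_vox:
            break
        stamp(i + 1, c)
    stall = 0
    while count < target_vox and stall < max_stall:
        lab = int(rng.integers(n_seeds)) + 1
        chunks = label_pixels[lab - 1]
        if not chunks:
            stall += 1
            continue
        # bias growth toward the patch seed so footprints stay compact
        # (roundish with an irregular outline) rather than snake-like
        cand = []
        for _ in range(4):
            pix = chunks[int(rng.integers(len(chunks)))]
            cand.append(pix[int(rng.integers(len(pix)))])
        cand = np.array(cand)
        d_seed = np.linalg.norm((cand - centers[lab - 1]) * vs2, axis=1)
        anchor = cand[int(np.argmin(d_seed))]
        center = np.round(anchor + rng.normal(0.0, 0.6 * disk_radius_um / dx, size=2)).astype(int)
        added = stamp(lab, center)
        stall = 0 if added else stall + 1
    if count < target_vox:
        raise ValueError(
            f"target_coverage unreachable: grew {count} of {target_vox} voxels "
            "before stalling (pouch too full for the requested patch layout)"
        )
    return (fp[None, :, :] * pouch).astype(np.int32)


def _grow_blobby_region(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target_vox: int,
    n_seeds: int,
    blob_offsets: np.ndarray,
    seed_min_sep_um: float,
    voxel_size,
) -> np.ndarray:
    """Stamp blobs at random unfilled voxels of ``allowed`` to an exact count.

    Used for apoptotic regions: small balls (one nuclear volume) are placed
    at random territory voxels, clipped to the territory, until the target
    voxel count is reached; the final ball is trimmed inside-out so the
    total is exact.  Each stamp covers at least its own center, so the loop
    terminates whenever ``target_vox`` does not exceed the territory size.
    ``n_seeds`` and ``seed_min_sep_um`` are kept for signature stability but
    unused (each blob is an independent placement).
    """
    labels = np.zeros(allowed.shape, dtype=np.int32)
    if target_vox <= 0:
        return labels
    allowed_idx = np.argwhere(allowed)
    if len(allowed_idx) == 0 or target_vox > len(allowed_idx):
        raise ValueError(
            "target volume unreachable: requested "
            f"{target_vox} voxels but the allowed region has {len(allowed_idx)}"
        )

    count = 0
    lab = 0
    free = np.ones(len(allowed_idx), dtype=bool)
    while count < target_vox:
        free_pos = np.flatnonzero(free)
        pick = free_pos[rng.integers(len(free_pos))]
        center = allowed_idx[pick]
        lab += 1
        pts = _stamp_targets(center, blob_offsets, allowed.shape)
        zi, yi, xi = pts.T
        ok = allowed[zi, yi, xi] & (labels[zi, yi, xi] == 0)
        pts = pts[ok]  # offsets are inside-out sorted, so pts stays sorted
        room = target_vox - count
        if len(pts) > room:
            pts = pts[:room]
        labels[pts[:, 0], pts[:, 1], pts[:, 2]] = lab
        count += len(pts)
        # mark consumed candidates lazily: refresh the free list in place
        still = labels[allowed_idx[:, 0], allowed_idx[:, 1], allowed_idx[:, 2]] == 0
        free &= still
    return labels


def _poisson_disc_centers(
    rng: np.random.Generator, allowed_idx: np.ndarray, min_sep_um: float, voxel_size, n_max: int
) -> np.ndarray:
    """Greedy dart-throwing sample of centers with a minimum separation."""
    vs = np.asarray(voxel_size)
    chosen: list[np.ndarray] = []
    tries = 0
    max_tries = 8 * n_max
    while len(chosen) < n_max and tries < max_tries:
        tries += 1
        c = allowed_idx[rng.integers(len(allowed_idx))]
        if chosen:
            d = np.linalg.norm((np.array(chosen) - c) * vs, axis=1)
            if (d < min_sep_um).any():
                continue
        chosen.append(c)
    return np.array(chosen) if chosen else np.empty((0, 3), dtype=int)


def simulate_disc(config: SimConfig) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic disc and its exact ground truth.

    Identical configs (including seed) produce voxel-identical stacks.
    Raises ``ValueError`` when the requested coverage cannot be reached with
    the configured patch count inside the pouch.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    vs = tuple(config.voxel_size)
    vox_vol = float(np.prod(vs))
    center_um = (
        tuple((n - 1) * v / 2 for n, v in zip(shape, vs))
        if config.pouch_center is None
        else config.pouch_center
    )
    pouch = _ellipsoid(shape, vs, center_um, config.pouch_semiaxes)
    n_pouch = int(pouch.sum())
    if n_pouch == 0:
        raise ValueError("pouch ellipsoid contains no voxels on this grid")

    # --- clone patches: union-of-spheres growth to the exact target count
    target_vox = int(round(config.target_coverage * n_pouch))
    if target_vox > 0 and config.n_patches < 1:
        raise ValueError("target_coverage > 0 requires n_patches >= 1")
    patch_labels = _grow_patch_columns(
        rng,
        pouch=pouch,
        target_vox=target_vox,
        n_seeds=config.n_patches,
        disk_radius_um=2.5 * config.cell_diameter,
        seed_min_sep_um=6.0 * config.cell_diameter,
        voxel_size=vs,
    ) if target_vox > 0 else np.zeros(shape, dtype=np.int32)
    patch_mask = LabelMask(labels=patch_labels, voxel_size=vs)
    patch_bool = patch_labels > 0
    realized_coverage = 100.0 * patch_bool.sum() / n_pouch

    # --- true territory decomposition of the true patches
    tmap: TerritoryMap | None = None
    if patch_bool.any():
        tmap = decompose_border_center(
            patch_mask, cell_diameter=config.cell_diameter, n_cell_diameters=config.n_cell_diameters
        )

    # --- apoptosis blobs per territory, one nuclear volume each
    death = np.zeros(shape, dtype=bool)
    death_blob = _ball_offsets(config.cell_diameter / 2.0, vs)
    realized_death: dict[str, float] = {}
    regions = {
        "border": tmap.mask(BORDER) if tmap is not None else np.zeros(shape, bool),
        "center": tmap.mask(CENTER) if tmap is not None else np.zeros(shape, bool),
        "exterior_wt": pouch & ~patch_bool,
    }
    rates = {
        "border": config.death_rate_border,
        "center": config.death_rate_center,
        "exterior_wt": config.death_rate_wt,
    }
    for name, region in regions.items():
        n_region = int(region.sum())
        if n_region == 0:
            realized_death[name] = float("nan")
            continue
        t = int(round(rates[name] * n_region))
        lab = _grow_blobby_region(
            rng,
            allowed=region,
            target_vox=t,
            n_seeds=max(1, t // max(1, len(death_blob))),
            blob_offsets=death_blob,
            seed_min_sep_um=0.0,
            voxel_size=vs,
        ) if t > 0 else np.zeros(shape, dtype=np.int32)
        death |= lab > 0
        realized_death[name] = 100.0 * (lab > 0).sum() / n_region
    death_mask = LabelMask(labels=death.astype(np.int32), voxel_size=vs)

    # --- speckles inside the pouch
    speckle_coords = np.empty((0, 3))
    if config.speckle_density > 0 and "stain2" in config.channels:
        n_speckles = int(round(config.speckle_density * n_pouch * vox_vol / 1000.0))
        idx = np.argwhere(pouch)
        centers = _poisson_disc_centers(rng, idx, min_sep_um=4.0, voxel_size=vs, n_max=n_speckles)
        speckle_coords = centers * np.asarray(vs)

    # --- nuclei: packed spheres of one cell diameter
    nuclei = np.zeros(shape, dtype=bool)
    if "nuclei" in config.channels:
        idx = np.argwhere(pouch)
        n_target = max(1, int(n_pouch * vox_vol / (1.8 * config.cell_diameter) ** 3))
        centers = _poisson_disc_centers(
            rng, idx, min_sep_um=0.95 * config.cell_diameter, voxel_size=vs, n_max=n_target
        )
        nuc_blob = _ball_offsets(config.cell_diameter / 2.0, vs)
        for c in centers:
            pts = _stamp_targets(c, nuc_blob, shape)
            nuclei[pts[:, 0], pts[:, 1], pts[:, 2]] = True

    # --- render channels
    x_center = center_um[2]
    xx = np.arange(shape[2]) * vs[2]
    posterior_cols = xx >= x_center
    data = []
    channel_map = {}
    for role in config.channels:
        if role == "nuclei":
            img = config.background_level + config.signal_level * nuclei
        elif role == "gfp":
            img = config.background_level + config.signal_level * patch_bool
        elif role == "stain":
            # reporter: posterior pouch = fold × anterior pouch, exact before noise
            img = np.full(shape, config.background_level, dtype=np.float64)
            amp = np.where(posterior_cols, config.signal_level * config.pa_fold_change,
                           config.signal_level)
            img = np.where(pouch, amp[None, None, :], img)
        elif role == "stain2":
            img = np.full(shape, config.background_level, dtype=np.float64)
            img = img + _render_speckles(shape, vs, speckle_coords, 2.5 * config.signal_level)
        elif role == "death":
            img = config.background_level + config.signal_level * death
        channel_map[role] = len(data)
        img = np.asarray(img, dtype=np.float64)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        data.append(np.clip(img, 0.0, None).astype(np.float32))

    stack = ImageStack(data=np.stack(data), voxel_size=vs, channel_map=channel_map)
    truth = GroundTruth(
        pouch_mask=LabelMask(labels=pouch.astype(np.int32), voxel_size=vs),
        patch_mask=patch_mask,
        territory_map=tmap,
        death_mask=death_mask,
        speckle_coords=speckle_coords,
        realized_coverage=float(realized_coverage),
        realized_death_density=realized_death,
        true_pa_ratio=float(config.pa_fold_change),
        cell_diameter=float(config.cell_diameter),
        seed=config.seed,
        config=config,
    )
    return stack, truth


def _render_speckles(shape, voxel_size, coords_um, amplitude, sigma_um=(1.0, 0.6, 0.6)):
    """Additive anisotropic Gaussian spots (confocal-like z elongation)."""
    img = np.zeros(shape, dtype=np.float64)
    if len(coords_um) == 0:
        return img
    vs = np.asarray(voxel_size)
    sig_vox = np.asarray(sigma_um) / vs
    half = np.ceil(3 * sig_vox).astype(int)
    for c_um in coords_um:
        c = c_um / vs
        lo = np.maximum(np.floor(c - half).astype(int), 0)
        hi = np.minimum(np.ceil(c + half).astype(int) + 1, shape)
        if (lo >= hi).any():
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        d2 = (
            ((zz - c[0]) / sig_vox[0]) ** 2
            + ((yy - c[1]) / sig_vox[1]) ** 2
            + ((xx - c[2]) / sig_vox[2]) ** 2
        )
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-d2 / 2.0)
    return img


def per_disc_seed(base_seed: int, index: int) -> int:
    """Seed-splitting rule for cohorts: base seed + disc index (mod 2^31)."""
    return int((base_seed + index) % 2**31)


def simulate_cohort(
    config: SimConfig, n_discs: int, per_disc_jitter: float = 0.0
) -> list[tuple[ImageStack, GroundTruth]]:
    """Simulate ``n_discs`` discs with deterministic per-disc seeds.

    ``per_disc_jitter`` is a relative standard deviation: each disc's effect
    parameters (death rates, P/A fold change) are multiplied by independent
    mean-one log-normal factors, emulating disc-to-disc biological
    variability.  Disc i uses seed ``config.seed + i``.
    """
    if n_discs < 1:
        raise ValueError("n_discs must be >= 1")
    jrng = np.random.default_rng([int(config.seed) % 2**31, 7919])
    out = []
    for i in range(n_discs):
        cfg = replace(config, seed=per_disc_seed(config.seed, i))
        if per_disc_jitter > 0:
            s = float(per_disc_jitter)

            def factor() -> float:
                return float(np.exp(jrng.normal(-0.5 * s**2, s)))

            cfg = replace(
                cfg,
                death_rate_border=min(1.0, config.death_rate_border * factor()),
                death_rate_center=min(1.0, config.death_rate_center * factor()),
                death_rate_wt=min(1.0, config.death_rate_wt * factor()),
                pa_fold_change=config.pa_fold_change * factor(),
            )
        out.append(simulate_disc(cfg))
    return out


def simulate_proteome(
    n_ssu: int = 29,
    n_lsu: int = 49,
    mean_ssu: float = -0.35,
    mean_lsu: float = 0.15,
    sd: float = 0.2,
    seed: int = 0,
    comparison: str = "mutant_vs_wt",
) -> tuple[pd.DataFrame, dict]:
    """Synthetic per-protein log2-fold-change table with SSU/LSU classes.

    Defaults match the detected ribosomal protein counts of the proteomics
    experiment being emulated (29 small-subunit, 49 large-subunit proteins).
    Log fold changes are Gaussian around the class means.

    Returns the table (columns ``protein_id, gene_symbol, subunit_class,
    comparison, lfc``) and a truth record of the generating parameters.
    """
    if n_ssu < 1 or n_lsu < 1:
        raise ValueError("need at least one protein per class")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    symbols = [f"RpS{i + 2}" for i in range(n_ssu)] + [f"RpL{i + 3}" for i in range(n_lsu)]
    classes = ["SSU"] * n_ssu + ["LSU"] * n_lsu
    means = np.array([mean_ssu] * n_ssu + [mean_lsu] * n_lsu)
    lfc = means + rng.normal(0.0, sd, size=n_ssu + n_lsu)
    table = pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(n_ssu + n_lsu)],
            "gene_symbol": symbols,
            "subunit_class": classes,
            "comparison": comparison,
            "lfc": lfc,
        }
    )
    truth = {
        "mean_ssu": mean_ssu,
        "mean_lsu": mean_lsu,
        "sd": sd,
        "n_ssu": n_ssu,
        "n_lsu": n_lsu,
        "seed": seed,
    }
    return table, truth
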