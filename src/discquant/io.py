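"""Reading/writing stacks, masks, configs and results tables.

Stacks are stored as multi-page TIFF with axis order ``(C, Z, Y, X)`` and a
JSON metadata block carrying the voxel size (µm) and the channel-role map;
OME-TIFF physical pixel sizes are honored when present.  Masks travel as
label TIFFs or per-section polygon JSON.  Results are long-format CSV — one
row per disc × metric × scope, plus cohort-level test rows — so every
figure-style number is re-derivable from the CSV alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, LabelMask
from .stats import TestResult

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "disc_id", "kind", "metric", "scope", "value", "units",
    "test_name", "statistic", "p_value", "n", "n2", "method", "flag",
]


# ---------------------------------------------------------------- stacks

def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF with voxel size and channel map."""
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(stack.voxel_size),
        "channel_map": stack.channel_map,
    }
    tifffile.imwrite(path, stack.data, metadata=meta, photometric="minisblack")
    return path


def _ome_voxel_size(tif: tifffile.TiffFile) -> tuple | None:
    try:
        ome = tifffile.xml2dict(tif.ome_metadata)
        px = ome["OME"]["Image"]["Pixels"]
        if isinstance(px, list):
            px = px[0]
        return (
            float(px.get("PhysicalSizeZ")),
            float(px.get("PhysicalSizeY")),
            float(px.get("PhysicalSizeX")),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(path, channel_map: dict | None = None, voxel_size: tuple | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack written by :func:`write_stack` or similar.

    Metadata voxel sizes (shaped-TIFF JSON or OME PhysicalSize*) are used
    unless overridden; a missing voxel size without an override is an error.
    Channel maps are validated against the channel count.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        if voxel_size is None:
            if "voxel_size_um" in meta:
                voxel_size = tuple(meta["voxel_size_um"])
            elif tif.is_ome:
                voxel_size = _ome_voxel_size(tif)
    if data.ndim == 3:
        data = data[None]
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size in metadata; pass voxel_size=(dz, dy, dx) in µm"
        )
    if channel_map is None:
        channel_map = meta.get("channel_map", {})
    channel_map = {k: int(v) for k, v in channel_map.items()}
    for role, idx in channel_map.items():
        if idx >= data.shape[0]:
            raise ValueError(
                f"{path}: channel_map[{role!r}]={idx} but file has {data.shape[0]} channels"
            )
    return ImageStack(data=data, voxel_size=tuple(voxel_size), channel_map=channel_map)


def write_label_mask(mask: LabelMask, path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        mask.labels.astype(np.int32),
        metadata={"axes": "ZYX", "voxel_size_um": list(mask.voxel_size)},
        photometric="minisblack",
    )
    return path


def read_label_mask(path, voxel_size: tuple | None = None) -> LabelMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = dict(tif.shaped_metadata[0]) if tif.shaped_metadata else {}
    if voxel_size is None:
        if "voxel_size_um" not in meta:
            raise ValueError(f"{path}: no voxel size; pass voxel_size=(dz, dy, dx)")
        voxel_size = tuple(meta["voxel_size_um"])
    if data.ndim == 2:
        data = data[None]
    return LabelMask(labels=data.astype(np.int32), voxel_size=tuple(voxel_size))


def polygons_to_mask(polygons: dict, shape, voxel_size) -> LabelMask:
    """Rasterize per-section polygons (JSON: {z: [[y, x], ...]}) to a mask."""
    from skimage.draw import polygon as sk_polygon

    labels = np.zeros(shape, dtype=np.int32)
    for z_str, pts in polygons.items():
        pts = np.asarray(pts, dtype=float)
        rr, cc = sk_polygon(pts[:, 0], pts[:, 1], shape=shape[1:])
        labels[int(z_str), rr, cc] = 1
    return LabelMask(labels=labels, voxel_size=tuple(voxel_size))


def write_ground_truth(truth, out_dir) -> Path:
    """Persist a GroundTruth as label-mask TIFFs plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_label_mask(truth.pouch_mask, out_dir / "pouch_mask.tif")
    write_label_mask(truth.patch_mask, out_dir / "patch_mask.tif")
    write_label_mask(truth.death_mask, out_dir / "death_mask.tif")
    if truth.territory_map is not None:
        write_label_mask(
            LabelMask(truth.territory_map.territory.astype(np.int32),
                      truth.territory_map.voxel_size),
            out_dir / "territory_map.tif",
        )
    sidecar = {
        "realized_coverage_pct": truth.realized_coverage,
        "realized_death_density_pct": truth.realized_death_density,
        "true_pa_ratio": truth.true_pa_ratio,
        "cell_diameter_um": truth.cell_diameter,
        "speckle_coords_um": np.asarray(truth.speckle_coords).tolist(),
        "seed": truth.seed,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


# ---------------------------------------------------------------- config

@dataclasses.dataclass
class ExperimentConfig:
    """Parameters of one quantification run (YAML-loadable)."""

    mode: str = "mosaic"  # mosaic | compartment | proteome
    channel_map: dict = dataclasses.field(default_factory=dict)
    cell_diameter: float | str = "auto"
    n_cell_diameters: float = 2.0
    smooth_sigma: float = 1.0
    threshold: float | None = None
    min_volume: float | None = None
    stack_paths: list = dataclasses.field(default_factory=list)
    roi_paths: list = dataclasses.field(default_factory=list)
    compartment_paths: list = dataclasses.field(default_factory=list)
    intensity_roles: list = dataclasses.field(default_factory=lambda: ["stain"])
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        if cfg.mode not in ("mosaic", "compartment", "proteome"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        return cfg


# ---------------------------------------------------------------- results

def measurement_row(disc_id, metric, scope, value, units="", flag="") -> dict:
    return {
        "disc_id": disc_id, "kind": "measurement", "metric": metric, "scope": scope,
        "value": value, "units": units, "test_name": "", "statistic": np.nan,
        "p_value": np.nan, "n": np.nan, "n2": np.nan, "method": "", "flag": flag,
    }


def test_row(metric, scope, result: TestResult | None, flag="") -> dict:
    row = {
        "disc_id": "", "kind": "test", "metric": metric, "scope": scope,
        "value": np.nan, "units": "", "test_name": "", "statistic": np.nan,
        "p_value": np.nan, "n": np.nan, "n2": np.nan, "method": "", "flag": flag,
    }
    if result is not None:
        row.update(
            test_name=result.test_name, statistic=result.statistic,
            p_value=result.p_value, n=result.n,
            n2=result.n2 if result.n2 is not None else np.nan, method=result.method,
        )
    return row


def results_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.astype({"value": float, "statistic": float, "p_value": float})


def write_results(table: pd.DataFrame, out_dir, plot: bool = False) -> dict[str, Path]:
    """Write a results table as long-format CSV plus a JSON summary.

    The JSON summary holds per-metric×scope medians (the line drawn on
    scatter plots) and the cohort test rows.  ``plot=True`` additionally
    renders one scatter panel per metric with the median line.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    table = table.reindex(columns=RESULT_COLUMNS)
    table.to_csv(csv_path, index=False, float_format="%.10g")

    meas = table[table["kind"] == "measurement"]
    summary = {
        "medians": [
            {"metric": m, "scope": s, "median": float(g["value"].median()), "n": int(len(g))}
            for (m, s), g in meas.groupby(["metric", "scope"], sort=True)
        ],
        "tests": table[table["kind"] == "test"][
            ["metric", "scope", "test_name", "statistic", "p_value", "n", "n2", "method", "flag"]
        ].to_dict(orient="records"),
    }
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, default=float))
    paths = {"csv": csv_path, "json": json_path}
    if plot and len(meas):
        paths["plot"] = plot_scatter(meas, out_dir / "scatter.png")
    return paths


def plot_scatter(meas: pd.DataFrame, path) -> Path:
    """Scatter of per-disc values per metric×scope with a median line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(meas.groupby(["metric", "scope"], sort=True))
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.2))
    rng = np.random.default_rng(0)
    for i, ((metric, scope), g) in enumerate(groups):
        x = i + rng.uniform(-0.12, 0.12, size=len(g))
        ax.scatter(x, g["value"], s=14, alpha=0.8)
        ax.hlines(g["value"].median(), i - 0.25, i + 0.25, colors="k", linewidth=1.6)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([f"{m}\n{s}" for (m, s), _ in groups], fontsize=7)
    ax.set_ylabel("value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
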