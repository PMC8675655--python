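"""End-to-end quantification pipelines over disc cohorts.

Two experiment designs are covered.  *Mosaic* discs carry GFP-marked clone
patches: each disc yields pouch coverage and a paired border/center death
density, and the cohort is tested with the paired Wilcoxon signed-rank
test.  *Compartment* discs express a transgene in the posterior half: each
disc yields posterior/anterior intensity ratios (and optionally speckle
densities per compartment), and the cohort is tested within discs
(one-sample Wilcoxon on the ratios against 1) or between genotypes
(Mann–Whitney).

Pipelines are deterministic given their inputs; per-disc problems
(empty center territory, missing masks) are flagged and logged, and the
affected disc is dropped from the paired test rather than failing the run.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import quantify, segment, territories
from .core import CompartmentMasks, ImageStack, LabelMask
from .io import measurement_row, results_frame, test_row
from .stats import mann_whitney_u, one_sample_wilcoxon, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

NUCLEAR_VOLUME_FACTOR = np.pi / 6.0  # sphere volume for diameter d: πd³/6


def run_mosaic_pipeline(
    discs: Sequence[tuple[str, ImageStack, LabelMask]],
    cell_diameter: float | str = "auto",
    n_cell_diameters: float = 2.0,
    smooth_sigma: float = 1.0,
    death_smooth_sigma: float = 0.5,
    min_volume: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quantify a mosaic cohort: coverage + paired border/center death.

    ``discs`` is a sequence of ``(disc_id, stack, pouch_roi)``.  Per disc:
    clone patches are segmented in the GFP channel, decomposed into border
    (``n_cell_diameters`` × cell diameter) and center territories, the
    apoptosis channel is segmented, and death density per territory is
    recorded along with pouch coverage.  The cohort-level comparison is a
    two-sided paired Wilcoxon of border vs center density over discs with
    both territories non-empty.
    """
    rows = []
    border_vals, center_vals = [], []
    for disc_id, stack, roi in discs:
        if cell_diameter == "auto":
            cd = segment.estimate_cell_diameter(stack)
        else:
            cd = float(cell_diameter)
        mv = NUCLEAR_VOLUME_FACTOR * cd**3 if min_volume is None else min_volume
        patches = segment.segment_patches(
            stack, roi, min_volume=mv, smooth_sigma=smooth_sigma
        )
        cov = quantify.pouch_coverage(patches, roi)
        rows.append(measurement_row(disc_id, "coverage_pct", "pouch", cov, "%"))
        if patches.n_labels == 0:
            logger.warning("%s: no patches segmented; skipping territories", disc_id)
            rows.append(
                measurement_row(disc_id, "death_density_pct", "border", np.nan, "%", "no_patches")
            )
            continue
        tmap = territories.decompose_border_center(
            patches, cell_diameter=cd, n_cell_diameters=n_cell_diameters
        )
        death = segment.segment_death(stack, roi, smooth_sigma=death_smooth_sigma)
        dens = quantify.death_density(death, tmap, roi=roi)
        empty_center = not np.isfinite(dens["center"])
        for scope in ("border", "center", "exterior_wt"):
            flag = "empty_territory" if not np.isfinite(dens[scope]) else ""
            rows.append(
                measurement_row(disc_id, "death_density_pct", scope, dens[scope], "%", flag)
            )
        if empty_center:
            logger.warning("%s: empty center territory; excluded from paired test", disc_id)
        elif np.isfinite(dens["border"]):
            border_vals.append(dens["border"])
            center_vals.append(dens["center"])

    if len(border_vals) >= 2:
        try:
            res = wilcoxon_signed_rank(border_vals, center_vals, two_sided=True)
            rows.append(test_row("death_density_pct", "border_vs_center", res))
        except ValueError as exc:
            rows.append(test_row("death_density_pct", "border_vs_center", None, flag=str(exc)))
    else:
        rows.append(
            test_row("death_density_pct", "border_vs_center", None, flag="insufficient n")
        )
    return results_frame(rows)


def run_compartment_pipeline(
    discs: Sequence[tuple[str, ImageStack, CompartmentMasks]],
    roles: Sequence[str] = ("stain",),
    speckle_roles: Sequence[str] = (),
    mu0: float = 1.0,
    diameter_range: tuple[float, float] = (0.8, 3.0),
    speckle_threshold: float = 0.05,
) -> pd.DataFrame:
    """Quantify a compartment cohort: P/A ratios and speckle densities.

    ``discs`` is a sequence of ``(disc_id, stack, compartment_masks)``.  For
    each configured channel role the posterior/anterior mean-intensity ratio
    is recorded per disc; the cohort test is a two-sided one-sample Wilcoxon
    of the ratios against ``mu0`` (the within-disc paired design).  Roles in
    ``speckle_roles`` are additionally quantified as speckle density per
    compartment, paired-tested posterior vs anterior.
    """
    rows = []
    ratios: dict[str, list[float]] = {r: [] for r in roles}
    dens_p: dict[str, list[float]] = {r: [] for r in speckle_roles}
    dens_a: dict[str, list[float]] = {r: [] for r in speckle_roles}
    for disc_id, stack, comps in discs:
        if comps is None:
            logger.warning("%s: missing compartment masks; disc skipped", disc_id)
            continue
        for role in roles:
            r = quantify.pa_ratio(stack, role, comps)
            ratios[role].append(r)
            rows.append(measurement_row(disc_id, "pa_ratio", role, r, "ratio"))
        for role in speckle_roles:
            spots = segment.detect_speckles(
                stack, role, diameter_range=diameter_range, threshold=speckle_threshold
            )
            vs = stack.voxel_size
            for name, mask_arr, acc in (
                ("posterior", comps.posterior, dens_p),
                ("anterior", comps.anterior, dens_a),
            ):
                d = quantify.speckle_density(
                    spots, LabelMask(mask_arr.astype(np.int32), vs)
                )
                acc[role].append(d)
                rows.append(
                    measurement_row(
                        disc_id, "speckle_density", f"{role}:{name}", d, "per 1000 µm³"
                    )
                )

    for role in roles:
        vals = ratios[role]
        if len(vals) >= 2:
            try:
                res = one_sample_wilcoxon(vals, mu0=mu0, two_sided=True)
                rows.append(test_row("pa_ratio", role, res))
            except ValueError as exc:
                rows.append(test_row("pa_ratio", role, None, flag=str(exc)))
        else:
            rows.append(test_row("pa_ratio", role, None, flag="insufficient n"))
    for role in speckle_roles:
        if len(dens_p[role]) >= 2:
            try:
                res = wilcoxon_signed_rank(dens_p[role], dens_a[role], two_sided=True)
                rows.append(test_row("speckle_density", f"{role}:posterior_vs_anterior", res))
            except ValueError as exc:
                rows.append(
                    test_row("speckle_density", f"{role}:posterior_vs_anterior", None, flag=str(exc))
                )
    return results_frame(rows)


def compare_cohorts(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Between-genotype comparison: one Mann–Whitney row per metric×scope.

    Pools the measurement rows of two cohort tables and tests each
    metric×scope present in both with a two-sided Mann–Whitney U-test.
    """
    rows = []
    ma = table_a[table_a["kind"] == "measurement"]
    mb = table_b[table_b["kind"] == "measurement"]
    keys = sorted(
        set(map(tuple, ma[["metric", "scope"]].itertuples(index=False)))
        & set(map(tuple, mb[["metric", "scope"]].itertuples(index=False)))
    )
    for metric, scope in keys:
        va = ma[(ma["metric"] == metric) & (ma["scope"] == scope)]["value"].dropna()
        vb = mb[(mb["metric"] == metric) & (mb["scope"] == scope)]["value"].dropna()
        if len(va) and len(vb):
            res = mann_whitney_u(va.to_numpy(), vb.to_numpy(), two_sided=True)
            rows.append(test_row(metric, scope, res))
    return results_frame(rows)
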