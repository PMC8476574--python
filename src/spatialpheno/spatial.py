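"""Spatial phenotyping from multiplexed-imaging cell tables.

Cells are segmented within rectangular fields of view ("stamps",
670 x 502 um^2) placed at the tumor border (invasive margin) and center.
Cell densities per marker and region are computed as pooled counts over
all stamps divided by total stamp area, and the spatial immunophenotype
is assigned from the CD8+ T cell density by fixed thresholds:

* inflamed — border density > 200 cells/mm^2 and border/center ratio < 10,
* excluded — border density > 200 cells/mm^2 and border/center ratio > 10,
* ignored  — border and center densities both < 150 cells/mm^2.

The three predicates leave gaps (e.g. border density in [150, 200], or a
ratio of exactly 10); such scans are returned as ``unassigned`` with a
machine-readable reason rather than silently coerced. A zero center
density yields a ratio of +inf, hence ``excluded`` whenever the border
density clears 200 (limiting behavior of the ratio rule).

Nearest-neighbor statistics (counts within a radius, mean nearest
distances) are 2-D Euclidean in um and are computed within single stamps
only — stamps are disjoint fields of view, so cross-stamp distances are
undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

REGIONS = ("border", "center")
COMPARTMENTS = ("tumor", "stroma")

CELL_TABLE_COLUMNS = [
    "sample_id", "stamp_id", "region", "compartment",
    "marker", "x_um", "y_um",
]


@dataclass(frozen=True)
class StampGeometry:
    """Stamp (field of view) geometry and the minimum-stamp QC rule."""

    width_um: float = 670.0
    height_um: float = 502.0
    min_stamps_per_region: int = 3

    @property
    def area_mm2(self) -> float:
        """Stamp area in mm^2 (0.33634 for the default geometry)."""
        return self.width_um * self.height_um / 1e6


@dataclass(frozen=True)
class PhenotypeThresholds:
    """CD8 density thresholds (cells/mm^2) for digital phenotype calls."""

    high_border: float = 200.0
    low_both: float = 150.0
    ratio_cut: float = 10.0

    def __post_init__(self) -> None:
        if not self.low_both < self.high_border:
            raise ValueError("low_both must be < high_border")
        if not self.ratio_cut > 1:
            raise ValueError("ratio_cut must be > 1")


STAMP_GEOMETRY = StampGeometry()
DEFAULT_THRESHOLDS = PhenotypeThresholds()


@dataclass
class DensityProfile:
    """Per-sample marker densities (cells/mm^2) by region.

    ``densities`` maps ``(marker, region)`` — or ``(marker, region,
    compartment)`` when compartment-resolved — to cells/mm^2. Samples
    with fewer than the minimum number of stamps in either region are
    flagged excluded-from-analysis; regions with zero stamps have
    missing (NaN) densities.
    """

    sample_id: str
    densities: dict[tuple, float]
    n_stamps: dict[str, int]
    flagged: bool = False
    reason: str | None = None
    markers: tuple = field(default_factory=tuple)

    def density(self, marker: str, region: str, compartment: str | None = None):
        """Density for a marker/region; 0.0 if no such cell was observed,
        NaN if the region has no stamps."""
        if self.n_stamps.get(region, 0) == 0:
            return math.nan
        key = (marker, region) if compartment is None else (
            marker, region, compartment
        )
        return self.densities.get(key, 0.0)

    def cd8(self, region: str) -> float:
        return self.density("CD8", region)


@dataclass(frozen=True)
class PhenotypeCall:
    """Result of a digital phenotype assignment."""

    label: str  # excluded / ignored / inflamed / unassigned
    reason: str | None = None
    border_cd8: float = math.nan
    center_cd8: float = math.nan


def _validate_cells(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    bad_region = set(cells["region"].unique()) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region values: {sorted(bad_region)}")
    bad_comp = set(cells["compartment"].unique()) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartment values: {sorted(bad_comp)}")


def compute_densities(
    cells: pd.DataFrame,
    geometry: StampGeometry = STAMP_GEOMETRY,
    by_compartment: bool = False,
    n_stamps: dict[str, int] | None = None,
    method: str = "pooled",
) -> dict[str, DensityProfile]:
    """Compute cell densities per sample, marker and region.

    With ``method="pooled"`` (default) density = total cell count over
    all stamps of a region divided by (number of stamps x stamp area in
    mm^2) — counts are summarized over all stamps per sample. With
    ``method="stamp-median"`` density = median over stamps of the
    per-stamp density (stamps without a marker's cells contribute zero).
    Stamp counts are inferred from the distinct ``stamp_id`` values per
    region unless declared via ``n_stamps`` (a region -> count mapping
    applied to every sample; needed e.g. for empty tables where stamps
    held no cells). Samples with fewer than
    ``geometry.min_stamps_per_region`` stamps in either region are
    flagged and should not receive a phenotype call.

    Returns a mapping sample_id -> :class:`DensityProfile`.
    """
    if method not in ("pooled", "stamp-median"):
        raise ValueError("method must be 'pooled' or 'stamp-median'")
    _validate_cells(cells)
    profiles: dict[str, DensityProfile] = {}
    sample_ids = (
        cells["sample_id"].unique() if len(cells) else
        ([] if n_stamps is None else ["<declared>"])
    )
    if len(cells) == 0 and n_stamps is not None:
        # an empty table with declared stamps: one anonymous profile
        sample_ids = ["<declared>"]

    for sid in sample_ids:
        sub = cells[cells["sample_id"] == sid] if len(cells) else cells
        counts_per_region: dict[str, int] = {}
        for region in REGIONS:
            if n_stamps is not None and region in n_stamps:
                counts_per_region[region] = int(n_stamps[region])
            else:
                counts_per_region[region] = int(
                    sub.loc[sub["region"] == region, "stamp_id"].nunique()
                )
        densities: dict[tuple, float] = {}
        markers = tuple(sorted(sub["marker"].unique()))
        for region in REGIONS:
            ns = counts_per_region[region]
            if ns == 0:
                continue
            total_area = ns * geometry.area_mm2
            reg = sub[sub["region"] == region]
            if method == "pooled":
                for marker, cnt in reg.groupby("marker").size().items():
                    densities[(marker, region)] = cnt / total_area
            else:  # stamp-median; stamps with no cells contribute zeros
                per_stamp = reg.groupby(["marker", "stamp_id"]).size()
                for marker in reg["marker"].unique():
                    counts = per_stamp[marker].to_numpy()
                    padded = np.concatenate(
                        [counts, np.zeros(max(0, ns - len(counts)))]
                    )
                    densities[(marker, region)] = float(
                        np.median(padded) / geometry.area_mm2
                    )
            if by_compartment:
                grouped = reg.groupby(["marker", "compartment"]).size()
                for (marker, comp), cnt in grouped.items():
                    densities[(marker, region, comp)] = cnt / total_area

        flagged = False
        reason = None
        low = [
            r for r in REGIONS
            if counts_per_region[r] < geometry.min_stamps_per_region
        ]
        if low:
            flagged = True
            reason = (
                f"fewer than {geometry.min_stamps_per_region} stamps in "
                + " and ".join(low)
            )
        profiles[sid] = DensityProfile(
            sample_id=sid,
            densities=densities,
            n_stamps=counts_per_region,
            flagged=flagged,
            reason=reason,
            markers=markers,
        )
    return profiles


def assign_phenotype_digital(
    border_cd8: float,
    center_cd8: float,
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
) -> PhenotypeCall:
    """Assign the spatial phenotype from CD8 densities by the digital rules.

    The border/center ratio with zero center density is +inf (hence
    ``excluded`` when the border density clears the high threshold).
    Density combinations covered by none of the three predicates return
    ``unassigned`` with reason ``"threshold gap"``; missing densities
    return ``unassigned`` with reason ``"missing density"``.
    """
    b, c = border_cd8, center_cd8
    if b is None or c is None or math.isnan(b) or math.isnan(c):
        return PhenotypeCall("unassigned", "missing density", b, c)
    if b < 0 or c < 0:
        raise ValueError("densities must be >= 0")
    ratio = math.inf if c == 0 else b / c
    if b > thresholds.high_border:
        if ratio < thresholds.ratio_cut:
            return PhenotypeCall("inflamed", None, b, c)
        if ratio > thresholds.ratio_cut:
            return PhenotypeCall("excluded", None, b, c)
        return PhenotypeCall("unassigned", "threshold gap", b, c)
    if b < thresholds.low_both and c < thresholds.low_both:
        return PhenotypeCall("ignored", None, b, c)
    return PhenotypeCall("unassigned", "threshold gap", b, c)


def assign_phenotype_manual(
    border_count: float,
    center_count: float,
    hardly_any_cutoff: float = 10,
    ratio_cut: float = 10.0,
) -> str:
    """Mirror the manual scoring criteria on raw CD8 counts.

    * ignored — "hardly any" cells: both counts below the cutoff
      (default 10 cells per region),
    * excluded — more than ``ratio_cut`` times more cells at the border
      than the center,
    * inflamed — otherwise (near-equal frequencies at border and center).
    """
    if border_count < 0 or center_count < 0:
        raise ValueError("counts must be >= 0")
    if border_count < hardly_any_cutoff and center_count < hardly_any_cutoff:
        return "ignored"
    ratio = math.inf if center_count == 0 else border_count / center_count
    if ratio > ratio_cut:
        return "excluded"
    return "inflamed"


def assign_sample_phenotypes(
    profiles: dict[str, DensityProfile],
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Phenotype every density profile; flagged samples stay unassigned.

    Returns a DataFrame (one row per sample) with the CD8 densities,
    stamp counts, phenotype and reason — the TSV-ready assignment table.
    """
    rows = []
    for sid, prof in profiles.items():
        if prof.flagged:
            call = PhenotypeCall(
                "unassigned", prof.reason, prof.cd8("border"), prof.cd8("center")
            )
        else:
            call = assign_phenotype_digital(
                prof.cd8("border"), prof.cd8("center"), thresholds
            )
        rows.append(
            {
                "sample_id": sid,
                "border_cd8_per_mm2": call.border_cd8,
                "center_cd8_per_mm2": call.center_cd8,
                "n_stamps_border": prof.n_stamps.get("border", 0),
                "n_stamps_center": prof.n_stamps.get("center", 0),
                "phenotype": call.label,
                "reason": call.reason or "",
            }
        )
    return pd.DataFrame(rows)


def neighbor_counts_within_radius(
    cells: pd.DataFrame,
    reference_marker: str,
    radius_um: float = 10.0,
) -> pd.DataFrame:
    """Count, per reference cell, neighbors of each marker within a radius.

    For every cell carrying ``reference_marker``, cells of each marker at
    Euclidean distance <= ``radius_um`` (closed ball) within the same
    stamp are counted; the reference cell itself is excluded. Returns a
    DataFrame indexed like the reference cells' rows with one column per
    marker present in the table.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    _validate_cells(cells)
    markers = sorted(cells["marker"].unique())
    if reference_marker not in markers:
        logger.warning(
            "reference marker %r absent from cell table", reference_marker
        )
        return pd.DataFrame(columns=markers)

    out_index: list = []
    out_rows: list[list[int]] = []
    for (_, _), stamp in cells.groupby(["sample_id", "stamp_id"], sort=False):
        refs = stamp[stamp["marker"] == reference_marker]
        if refs.empty:
            continue
        ref_xy = refs[["x_um", "y_um"]].to_numpy()
        counts = np.zeros((len(refs), len(markers)), dtype=int)
        for j, marker in enumerate(markers):
            targets = stamp[stamp["marker"] == marker]
            if targets.empty:
                continue
            tree = cKDTree(targets[["x_um", "y_um"]].to_numpy())
            hits = tree.query_ball_point(ref_xy, r=radius_um)
            counts[:, j] = [len(h) for h in hits]
            if marker == reference_marker:
                counts[:, j] -= 1  # self falls inside its own ball
        out_index.extend(refs.index)
        out_rows.extend(counts)
    return pd.DataFrame(out_rows, index=out_index, columns=markers)


def mean_nearest_distance(
    cells: pd.DataFrame,
    reference_marker: str,
    target_marker: str,
) -> float:
    """Mean distance (um) from reference cells to their nearest target cell.

    Nearest-neighbor distances are computed within each stamp; stamps
    lacking the target marker contribute no reference cells. When the
    reference and target markers coincide, the nearest *other* cell of
    that marker is used. Returns NaN with a warning when no stamp holds
    both markers.
    """
    _validate_cells(cells)
    same = reference_marker == target_marker
    dists: list[np.ndarray] = []
    for (_, _), stamp in cells.groupby(["sample_id", "stamp_id"], sort=False):
        refs = stamp[stamp["marker"] == reference_marker]
        targets = stamp[stamp["marker"] == target_marker]
        if refs.empty or targets.empty:
            continue
        if same and len(targets) < 2:
            continue
        tree = cKDTree(targets[["x_um", "y_um"]].to_numpy())
        k = 2 if same else 1
        d, _ = tree.query(refs[["x_um", "y_um"]].to_numpy(), k=k)
        dists.append(d[:, -1] if k == 2 else np.atleast_1d(d))
    if not dists:
        logger.warning(
            "no stamp holds both %r and %r cells",
            reference_marker, target_marker,
        )
        return math.nan
    return float(np.concatenate(dists).mean())
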