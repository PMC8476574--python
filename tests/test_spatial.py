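"""Density quantification, threshold phenotype rules, neighbor statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from spatialpheno import (
    STAMP_GEOMETRY,
    assign_phenotype_digital,
    assign_phenotype_manual,
    compute_densities,
    generate_cell_pattern,
    mean_nearest_distance,
    neighbor_counts_within_radius,
)


def make_cells(rows):
    """rows: (stamp_id, region, marker, x, y) tuples for one sample."""
    return pd.DataFrame(
        [
            {
                "sample_id": "S1",
                "stamp_id": sid,
                "region": region,
                "compartment": "tumor",
                "marker": marker,
                "x_um": x,
                "y_um": y,
            }
            for sid, region, marker, x, y in rows
        ]
    )


class TestDensities:
    def test_hand_computed_density_single_stamp(self):
        rows = [("b1", "border", "CD8", float(i % 600), float(i % 500))
                for i in range(100)]
        rows += [("c1", "center", "CD8", 10.0, 10.0)]
        profiles = compute_densities(make_cells(rows))
        prof = profiles["S1"]
        # 100 cells over one 0.33634 mm^2 stamp
        assert prof.cd8("border") == pytest.approx(100 / 0.33634, abs=0.05)
        assert prof.cd8("border") == pytest.approx(297.3, abs=0.1)

    def test_density_scales_inversely_with_stamp_count(self):
        rows = [("b1", "border", "CD8", 5.0, 5.0)] * 50
        one = compute_densities(make_cells(rows))["S1"].cd8("border")
        two = compute_densities(
            make_cells(rows), n_stamps={"border": 2, "center": 3}
        )["S1"].cd8("border")
        assert two == pytest.approx(one / 2)

    def test_density_invariant_under_translation(self):
        rng = np.random.default_rng(0)
        rows = [("b1", "border", "CD8", x, y)
                for x, y in rng.uniform(0, 300, (40, 2))]
        cells = make_cells(rows + [("c1", "center", "CD8", 1.0, 1.0)])
        shifted = cells.copy()
        shifted[["x_um", "y_um"]] += 100.0
        d0 = compute_densities(cells, n_stamps={"border": 3, "center": 3})
        d1 = compute_densities(shifted, n_stamps={"border": 3, "center": 3})
        assert d0["S1"].cd8("border") == d1["S1"].cd8("border")

    def test_empty_table_with_declared_stamps_all_zero(self):
        cells = generate_cell_pattern(
            marker_intensities={"CD8": (0.0, 0.0)}, seed=1
        )
        profiles = compute_densities(
            cells, n_stamps={"border": 8, "center": 8}
        )
        (prof,) = profiles.values()
        assert prof.cd8("border") == 0.0
        assert prof.cd8("center") == 0.0
        assert not prof.flagged

    def test_too_few_stamps_flagged(self):
        rows = [("b1", "border", "CD8", 1.0, 1.0),
                ("b2", "border", "CD8", 2.0, 2.0),
                ("c1", "center", "CD8", 1.0, 1.0),
                ("c2", "center", "CD8", 1.0, 1.0),
                ("c3", "center", "CD8", 1.0, 1.0)]
        prof = compute_densities(make_cells(rows))["S1"]
        assert prof.flagged
        assert "border" in prof.reason

    def test_zero_stamps_region_reports_missing(self):
        rows = [("b1", "border", "CD8", 1.0, 1.0)]
        prof = compute_densities(make_cells(rows))["S1"]
        assert math.isnan(prof.cd8("center"))

    def test_unknown_region_rejected(self):
        cells = make_cells([("b1", "border", "CD8", 1.0, 1.0)])
        cells.loc[0, "region"] = "edge"
        with pytest.raises(ValueError):
            compute_densities(cells)

    def test_stamp_median_variant(self):
        # three border stamps with 2, 4 and 0 CD8 cells: pooled density is
        # 6/(3*area), the per-stamp-median is median(2,4,0)/area = 2/area
        rows = [("b1", "border", "CD8", 1.0, 1.0)] * 2
        rows += [("b2", "border", "CD8", 1.0, 1.0)] * 4
        rows += [("c1", "center", "CD8", 1.0, 1.0)] * 3
        cells = make_cells(rows)
        area = STAMP_GEOMETRY.area_mm2
        pooled = compute_densities(
            cells, n_stamps={"border": 3, "center": 3}
        )["S1"]
        med = compute_densities(
            cells, n_stamps={"border": 3, "center": 3}, method="stamp-median"
        )["S1"]
        assert pooled.cd8("border") == pytest.approx(6 / (3 * area))
        assert med.cd8("border") == pytest.approx(2 / area)
        with pytest.raises(ValueError):
            compute_densities(cells, method="per-stamp")

    def test_by_compartment_resolves_and_pools(self):
        rows = [("b1", "border", "CD8", 1.0, 1.0)] * 4
        cells = make_cells(rows + [("c1", "center", "CD8", 1.0, 1.0)])
        cells.loc[:1, "compartment"] = "stroma"
        prof = compute_densities(cells, by_compartment=True)["S1"]
        tumor = prof.density("CD8", "border", "tumor")
        stroma = prof.density("CD8", "border", "stroma")
        assert tumor + stroma == pytest.approx(prof.cd8("border"))


class TestDigitalAssignment:
    @pytest.mark.parametrize(
        "border,center,expected",
        [
            (250.0, 20.0, "excluded"),   # ratio 12.5
            (250.0, 100.0, "inflamed"),  # ratio 2.5
            (100.0, 50.0, "ignored"),
            (180.0, 5.0, "unassigned"),  # gap: border in [150, 200]
            (250.0, 0.0, "excluded"),    # ratio +inf
            (100.0, 160.0, "unassigned"),  # gap: center >= 150, border low
            (250.0, 25.0, "unassigned"),   # ratio exactly 10
        ],
    )
    def test_threshold_rules(self, border, center, expected):
        assert assign_phenotype_digital(border, center).label == expected

    def test_missing_density_unassigned_with_reason(self):
        call = assign_phenotype_digital(math.nan, 50.0)
        assert call.label == "unassigned"
        assert call.reason == "missing density"

    def test_predicates_mutually_exclusive_on_grid(self):
        # the three rules never overlap anywhere on a dense density grid
        grid = np.linspace(0, 1000, 81)
        for b in grid:
            for c in grid:
                labels = []
                ratio = math.inf if c == 0 else b / c
                if b > 200 and ratio < 10:
                    labels.append("inflamed")
                if b > 200 and ratio > 10:
                    labels.append("excluded")
                if b < 150 and c < 150:
                    labels.append("ignored")
                assert len(labels) <= 1
                call = assign_phenotype_digital(float(b), float(c))
                expected = labels[0] if labels else "unassigned"
                assert call.label == expected

    def test_archetype_recovery_rate(self):
        # the generator's default intensities must be recovered by the
        # threshold rules in >= 95% of seeds
        from spatialpheno import PHENOTYPES

        hits = 0
        n_seeds = 40
        for phen in PHENOTYPES:
            for seed in range(n_seeds):
                cells = generate_cell_pattern(phen, seed=seed)
                prof = compute_densities(
                    cells, n_stamps={"border": 8, "center": 8}
                )["SYN001"]
                call = assign_phenotype_digital(
                    prof.cd8("border"), prof.cd8("center")
                )
                hits += call.label == phen
        assert hits / (3 * n_seeds) >= 0.95


class TestManualAssignment:
    @pytest.mark.parametrize(
        "border,center,expected",
        [
            (500, 20, "excluded"),   # ratio 25
            (5, 2, "ignored"),       # both below "hardly any"
            (300, 250, "inflamed"),  # near-equal frequencies
            (50, 0, "excluded"),     # infinite ratio
        ],
    )
    def test_manual_rules(self, border, center, expected):
        assert assign_phenotype_manual(border, center) == expected


def brute_force_neighbor_counts(cells, reference_marker, radius):
    """All-pairs oracle over (sample, stamp) groups."""
    out = {}
    for _, stamp in cells.groupby(["sample_id", "stamp_id"]):
        refs = stamp[stamp["marker"] == reference_marker]
        for i, ref in refs.iterrows():
            counts = {}
            for j, other in stamp.iterrows():
                if i == j:
                    continue
                d = math.hypot(
                    ref["x_um"] - other["x_um"], ref["y_um"] - other["y_um"]
                )
                if d <= radius:
                    counts[other["marker"]] = counts.get(other["marker"], 0) + 1
            out[i] = counts
    return out


class TestNeighborCounts:
    def test_two_cells_count_each_other(self):
        cells = make_cells(
            [("b1", "border", "CD8", 0.0, 0.0),
             ("b1", "border", "CD68", 3.0, 4.0)]
        )
        counts = neighbor_counts_within_radius(cells, "CD8", 10.0)
        assert counts.loc[0, "CD68"] == 1
        counts2 = neighbor_counts_within_radius(cells, "CD68", 10.0)
        assert counts2.loc[1, "CD8"] == 1

    def test_exactly_radius_apart_counts(self):
        cells = make_cells(
            [("b1", "border", "CD8", 0.0, 0.0),
             ("b1", "border", "CD68", 10.0, 0.0)]
        )
        counts = neighbor_counts_within_radius(cells, "CD8", 10.0)
        assert counts.loc[0, "CD68"] == 1  # closed ball

    def test_self_excluded_and_cross_stamp_ignored(self):
        cells = make_cells(
            [("b1", "border", "CD8", 0.0, 0.0),
             ("b1", "border", "CD8", 5.0, 0.0),
             ("b2", "border", "CD8", 1.0, 0.0)]
        )
        counts = neighbor_counts_within_radius(cells, "CD8", 10.0)
        assert counts.loc[0, "CD8"] == 1  # stampmate only, not itself/b2
        assert counts.loc[2, "CD8"] == 0

    def test_matches_brute_force_on_random_pattern(self, rng):
        markers = ["CD8", "CD68", "CD4"]
        n = 400
        cells = pd.DataFrame(
            {
                "sample_id": "S1",
                "stamp_id": rng.choice(["a", "b", "c"], n),
                "region": "border",
                "compartment": "tumor",
                "marker": rng.choice(markers, n),
                "x_um": rng.uniform(0, 100, n),
                "y_um": rng.uniform(0, 100, n),
            }
        )
        got = neighbor_counts_within_radius(cells, "CD8", 10.0)
        expected = brute_force_neighbor_counts(cells, "CD8", 10.0)
        assert set(got.index) == set(expected)
        for i in got.index:
            for m in markers:
                assert got.loc[i, m] == expected[i].get(m, 0), (i, m)

    def test_aggregate_pair_symmetry(self, rng):
        n = 300
        cells = pd.DataFrame(
            {
                "sample_id": "S1",
                "stamp_id": rng.choice(["a", "b"], n),
                "region": "border",
                "compartment": "tumor",
                "marker": rng.choice(["CD8", "CD68"], n),
                "x_um": rng.uniform(0, 80, n),
                "y_um": rng.uniform(0, 80, n),
            }
        )
        a_near_b = neighbor_counts_within_radius(cells, "CD8", 12.0)["CD68"].sum()
        b_near_a = neighbor_counts_within_radius(cells, "CD68", 12.0)["CD8"].sum()
        assert a_near_b == b_near_a

    def test_absent_reference_marker_returns_empty(self):
        cells = make_cells([("b1", "border", "CD68", 1.0, 1.0)])
        assert neighbor_counts_within_radius(cells, "CD8").empty


class TestMeanNearestDistance:
    def test_three_four_five_triangle(self):
        cells = make_cells(
            [("b1", "border", "CD8", 0.0, 0.0),
             ("b1", "border", "CK", 3.0, 4.0),
             ("b1", "border", "CK", 6.0, 8.0)]
        )
        assert mean_nearest_distance(cells, "CD8", "CK") == pytest.approx(5.0)

    def test_same_marker_excludes_self(self):
        cells = make_cells(
            [("b1", "border", "CD8", 0.0, 0.0),
             ("b1", "border", "CD8", 7.0, 0.0)]
        )
        assert mean_nearest_distance(cells, "CD8", "CD8") == pytest.approx(7.0)

    def test_matches_brute_force(self, rng):
        n = 350
        cells = pd.DataFrame(
            {
                "sample_id": "S1",
                "stamp_id": rng.choice(["a", "b"], n),
                "region": "center",
                "compartment": "stroma",
                "marker": rng.choice(["CD8", "CK"], n),
                "x_um": rng.uniform(0, 200, n),
                "y_um": rng.uniform(0, 200, n),
            }
        )
        got = mean_nearest_distance(cells, "CD8", "CK")
        dists = []
        for _, stamp in cells.groupby("stamp_id"):
            refs = stamp[stamp["marker"] == "CD8"]
            targets = stamp[stamp["marker"] == "CK"]
            if refs.empty or targets.empty:
                continue
            for _, ref in refs.iterrows():
                dists.append(
                    min(
                        math.hypot(ref["x_um"] - t["x_um"],
                                   ref["y_um"] - t["y_um"])
                        for _, t in targets.iterrows()
                    )
                )
        assert got == pytest.approx(np.mean(dists), abs=1e-12)

    def test_target_absent_everywhere_is_nan(self):
        cells = make_cells([("b1", "border", "CD8", 1.0, 1.0)])
        assert math.isnan(mean_nearest_distance(cells, "CD8", "CK"))
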