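"""Spatial statistics: worked geometric examples, brute-force oracle
equivalence, rigid-transform invariance, and monotonicity."""

import numpy as np
import pandas as pd
import pytest

from lrtme.spatial import (
    SpatialConfig,
    call_rosettes,
    compare_between_groups,
    mean_nn_distance,
    neighborhood_proportion,
    touching_pairs,
)


def table(points, phenotypes, sample_id="s0"):
    points = np.asarray(points, float)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"c{i}" for i in range(len(points))],
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "phenotype": phenotypes,
        }
    )


def random_table(rng, n, sample_id="s0", phenotypes=("HRS", "TFH", "B", "other")):
    pts = rng.uniform(0, 800, size=(n, 2))
    phen = rng.choice(phenotypes, size=n, p=(0.05, 0.25, 0.3, 0.4))
    return table(pts, phen, sample_id)


# --- brute-force oracles ---------------------------------------------------


def brute_neighborhood(df, reference, target, r):
    refs = df[df["phenotype"] == reference]
    others = df[df["phenotype"] != reference]
    in_region = []
    for _, row in others.iterrows():
        d = np.hypot(
            refs["x_um"] - row["x_um"], refs["y_um"] - row["y_um"]
        )
        in_region.append((d <= r).any())
    in_region = np.array(in_region, bool)
    n_in = in_region.sum()
    n_target = (in_region & (others["phenotype"] == target).to_numpy()).sum()
    return n_in, n_target


def brute_nn(df, reference, target):
    refs = df[df["phenotype"] == reference]
    targets = df[df["phenotype"] == target]
    dists = []
    for _, row in refs.iterrows():
        d = np.hypot(
            targets["x_um"] - row["x_um"], targets["y_um"] - row["y_um"]
        )
        dists.append(d.min())
    return float(np.mean(dists))


def brute_pairs(df, a, b, threshold):
    ca = df[df["phenotype"] == a]
    cb = df[df["phenotype"] == b]
    found = set()
    for _, ra in ca.iterrows():
        for _, rb in cb.iterrows():
            d = np.hypot(ra["x_um"] - rb["x_um"], ra["y_um"] - rb["y_um"])
            if d <= threshold:
                found.add((ra["cell_id"], rb["cell_id"]))
    return found


class TestNeighborhoodProportion:
    def test_worked_example_half(self):
        # targets at 50 and 100, non-target at 60; r=75 keeps two cells
        df = table(
            [(0, 0), (50, 0), (60, 0), (100, 0)],
            ["HRS", "TFH", "B", "TFH"],
        )
        res = neighborhood_proportion(df, "HRS", "TFH", SpatialConfig())
        assert res.loc[0, "n_in_region"] == 2
        assert res.loc[0, "proportion"] == pytest.approx(0.5)

    def test_empty_region_is_undefined_not_zero(self):
        df = table([(0, 0), (500, 500)], ["HRS", "TFH"])
        res = neighborhood_proportion(df, "HRS", "TFH", SpatialConfig())
        assert not res.loc[0, "defined"] or res.loc[0, "n_in_region"] == 0
        assert np.isnan(res.loc[0, "proportion"])

    def test_no_reference_cells_flagged(self):
        df = table([(0, 0)], ["TFH"])
        res = neighborhood_proportion(df, "HRS", "TFH", SpatialConfig())
        assert not res.loc[0, "defined"]
        assert res.loc[0, "n_reference"] == 0

    def test_overlapping_disks_count_cell_once(self):
        # one target inside the overlap of two reference disks
        one = table([(0, 0), (30, 0)], ["HRS", "TFH"])
        two = table([(0, 0), (40, 0), (30, 0)], ["HRS", "HRS", "TFH"])
        r1 = neighborhood_proportion(one, "HRS", "TFH", SpatialConfig())
        r2 = neighborhood_proportion(two, "HRS", "TFH", SpatialConfig())
        assert r1.loc[0, "proportion"] == r2.loc[0, "proportion"] == 1.0
        assert r2.loc[0, "n_in_region"] == 1

    def test_matches_brute_force(self, rng):
        df = random_table(rng, 400)
        cfg = SpatialConfig()
        res = neighborhood_proportion(df, "HRS", "TFH", cfg)
        n_in, n_target = brute_neighborhood(df, "HRS", "TFH", cfg.neighborhood_radius_um)
        assert res.loc[0, "n_in_region"] == n_in
        assert res.loc[0, "n_target_in_region"] == n_target


class TestMeanNN:
    def test_three_four_five_triangle(self):
        df = table([(0, 0), (30, 40), (60, 80)], ["HRS", "TFH", "TFH"])
        res = mean_nn_distance(df, "HRS", "TFH")
        assert res.loc[0, "mean_nn_um"] == pytest.approx(50.0)

    def test_single_pair_distance(self):
        df = table([(0, 0), (7, 0)], ["HRS", "TFH"])
        res = mean_nn_distance(df, "HRS", "TFH")
        assert res.loc[0, "mean_nn_um"] == pytest.approx(7.0)

    def test_missing_phenotype_flagged_undefined(self):
        df = table([(0, 0)], ["HRS"])
        res = mean_nn_distance(df, "HRS", "TFH")
        assert not res.loc[0, "defined"]
        assert np.isnan(res.loc[0, "mean_nn_um"])

    def test_matches_brute_force_on_500_cells(self, rng):
        df = random_table(rng, 500)
        res = mean_nn_distance(df, "HRS", "TFH")
        assert res.loc[0, "mean_nn_um"] == pytest.approx(
            brute_nn(df, "HRS", "TFH"), abs=1e-9
        )

    def test_median_option(self):
        df = table([(0, 0), (100, 0), (1, 0), (99, 0)],
                   ["HRS", "HRS", "TFH", "TFH"])
        mean = mean_nn_distance(df, "HRS", "TFH", statistic="mean")
        med = mean_nn_distance(df, "HRS", "TFH", statistic="median")
        assert mean.loc[0, "mean_nn_um"] == med.loc[0, "mean_nn_um"] == 1.0


class TestRosettes:
    def ring(self, n, radius, center=(0.0, 0.0)):
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.c_[center[0] + radius * np.cos(angles),
                     center[1] + radius * np.sin(angles)]

    def test_planted_ring_is_called(self):
        pts = np.vstack([[(0, 0)], self.ring(6, 20)])
        df = table(pts, ["HRS"] + ["TFH"] * 6)
        calls, per_sample = call_rosettes(df, "HRS", "TFH", SpatialConfig())
        assert calls.loc[0, "n_phenotype_within_radius"] == 6
        assert bool(calls.loc[0, "is_rosette"])
        assert per_sample.loc[0, "rosette_fraction"] == 1.0

    def test_isolated_hrs_not_called(self):
        df = table([(0, 0), (400, 400)], ["HRS", "TFH"])
        calls, _ = call_rosettes(df, "HRS", "TFH", SpatialConfig())
        assert not calls["is_rosette"].any()

    def test_no_hrs_cells_not_evaluable(self):
        df = table([(0, 0)], ["TFH"])
        calls, per_sample = call_rosettes(df, "HRS", "TFH", SpatialConfig())
        assert calls.empty
        assert not per_sample.loc[0, "evaluable"]

    def test_rosette_count_nonincreasing_in_min_cells(self, rng):
        df = random_table(rng, 600)
        counts = []
        for k in (1, 3, 5, 8, 12):
            _, per = call_rosettes(
                df, "HRS", "TFH", SpatialConfig(rosette_min_cells=k)
            )
            counts.append(per.loc[0, "n_rosette"])
        assert counts == sorted(counts, reverse=True)

    def test_zero_noise_recovery_is_exact(self, zero_noise_cohort, zero_noise_spec):
        from lrtme.phenotyping import assign_phenotypes, gate_cells
        from lrtme.synthetic import default_phenotype_defs

        cells, truth = zero_noise_cohort
        gated = assign_phenotypes(gate_cells(cells), default_phenotype_defs())
        calls, per_sample = call_rosettes(gated, "HRS", "TFH_CXCL13")
        merged = calls.merge(
            truth[truth["true_phenotype"] == "HRS"],
            left_on=["sample_id", "hrs_cell_id"],
            right_on=["sample_id", "cell_id"],
        )
        assert (
            merged["is_rosette"] == merged["hrs_is_rosette"].astype(bool)
        ).all()
        assert (
            per_sample["rosette_fraction"] == zero_noise_spec.rosette_fraction
        ).all()


class TestTouchingPairs:
    def test_threshold_inclusion(self):
        df = table([(0, 0), (8, 0), (50, 0), (62, 0)],
                   ["HRS", "TFH", "HRS", "TFH"])
        pairs = touching_pairs(df, "HRS", "TFH", SpatialConfig())
        assert len(pairs) == 1  # 8 um pair in, 12 um pair out
        assert pairs.loc[0, "distance_um"] == pytest.approx(8.0)

    def test_matches_brute_force_on_300_cells(self, rng):
        df = random_table(rng, 300)
        cfg = SpatialConfig(touching_distance_um=25.0)
        pairs = touching_pairs(df, "HRS", "TFH", cfg)
        got = set(zip(pairs["cell_id_a"], pairs["cell_id_b"]))
        assert got == brute_pairs(df, "HRS", "TFH", 25.0)

    def test_same_phenotype_rejected(self):
        df = table([(0, 0)], ["HRS"])
        with pytest.raises(ValueError):
            touching_pairs(df, "HRS", "HRS")


def rigid_transform(df, angle, shift):
    c, s = np.cos(angle), np.sin(angle)
    x, y = df["x_um"].to_numpy(), df["y_um"].to_numpy()
    out = df.copy()
    out["x_um"] = c * x - s * y + shift[0]
    out["y_um"] = s * x + c * y + shift[1]
    return out


def test_statistics_invariant_under_rigid_transform(rng):
    df = random_table(rng, 400)
    moved = rigid_transform(df, angle=0.7, shift=(123.0, -45.0))
    cfg = SpatialConfig()
    a = neighborhood_proportion(df, "HRS", "TFH", cfg)
    b = neighborhood_proportion(moved, "HRS", "TFH", cfg)
    assert a.loc[0, "n_in_region"] == b.loc[0, "n_in_region"]
    assert a.loc[0, "proportion"] == pytest.approx(b.loc[0, "proportion"])
    assert mean_nn_distance(df, "HRS", "TFH").loc[0, "mean_nn_um"] == pytest.approx(
        mean_nn_distance(moved, "HRS", "TFH").loc[0, "mean_nn_um"]
    )
    ca, _ = call_rosettes(df, "HRS", "TFH", cfg)
    cb, _ = call_rosettes(moved, "HRS", "TFH", cfg)
    assert ca["n_phenotype_within_radius"].tolist() == cb[
        "n_phenotype_within_radius"
    ].tolist()


def test_region_size_nondecreasing_in_radius(rng):
    df = random_table(rng, 400)
    sizes = [
        neighborhood_proportion(
            df, "HRS", "TFH", SpatialConfig(neighborhood_radius_um=r)
        ).loc[0, "n_in_region"]
        for r in (20, 50, 75, 120, 200)
    ]
    assert sizes == sorted(sizes)


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        res = compare_between_groups(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 2.0, "f": 3.0},
            {"a": "LR", "b": "LR", "c": "LR", "d": "other", "e": "other", "f": "other"},
        )
        assert res.test == "welch_t"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_groups_use_anova(self):
        values = {f"s{i}": float(i) for i in range(9)}
        groups = {f"s{i}": ["A", "B", "C"][i % 3] for i in range(9)}
        assert compare_between_groups(values, groups).test == "anova"

    def test_undefined_samples_excluded_and_counted(self):
        res = compare_between_groups(
            {"a": 1.0, "b": 2.0, "c": np.nan, "d": 1.5, "e": 2.5},
            {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y"},
        )
        assert res.n_excluded == 1

    def test_fully_undefined_group_is_error(self):
        with pytest.raises(ValueError, match="y"):
            compare_between_groups(
                {"a": 1.0, "b": np.nan},
                {"a": "x", "b": "y"},
            )

    def test_power_on_planted_nn_shift(self):
        """A 2-SD shift between groups (n=8/group) is detected in >=90%
        of 200 simulated cohorts."""
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(200):
            lr = rng.normal(30.0, 5.0, 8)
            other = rng.normal(40.0, 5.0, 8)  # 2 SD shift
            values = {f"l{i}": v for i, v in enumerate(lr)}
            values.update({f"o{i}": v for i, v in enumerate(other)})
            groups = {k: ("LR" if k.startswith("l") else "other") for k in values}
            if compare_between_groups(values, groups).p_value < 0.05:
                hits += 1
        assert hits / 200 >= 0.90
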