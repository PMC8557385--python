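"""Circle construction, toroidal edge correction and local density metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from mixstand.neighborhood import (
    annual_diameter_increment,
    circle_features,
    classify_mixed,
    local_sdi,
    mixing_proportions,
    search_radius,
    toroidal_neighbors,
)
from mixstand.records import PlotDefinition


def brute_force_neighbors(plot, center_xy, x, y, sr, exclude=None):
    """Oracle: plain Euclidean search over all nine shifted plot copies."""
    best = np.full(len(x), np.inf)
    for sx in (-plot.width, 0.0, plot.width):
        for sy in (-plot.height, 0.0, plot.height):
            d = np.hypot(x + sx - center_xy[0], y + sy - center_xy[1])
            best = np.minimum(best, d)
    mask = best < sr
    if exclude is not None:
        mask[exclude] = False
    return np.flatnonzero(mask)


class TestSearchRadius:
    def test_quarter_height(self):
        assert search_radius(28.0) == 7.0
        assert search_radius(10.0) == 2.5

    def test_linear_scaling(self):
        assert search_radius(2 * 13.7) == pytest.approx(2 * search_radius(13.7))

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            search_radius(0.0)


class TestToroidalNeighbors:
    plot = PlotDefinition("t", 100.0, 100.0, (50.0,))

    def test_interior_equivalence_with_plain_search(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(40, 60, 30), rng.uniform(40, 60, 30)
        idx = toroidal_neighbors(self.plot, (50, 50), x, y, 8.0)
        plain = np.flatnonzero(np.hypot(x - 50, y - 50) < 8.0)
        assert np.array_equal(idx, plain)

    def test_periodic_wrap_distance(self):
        x = np.array([99.5])
        y = np.array([0.5])
        idx = toroidal_neighbors(self.plot, (0.5, 0.5), x, y, 1.5)
        assert list(idx) == [0]  # wrapped distance is exactly 1.0 m

    def test_matches_nine_copy_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.uniform(0, 100, 50)
            y = rng.uniform(0, 100, 50)
            center = (float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
            sr = float(rng.uniform(3, 40))
            got = toroidal_neighbors(self.plot, center, x, y, sr)
            want = brute_force_neighbors(self.plot, center, x, y, sr)
            assert np.array_equal(got, want)

    def test_self_image_overlap_rejected(self):
        with pytest.raises(ValueError, match="periodic image"):
            toroidal_neighbors(self.plot, (50, 50), np.array([1.0]),
                               np.array([1.0]), 50.0)


class TestLocalSDI:
    alpha = {"spruce": -1.605}

    def test_index_diameter_identity(self):
        # at dq = 25 cm the SDI equals the per-ha stem count for any alpha
        for a in (-1.2, -1.605, -1.9):
            sdi = local_sdi(np.full(6, 25.0), np.full(6, "spruce"), 100.0,
                            {"spruce": a})
            assert sdi == pytest.approx(10_000 / 100.0 * 6, rel=1e-12)

    def test_hand_value_eight_trees(self):
        area = math.pi * 7.0 ** 2
        sdi = local_sdi(np.full(8, 20.0), np.full(8, "spruce"), area,
                        self.alpha)
        N = 10_000 / area * 8
        assert N == pytest.approx(519.7, abs=0.05)
        assert sdi == pytest.approx(N * (20 / 25) ** 1.605, rel=1e-12)
        assert sdi == pytest.approx(363.3, abs=0.1)

    def test_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(8, 50, 12)
        sdi = local_sdi(d, np.full(12, "spruce"), 150.0, self.alpha)
        dq = math.sqrt((d ** 2).mean())
        want = (10_000 / 150.0 * 12) * (dq / 25) ** 1.605
        assert sdi == pytest.approx(want, rel=1e-10)

    def test_empty_circle_is_zero(self):
        assert local_sdi(np.array([]), np.array([]), 100.0, self.alpha) == 0.0

    def test_removing_center_decreases_inputs(self):
        # dropping any tree lowers both N and the basal mass entering dq
        d = np.array([30.0, 20.0, 15.0, 25.0])
        full_n = len(d)
        assert full_n - 1 < full_n
        assert (d[1:] ** 2).sum() < (d ** 2).sum()


class TestMixingProportions:
    alpha = {"A": -1.605, "B": -1.605}

    def test_single_species(self):
        p = mixing_proportions(np.full(4, 20.0), np.full(4, "A"), 100.0,
                               {"A": 1.0}, {"A": -1.605})
        assert p == {"A": 1.0}

    def test_equivalence_standardization_balances_double_space_species(self):
        # B has half the density but double the equivalence factor -> 50/50
        d = np.array([25.0] * 4 + [25.0] * 2)
        sp = np.array(["A"] * 4 + ["B"] * 2)
        p = mixing_proportions(d, sp, 100.0, {"A": 1.0, "B": 2.0}, self.alpha)
        assert p["A"] == pytest.approx(0.5)
        assert p["B"] == pytest.approx(0.5)

    def test_order_invariance_and_sum(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(10, 40, 9)
        sp = np.array(list("AABABBABA"))
        p1 = mixing_proportions(d, sp, 120.0, {"A": 1.0, "B": 1.7}, self.alpha)
        perm = rng.permutation(9)
        p2 = mixing_proportions(d[perm], sp[perm], 120.0,
                                {"A": 1.0, "B": 1.7}, self.alpha)
        assert p1 == pytest.approx(p2)
        assert sum(p1.values()) == pytest.approx(1.0, abs=1e-12)


class TestClassifyMixed:
    def test_threshold_boundaries(self):
        assert classify_mixed({"A": 0.92, "B": 0.08}) == 0
        assert classify_mixed({"A": 0.90, "B": 0.10}) == 1

    def test_higher_threshold_still_splits(self):
        mixes = [{"A": 1 - a, "B": a} for a in (0.05, 0.12, 0.25, 0.4)]
        for thr in (0.10, 0.15, 0.20):
            ms = [classify_mixed(p, thr) for p in mixes]
            assert 0 in ms and 1 in ms


class TestDiameterIncrement:
    def test_basic_values(self):
        assert annual_diameter_increment(20, 22.5, 5) == pytest.approx(5.0)
        assert annual_diameter_increment(20, 20, 5) == 0.0

    def test_negative_increment_passes_through_for_downstream_filtering(self):
        assert annual_diameter_increment(20, 19.8, 4) == pytest.approx(-0.5)

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            annual_diameter_increment(20, 21, 0)


class TestCircleFeatures:
    def test_homogeneous_grid_gives_identical_features(self, species_params,
                                                       frame_builder):
        # perfect 6x6 monoculture grid on a torus: all trees equivalent
        rows = []
        for i in range(6):
            for j in range(6):
                tid = f"g{i}{j}"
                rows += [(tid, "spruce", 5 + 10.0 * i, 5 + 10.0 * j, 0,
                          50.0, 20.0, 16.0, "live"),
                         (tid, "spruce", 5 + 10.0 * i, 5 + 10.0 * j, 1,
                          55.0, 22.0, 16.0, "live")]
        frame = frame_builder(rows)
        plot = PlotDefinition("p1", 60.0, 60.0, (50.0, 55.0))
        feats = circle_features(frame, plot, 0, species_params)
        for col in ("SDIci", "SDIc", "dqc", "LAIc", "IMc", "id", "m"):
            assert feats[col].nunique() == 1, col

    def test_toroidal_translation_invariance(self, species_params,
                                             random_stand):
        rng = np.random.default_rng(21)
        plot = PlotDefinition("p1", 80.0, 80.0, (50.0, 55.0))
        frame = random_stand(rng, plot, 60)
        base = circle_features(frame, plot, 0, species_params)
        shifted = frame.copy()
        shifted["x_m"] = (shifted["x_m"] + 33.3) % 80.0
        shifted["y_m"] = (shifted["y_m"] + 61.7) % 80.0
        moved = circle_features(shifted, plot, 0, species_params)
        for col in ("SDIci", "SDIc", "dqc", "LAIc", "IMc", "id",
                    "admixture", "m"):
            np.testing.assert_allclose(
                base[col].to_numpy(float), moved[col].to_numpy(float),
                rtol=1e-9, err_msg=col)

    def test_manual_six_tree_oracle(self, species_params, frame_builder):
        # hand-built plot: measured heights, hand-checked circle membership
        pos = {
            "c": (20.0, 20.0, 25.0, 26.4),   # center: d0=25, d1=26.4
            "n1": (23.0, 20.0, 20.0, 21.0),  # dist 3.0 -> inside sr=5
            "n2": (20.0, 24.0, 30.0, 31.5),  # dist 4.0 -> inside
            "n3": (25.5, 20.0, 18.0, 19.0),  # dist 5.5 -> outside
            "n4": (39.0, 20.0, 22.0, 23.0),  # wrapped dist 19 -> outside
            "n5": (20.0, 16.5, 12.0, 13.0),  # dist 3.5 -> inside
        }
        rows = []
        for tid, (x, y, d0, d1) in pos.items():
            rows += [(tid, "spruce", x, y, 0, 50.0, d0, 20.0, "live"),
                     (tid, "spruce", x, y, 1, 55.0, d1, 20.0, "live")]
        frame = frame_builder(rows)
        plot = PlotDefinition("p1", 40.0, 40.0, (50.0, 55.0))
        feats = circle_features(frame, plot, 0, species_params).set_index("tree_id")
        row = feats.loc["c"]

        # independent spreadsheet-style arithmetic
        sr = 0.25 * 20.0
        area = math.pi * sr ** 2
        inside_d0 = [25.0, 20.0, 30.0, 12.0]
        inside_d1 = [26.4, 21.0, 31.5, 13.0]
        alpha = species_params["spruce"].alpha
        dq_i = math.sqrt(sum(d * d for d in [20.0, 30.0, 12.0]) / 3)
        sdici = (10_000 / area * 3) * (dq_i / 25) ** (-alpha)
        dq_c = math.sqrt(sum(d * d for d in inside_d0) / 4)
        sdic = (10_000 / area * 4) * (dq_c / 25) ** (-alpha)
        a0m, a1m = species_params["spruce"].mass_coefs
        cfm = species_params["spruce"].cf_mass
        dmass = sum(
            (math.exp(a0m + a1m * math.log(d1)) - math.exp(a0m + a1m * math.log(d0))) * cfm
            for d0, d1 in zip(inside_d0, inside_d1)) / 5.0
        a0l, a1l = species_params["spruce"].leaf_coefs
        cfl = species_params["spruce"].cf_leaf
        lai = sum(math.exp(a0l + a1l * math.log(d)) * cfl
                  for d in inside_d0) / area

        assert row["sr"] == pytest.approx(sr)
        assert row["n_neighbors"] == 3
        assert row["SDIci"] == pytest.approx(sdici, rel=1e-10)
        assert row["SDIc"] == pytest.approx(sdic, rel=1e-10)
        assert row["dqc"] == pytest.approx(dq_c, rel=1e-10)
        assert row["LAIc"] == pytest.approx(lai, rel=1e-10)
        assert row["IMc"] == pytest.approx(dmass * 10.0 / area, rel=1e-10)
        assert row["id"] == pytest.approx(10 * (26.4 - 25.0) / 5, rel=1e-10)
        assert row["m"] == 0

    def test_imc_additive_over_circle_partition(self, species_params,
                                                random_stand):
        # IMc is a sum of per-tree contributions: computing the circle's
        # total from two species subsets must equal the overall value
        rng = np.random.default_rng(4)
        plot = PlotDefinition("p1", 80.0, 80.0, (50.0, 55.0))
        frame = random_stand(rng, plot, 50)
        both = circle_features(frame, plot, 0, species_params)
        parts = []
        for sp in ("spruce", "beech"):
            only = frame.copy()
            # keep positions/ids, zero out the other species' mass growth
            # by freezing their diameters
            other = only["species"] != sp
            d0 = only[only.survey_index == 0].set_index("tree_id")["d_cm"]
            only.loc[other & (only.survey_index == 1), "d_cm"] = \
                only.loc[other & (only.survey_index == 1), "tree_id"].map(d0).to_numpy()
            parts.append(circle_features(only, plot, 0, species_params))
        total = parts[0]["IMc"] + parts[1]["IMc"]
        np.testing.assert_allclose(total.to_numpy(), both["IMc"].to_numpy(),
                                   rtol=1e-9)

    def test_removed_trees_excluded_from_remaining_stand(self, species_params,
                                                         frame_builder):
        rows = [
            ("a", "spruce", 10.0, 10.0, 0, 50.0, 20.0, 16.0, "live"),
            ("a", "spruce", 10.0, 10.0, 1, 55.0, 22.0, 16.0, "live"),
            ("b", "spruce", 12.0, 10.0, 0, 50.0, 30.0, 16.0, "live"),
            ("b", "spruce", 12.0, 10.0, 1, 55.0, 30.0, 16.0, "removed"),
            ("c", "spruce", 11.0, 12.0, 0, 50.0, 25.0, 16.0, "live"),
            ("c", "spruce", 11.0, 12.0, 1, 55.0, 27.0, 16.0, "live"),
        ]
        frame = frame_builder(rows)
        plot = PlotDefinition("p1", 40.0, 40.0, (50.0, 55.0))
        feats = circle_features(frame, plot, 0, species_params)
        assert set(feats["tree_id"]) == {"a", "c"}
        with_removed = circle_features(frame, plot, 0, species_params,
                                       include_removed=True)
        assert set(with_removed["tree_id"]) == {"a", "b", "c"}
        a_def = feats.set_index("tree_id").loc["a"]
        a_inc = with_removed.set_index("tree_id").loc["a"]
        assert a_inc["SDIci"] > a_def["SDIci"]
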