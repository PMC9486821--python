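"""Covariate engineering: TRI, kernel density, distances, scaling, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point

from occomm import (
    Scaler,
    distance_to_access,
    retain_covariate,
    spearman_screen,
    terrain_ruggedness,
    village_density,
)


class TestTerrainRuggedness:
    def test_flat_terrain_is_zero(self):
        assert np.allclose(terrain_ruggedness(np.full((6, 7), 123.0), 3), 0.0)

    def test_center_cell_hand_value(self):
        # center 10, seven neighbours 10, one neighbour 18:
        # mean |difference| = 8/8 = 1.0
        g = np.full((3, 3), 10.0)
        g[0, 0] = 18.0
        assert terrain_ruggedness(g, 3)[1, 1] == pytest.approx(1.0)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.random((8, 8)) * 100
        base = terrain_ruggedness(g, 3)
        assert np.allclose(terrain_ruggedness(g + 57.0, 3), base)
        assert np.allclose(terrain_ruggedness(g * 2.5, 3), 2.5 * base)

    def test_edge_cells_use_available_neighbours(self):
        g = np.array([[0.0, 1.0], [1.0, 1.0]])
        # corner (0,0): neighbours 1,1,1 -> TRI 1
        assert terrain_ruggedness(g, 3)[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("window", [2, 1, 0, -3, 4])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            terrain_ruggedness(np.zeros((5, 5)), window)

    def test_window7_uses_wider_neighbourhood(self):
        g = np.zeros((9, 9))
        g[0, 0] = 48.0
        t3 = terrain_ruggedness(g, 3)
        t7 = terrain_ruggedness(g, 7)
        assert t3[4, 4] == 0.0 and t7[3, 3] > 0.0


class TestVillageDensity:
    def test_outside_radius_is_zero(self):
        assert village_density((0.0, 0.0), [(20000.0, 0.0)], 15000.0) == 0.0

    def test_quartic_shape_at_half_radius(self):
        # d/r = 0.5 -> (1 - 0.25)^2 = 0.5625
        v = village_density((0.0, 0.0), [(7500.0, 0.0)], 15000.0)
        assert v == pytest.approx(0.5625)

    def test_coincident_village_is_kernel_maximum(self):
        assert village_density((3.0, 4.0), [(3.0, 4.0)], 15000.0) == pytest.approx(1.0)

    def test_empty_village_set_is_zero(self):
        assert village_density((0.0, 0.0), np.empty((0, 2)), 15000.0) == 0.0

    def test_monotone_in_distance(self):
        ds = np.linspace(0, 14999, 50)
        vals = [village_density((0.0, 0.0), [(d, 0.0)]) for d in ds]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            village_density((0, 0), [(1, 1)], radius=0)


class TestDistanceToAccess:
    def test_point_on_road_segment(self):
        road = LineString([(0, 0), (10, 0)])
        assert distance_to_access((5.0, 0.0), [road]) == 0.0

    def test_pythagorean_distance(self):
        assert distance_to_access((3000.0, 4000.0), [Point(0, 0)]) == pytest.approx(5000.0)

    def test_distance_is_to_segment_interior_not_vertices(self):
        road = LineString([(-100, 10), (100, 10)])
        assert distance_to_access((0.0, 0.0), [road]) == pytest.approx(10.0)

    def test_adding_features_never_increases_distance(self):
        pts = (2.0, 7.0)
        d1 = distance_to_access(pts, [Point(50, 50)])
        d2 = distance_to_access(pts, [Point(50, 50), Point(100, 100)])
        assert d2 <= d1

    def test_empty_feature_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_access((0, 0), [])


class TestScaler:
    def test_scale_then_unscale_is_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.random(30) * 40, "b": rng.normal(5, 2, 30)})
        sc = Scaler.fit(df)
        out = sc.transform(df)
        assert abs(out["a"].mean()) < 1e-12 and abs(out["a"].std(ddof=0) - 1) < 1e-12
        back = sc.inverse(out)
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-10)

    def test_signature_round_trip(self, tmp_path):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        sc = Scaler.fit(df)
        sc.to_json(tmp_path / "s.json")
        assert Scaler.from_json(tmp_path / "s.json").signature() == sc.signature()

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            Scaler.fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


def _brute_spearman(x, y):
    """Rank-correlation oracle: Pearson correlation of midranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanScreen:
    def test_monotone_transform_has_rho_one(self):
        x = np.linspace(0, 3, 20)
        df = pd.DataFrame({"x": x, "expx": np.exp(x)})
        pairs = spearman_screen(df, 0.7)
        assert pairs == [("x", "expx", pytest.approx(1.0))]

    def test_hand_case_rho_point_six_not_flagged(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/60 = 0.6
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        assert spearman_screen(df, 0.7) == []
        assert _brute_spearman(df["x"], df["y"]) == pytest.approx(0.6)

    def test_agrees_with_rank_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 3))
        df = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": 0.9 * base[:, 0] + 0.1 * base[:, 1],
                "c": base[:, 1],
                "d": np.round(base[:, 2], 1),  # ties -> midranks
                "e": np.round(base[:, 2] + 0.05 * base[:, 0], 1),
            }
        )
        flagged = {(a, b): r for a, b, r in spearman_screen(df, 0.7)}
        from itertools import combinations

        for a, b in combinations(df.columns, 2):
            rho = _brute_spearman(df[a], df[b])
            if abs(rho) > 0.7:
                assert (a, b) in flagged
                assert flagged[(a, b)] == pytest.approx(rho, abs=1e-12)
            else:
                assert (a, b) not in flagged

    def test_constant_column_warned_and_excluded(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "k": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            assert spearman_screen(df, 0.7) == []

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError, match="3 stations"):
            spearman_screen(pd.DataFrame({"x": [1, 2], "y": [3, 4]}), 0.7)


def _support_table(strong, moderate, total=10):
    rows = ["strong"] * strong + ["moderate"] * moderate
    rows += ["weak"] * (total - len(rows))
    return pd.DataFrame({"support": rows})


class TestRetainCovariate:
    def test_majority_rule(self):
        chosen, counts = retain_covariate(
            ("SCI", "canopy"),
            {"SCI": _support_table(5, 0), "canopy": _support_table(2, 0)},
        )
        assert chosen == "SCI" and counts["SCI"] == (5, 0)

    def test_tie_broken_by_moderate_support(self):
        chosen, _ = retain_covariate(
            ("SCI", "canopy"),
            {"SCI": _support_table(3, 1), "canopy": _support_table(3, 4)},
        )
        assert chosen == "canopy"

    def test_full_tie_broken_alphabetically(self):
        chosen, _ = retain_covariate(
            ("zeta", "alpha"),
            {"zeta": _support_table(3, 3), "alpha": _support_table(3, 3)},
        )
        assert chosen == "alpha"


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0, 5000), min_size=1, max_size=6),
    st.floats(100, 20000),
)
def test_density_bounded_by_village_count(distances, radius):
    villages = [(d, 0.0) for d in distances]
    v = village_density((0.0, 0.0), villages, radius)
    assert 0.0 <= v <= len(villages)
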