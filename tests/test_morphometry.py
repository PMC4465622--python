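"""Geometry primitives, measure extraction, PCA screening and group tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from osteomorph import (
    AnnotatedLarva,
    angle,
    compare_measures,
    compare_measures_anova,
    distance,
    extract_measures,
    screen_measures_pca,
    triangle_area,
)
from osteomorph.synthetic import bone_template_coords

coords = st.floats(-1e4, 1e4, allow_nan=False)
points = st.tuples(coords, coords)


class TestGeometry:
    def test_distance_examples(self):
        assert distance((0, 0), (0, 0)) == 0.0
        assert distance((0, 0), (3, 4)) == 5.0

    @given(points, points)
    def test_distance_matches_coordinatewise_oracle(self, p, q):
        oracle = math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
        assert distance(p, q) == pytest.approx(oracle, abs=1e-9)
        assert distance(q, p) == distance(p, q)

    def test_angle_examples(self):
        assert angle((0, 0), (1, 0), (0, 1)) == pytest.approx(math.pi / 2)
        assert angle((0, 0), (1, 0), (2, 0)) == pytest.approx(0.0)

    def test_degenerate_angle_names_the_landmarks(self):
        with pytest.raises(ValueError, match="parasphenoid_b"):
            angle((0, 0), (0, 0), (1, 1), names=("parasphenoid_a", "parasphenoid_b", "parasphenoid_c"))

    def test_triangle_angles_sum_to_pi(self, rng):
        for _ in range(300):
            a, b, c = rng.uniform(-100, 100, size=(3, 2))
            if triangle_area(a, b, c) < 1e-6:
                continue
            total = angle(a, b, c) + angle(b, a, c) + angle(c, a, b)
            assert total == pytest.approx(math.pi, abs=1e-9)

    def test_area_examples(self):
        assert triangle_area((0, 0), (1, 0), (0, 1)) == 0.5
        assert triangle_area((0, 0), (1, 1), (2, 2)) == 0.0

    def test_area_matches_heron(self, rng):
        for _ in range(300):
            a, b, c = rng.uniform(-100, 100, size=(3, 2))
            x, y, z = distance(a, b), distance(b, c), distance(c, a)
            s = (x + y + z) / 2
            heron = math.sqrt(max(s * (s - x) * (s - y) * (s - z), 0.0))
            assert triangle_area(a, b, c) == pytest.approx(heron, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        for _ in range(100):
            pts = rng.uniform(-100, 100, size=(3, 2))
            theta = rng.uniform(0, 2 * math.pi)
            rot = np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
            shift = rng.uniform(-50, 50, size=2)
            moved = pts @ rot.T + shift
            assert distance(moved[0], moved[1]) == pytest.approx(
                distance(pts[0], pts[1]), rel=1e-9)
            assert triangle_area(*moved) == pytest.approx(
                triangle_area(*pts), rel=1e-9, abs=1e-9)
            if triangle_area(*pts) > 1e-6:
                assert angle(*moved) == pytest.approx(angle(*pts), abs=1e-9)

    def test_scaling_behaviour(self, rng):
        pts = rng.uniform(-10, 10, size=(3, 2))
        k = 3.7
        scaled = pts * k
        assert distance(scaled[0], scaled[1]) == pytest.approx(
            k * distance(pts[0], pts[1]), rel=1e-12)
        assert triangle_area(*scaled) == pytest.approx(
            k**2 * triangle_area(*pts), rel=1e-12)
        assert angle(*scaled) == pytest.approx(angle(*pts), abs=1e-12)


class TestExtractMeasures:
    def test_complete_bone_larva_yields_13_values(self, bone_larva, ontologies):
        table = extract_measures([bone_larva], ontologies["bone_29"])
        values = table.drop(columns="condition")
        assert values.shape == (1, 13)
        assert values.notna().all().all()

    def test_missing_landmark_voids_only_its_measures(self, ontologies):
        coords = dict(bone_template_coords())
        del coords["maxilla_up"]
        larva = AnnotatedLarva("L1", "c", "alizarin_red", coords)
        table = extract_measures([larva], ontologies["bone_29"])
        assert np.isnan(table.loc["L1", "maxilla_down_to_maxilla_up"])
        others = table.drop(columns=["condition", "maxilla_down_to_maxilla_up"])
        assert others.notna().all().all()

    def test_row_and_column_order(self, ontologies):
        base = bone_template_coords()
        larvae = [
            AnnotatedLarva(f"L{i}", "c", "alizarin_red", dict(base)) for i in range(20)
        ]
        table = extract_measures(larvae, ontologies["bone_29"])
        assert list(table.index) == [f"L{i}" for i in range(20)]
        assert list(table.columns[1:]) == [m.name for m in ontologies["bone_29"].measures]
        # permuting larvae permutes rows only
        perm = extract_measures(larvae[::-1], ontologies["bone_29"])
        assert perm.loc["L3"].equals(table.loc["L3"])

    def test_stain_mismatch_warns_but_proceeds(self, ontologies):
        larva = AnnotatedLarva("L1", "c", "alizarin_red", bone_template_coords())
        with pytest.warns(UserWarning, match="stain"):
            table = extract_measures([larva], ontologies["cartilage_21"])
        assert len(table) == 1


class TestPcaScreening:
    def _table(self, rng, n=40):
        import pandas as pd

        sig1 = rng.normal(0, 3, n)
        sig2 = rng.normal(0, 2, n)
        df = pd.DataFrame({"condition": "c", "s1": sig1, "s2": sig2})
        return df

    def test_constant_column_dropped(self, rng):
        df = self._table(rng)
        df["flat"] = 7.0
        retained = screen_measures_pca(df)
        assert "flat" not in retained
        assert {"s1", "s2"} <= set(retained)

    def test_duplicated_column_drops_exactly_one(self, rng):
        df = self._table(rng)
        df["s1_copy"] = df["s1"]
        retained = screen_measures_pca(df)
        assert len({"s1", "s1_copy"} & set(retained)) == 1

    def test_cluster_representatives(self, rng):
        # two independent signals, each with 3 slightly noisy copies
        import pandas as pd

        n = 60
        s1, s2 = rng.normal(0, 3, n), rng.normal(0, 3, n)
        cols = {"condition": "c"}
        for i in range(3):
            cols[f"a{i}"] = s1 + rng.normal(0, 0.05, n)
            cols[f"b{i}"] = s2 + rng.normal(0, 0.05, n)
        retained = screen_measures_pca(pd.DataFrame(cols))
        assert len(retained) <= 4
        # exhaustive check: one representative per correlated cluster
        assert any(c.startswith("a") for c in retained)
        assert any(c.startswith("b") for c in retained)

    def test_requires_three_complete_rows(self, rng):
        df = self._table(rng, n=2)
        with pytest.raises(ValueError, match="complete rows"):
            screen_measures_pca(df)


class TestGroupComparisons:
    def _table_from_scores(self, a, b, name="m"):
        import pandas as pd

        return pd.DataFrame(
            {
                "condition": ["A"] * len(a) + ["B"] * len(b),
                name: np.concatenate([a, b]),
            }
        )

    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(10, 1, 30)
        table = self._table_from_scores(x, x.copy())
        res = compare_measures(table, "A", "B")
        assert res.loc["m", "p"] == pytest.approx(1.0)
        assert res.loc["m", "stars"] == ""

    def test_absent_group_errors(self, rng):
        table = self._table_from_scores(rng.normal(size=5), rng.normal(size=5))
        with pytest.raises(ValueError, match="absent"):
            compare_measures(table, "A", "Z")

    def test_type_I_error_rate_at_alpha_05(self, rng):
        reps, n = 10_000, 20
        a = rng.normal(0, 1, size=(n, reps))
        b = rng.normal(0, 1, size=(n, reps))
        _, p = stats.ttest_ind(a, b, equal_var=False, axis=0)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06

    def test_power_at_two_sd_shift(self, rng):
        reps, n = 2_000, 20
        a = rng.normal(0, 1, size=(n, reps))
        b = rng.normal(2.0, 1, size=(n, reps))
        _, p = stats.ttest_ind(a, b, equal_var=False, axis=0)
        assert float(np.mean(p < 0.05)) > 0.99

    def test_anova_equals_squared_t_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 17)
        table = self._table_from_scores(a, b)
        f_res = compare_measures_anova(table, ["A", "B"])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert f_res.loc["m", "F"] == pytest.approx(t**2, abs=1e-9)

    def test_anova_identical_groups(self, rng):
        x = rng.normal(5, 1, 20)
        import pandas as pd

        table = pd.DataFrame(
            {"condition": ["A"] * 20 + ["B"] * 20 + ["C"] * 20,
             "m": np.concatenate([x, x, x])}
        )
        res = compare_measures_anova(table, ["A", "B", "C"])
        assert res.loc["m", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["m", "stars"] == ""

    def test_anova_type_I_error(self, rng):
        reps, n = 10_000, 10
        groups = [rng.normal(0, 1, size=(n, reps)) for _ in range(3)]
        _, p = stats.f_oneway(*groups, axis=0)
        rate = float(np.mean(p < 0.05))
        assert 0.04 <= rate <= 0.06
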