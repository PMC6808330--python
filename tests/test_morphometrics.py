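"""Outline resampling, GPA, CVA, polygon area, morphotype classification."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st

from cyclodelim import (
    Outline,
    OutlineGroupConfig,
    OutlineSimConfig,
    SemiLandmarkSet,
    SpecimenRecord,
    classify_morphotype,
    cva,
    gen_outlines,
    gpa,
    polygon_area,
    procrustes_distance,
    read_tps,
    resample_outline,
    size_summary,
    write_tps,
)
from cyclodelim.exceptions import InputError
from cyclodelim.morphometrics import _signed_area


def circle_outline(n=1000, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline("circle", np.column_stack([r * np.cos(th), r * np.sin(th)]))


class TestResampleOutline:
    def test_unit_circle_stays_on_circle(self):
        s = resample_outline(circle_outline(), 200)
        radii = np.linalg.norm(s.points, axis=1)
        assert np.all(np.abs(radii - 1.0) < 1e-3)
        # uniform angular gaps
        ang = np.unwrap(np.arctan2(s.points[:, 1], s.points[:, 0]))
        gaps = np.diff(ang)
        assert np.all(np.abs(gaps - gaps[0]) < 1e-3)

    def test_equally_spaced_input_is_fixed_point(self):
        k = 16
        th = np.linspace(0, 2 * np.pi, k, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        s = resample_outline(Outline("fp", pts, start_index=0), k)
        assert np.abs(s.points - pts).max() < 1e-9

    def test_clockwise_input_normalized_to_ccw(self):
        square_cw = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        s = resample_outline(Outline("sq", square_cw), 4)
        assert _signed_area(s.points) > 0

    def test_default_start_is_rightmost_point(self):
        s = resample_outline(circle_outline(), 8)
        assert s.points[0] == pytest.approx([1.0, 0.0])

    def test_degenerate_outline_rejected(self):
        with pytest.raises(InputError, match="perimeter"):
            resample_outline(Outline("z", np.zeros((5, 2))), 10)


class TestGPA:
    def test_similarity_transformed_copy_has_zero_distance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(40, 2))
        ang = np.deg2rad(37.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        copy = 3.0 * (base @ rot) + np.array([5.0, -2.0])
        assert procrustes_distance(base, copy) < 1e-9

    def test_reflection_not_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 2))
        mirrored = base * np.array([-1.0, 1.0])
        assert procrustes_distance(base, mirrored) > 1e-3

    def test_consensus_is_aligned_mean(self):
        rng = np.random.default_rng(2)
        sets = [SemiLandmarkSet(f"s{i}", rng.normal(size=(30, 2))) for i in range(3)]
        space = gpa(sets)
        assert space.converged
        mean = space.aligned.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= np.sqrt((mean ** 2).sum())
        np.testing.assert_allclose(space.consensus, mean, atol=1e-6)

    def test_invariant_to_input_similarity_transforms(self):
        rng = np.random.default_rng(3)
        raw = [rng.normal(size=(25, 2)) for _ in range(4)]
        sets1 = [SemiLandmarkSet(f"s{i}", p) for i, p in enumerate(raw)]
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        sets2 = [
            SemiLandmarkSet(f"s{i}", 2.5 * (p @ rot) + 7.0)
            for i, p in enumerate(raw)
        ]
        a1, a2 = gpa(sets1).aligned, gpa(sets2).aligned
        d = [procrustes_distance(x, y) for x, y in zip(a1, a2)]
        assert max(d) < 1e-6

    def test_aligned_configs_standardized(self):
        # unrelated gaussian "shapes" are a worst case for the consensus
        # iteration, hence the raised iteration cap
        rng = np.random.default_rng(4)
        sets = [SemiLandmarkSet(f"s{i}", rng.normal(size=(20, 2)) + i) for i in range(3)]
        space = gpa(sets, max_iter=300)
        assert space.converged
        for cfg in space.aligned:
            assert np.abs(cfg.mean(axis=0)).max() < 1e-9
            assert np.sqrt((cfg ** 2).sum()) == pytest.approx(1.0)

    def test_non_convergence_flags_partial_result(self):
        rng = np.random.default_rng(4)
        sets = [SemiLandmarkSet(f"s{i}", rng.normal(size=(20, 2)) + i) for i in range(3)]
        with pytest.warns(RuntimeWarning, match="did not converge"):
            space = gpa(sets, max_iter=2)
        assert not space.converged


class TestCVA:
    def _space(self, cfg):
        outs, labels, _ = gen_outlines(cfg)
        sets = [resample_outline(o, 80) for o in outs]
        return gpa(sets), labels

    def test_three_groups_two_axes(self):
        cfg = OutlineSimConfig(
            groups=(
                OutlineGroupConfig("A", aspect=0.80, spire=0.10, n=6),
                OutlineGroupConfig("B", aspect=1.00, spire=0.20, n=6),
                OutlineGroupConfig("C", aspect=0.90, spire=0.30, n=6),
            ),
            noise_sd_mm=0.3,
            seed=1,
        )
        space, labels = self._space(cfg)
        res = cva(space, labels)
        assert res.n_axes == 2
        assert res.percents.sum() == pytest.approx(100.0)

    def test_two_groups_single_axis_explains_all(self):
        cfg = OutlineSimConfig(
            groups=(
                OutlineGroupConfig("A", aspect=0.80, n=8),
                OutlineGroupConfig("B", aspect=1.10, n=8),
            ),
            noise_sd_mm=0.2,
            seed=2,
        )
        space, labels = self._space(cfg)
        res = cva(space, labels)
        assert res.n_axes == 1
        assert res.percents[0] == pytest.approx(100.0)

    def test_matches_dense_eigen_oracle(self):
        cfg = OutlineSimConfig(
            groups=(
                OutlineGroupConfig("A", aspect=0.80, spire=0.10, n=5),
                OutlineGroupConfig("B", aspect=1.00, spire=0.25, n=5),
                OutlineGroupConfig("C", aspect=0.90, spire=0.35, n=5),
            ),
            noise_sd_mm=0.4,
            seed=3,
        )
        space, labels = self._space(cfg)
        res = cva(space, labels)
        # oracle: explicit matrices in the PCA space, plain (non-symmetric)
        # eigensolver on W^-1 B
        n, k, _ = space.aligned.shape
        ids = space.specimen_ids
        groups = [labels[i] for i in ids]
        X = space.aligned.reshape(n, 2 * k)
        X = X - X.mean(axis=0)
        g = len(set(groups))
        r = min(n - g, 2 * k - 4)
        _, sv, vt = np.linalg.svd(X, full_matrices=False)
        Z = X @ vt[: min(r, (sv > sv[0] * 1e-10).sum())].T
        grand = Z.mean(axis=0)
        W = np.zeros((Z.shape[1],) * 2)
        B = np.zeros_like(W)
        for gname in set(groups):
            idx = [i for i, lab in enumerate(groups) if lab == gname]
            dev = Z[idx] - Z[idx].mean(axis=0)
            W += dev.T @ dev
            dm = (Z[idx].mean(axis=0) - grand)[:, None]
            B += len(idx) * dm @ dm.T
        W /= n - g
        B /= g - 1
        ev = np.sort(np.real(scipy.linalg.eig(np.linalg.solve(W, B))[0]))[::-1]
        np.testing.assert_allclose(res.eigenvalues, ev[: res.n_axes], rtol=1e-6)

    def test_group_of_one_rejected(self):
        rng = np.random.default_rng(5)
        sets = [SemiLandmarkSet(f"s{i}", rng.normal(size=(20, 2))) for i in range(5)]
        space = gpa(sets)
        labels = {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C"}
        with pytest.raises(InputError, match="C"):
            cva(space, labels)


class TestPolygonArea:
    def test_unit_square(self):
        sq = SemiLandmarkSet("sq", np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        assert polygon_area(sq) == 1.0

    def test_regular_200_gon_closed_form(self):
        s = resample_outline(circle_outline(), 200)
        assert polygon_area(s) == pytest.approx(100 * np.sin(2 * np.pi / 200), abs=1e-5)

    def test_orientation_invariant(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        cw = SemiLandmarkSet("cw", pts[::-1])
        assert polygon_area(cw) == 1.0

    def test_rotation_translation_invariant_scale_quadratic(self):
        rng = np.random.default_rng(6)
        s = resample_outline(circle_outline(), 50)
        a0 = polygon_area(s)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = SemiLandmarkSet("m", s.points @ rot + 11.0)
        scaled = SemiLandmarkSet("x", 3.0 * s.points)
        assert polygon_area(moved) == pytest.approx(a0)
        assert polygon_area(scaled) == pytest.approx(9.0 * a0)

    def test_self_intersection_warns(self):
        bow = SemiLandmarkSet("bow", np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]]))
        with pytest.warns(RuntimeWarning, match="self-intersecting"):
            polygon_area(bow)


class TestMorphotypeClassifier:
    @pytest.mark.parametrize(
        "sid,h,b,expected",
        [
            ("VNM022", 24.8, 29.0, "widespread"),
            ("VNM023", 22.6, 26.3, "slightly_deviating"),
            ("VNM019", 32.2, 39.0, "deviating"),
            ("VNM045", 21.8, 25.1, "deviating"),
            ("boundary-low", 23.0, 28.0, "widespread"),
            ("boundary-high", 31.0, 35.0, "widespread"),
            ("slight-edge", 21.0, 26.0, "slightly_deviating"),
            ("deviating-edge", 20.9, 30.0, "deviating"),
        ],
    )
    def test_interval_rule(self, sid, h, b, expected):
        assert classify_morphotype(SpecimenRecord(sid, h, b)) == expected

    @given(
        st.floats(min_value=0.1, max_value=60, allow_nan=False),
        st.floats(min_value=0.1, max_value=60, allow_nan=False),
    )
    def test_every_measurement_maps_to_exactly_one_class(self, h, b):
        label = classify_morphotype(SpecimenRecord("x", h, b))
        in_wide = 23 <= h <= 31 and 28 <= b <= 35
        in_dev = h < 21 or h > 33 or b < 26 or b > 37
        if in_dev:
            assert label == "deviating"
        elif in_wide:
            assert label == "widespread"
        else:
            assert label == "slightly_deviating"

    def test_missing_measurement_rejected(self):
        with pytest.raises(InputError):
            classify_morphotype(SpecimenRecord("x", float("nan"), 30.0))


class TestSizeSummary:
    def test_five_number_summary(self):
        out = size_summary([1, 2, 3, 4, 5], ["g"] * 5)
        row = out.loc["g"]
        assert (row["min"], row.q1, row["median"], row.q3, row["max"]) == (1, 2, 3, 4, 5)

    def test_single_value_group(self):
        row = size_summary([7.0], ["g"]).loc["g"]
        assert row["min"] == row["median"] == row["max"] == 7.0

    def test_planted_size_shift_orders_medians(self):
        cfg = OutlineSimConfig(
            groups=(
                OutlineGroupConfig("small", breadth_mean_mm=25.0, breadth_sd_mm=1.0, n=10),
                OutlineGroupConfig("large", breadth_mean_mm=35.0, breadth_sd_mm=1.0, n=10),
            ),
            seed=7,
        )
        outs, labels, _ = gen_outlines(cfg)
        areas = [polygon_area(resample_outline(o, 100)) for o in outs]
        out = size_summary(areas, [labels[o.specimen_id] for o in outs])
        assert out.loc["small", "median"] < out.loc["large", "median"]


class TestTpsIO:
    def test_roundtrip(self, tmp_path):
        outs, _, _ = gen_outlines(
            OutlineSimConfig(groups=(OutlineGroupConfig("A", n=2),), seed=0)
        )
        path = tmp_path / "o.tps"
        write_tps(outs, path)
        again = read_tps(path)
        assert [o.specimen_id for o in again] == [o.specimen_id for o in outs]
        np.testing.assert_allclose(again[0].points, outs[0].points, atol=1e-6)
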