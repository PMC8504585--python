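import numpy as np
import pytest

from geldose import (
    DoseGrid,
    FiducialSet,
    GridGeometry,
    RigidTransform,
    normalize_to_isocenter,
    resample_grid,
    rigid_from_fiducials,
)
from geldose.dose_mapping import load_transform, read_fiducials_csv, save_transform


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


FIDUCIALS = np.array(
    [[0.0, 0.0, 0.0], [30.0, 0.0, 0.0], [0.0, 40.0, 0.0], [0.0, 0.0, 25.0], [15.0, 20.0, 5.0]]
)
LABELS = ("circle", "square", "triangle", "rod", "notch")


class TestRigidFromFiducials:
    def test_identical_point_sets_give_identity(self):
        fid = FiducialSet(LABELS, FIDUCIALS, FIDUCIALS)
        transform, fre = rigid_from_fiducials(fid)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-12)
        assert fre == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_plus_translation_recovered_exactly(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([5.0, 0.0, 0.0])
        planned = FIDUCIALS @ Rz.T + t
        transform, fre = rigid_from_fiducials(FiducialSet(LABELS, FIDUCIALS, planned))
        np.testing.assert_allclose(transform.rotation, Rz, atol=1e-9)
        np.testing.assert_allclose(transform.translation, t, atol=1e-9)
        assert fre < 1e-9

    def test_random_rigid_transforms_recovered(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            R = _random_rotation(rng)
            t = rng.uniform(-50, 50, 3)
            pts = rng.uniform(-40, 40, (4, 3))
            fid = FiducialSet(("a", "b", "c", "d"), pts, pts @ R.T + t)
            transform, fre = rigid_from_fiducials(fid)
            assert np.linalg.norm(transform.rotation - R) < 1e-9
            assert np.linalg.norm(transform.translation - t) < 1e-9
            assert fre < 1e-9

    def test_noisy_fiducials_fre_within_monte_carlo_expectation(self):
        rng_mc = np.random.default_rng(100)
        sd = 0.5

        def one_fre(rng):
            noisy = FIDUCIALS + rng.normal(0, sd, FIDUCIALS.shape)
            return rigid_from_fiducials(FiducialSet(LABELS, FIDUCIALS, noisy))[1]

        expectation = np.mean([one_fre(rng_mc) for _ in range(500)])
        fre = one_fre(np.random.default_rng(9))
        assert fre < 3 * expectation

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            rigid_from_fiducials(FiducialSet(("a", "b", "c"), pts, pts))

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label"):
            FiducialSet(("a", "b"), FIDUCIALS[:3], FIDUCIALS[:3])

    def test_transform_json_round_trip(self, tmp_path):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        tr = RigidTransform(Rz, np.array([1.0, 2.0, 3.0]))
        save_transform(tr, tmp_path / "t.json", fre=0.1)
        back = load_transform(tmp_path / "t.json")
        np.testing.assert_allclose(back.rotation, tr.rotation)
        np.testing.assert_allclose(back.translation, tr.translation)

    def test_fiducial_csv_round_trip(self, tmp_path):
        import pandas as pd

        rows = []
        for lbl, m, p in zip(LABELS, FIDUCIALS, FIDUCIALS + 2.0):
            rows.append({"label": lbl, "frame": "measured", "x": m[0], "y": m[1], "z": m[2]})
            rows.append({"label": lbl, "frame": "planned", "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(rows).to_csv(tmp_path / "f.csv", index=False)
        fid = read_fiducials_csv(tmp_path / "f.csv")
        transform, fre = rigid_from_fiducials(fid)
        np.testing.assert_allclose(transform.translation, 2.0, atol=1e-9)
        assert fre < 1e-9


class TestResample:
    def _grid(self, rng, shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)):
        geom = GridGeometry(shape, spacing, (0.0, 0.0, 0.0))
        return DoseGrid(geom, rng.random(shape))

    def test_identity_resampling_is_exact(self):
        grid = self._grid(np.random.default_rng(0))
        out, mask = resample_grid(grid, RigidTransform.identity(), grid.geometry)
        np.testing.assert_allclose(out.values, grid.values, atol=1e-12)
        assert mask.all()

    def test_one_voxel_translation_shifts_values(self):
        grid = self._grid(np.random.default_rng(1))
        shift = RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))  # one x pitch
        out, mask = resample_grid(grid, shift, grid.geometry)
        np.testing.assert_allclose(out.values[1:, :, :], grid.values[:-1, :, :], atol=1e-12)
        assert not mask[0].any() and mask[1:].all()

    def test_matches_brute_force_trilinear_loop(self):
        rng = np.random.default_rng(2)
        src = self._grid(rng)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        tr = RigidTransform(Rz, np.array([3.0, -1.0, 0.5]))
        target = GridGeometry((6, 6, 6), (2.5, 2.5, 2.5), (-2.0, -2.0, 1.0))
        out, mask = resample_grid(src, tr, target)

        inv_R, inv_t = tr.rotation.T, -tr.rotation.T @ tr.translation
        sg = src.geometry
        for idx in np.ndindex(target.shape):
            world = np.asarray(target.origin) + np.asarray(idx) * np.asarray(target.spacing)
            s = inv_R @ world + inv_t
            f = (s - np.asarray(sg.origin)) / np.asarray(sg.spacing)
            if np.any(f < 0) or np.any(f > np.asarray(sg.shape) - 1):
                assert not mask[idx]
                continue
            i0 = np.floor(f).astype(int)
            i0 = np.minimum(i0, np.asarray(sg.shape) - 2)
            w = f - i0
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        wgt = (
                            (w[0] if dx else 1 - w[0])
                            * (w[1] if dy else 1 - w[1])
                            * (w[2] if dz else 1 - w[2])
                        )
                        acc += wgt * src.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            assert out.values[idx] == pytest.approx(acc, abs=1e-6)

    def test_resampling_is_linear_in_source_values(self):
        rng = np.random.default_rng(3)
        a, b = self._grid(rng), self._grid(rng)
        tr = RigidTransform(np.eye(3), np.array([0.7, -0.3, 1.1]))
        summed = DoseGrid(a.geometry, a.values + b.values)
        out_sum, _ = resample_grid(summed, tr, a.geometry)
        out_a, _ = resample_grid(a, tr, a.geometry)
        out_b, _ = resample_grid(b, tr, a.geometry)
        np.testing.assert_allclose(out_sum.values, out_a.values + out_b.values, atol=1e-12)


class TestNormalization:
    def test_uniform_grid_normalizes_to_one(self):
        geom = GridGeometry((6, 6, 6), (2, 2, 2), (-5, -5, -5))
        out = normalize_to_isocenter(DoseGrid(geom, np.full((6, 6, 6), 2.0)), (0, 0, 0))
        np.testing.assert_allclose(out.values, 1.0)
        assert out.normalized and out.normalization_value == pytest.approx(2.0)

    def test_voxel_at_half_isocenter_dose_maps_to_half(self):
        geom = GridGeometry((6, 6, 6), (2, 2, 2), (-5, -5, -5))
        vals = np.full((6, 6, 6), 2.0)
        vals[0, 0, 0] = 1.0
        out = normalize_to_isocenter(DoseGrid(geom, vals), (0, 0, 0), averaging_radius=2.0)
        assert out.values[0, 0, 0] == pytest.approx(0.5)

    def test_normalization_is_idempotent(self, box_dose):
        once = normalize_to_isocenter(box_dose, (0, 0, 0))
        twice = normalize_to_isocenter(once, (0, 0, 0))
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
        assert twice.normalization_value == once.normalization_value

    def test_synthetic_box_plan_isocenter_normalizes_to_one(self, box_dose):
        normed = normalize_to_isocenter(box_dose, (0, 0, 0))
        iso_idx = normed.geometry.nearest_voxel((0.0, 0.0, 0.0))
        assert normed.values[iso_idx] == pytest.approx(1.0, rel=5e-3)

    def test_error_cases(self):
        geom = GridGeometry((4, 4, 4), (1, 1, 1))
        grid = DoseGrid(geom, np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="outside"):
            normalize_to_isocenter(grid, (100, 0, 0))
        with pytest.raises(ValueError, match="normalize"):
            normalize_to_isocenter(grid, (1, 1, 1))
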