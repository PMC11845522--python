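"""Domain types, geometry conventions and file round trips."""

import numpy as np
import pytest
import SimpleITK as sitk
from hypothesis import given, settings
from hypothesis import strategies as st

from labnorm import (
    LandmarkTriplet,
    RatingRecord,
    RigidTransform,
    Volume,
    read_landmarks,
    read_ratings,
    read_transform,
    read_volume,
    write_landmarks,
    write_ratings,
    write_transform,
    write_volume,
)


class TestVolume:
    def test_validation(self):
        with pytest.raises(ValueError, match="3D"):
            Volume(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="spacing"):
            Volume(np.zeros((4, 4, 4)), (1, 0, 1))
        with pytest.raises(ValueError, match="orthonormal"):
            Volume(np.zeros((4, 4, 4)), (1, 1, 1), direction=np.eye(3) * 2)

    def test_index_physical_round_trip(self, small_volume):
        idx = np.array([[0, 0, 0], [3, 2, 1], [7, 7, 7]], float)
        pts = small_volume.index_to_physical(idx)
        back = small_volume.physical_to_index(pts)
        np.testing.assert_allclose(back, idx, atol=1e-12)

    def test_physical_center_of_symmetric_grid(self):
        v = Volume(np.zeros((5, 5, 5)), (2, 2, 2), origin=(-4, -4, -4))
        np.testing.assert_allclose(v.physical_center(), [0, 0, 0], atol=1e-12)


class TestVolumeIO:
    def test_round_trip_identity(self, tmp_path, rng):
        vol = Volume(
            rng.normal(size=(8, 8, 8)),
            (0.5, 0.5, 0.5),
            origin=(1.5, -2.0, 3.25),
        )
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=1e-6)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)
        np.testing.assert_allclose(back.direction, vol.direction, atol=1e-6)

    def test_integer_data_lossless(self, tmp_path, rng):
        vol = Volume(rng.integers(0, 1000, (6, 6, 6)).astype(np.int32), (1, 1, 1))
        path = tmp_path / "i.nii.gz"
        write_volume(vol, path)
        assert read_volume(path).voxels.sum() == vol.voxels.sum()

    def test_anisotropic_spacing_survives(self, tmp_path):
        vol = Volume(np.zeros((4, 4, 4)), (0.5, 0.5, 1.0))
        path = tmp_path / "a.nii.gz"
        write_volume(vol, path)
        np.testing.assert_allclose(read_volume(path).spacing, [0.5, 0.5, 1.0], atol=1e-6)

    def test_half_millimetre_isotropic_header(self, tmp_path):
        vol = Volume(np.zeros((4, 4, 4)), (0.5, 0.5, 0.5))
        path = tmp_path / "s.nii.gz"
        write_volume(vol, path)
        np.testing.assert_allclose(read_volume(path).spacing, [0.5, 0.5, 0.5])

    def test_4d_image_rejected(self, tmp_path):
        img4 = sitk.GetImageFromArray(np.zeros((2, 3, 3, 3), dtype=np.float32))
        path = tmp_path / "v4.nii.gz"
        sitk.WriteImage(img4, str(path))
        with pytest.raises(ValueError, match="4D"):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")


class TestRigidTransform:
    def test_rejects_scaling_and_reflection(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.1)
        with pytest.raises(ValueError, match="reflection"):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_compose_and_inverse_close_over_rigid(self, seed):
        rng = np.random.default_rng(seed)
        a = RigidTransform.from_euler(rng.uniform(-90, 90, 3), rng.uniform(-10, 10, 3))
        b = RigidTransform.from_euler(rng.uniform(-90, 90, 3), rng.uniform(-10, 10, 3), center=(1, 2, 3))
        ab = a.compose(b)  # constructor re-validates rigidity
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(ab.apply(pts), a.apply(b.apply(pts)), atol=1e-9)
        ident = ab.compose(ab.inverse())
        assert ident.is_identity(rot_tol_deg=1e-9, trans_tol_mm=1e-9)
        assert np.linalg.det(ab.rotation) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
        trans=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    def test_inverse_undoes_any_rigid_motion(self, angles, trans):
        t = RigidTransform.from_euler(angles, trans)
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [-4.0, 5.0, -6.0]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_center_folding(self):
        t = RigidTransform.from_euler((0, 0, 90), (0, 0, 0), center=(1, 0, 0))
        # rotating about (1,0,0): the center itself is fixed
        np.testing.assert_allclose(t.apply([1, 0, 0]), [1, 0, 0], atol=1e-12)

    def test_transform_file_round_trip(self, tmp_path):
        t = RigidTransform.from_euler((10, 20, 30), (1.5, -2.5, 3.5), center=(0.5, 0, -1))
        path = tmp_path / "t.tfm"
        write_transform(t, path)
        back = read_transform(path)
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-15)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-15)
        np.testing.assert_allclose(back.center, t.center, atol=1e-15)


class TestLandmarks:
    def test_file_round_trip(self, tmp_path):
        lm = LandmarkTriplet((1.25, -2.5, 3.0), (4.0, 5.5, -6.0), (-7.0, 8.0, 9.75))
        path = tmp_path / "lm.csv"
        write_landmarks(lm, path)
        back = read_landmarks(path)
        np.testing.assert_allclose(back.as_array(), lm.as_array(), atol=1e-15)

    def test_missing_row_names_the_landmark(self, tmp_path):
        path = tmp_path / "lm.csv"
        path.write_text("name,x_mm,y_mm,z_mm\nposterior_scc_lateral,0,0,0\nsuperior_scc_apex,1,0,0\n")
        with pytest.raises(ValueError, match="cochlea_apex"):
            read_landmarks(path)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            LandmarkTriplet((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "lm.csv"
        path.write_text(
            "name,x_mm,y_mm,z_mm\nposterior_scc_lateral,0,0,0\nposterior_scc_lateral,1,0,0\n"
            "superior_scc_apex,0,1,0\ncochlea_apex,0,0,1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_landmarks(path)


class TestRatings:
    def test_half_step_grade_parsed(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("dataset_id,method,rater_id,grade\nd001,TIE,EK,2.5\n")
        (rec,) = read_ratings(path)
        assert rec == RatingRecord("d001", "TIE", "EK", 2.5)

    @pytest.mark.parametrize("bad,msg", [(6.5, "outside"), (2.25, "half-step"), (0.5, "outside")])
    def test_invalid_grades_rejected(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            RatingRecord("d", "TIE", "r", bad)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            RatingRecord("d", "SPM", "r", 2.0)

    def test_ratings_file_round_trip_and_duplicates(self, tmp_path):
        recs = [RatingRecord("d1", "3P", "a", 1.5), RatingRecord("d1", "TIE", "a", 5.0)]
        path = tmp_path / "r.csv"
        write_ratings(recs, path)
        assert read_ratings(path) == recs
        path.write_text(
            "dataset_id,method,rater_id,grade\nd1,TIE,a,2.0\nd1,TIE,a,3.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_ratings(path)
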