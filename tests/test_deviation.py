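import numpy as np
import pytest
import trimesh

from maxillomorph.deviation import (
    DeviationError,
    DeviationField,
    false_color,
    sample_region,
    signed_deviation,
    summarize_region,
)
from maxillomorph.phantom import PhantomSpec, synthesize_subject

from conftest import zero_offsets


def planar_square(n=10, size=10.0):
    """Flat square of area size^2 in the z=0 plane, normals +z."""
    g = np.linspace(0, size, n + 1)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)
    faces = []
    for i in range(n):
        for j in range(n):
            v00, v10, v01, v11 = (
                i * (n + 1) + j,
                (i + 1) * (n + 1) + j,
                i * (n + 1) + j + 1,
                (i + 1) * (n + 1) + j + 1,
            )
            faces += [[v00, v10, v11], [v00, v11, v01]]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


class TestSampleRegion:
    def test_single_right_triangle(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        s = sample_region(tri, [0])
        assert len(s.points) == 1
        assert s.area_weights[0] == pytest.approx(0.5)
        assert abs(s.normals[0][2]) == pytest.approx(1.0)

    def test_area_weights_sum_to_region_area(self):
        square = planar_square()
        s = sample_region(square, np.arange(len(square.faces)))
        assert s.area_weights.sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_region_rejected(self, sphere_pair):
        with pytest.raises(DeviationError):
            sample_region(sphere_pair[0], [])


class TestSignedDeviation:
    def test_identical_meshes_give_zero(self, sphere_pair):
        ref, _ = sphere_pair
        s = sample_region(ref, np.arange(0, len(ref.faces), 7))
        f = signed_deviation(s, ref)
        assert f.valid.all()
        assert np.allclose(f.d, 0.0, atol=1e-9)

    def test_concentric_sphere_oracle(self, sphere_pair):
        """Subject sphere 2 mm outside the reference: d = -2 everywhere."""
        ref, subj = sphere_pair
        cap = np.flatnonzero(ref.triangles_center[:, 2] > 15.0)
        f = signed_deviation(sample_region(ref, cap), subj)
        assert f.valid.all()
        assert np.allclose(f.d, -2.0, atol=0.02)

    def test_window_invalidates_larger_deviation(self, sphere_pair):
        ref, _ = sphere_pair
        subj = trimesh.creation.icosphere(subdivisions=4, radius=36.0)
        cap = np.flatnonzero(ref.triangles_center[:, 2] > 15.0)
        f = signed_deviation(sample_region(ref, cap), subj, window=5.0)
        assert not f.valid.any()  # unsigned distance ~6 mm > window
        assert np.all(np.isnan(f.d))

    def test_behind_reference_is_positive(self, sphere_pair):
        ref, _ = sphere_pair
        inner = trimesh.creation.icosphere(subdivisions=4, radius=28.0)
        cap = np.flatnonzero(ref.triangles_center[:, 2] > 15.0)
        f = signed_deviation(sample_region(ref, cap), inner)
        assert np.allclose(f.d, 2.0, atol=0.02)

    def test_translation_of_flat_phantom_shifts_dmean(self):
        square = planar_square()
        s = sample_region(square, np.arange(len(square.faces)))
        shifted = square.copy()
        shifted.apply_translation([0, 0, 1.0])  # +1 mm along every normal
        f = signed_deviation(s, shifted)
        assert f.valid.all()
        assert np.allclose(f.d, -1.0, atol=1e-9)
        assert summarize_region(f).Dmean == pytest.approx(-1.0, abs=1e-9)

    def test_missing_surface_marked_invalid(self):
        """Samples over removed surface have no genuine correspondence
        (closest point on an open boundary) and are invalid."""
        square = planar_square()
        s = sample_region(square, np.arange(len(square.faces)))
        holed = square.copy()
        keep = np.ones(len(square.faces), dtype=bool)
        centers = square.triangles_center
        hole = (centers[:, 0] > 3) & (centers[:, 0] < 7) & (centers[:, 1] > 3) & (centers[:, 1] < 7)
        keep[hole] = False
        holed.update_faces(keep)
        f = signed_deviation(s, holed)
        assert not f.valid[hole].any()
        assert f.valid[~hole].all()

    def test_empty_subject_rejected(self, sphere_pair):
        s = sample_region(sphere_pair[0], [0, 1])
        empty = trimesh.Trimesh(
            vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int), process=False
        )
        with pytest.raises(DeviationError):
            signed_deviation(s, empty)


class TestSummarizeRegion:
    def field(self, d, a=None, valid=None):
        d = np.asarray(d, dtype=float)
        a = np.ones_like(d) if a is None else np.asarray(a, dtype=float)
        valid = np.isfinite(d) if valid is None else valid
        return DeviationField(d=d, valid=valid, area_weights=a, window=5.0)

    def test_zero_field(self):
        s = summarize_region(self.field([0.0, 0.0, 0.0], a=[2.0, 3.0, 5.0]))
        assert s.Dmean == s.ID == s.IAD == 0.0
        assert s.AVD == 10.0

    def test_id_identity_and_order(self, sphere_pair):
        ref, subj = sphere_pair
        cap = np.flatnonzero(ref.triangles_center[:, 2] > 15.0)
        samples = sample_region(ref, cap)
        s = summarize_region(signed_deviation(samples, subj))
        assert s.ID == pytest.approx(s.Dmean * s.AVD, rel=1e-12)
        assert s.IAD >= abs(s.ID)
        assert s.IAD == pytest.approx(abs(s.ID), rel=1e-9)  # single-signed field
        assert s.ID == pytest.approx(-2.0 * samples.total_area, rel=0.02)
        assert s.DSD < 0.02
        assert s.Dmin <= s.Dmean <= s.Dmax

    def test_symmetric_two_sample_field(self):
        s = summarize_region(self.field([-1.0, 1.0], a=[3.0, 3.0]))
        assert s.Dmean == 0.0
        assert s.ID == 0.0
        assert s.IAD == pytest.approx(6.0)
        assert s.DSD == pytest.approx(1.0)

    def test_fully_invalid_region_empty_summary(self):
        s = summarize_region(self.field([np.nan, np.nan]))
        assert s.AVD == 0.0 and s.ID == 0.0 and s.IAD == 0.0
        assert np.isnan(s.Dmean) and np.isnan(s.Dmax)

    def test_area_weighting(self):
        # Dmean is area-weighted, not a plain average
        s = summarize_region(self.field([-2.0, 0.0], a=[3.0, 1.0]))
        assert s.Dmean == pytest.approx(-1.5)
        assert s.ID == pytest.approx(-6.0)


class TestFalseColor:
    def test_semantics(self):
        f = DeviationField(
            d=np.array([0.0, -3.2, 3.2, np.nan, -0.5]),
            valid=np.array([True, True, True, False, True]),
            area_weights=np.ones(5),
            window=5.0,
        )
        labels, rgb = false_color(f, green_band=1.0)
        assert labels.tolist() == ["green", "blue", "red", "grey", "green"]
        assert rgb[3].tolist() == [128, 128, 128]

    def test_intensity_ramps_toward_window(self):
        f = DeviationField(
            d=np.array([-1.5, -4.9]),
            valid=np.array([True, True]),
            area_weights=np.ones(2),
            window=5.0,
        )
        _, rgb = false_color(f)
        assert rgb[1][2] > rgb[0][2]  # deeper deviation -> bluer


class TestPhantomRecovery:
    def test_offset_recovered_as_dmean(self, reference_coarse):
        """Known region offsets reappear as Dmean of the region once the
        subject is brought back by the ground-truth transform."""
        means = zero_offsets()
        means["male"]["R1"] = means["female"]["R1"] = -2.0
        means["male"]["R2"] = means["female"]["R2"] = 1.0
        spec = PhantomSpec(
            seed=21, n_subjects=1, region_offset_mean=means, region_offset_sd=0.0,
            noise_sd=0.0, dropout_fraction=0.0,
        )
        sub = synthesize_subject(reference_coarse, spec, 0)
        registered = sub.truth.applied_transform.inverse().apply_mesh(sub.mesh)
        for region, expected in (("R1", -2.0), ("R2", 1.0), ("R3", 0.0)):
            for side in ("left", "right"):
                samples = sample_region(
                    reference_coarse.mesh, reference_coarse.region_faces[f"{region}_{side}"]
                )
                s = summarize_region(signed_deviation(samples, registered))
                assert s.Dmean == pytest.approx(expected, abs=0.02), (region, side)

    def test_dropout_recovered_as_valid_area(self, reference_coarse):
        spec = PhantomSpec(
            seed=22, n_subjects=1, region_offset_mean=zero_offsets(), region_offset_sd=0.0,
            noise_sd=0.0, dropout_fraction=0.3,
        )
        sub = synthesize_subject(reference_coarse, spec, 0)
        registered = sub.truth.applied_transform.inverse().apply_mesh(sub.mesh)
        ratios = []
        for side in ("left", "right"):
            samples = sample_region(
                reference_coarse.mesh, reference_coarse.region_faces[f"R4_{side}"]
            )
            s = summarize_region(signed_deviation(samples, registered))
            ratios.append(s.AVD / samples.total_area)
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.05)
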