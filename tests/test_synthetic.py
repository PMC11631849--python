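import numpy as np
import pytest

from lase.association import AU_PER_MV
from lase.entropy import detect_lva, voltage_map
from lase.mesh import vertex_normals
from lase.association import associate
from lase.synthetic import (
    SimulationSpec,
    SubstrateModel,
    make_atrium_mesh,
    make_cohort,
    paint_substrate,
    sample_egm_points,
)


def _vertex_areas(mesh):
    fa = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], fa / 3.0)
    return va


class TestMeshGenerator:
    def test_mesh_passes_invariants_and_is_closed(self):
        spec = SimulationSpec(n_mesh_vertices=2000, n_points=0, seed=0)
        mesh = make_atrium_mesh(spec)
        mesh.validate()
        assert mesh.is_closed()
        assert abs(mesh.n_vertices - 2000) <= 40  # within 2%

    def test_same_seed_reproduces_identical_mesh(self):
        spec = SimulationSpec(n_mesh_vertices=650, n_points=0, seed=3)
        m1, m2 = make_atrium_mesh(spec), make_atrium_mesh(spec)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)

    def test_different_seeds_differ(self):
        a = make_atrium_mesh(SimulationSpec(n_mesh_vertices=650, n_points=0, seed=1))
        b = make_atrium_mesh(SimulationSpec(n_mesh_vertices=650, n_points=0, seed=2))
        assert not np.array_equal(a.vertices, b.vertices)


class TestSubstrate:
    def test_patch_area_fraction_close_to_request(self, medium_atrium):
        model = SubstrateModel(lva_fraction=0.3, n_patches=3)
        _, mask = paint_substrate(medium_atrium, model, seed=5)
        va = _vertex_areas(medium_atrium)
        frac = va[mask].sum() / va.sum()
        assert 0.28 <= frac <= 0.32

    def test_healthy_tissue_mostly_above_threshold(self, medium_atrium):
        """Without patches, sub-0.5 mV tissue is limited to the distribution
        tail (few percent of the surface)."""
        model = SubstrateModel(lva_fraction=0.0, n_patches=0)
        amp, mask = paint_substrate(medium_atrium, model, seed=0)
        assert not mask.any()
        assert (amp < 0.5).mean() < 0.05

    def test_abnormal_low_fraction_tracks_lva_fraction(self, medium_atrium):
        model = SubstrateModel(lva_fraction=0.25, n_patches=3)
        amp, _ = paint_substrate(medium_atrium, model, seed=1)
        assert abs((amp < 0.5).mean() - 0.25) < 0.05

    def test_patches_are_subthreshold_by_construction(self, medium_atrium):
        model = SubstrateModel(lva_fraction=0.2, n_patches=2)
        amp, mask = paint_substrate(medium_atrium, model, seed=2)
        assert (amp[mask] < 0.5).mean() > 0.99

    def test_fraction_without_patches_is_an_error(self):
        with pytest.raises(ValueError, match="n_patches"):
            SubstrateModel(lva_fraction=0.5, n_patches=0)

    def test_determinism(self, medium_atrium):
        model = SubstrateModel(lva_fraction=0.1, n_patches=2)
        a1, m1 = paint_substrate(medium_atrium, model, seed=9)
        a2, m2 = paint_substrate(medium_atrium, model, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(m1, m2)


class TestEgmSampling:
    def test_peak_to_peak_matches_target_without_noise(self, small_atrium):
        """1.0 mV target with all noise terms off gives traces of exactly
        333.33 a.u. peak-to-peak (within 1%)."""
        spec = SimulationSpec(
            n_mesh_vertices=650, n_points=200, seed=0, noise_floor_mv=0.0
        )
        model = SubstrateModel(base_cv=0.0)
        amp = np.full(small_atrium.n_vertices, 1.0)
        pts = sample_egm_points(small_atrium, amp, spec, model, seed=0)
        pp = np.array([p.trace.max() - p.trace.min() for p in pts])
        assert np.all(np.abs(pp - 1.0 * AU_PER_MV) / (1.0 * AU_PER_MV) < 0.01)

    def test_af_rhythm_inflates_amplitude_variability(self, small_atrium):
        spec = SimulationSpec(n_mesh_vertices=650, n_points=600, seed=4)
        amp = np.full(small_atrium.n_vertices, 1.5)
        sr = sample_egm_points(
            small_atrium, amp, spec, SubstrateModel(rhythm="SR"), seed=4
        )
        af = sample_egm_points(
            small_atrium, amp, spec, SubstrateModel(rhythm="AF"), seed=4
        )
        var_sr = np.var([p.trace.max() - p.trace.min() for p in sr])
        var_af = np.var([p.trace.max() - p.trace.min() for p in af])
        assert var_af > var_sr

    def test_bitwise_determinism(self, small_atrium):
        spec = SimulationSpec(n_mesh_vertices=650, n_points=50, seed=8)
        model = SubstrateModel()
        amp = np.full(small_atrium.n_vertices, 1.0)
        p1 = sample_egm_points(small_atrium, amp, spec, model)
        p2 = sample_egm_points(small_atrium, amp, spec, model)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.trace, b.trace)
            assert np.array_equal(a.position, b.position)

    def test_zero_points_gives_empty_list(self, small_atrium):
        spec = SimulationSpec(n_mesh_vertices=650, n_points=0, seed=0)
        amp = np.full(small_atrium.n_vertices, 1.0)
        assert sample_egm_points(small_atrium, amp, spec, SubstrateModel()) == []


class TestLvaRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_detect_lva_recovers_painted_patches(self, seed):
        """The detector applied to a sampled map recovers the ground-truth
        patch vertices with high overlap."""
        spec = SimulationSpec(n_mesh_vertices=800, n_points=3000, seed=seed)
        mesh = make_atrium_mesh(spec)
        model = SubstrateModel(lva_fraction=0.25, n_patches=2)
        amp, mask = paint_substrate(mesh, model, seed=seed)
        pts = sample_egm_points(mesh, amp, spec, model, seed=seed)
        nset = associate(mesh, vertex_normals(mesh), pts)
        vmap = voltage_map(mesh, nset, pts)
        regions = detect_lva(vmap, mesh)
        predicted = set()
        for r in regions:
            predicted |= set(r.vertices.tolist())
        truth = set(np.flatnonzero(mask).tolist())
        jaccard = len(predicted & truth) / len(predicted | truth)
        assert jaccard >= 0.7
        recall = len(predicted & truth) / len(truth)
        assert recall >= 0.8


class TestCohortGenerator:
    def test_cohort_sizes_and_truth(self):
        spec = SimulationSpec(n_mesh_vertices=650, n_points=100, seed=0)
        cohort = make_cohort(2, 1, spec, seed=0)
        assert [s.substrate for s in cohort] == ["normal", "normal", "abnormal"]
        for s in cohort:
            if s.substrate == "normal":
                assert s.lva_fraction <= 0.02
            else:
                assert 0.15 <= s.lva_fraction <= 0.30

    def test_empty_cohort(self):
        assert make_cohort(0, 0, seed=0) == []
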