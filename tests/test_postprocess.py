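import numpy as np
import pytest

from micromotion_fem.fem import StrainField
from micromotion_fem.geometry import (REGION_TISSUE, MeshParams,
                                      build_domain_spec, generate_hex_mesh)
from micromotion_fem.postprocess import (StrainProfile, classify_max_location,
                                         decay_span, max_tissue_strain,
                                         normalize_to_baseline,
                                         percent_reduction, strain_profile)

COARSE = MeshParams(n_through_thickness=3, near_size=20.0, grading=1.6,
                    far_size=220.0)


@pytest.fixture(scope="module")
def case_mesh():
    spec = build_domain_spec(1125.0, 125.0, 25.0)
    return spec, generate_hex_mesh(spec, COARSE)


def _field(mesh, values):
    return StrainField(tensor=np.zeros((mesh.n_elements, 6)),
                       von_mises=np.asarray(values, float),
                       region=mesh.region)


class TestMaxTissueStrain:
    def test_uniform_field_returns_uniform_value(self, case_mesh):
        _, mesh = case_mesh
        v, _ = max_tissue_strain(_field(mesh, np.full(mesh.n_elements, 0.3)),
                                 mesh)
        assert v == 0.3

    def test_probe_elements_excluded(self, case_mesh):
        _, mesh = case_mesh
        vm = np.full(mesh.n_elements, 0.1)
        vm[mesh.region != REGION_TISSUE] = 99.0
        v, loc = max_tissue_strain(_field(mesh, vm), mesh)
        assert v == 0.1

    def test_argmax_location_is_element_centroid(self, case_mesh):
        _, mesh = case_mesh
        vm = np.zeros(mesh.n_elements)
        k = np.flatnonzero(mesh.region == REGION_TISSUE)[7]
        vm[k] = 1.0
        v, loc = max_tissue_strain(_field(mesh, vm), mesh)
        assert v == 1.0
        assert np.allclose(loc, mesh.nodes[mesh.elements[k]].mean(axis=0))

    def test_tie_breaks_to_smallest_element_index(self, case_mesh):
        _, mesh = case_mesh
        tissue = np.flatnonzero(mesh.region == REGION_TISSUE)
        vm = np.zeros(mesh.n_elements)
        vm[tissue[[5, 11]]] = 2.0
        _, loc = max_tissue_strain(_field(mesh, vm), mesh)
        k = tissue[5]
        assert np.allclose(loc, mesh.nodes[mesh.elements[k]].mean(axis=0))

    def test_no_tissue_elements_rejected(self, case_mesh):
        _, mesh = case_mesh
        f = _field(mesh, np.zeros(mesh.n_elements))
        f.region = np.ones(mesh.n_elements, dtype=np.int8)
        with pytest.raises(ValueError, match="tissue"):
            max_tissue_strain(f, mesh)


class TestClassifyLocation:
    @pytest.mark.parametrize("frac,expected",
                             [(0.05, "top"), (0.5, "mid"), (0.95, "tip"),
                              (1.1, "tip")])
    def test_thirds_rule(self, frac, expected):
        spec = build_domain_spec(1125.0, 125.0, 25.0)
        loc = np.array([0.0, frac * spec.embed_depth, 0.0])
        assert classify_max_location(loc, spec) == expected


class TestNormalisation:
    def test_equal_values_normalise_to_one(self):
        assert normalize_to_baseline(0.25, 0.25) == 1.0

    def test_percent_reduction_bounds(self):
        assert percent_reduction(0.25, 0.25) == 0.0
        assert percent_reduction(0.0, 0.25) == 100.0

    @pytest.mark.parametrize("fn", [normalize_to_baseline, percent_reduction])
    def test_nonpositive_baseline_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, 0.0)


class TestStrainProfile:
    def test_uniform_field_gives_flat_profile(self, case_mesh):
        spec, mesh = case_mesh
        f = _field(mesh, np.full(mesh.n_elements, 0.07))
        p = strain_profile(f, mesh, spec, "tip")
        assert np.allclose(p.values, 0.07)
        assert p.distances[0] > 0
        assert np.all(np.diff(p.distances) > 0)

    def test_profile_reproduces_distance_function(self, case_mesh):
        """A field set to a known function of centroid z-distance comes back
        exactly at the sampled distances."""
        spec, mesh = case_mesh
        c = mesh.element_centroids()
        dist = c[:, 2] - spec.probe_thickness / 2.0
        vm = np.where(dist > 0, np.exp(-np.maximum(dist, 0.0) / 50.0), 0.0)
        p = strain_profile(_field(mesh, vm), mesh, spec, "tip",
                           max_distance=300.0)
        assert np.allclose(p.values, np.exp(-p.distances / 50.0), rtol=1e-9)

    def test_mid_section_starts_at_62p5_um_from_axis(self, case_mesh):
        spec, mesh = case_mesh
        f = _field(mesh, np.ones(mesh.n_elements))
        p = strain_profile(f, mesh, spec, "mid")
        assert p.distances[0] + spec.probe_thickness / 2.0 >= 62.5

    def test_distance_beyond_tissue_truncated_with_warning(self, case_mesh):
        spec, mesh = case_mesh
        f = _field(mesh, np.ones(mesh.n_elements))
        with pytest.warns(UserWarning, match="truncated"):
            p = strain_profile(f, mesh, spec, "tip", max_distance=5000.0)
        assert p.distances[-1] <= spec.tissue_length / 2.0

    def test_unknown_section_rejected(self, case_mesh):
        spec, mesh = case_mesh
        f = _field(mesh, np.ones(mesh.n_elements))
        with pytest.raises(ValueError, match="section"):
            strain_profile(f, mesh, spec, "bottom")


class TestDecaySpan:
    def test_flat_profile_never_reaches_threshold(self):
        p = StrainProfile("tip", np.linspace(1, 100, 20), np.full(20, 0.5))
        d, reached = decay_span(p)
        assert not reached and d == 100.0

    def test_exponential_profile_crosses_at_decay_length(self):
        L = 40.0
        x = np.linspace(0.0, 5 * L, 201)  # includes x = L exactly
        p = StrainProfile("tip", x[1:], np.exp(-x[1:] / L))
        x0 = x[1]
        d, reached = decay_span(p, threshold_fraction=np.exp(-(L - x0) / L))
        assert reached and d == pytest.approx(L)

    def test_threshold_one_returns_first_distance(self):
        p = StrainProfile("tip", np.array([2.0, 4.0]), np.array([1.0, 0.5]))
        d, reached = decay_span(p, threshold_fraction=1.0)
        assert reached and d == 2.0

    def test_invalid_threshold_rejected(self):
        p = StrainProfile("tip", np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            decay_span(p, threshold_fraction=0.0)
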