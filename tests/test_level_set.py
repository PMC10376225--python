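import numpy as np
import pytest
from scipy import ndimage

from qdaseg.contour import signed_distance_init
from qdaseg.level_set import (
    EdgeMap,
    LevelSetParams,
    edge_indicator,
    evolve,
    phi_to_mask,
    reinitialize,
    segment_slice,
    stability_dt,
)
from qdaseg.mri_io import Slice


def _disk(n, r, c=None):
    c = (n - 1) / 2 if c is None else c
    yy, xx = np.mgrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


class TestEdgeIndicator:
    def test_constant_image_gives_one(self):
        em = edge_indicator(Slice(np.full((20, 20), 80.0)), sigma=1.5)
        assert np.allclose(em.g, 1.0)

    def test_step_edge_darker_than_flat(self):
        img = np.zeros((30, 30))
        img[:, 15:] = 200.0
        em = edge_indicator(Slice(img), sigma=1.5)
        assert em.g[15, 14] < em.g[15, 2]
        assert (em.g > 0).all() and (em.g <= 1).all()

    def test_pointwise_oracle(self, rng):
        img = rng.uniform(0, 255, (25, 25))
        sigma = 2.0
        em = edge_indicator(Slice(img), sigma=sigma)
        smooth = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")
        gy, gx = np.gradient(smooth)
        assert np.allclose(em.g, 1.0 / (1.0 + gx**2 + gy**2))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            edge_indicator(Slice(np.zeros((4, 4))), sigma=0.0)


class TestStabilityDt:
    @pytest.mark.parametrize(
        "Wa,Wc,expected", [(1.0, 1.0, 1 / 6), (2.0, 1.0, 1 / 12), (1.0, 3.0, 1 / 18)]
    )
    def test_formula(self, Wa, Wc, expected):
        assert stability_dt(LevelSetParams(Wa=Wa, Wc=Wc)) == pytest.approx(expected)

    def test_override(self):
        p = LevelSetParams(dt_override=0.05)
        assert p.dt == 0.05


class TestEvolve:
    def test_zero_iterations_identity(self):
        phi = signed_distance_init(_disk(41, 10))
        em = EdgeMap(g=np.ones((41, 41)), sigma=1.0)
        out, iters = evolve(phi, em, LevelSetParams(max_iters=0))
        assert iters == 0
        assert np.array_equal(out, phi)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            evolve(np.zeros((4, 4)), EdgeMap(g=np.ones((5, 5)), sigma=1.0))

    def test_deterministic(self):
        phi = signed_distance_init(_disk(41, 12))
        em = EdgeMap(g=np.ones((41, 41)) * 0.8, sigma=1.0)
        p = LevelSetParams(max_iters=50, convergence_tol=0.0, check_every=0)
        a, _ = evolve(phi, em, p)
        b, _ = evolve(phi, em, p)
        assert np.array_equal(a, b)

    def test_equilibrium_on_deep_edge_minimum(self):
        img = np.where(_disk(101, 30), 200.0, 50.0)
        em = edge_indicator(Slice(img), sigma=1.5)
        phi = signed_distance_init(_disk(101, 30))
        p = LevelSetParams(nu=1e-9, max_iters=100, convergence_tol=0.0, check_every=0)
        out, _ = evolve(phi, em, p)
        assert (phi_to_mask(out) ^ phi_to_mask(phi)).sum() == 0

    def test_two_disks_merge_over_one_lump(self):
        lump = _disk(101, 30)
        img = np.where(lump, 200.0, 50.0)
        em = edge_indicator(Slice(img), sigma=1.5)
        init = _disk(101, 6, c=38) | _disk(101, 6, c=62)
        phi = signed_distance_init(init)
        p = LevelSetParams(nu=-0.4, max_iters=2500, convergence_tol=1e-4)
        out, _ = evolve(phi, em, p)
        m = phi_to_mask(out)
        _, n = ndimage.label(m)
        assert n == 1
        dice = 2 * (m & lump).sum() / (m.sum() + lump.sum())
        assert dice > 0.85

    def test_phi_stays_finite_long_run(self):
        phi = signed_distance_init(_disk(61, 20))
        em = EdgeMap(g=np.full((61, 61), 0.7), sigma=1.0)
        p = LevelSetParams(max_iters=1000, convergence_tol=0.0, check_every=0)
        out, _ = evolve(phi, em, p)
        assert np.all(np.isfinite(out))


class TestPhiToMask:
    def test_positive_field_empty(self):
        assert phi_to_mask(np.ones((5, 5))).sum() == 0

    def test_round_trip_through_signed_distance(self):
        m = _disk(31, 8)
        assert np.array_equal(phi_to_mask(signed_distance_init(m)), m)

    def test_area_monotone_in_constant_shift(self):
        phi = signed_distance_init(_disk(41, 10))
        areas = [phi_to_mask(phi - s).sum() for s in np.linspace(0, 5, 11)]
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_nonfinite_rejected(self):
        bad = np.zeros((3, 3))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            phi_to_mask(bad)


class TestReinitialize:
    def test_preserves_sign_pattern(self):
        phi = signed_distance_init(_disk(41, 9)) * 3.0  # stretched field
        out = reinitialize(phi)
        assert np.array_equal(out < 0, phi < 0)

    def test_restores_unit_gradient(self):
        phi = signed_distance_init(_disk(61, 15)) * 4.0
        out = reinitialize(phi)
        gy, gx = np.gradient(out)
        band = np.abs(out) <= 3.0
        assert 0.8 <= np.sqrt(gx**2 + gy**2)[band].mean() <= 1.2


class TestSegmentSlice:
    def test_empty_init_short_circuits(self):
        out = segment_slice(Slice(np.zeros((20, 20))), np.zeros((20, 20), bool))
        assert out.sum() == 0

    def test_refinement_does_not_hurt_on_phantom(self, tumor_slice):
        from qdaseg.cluster import identify_tumor_cluster, kmeans
        from qdaseg.contour import tumor_mask
        from qdaseg.preprocess import anisotropic_diffusion, skull_strip

        sl, truth, _ = tumor_slice
        brain, mask, _ = skull_strip(sl)
        smooth = anisotropic_diffusion(brain)
        cm = kmeans(smooth.data[mask], 4)
        labels = np.zeros(sl.data.shape, int) - 1
        labels[mask] = cm.labels
        init, empty = tumor_mask(labels, identify_tumor_cluster(cm))
        assert not empty
        seg = segment_slice(smooth, init) & mask

        def dice(a, b):
            return 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)

        assert dice(seg, truth) >= dice(init, truth) - 1e-9

    def test_deterministic(self, tumor_slice):
        sl, _, _ = tumor_slice
        init = _disk(sl.data.shape[0], 5)[: sl.data.shape[0], : sl.data.shape[1]]
        a = segment_slice(sl, init)
        b = segment_slice(sl, init)
        assert np.array_equal(a, b)
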