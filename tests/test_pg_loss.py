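"""PG loss: compartment factors, adaptive weights, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualgland.pg import (
    CompartmentMap,
    OrganelleReference,
    PGConfig,
    adaptive_weight,
    compartment_factor,
    homeostatic_penalty,
    organelle_structural_loss,
    pg_loss,
    pg_smoothness,
    pixel_features,
    temporal_decay,
)


@pytest.fixture()
def simple_map():
    # nucleus touching ER; mitochondria far away
    labels = np.zeros((8, 8), dtype=int)
    labels[1:3, 1:3] = 1   # nucleus
    labels[3:4, 1:3] = 3   # ER directly below nucleus (adjacent)
    labels[6:8, 6:8] = 2   # distant mitochondria
    return CompartmentMap.from_labels(labels)


class TestCompartmentFactor:
    def test_same_organelle(self, simple_map):
        assert compartment_factor(simple_map, (1, 1), (2, 2)) == 1.0

    def test_adjacent_organelles(self, simple_map):
        assert compartment_factor(simple_map, (2, 1), (3, 1)) == 0.5

    def test_distant_and_background(self, simple_map):
        assert compartment_factor(simple_map, (1, 1), (7, 7)) == 0.1
        assert compartment_factor(simple_map, (0, 0), (5, 5)) == 0.1

    def test_adjacency_symmetric_irreflexive(self, simple_map):
        adj = simple_map.adjacency
        assert all((b, a) in adj for (a, b) in adj)
        assert all(a != b for (a, b) in adj)


class TestAdaptiveWeight:
    def test_closed_forms(self):
        cfg = PGConfig()
        assert temporal_decay(0.0, 5.0) == 1.0
        assert temporal_decay(5.0, 5.0) == pytest.approx(np.exp(-1))
        f = np.array([0.2, 0.4])
        assert adaptive_weight(f, f, 1.0, 0.0, cfg) == pytest.approx(1.0)
        # ||df||^2 = 0.5, beta=2 -> exp(-1)
        g = f + np.sqrt(0.25)
        assert adaptive_weight(f, g, 1.0, 0.0, cfg) == pytest.approx(np.exp(-1))

    @given(st.floats(0, 10), st.floats(0, 5),
           st.sampled_from([1.0, 0.5, 0.1]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_compartment_times_decay(self, d2, t, c):
        cfg = PGConfig()
        f_i = np.array([0.0])
        f_j = np.array([np.sqrt(d2)])
        a = adaptive_weight(f_i, f_j, c, t, cfg)
        assert 0 < a <= c * temporal_decay(t, cfg.tau) + 1e-12


class TestSmoothness:
    def test_constant_zero(self, simple_map):
        img = np.full((4, 8, 8), 0.4)
        assert pg_smoothness(img, None, simple_map, 0.0, PGConfig()) == 0.0

    def test_two_pixel_enumeration(self):
        cmap = CompartmentMap.from_labels(np.zeros((1, 2), dtype=int))
        img = np.array([[[0.0, 1.0]]])
        val = pg_smoothness(img, None, cmap, 0.0, PGConfig(), alpha_override=1.0)
        assert val == pytest.approx(1.0)  # both ordered pairs contribute 1

    def test_linear_in_alpha(self):
        cmap = CompartmentMap.from_labels(np.zeros((1, 2), dtype=int))
        img = np.array([[[0.0, 1.0]]])
        full = pg_smoothness(img, None, cmap, 0.0, PGConfig(), alpha_override=1.0)
        half = pg_smoothness(img, None, cmap, 0.0, PGConfig(), alpha_override=0.5)
        assert half == pytest.approx(full / 2)

    def test_global_offset_invariance(self, rng, simple_map):
        img = rng.random((4, 8, 8))
        feats = pixel_features(img)
        a = pg_smoothness(img, feats, simple_map, 0.0, PGConfig())
        b = pg_smoothness(img + 0.17, feats, simple_map, 0.0, PGConfig())
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("trial", range(4))
    def test_double_loop_oracle(self, trial, simple_map):
        """Vectorized smoothness equals the explicit per-pixel double loop."""
        rng = np.random.default_rng(50 + trial)
        h = w = 6
        labels = np.asarray(simple_map.labels)[:h, :w]
        cmap = CompartmentMap.from_labels(labels)
        img = rng.random((2, h, w))
        cfg = PGConfig()
        feats = pixel_features(img)
        t = float(rng.uniform(0, 3))

        total, count = 0.0, 0
        for r in range(h):
            for c in range(w):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = r + dr, c + dc
                        if not (0 <= r2 < h and 0 <= c2 < w):
                            continue
                        a = adaptive_weight(feats[:, r, c], feats[:, r2, c2],
                                            compartment_factor(cmap, (r, c), (r2, c2)),
                                            t, cfg)
                        total += a * np.mean((img[:, r2, c2] - img[:, r, c]) ** 2)
                        count += 1
        expect = total / count
        assert pg_smoothness(img, feats, cmap, t, cfg) == pytest.approx(expect, rel=1e-10)

    def test_matches_graph_laplacian_quadratic_form(self, rng):
        """With symmetric alphas, smoothness equals the weighted Laplacian
        quadratic form (cross-check on a 5x5 single-channel image)."""
        labels = np.zeros((5, 5), dtype=int)
        labels[1:3, 1:3] = 1
        cmap = CompartmentMap.from_labels(labels)
        img = rng.random((1, 5, 5))
        cfg = PGConfig()
        feats = pixel_features(img)
        n = 25
        W = np.zeros((n, n))
        for r in range(5):
            for c in range(5):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < 5 and 0 <= c2 < 5:
                            W[r * 5 + c, r2 * 5 + c2] = adaptive_weight(
                                feats[:, r, c], feats[:, r2, c2],
                                compartment_factor(cmap, (r, c), (r2, c2)), 0.0, cfg)
        assert np.allclose(W, W.T)
        L = np.diag(W.sum(1)) - W
        x = img[0].ravel()
        n_pairs = int((W > 0).sum())
        expect = 2 * x @ L @ x / n_pairs
        assert pg_smoothness(img, feats, cmap, 0.0, cfg) == pytest.approx(expect)


class TestHomeostasis:
    def test_zero_at_reference_means(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        img = np.where(labels == 1, 0.60, 0.45)[None]
        assert homeostatic_penalty(img, labels) == pytest.approx(0.0)

    def test_single_organelle_deviation(self):
        labels = np.ones((4, 4), dtype=int)
        img = np.full((1, 4, 4), 0.7)
        assert homeostatic_penalty(img, labels) == pytest.approx(0.01)

    def test_locality_of_organelle_terms(self, rng):
        labels = np.zeros((6, 6), dtype=int)
        labels[:2] = 1
        labels[4:] = 3
        img = rng.random((1, 6, 6))
        base = homeostatic_penalty(img, labels)
        refs = OrganelleReference()
        shifted = img.copy()
        shifted[0, labels == 1] += 0.1
        delta_full = homeostatic_penalty(shifted, labels) - base
        # only the nucleus term moved
        mu = refs.mu[1]
        m0 = img[0, labels == 1].mean()
        expect = (m0 + 0.1 - mu) ** 2 - (m0 - mu) ** 2
        assert delta_full == pytest.approx(expect)

    def test_quadratic_growth(self):
        labels = np.ones((4, 4), dtype=int)
        devs = np.array([0.05, 0.1, 0.2])
        vals = [homeostatic_penalty(np.full((1, 4, 4), 0.60 + d), labels)
                for d in devs]
        assert np.allclose(vals, devs ** 2)


class TestPGLoss:
    def test_total_composition(self, rng, simple_map):
        img = rng.random((4, 8, 8))
        cfg = PGConfig(lambda_homeostasis=2.0)
        out = pg_loss(img, None, simple_map, simple_map.labels, None, 1.0, cfg)
        assert out.total == pytest.approx(
            out.components["smoothness"] + 2.0 * out.components["homeostasis"])

    def test_lambda_zero_reduces_to_smoothness(self, rng, simple_map):
        img = rng.random((4, 8, 8))
        cfg = PGConfig(lambda_homeostasis=0.0)
        out = pg_loss(img, None, simple_map, simple_map.labels, None, 0.0, cfg)
        assert out.total == out.components["smoothness"]

    def test_constant_at_reference_is_zero(self):
        labels = np.ones((6, 6), dtype=int)  # one organelle fills the cell
        cmap = CompartmentMap.from_labels(labels)
        img = np.full((4, 6, 6), 0.60)
        out = pg_loss(img, None, cmap, labels, None, 0.0, PGConfig())
        assert out.total == 0.0


class TestStructuralVariant:
    def test_constant_gen_hinge_only(self):
        masks = {1: np.zeros((8, 8), dtype=bool)}
        masks[1][2:6, 2:6] = True
        cfg = PGConfig(organelle_weights={1: 1.0})
        val = organelle_structural_loss(np.full((8, 8), 0.5), masks, cfg)
        assert val == pytest.approx(0.01)  # hinge(0.1 - 0)^2

    def test_sharp_boundary_smooth_interior_near_zero(self):
        img = np.zeros((12, 12))
        img[3:9, 3:9] = 1.0  # crisp step
        masks = {1: img.astype(bool)}
        cfg = PGConfig(organelle_weights={1: 1.0})
        val = organelle_structural_loss(img, masks, cfg)
        assert val < 0.01  # boundary gradient far above target; interior flat

    def test_zero_weights(self, rng):
        masks = {1: rng.random((8, 8)) > 0.5}
        cfg = PGConfig(organelle_weights={1: 0.0}, lambda_reg=0.0)
        assert organelle_structural_loss(rng.random((8, 8)), masks, cfg) == 0.0
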