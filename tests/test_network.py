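"""Network construction: torus geometry, direction fields, target sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import anisonet as an
from anisonet.network import (TorusGrid, ConnectivityProfile, DirectionField,
                              ShiftSpec, _edge_displacements, _wrap_delta,
                              sample_targets, perlin_coarse_size)


# ---------------------------------------------------------------------------
# torus displacement
# ---------------------------------------------------------------------------

class TestTorusDisplacement:
    def test_identity(self):
        g = TorusGrid(10, 10)
        dx, dy = an.torus_displacement((3, 4), (3, 4), g)
        assert dx == 0 and dy == 0

    def test_wraparound(self):
        g = TorusGrid(100, 100)
        dx, dy = an.torus_displacement((0, 0), (99, 0), g)
        assert dx == -1 and dy == 0

    def test_invalid_position_raises(self):
        with pytest.raises(ValueError, match="out of bounds"):
            an.torus_displacement((0, 0), (100, 0), TorusGrid(100, 100))

    @given(st.integers(2, 50), st.integers(2, 50), st.data())
    def test_matches_bruteforce_over_images(self, nrow, ncol, data):
        """Displacement equals the argmin over all 9 wrapped images."""
        g = TorusGrid(nrow, ncol)
        ax = data.draw(st.integers(0, ncol - 1))
        ay = data.draw(st.integers(0, nrow - 1))
        bx = data.draw(st.integers(0, ncol - 1))
        by = data.draw(st.integers(0, nrow - 1))
        dx, dy = an.torus_displacement((ax, ay), (bx, by), g)
        best = min(
            ((bx + i * ncol - ax) ** 2 + (by + j * nrow - ay) ** 2
             for i in (-1, 0, 1) for j in (-1, 0, 1)))
        assert dx * dx + dy * dy == pytest.approx(best)
        assert abs(dx) <= ncol / 2 and abs(dy) <= nrow / 2


# ---------------------------------------------------------------------------
# direction fields
# ---------------------------------------------------------------------------

class TestDirectionFields:
    def test_perlin_coarse_grid_arithmetic(self):
        assert perlin_coarse_size(100, 20) == 5
        assert perlin_coarse_size(120, 20) == 6
        with pytest.raises(ValueError):
            perlin_coarse_size(10, 100)

    def test_perlin_single_cell_degenerates_to_constant(self):
        g = TorusGrid(40, 40)
        phi = an.perlin_field(g, perlin_scale=40, seed=3)
        assert np.unique(phi).size == 1

    def test_perlin_marginal_uniform_and_quantized(self):
        g = TorusGrid(100, 100)
        phi = an.perlin_field(g, 20, seed=2)
        counts = np.bincount(np.rint(phi / (np.pi / 4)).astype(int) % 8,
                             minlength=8)
        assert set(np.unique(phi)) <= set(an.DIRECTIONS)
        assert counts.max() - counts.min() <= 1  # equal occupancy

    def test_perlin_correlation_increases_with_scale(self):
        """Neighbor direction agreement grows with the Perlin scale."""
        g = TorusGrid(100, 100)

        def agreement(scale, lag=3):
            f = an.perlin_field(g, scale, seed=11).reshape(100, 100)
            return np.mean(np.cos(f - np.roll(f, lag, axis=1)))

        vals = [agreement(s) for s in (2, 4, 10, 20, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_perlin_neighbors_similar_far_pairs_unrelated(self):
        g = TorusGrid(100, 100)
        near, far = [], []
        for seed in range(5):  # single fields carry realization noise
            f = an.perlin_field(g, 20, seed=seed).reshape(100, 100)
            near.append(np.mean(f == np.roll(f, 1, axis=0)))
            far.append(np.mean(f == np.roll(f, 50, axis=0)))
        assert np.mean(near) > 0.5  # far above the 1/8 chance level
        assert abs(np.mean(far) - 0.125) < 0.1

    def test_homogeneous_zero_variance(self):
        field = an.assign_phi("homogeneous", TorusGrid(30, 30), seed=4)
        assert np.ptp(field.phi) == 0.0

    def test_random_uniform_over_eight_directions(self):
        field = an.assign_phi("random", TorusGrid(100, 100), seed=4)
        counts = np.bincount(
            np.rint(field.phi / (np.pi / 4)).astype(int) % 8, minlength=8)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_symmetric_has_no_phi(self):
        assert an.assign_phi("symmetric", TorusGrid(10, 10)).phi is None

    def test_perlin_requires_scale(self):
        with pytest.raises(ValueError, match="perlin_scale"):
            an.assign_phi("perlin", TorusGrid(10, 10))

    def test_symmetric_field_rejects_phi(self):
        with pytest.raises(ValueError):
            DirectionField("symmetric", np.zeros(4))


# ---------------------------------------------------------------------------
# target sampling
# ---------------------------------------------------------------------------

class TestSampleTargets:
    def test_gamma_radial_distribution_matches_oracle(self, rng):
        """Sampled distances reproduce Gamma(4, 3) (two-sample KS against an
        independently rounded oracle sampler)."""
        g = TorusGrid(500, 500)
        prof = ConnectivityProfile("gamma", n_conn=100_000)
        field = an.assign_phi("symmetric", g)
        tgt = sample_targets(g.size // 2 + 250, prof, field, ShiftSpec(0), g,
                             rng=np.random.default_rng(1))
        row, col = g.rowcol(tgt)
        d = np.hypot(_wrap_delta(col - 250, 500), _wrap_delta(row - 250, 500))
        # oracle: same discretization applied to an independent gamma draw
        r = rng.gamma(4.0, 3.0, 200_000)
        a = rng.uniform(0, 2 * np.pi, 200_000)
        ox, oy = np.rint(r * np.cos(a)), np.rint(r * np.sin(a))
        keep = ~((ox == 0) & (oy == 0))
        oracle = np.hypot(ox[keep], oy[keep])
        assert stats.ks_2samp(d, oracle).pvalue > 0.01

    def test_no_self_targets(self, rng):
        g = TorusGrid(30, 30)
        prof = ConnectivityProfile("gamma", n_conn=500)
        field = an.assign_phi("homogeneous", g, seed=1)
        for s in (0, 1, 2):
            tgt = sample_targets(17, prof, field, ShiftSpec(s), g,
                                 rng=np.random.default_rng(2))
            assert 17 not in tgt
            assert tgt.size == 500

    def test_shift_biases_mean_displacement_along_phi(self):
        net = an.build_I_network(nrow=60, ncol=60, n_conn=300,
                                 configuration="homogeneous", shift=1, seed=3)
        phi0 = float(net.fields["I"].phi[0])
        _, dx, dy = _edge_displacements(net)
        along = dx.mean() * np.cos(phi0) + dy.mean() * np.sin(phi0)
        assert along == pytest.approx(1.0, abs=0.15)

    def test_shift_zero_isotropic(self):
        net = an.build_I_network(nrow=60, ncol=60, n_conn=300,
                                 configuration="symmetric", seed=3)
        _, dx, dy = _edge_displacements(net)
        assert abs(dx.mean()) < 0.05 and abs(dy.mean()) < 0.05


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

class TestBuildINetwork:
    def test_exact_out_degree_and_edge_conservation(self, toy_inet):
        t = toy_inet.targets[("I", "I")]
        assert t.shape == (400, 40)
        ind = toy_inet.in_degrees("I", "I")
        assert ind.sum() == 400 * 40
        assert ind.mean() == 40

    def test_no_self_connections(self, toy_inet):
        t = toy_inet.targets[("I", "I")]
        src = np.arange(t.shape[0])[:, None]
        assert not np.any(t == src)

    def test_determinism(self):
        kw = dict(nrow=20, ncol=20, n_conn=40, configuration="perlin",
                  perlin_scale=10, seed=9)
        a = an.build_I_network(**kw)
        b = an.build_I_network(**kw)
        assert np.array_equal(a.targets[("I", "I")], b.targets[("I", "I")])
        assert np.array_equal(a.fields["I"].phi, b.fields["I"].phi)

    def test_in_degree_distribution_similar_across_configurations(self):
        """All four layouts share the same in-degree distribution."""
        nets = {c: an.build_I_network(nrow=40, ncol=40, n_conn=160,
                                      configuration=c, shift=1,
                                      perlin_scale=10, seed=5)
                for c in ("symmetric", "random", "perlin", "homogeneous")}
        base = nets["symmetric"].in_degrees("I", "I")
        for c in ("random", "perlin", "homogeneous"):
            p = stats.ks_2samp(base, nets[c].in_degrees("I", "I")).pvalue
            assert p > 0.01, f"in-degree distribution differs for {c} (p={p})"

    def test_symmetric_configuration_forces_zero_shift(self):
        net = an.build_I_network(nrow=20, ncol=20, n_conn=40,
                                 configuration="symmetric", shift=2, seed=0)
        assert net.shift == 0

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            an.build_I_network(nrow=10, ncol=10, n_conn=100)


class TestBuildEINetwork:
    def test_class_out_degrees(self, toy_ei):
        assert toy_ei.targets[("E", "E")].shape == (576, 29)
        assert toy_ei.targets[("E", "I")].shape == (576, 7)
        assert toy_ei.targets[("I", "E")].shape == (144, 29)
        assert toy_ei.targets[("I", "I")].shape == (144, 7)

    def test_population_ratio(self, toy_ei):
        assert toy_ei.grids["E"].size == 4 * toy_ei.grids["I"].size

    def test_weights_follow_g_ratio(self, toy_ei):
        assert toy_ei.weights_pA["I"] == -8.0 * toy_ei.weights_pA["E"]

    def test_shift_only_on_EE(self):
        net = an.build_EI_network(nrow_E=40, ncol_E=40, nrow_I=20, ncol_I=20,
                                  sigma_EE=4, sigma_EI=2, sigma_IE=5,
                                  sigma_II=2.5, configuration="homogeneous",
                                  shift=1, seed=2)
        phi0 = float(net.fields["E"].phi[0])
        for cls in (("E", "I"), ("I", "E"), ("I", "I")):
            _, dx, dy = _edge_displacements(net, cls)
            along = dx.mean() * np.cos(phi0) + dy.mean() * np.sin(phi0)
            assert abs(along) < 0.1, f"class {cls} not isotropic"
        _, dx, dy = _edge_displacements(net, ("E", "E"))
        along = dx.mean() * np.cos(phi0) + dy.mean() * np.sin(phi0)
        assert along > 0.8


# ---------------------------------------------------------------------------
# measured phi
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pair_500():
    """Full-size grids with reduced out-degree: symmetric + homogeneous.

    The 100x100 grid keeps the Gamma profile's tail well inside the
    half-torus; on small toy grids the wrapped tail distorts angular
    statistics.
    """
    nS = an.build_I_network(n_conn=500, configuration="symmetric", seed=5)
    nH = an.build_I_network(n_conn=500, configuration="homogeneous",
                            shift=1, seed=5)
    return nS, nH


class TestMeasuredPhi:
    def test_degenerate_eastward_targets(self):
        g = TorusGrid(20, 20)
        net = an.Network(populations=("I",), grids={"I": g},
                         targets={("I", "I"): np.array([[1, 2, 3, 4]])},
                         weights_pA={"I": -10.0},
                         fields={"I": None}, shift=0)
        assert an.measured_phi(net, 0) == pytest.approx(0.0)

    def test_zero_out_degree_raises(self):
        g = TorusGrid(20, 20)
        net = an.Network(populations=("I",), grids={"I": g},
                         targets={("I", "I"): np.empty((1, 0), dtype=np.int32)},
                         weights_pA={"I": -10.0}, fields={"I": None}, shift=0)
        with pytest.raises(ValueError, match="out-degree"):
            an.measured_phi(net, 0)

    def test_homogeneous_concentrates_on_assigned_value(self, pair_500):
        net = pair_500[1]
        phi0 = float(net.fields["I"].phi[0])
        measured = np.array([an.measured_phi(net, i) for i in range(200)])
        err = np.angle(np.exp(1j * (measured - phi0)))
        # concentrated (population of measured phis far from uniform,
        # for which the resultant would be ~0.05) and centred on phi0
        assert np.abs(np.mean(np.exp(1j * err))) > 0.7
        assert abs(np.angle(np.mean(np.exp(1j * err)))) < 0.1

    def test_symmetric_uniform_over_circle(self, pair_500):
        """Rayleigh test does not reject uniformity of measured phi."""
        net = pair_500[0]
        measured = np.array([an.measured_phi(net, i) for i in range(400)])
        n = measured.size
        r = np.abs(np.mean(np.exp(1j * measured)))
        z = n * r * r
        p = np.exp(-z) * (1 + (2 * z - z * z) / (4 * n))  # Rayleigh approx
        assert p > 0.05


# ---------------------------------------------------------------------------
# connectivity change and multiplicity
# ---------------------------------------------------------------------------

class TestConnectivityChange:
    @pytest.fixture(scope="class")
    def pair(self, pair_500):
        return pair_500

    def test_zero_shift_no_change(self):
        nS = an.build_I_network(nrow=40, ncol=40, n_conn=160,
                                configuration="symmetric", seed=8)
        nH = an.build_I_network(nrow=40, ncol=40, n_conn=160,
                                configuration="homogeneous", shift=0, seed=8)
        cm = an.connectivity_change(nS, nH, n_dist_bins=8, max_dist=16)
        assert np.all(np.abs(cm.delta) < 0.2)  # sampling noise only

    def test_near_field_probability_roughly_doubles(self, pair):
        """Shifting the ring-shaped cloud roughly doubles the near-field
        connection probability on one side of the phi axis."""
        cm = an.connectivity_change(*pair, n_dist_bins=25)
        ratio = max(cm.H[0, 0] / cm.S[0, 0], cm.H[0, 4] / cm.S[0, 4])
        assert 1.5 < ratio < 2.7

    def test_increase_mirrored_by_opposite_decrease(self, pair):
        cm = an.connectivity_change(*pair, n_dist_bins=25)
        gain = cm.H[0, 4] - cm.S[0, 4]
        loss = cm.S[0, 0] - cm.H[0, 0]
        assert gain > 0 and loss > 0
        assert gain == pytest.approx(loss, rel=0.35)

    def test_mismatched_geometry_raises(self, pair):
        small = an.build_I_network(nrow=20, ncol=20, n_conn=40,
                                   configuration="homogeneous", shift=1, seed=1)
        with pytest.raises(ValueError, match="geometry"):
            an.connectivity_change(pair[0], small)


class TestMultiplicity:
    def test_bruteforce_recount(self):
        from collections import Counter
        net = an.build_I_network(nrow=10, ncol=10, n_conn=50,
                                 configuration="perlin", perlin_scale=5, seed=3)
        h = an.multiplicity_histogram(net)
        src, tgt, _ = net.edge_arrays()
        counter = Counter(Counter(zip(src.tolist(), tgt.tolist())).values())
        for m, c in counter.items():
            assert h[m] == c
        assert h.sum() == len(Counter(zip(src.tolist(), tgt.tolist())))

    def test_unique_sampling_all_multiplicity_one(self):
        g = TorusGrid(10, 10)
        t = np.array([np.random.default_rng(i).choice(100, 20, replace=False)
                      for i in range(100)], dtype=np.int32)
        net = an.Network(populations=("I",), grids={"I": g},
                         targets={("I", "I"): t}, weights_pA={"I": -1.0},
                         fields={"I": None}, shift=0)
        h = an.multiplicity_histogram(net)
        assert h[1] == 100 * 20 and h[2:].sum() == 0

    def test_configuration_has_minute_influence(self):
        """Multiplicity histograms nearly coincide across layouts."""
        hs = {}
        for c in ("symmetric", "perlin"):
            net = an.build_I_network(nrow=40, ncol=40, n_conn=160,
                                     configuration=c, shift=1,
                                     perlin_scale=10, seed=5)
            h = an.multiplicity_histogram(net).astype(float)
            hs[c] = h / h.sum()
        n = max(len(h) for h in hs.values())
        a, b = (np.pad(hs[c], (0, n - len(hs[c]))) for c in hs)
        assert 0.5 * np.abs(a - b).sum() < 0.02  # total variation distance
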