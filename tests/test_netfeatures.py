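"""Graph, dynamic and spectral features against closed forms and
brute-force from-definition oracles."""

import itertools

import numpy as np
import pytest

import gesturenet as gn
from gesturenet.netfeatures import (GLOBAL_FEATURES, HEMI_SCOPES,
                                    SCOPED_FAMILIES, FeatureConfig,
                                    diffusion_efficiency_scope, feature_names,
                                    node_strengths, psd_power,
                                    search_information_scope, strength_scope)

from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# Brute-force oracles (straight from the definitions, no shared code)

def oracle_shortest_path(a, i, j):
    """Min total length over all simple paths, lengths 1/w; returns
    (distance, path)."""
    n = a.shape[0]
    best, best_path = np.inf, None
    for k in range(n - 1):
        for mid in itertools.permutations(
                [v for v in range(n) if v not in (i, j)], k):
            path = (i,) + mid + (j,)
            ok = all(a[u, v] > 0 for u, v in zip(path, path[1:]))
            if not ok:
                continue
            d = sum(1.0 / a[u, v] for u, v in zip(path, path[1:]))
            if d < best - 1e-15:
                best, best_path = d, path
    return best, best_path


def oracle_search_information(a, i, j):
    d, path = oracle_shortest_path(a, i, j)
    if path is None:
        return np.inf
    s = a.sum(axis=1) - np.diag(a)
    p = 1.0
    for u, v in zip(path, path[1:]):
        p *= a[u, v] / s[u]
    return -np.log2(p)


def oracle_global_efficiency(a):
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d, _ = oracle_shortest_path(a, i, j)
            total += 1.0 / d if np.isfinite(d) else 0.0
    return total / (n * (n - 1))


def oracle_mfpt(a, i, j, off=None):
    """Absorbing-chain linear system: h_u = 1 + sum_v p_uv h_v, h_j = 0."""
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    s = off.sum(axis=1)
    keep = [u for u in range(n) if u != j]
    p = off[np.ix_(keep, keep)] / s[keep, None]
    h = np.linalg.solve(np.eye(len(keep)) - p, np.ones(len(keep)))
    return h[keep.index(i)]


def oracle_transitivity(a):
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    w = off / off.max()
    n = a.shape[0]
    num = 0.0
    den = 0.0
    for i in range(n):
        t_i = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    t_i += (w[i, j] * w[j, k] * w[k, i]) ** (1 / 3)
        t_i /= 2.0
        k_i = int((off[i] > 0).sum())
        num += 2 * t_i
        den += k_i * (k_i - 1)
    return num / den if den else 0.0


# ---------------------------------------------------------------------------
# Dynamic features: closed forms

class TestFlexibility:
    def test_constant_assignment_zero(self):
        a = np.ones((4, 10), dtype=int)
        np.testing.assert_array_equal(gn.flexibility(a), 0.0)

    def test_change_every_layer_one(self):
        a = np.tile([1, 2, 1, 2, 1], (3, 1))
        np.testing.assert_array_equal(gn.flexibility(a), 1.0)

    def test_one_change_in_three_layers_half(self):
        a = np.array([[1, 1, 2]])
        assert gn.flexibility(a)[0] == pytest.approx(0.5)

    def test_requires_two_layers(self):
        with pytest.raises(ValueError):
            gn.flexibility(np.ones((3, 1), dtype=int))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        f = gn.flexibility(rng.integers(1, 5, size=(10, 8)))
        assert (f >= 0).all() and (f <= 1).all()


class TestIntegrationRecruitment:
    def test_all_ones_allegiance(self):
        p = np.ones((6, 6))
        members = np.array([0, 1, 2])
        assert gn.integration(p, members, members) == 1.0
        assert gn.recruitment(p, members, members) == 1.0

    def test_block_diagonal_extremes(self):
        p = np.zeros((6, 6))
        p[:3, :3] = 1.0
        p[3:, 3:] = 1.0
        members = np.array([0, 1, 2])
        assert gn.integration(p, members, members) == 0.0
        assert gn.recruitment(p, members, members) == 1.0

    def test_four_node_hand_computation(self):
        p = np.array([[1.0, 0.8, 0.2, 0.4],
                      [0.8, 1.0, 0.6, 0.0],
                      [0.2, 0.6, 1.0, 0.5],
                      [0.4, 0.0, 0.5, 1.0]])
        cortex = np.array([0, 1])
        # integration: mean over {0,1} of mean allegiance to {2,3}
        expected_int = ((0.2 + 0.4) / 2 + (0.6 + 0.0) / 2) / 2
        assert gn.integration(p, cortex, cortex) == pytest.approx(expected_int)
        # recruitment: mean over {0,1} of allegiance to the other member
        assert gn.recruitment(p, cortex, cortex) == pytest.approx(0.8)

    def test_scope_subset_of_cortex(self):
        p = np.array([[1.0, 0.9, 0.1, 0.3],
                      [0.9, 1.0, 0.2, 0.6],
                      [0.1, 0.2, 1.0, 0.7],
                      [0.3, 0.6, 0.7, 1.0]])
        cortex = np.array([0, 1, 2])
        left = np.array([0])
        assert gn.integration(p, left, cortex) == pytest.approx(0.3)
        assert gn.recruitment(p, left, cortex) == pytest.approx((0.9 + 0.1) / 2)

    def test_empty_complement_rejected(self):
        p = np.ones((3, 3))
        with pytest.raises(ValueError):
            gn.integration(p, np.arange(3), np.arange(3))


# ---------------------------------------------------------------------------
# Weighted-graph features

class TestSearchInformation:
    def test_two_nodes_single_edge_zero_bits(self):
        a = np.array([[1.0, 0.7], [0.7, 1.0]])
        si = gn.search_information_matrix(a)
        assert si[0, 1] == pytest.approx(0.0)

    def test_equal_split_one_bit(self):
        # node 0 has two equal edges; following the direct hop costs 1 bit
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.5
        si = gn.search_information_matrix(a)
        assert si[0, 1] == pytest.approx(1.0)
        assert si[0, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, seed):
        a = random_weighted_graph(5, seed, density=0.8)
        si = gn.search_information_matrix(a)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                expect = oracle_search_information(a, i, j)
                if np.isfinite(expect):
                    assert si[i, j] == pytest.approx(expect, abs=1e-9)

    def test_disconnected_pair_excluded_from_scope_mean(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.5  # component {0,1}; 2 and 3 isolated
        val = search_information_scope(a, np.arange(4))
        assert val == pytest.approx(0.0 + 0.0)  # only the 0<->1 pair counts

    def test_asymmetric_in_general(self):
        a = random_weighted_graph(5, 3)
        si = gn.search_information_matrix(a)
        assert not np.allclose(si, si.T)


class TestStrength:
    def test_two_edges_sum(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.2
        a[0, 2] = a[2, 0] = 0.3
        assert node_strengths(a)[0] == pytest.approx(0.5)

    def test_zero_matrix(self):
        assert strength_scope(np.zeros((4, 4)), np.arange(4)) == 0.0

    def test_scope_mean_is_member_mean(self):
        a = random_weighted_graph(6, 1)
        members = np.array([1, 3, 4])
        assert strength_scope(a, members) == pytest.approx(
            node_strengths(a)[members].mean())


class TestDiffusionEfficiency:
    def test_two_node_walk(self):
        a = np.array([[1.0, 0.8], [0.8, 1.0]])
        m = gn.mfpt_matrix(a)
        assert m[0, 1] == pytest.approx(1.0)
        e = gn.diffusion_efficiency_matrix(a)
        assert e[0, 1] == pytest.approx(1.0)

    def test_triangle_adjacent_mfpt_two(self):
        a = np.ones((3, 3))
        m = gn.mfpt_matrix(a)
        assert m[0, 1] == pytest.approx(2.0)
        e = gn.diffusion_efficiency_matrix(a)
        assert e[0, 1] == pytest.approx(0.5)

    def test_disconnected_pair_zero_efficiency(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        e = gn.diffusion_efficiency_matrix(a)
        assert e[0, 2] == 0.0 and e[2, 0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_absorbing_chain_oracle(self, seed):
        a = random_weighted_graph(6, seed)
        m = gn.mfpt_matrix(a)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert m[i, j] == pytest.approx(oracle_mfpt(a, i, j),
                                                    abs=1e-9)


class TestTransitivity:
    def test_unit_triangle_one(self):
        a = np.ones((3, 3))
        assert gn.transitivity(a) == pytest.approx(1.0)

    def test_path_zero(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        a[1, 2] = a[2, 1] = 1.0
        assert gn.transitivity(a) == pytest.approx(0.0)

    def test_four_node_weighted_hand_formula(self):
        a = random_weighted_graph(4, 7, density=0.8)
        assert gn.transitivity(a) == pytest.approx(oracle_transitivity(a),
                                                   abs=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            gn.transitivity(np.ones((2, 2)))


class TestGlobalEfficiency:
    def test_complete_unit_graph_one(self):
        assert gn.global_efficiency(np.ones((5, 5))) == pytest.approx(1.0)

    def test_two_isolated_nodes_zero(self):
        assert gn.global_efficiency(np.eye(2)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        a = random_weighted_graph(6, seed + 20, density=0.5)
        assert gn.global_efficiency(a) == pytest.approx(
            oracle_global_efficiency(a), abs=1e-9)


class TestScalingInvariances:
    """Multiplying all weights by c > 0: strength and efficiency scale by c,
    transitivity and search information are invariant."""

    def test_scaling_behaviour(self):
        a = random_weighted_graph(6, 9)
        c = 3.7
        b = a * c
        np.testing.assert_allclose(node_strengths(b), c * node_strengths(a))
        assert gn.global_efficiency(b) == pytest.approx(
            c * gn.global_efficiency(a))
        assert gn.transitivity(b) == pytest.approx(gn.transitivity(a))
        np.testing.assert_allclose(gn.search_information_matrix(b),
                                   gn.search_information_matrix(a),
                                   atol=1e-9)
        np.testing.assert_allclose(gn.diffusion_efficiency_matrix(b),
                                   gn.diffusion_efficiency_matrix(a),
                                   atol=1e-9)

    def test_permutation_invariance(self):
        a = random_weighted_graph(7, 11)
        rng = np.random.default_rng(1)
        perm = rng.permutation(7)
        b = a[np.ix_(perm, perm)]
        assert gn.transitivity(b) == pytest.approx(gn.transitivity(a))
        assert gn.global_efficiency(b) == pytest.approx(
            gn.global_efficiency(a))
        assert diffusion_efficiency_scope(b, np.arange(7)) == pytest.approx(
            diffusion_efficiency_scope(a, np.arange(7)))
        assert search_information_scope(b, np.arange(7)) == pytest.approx(
            search_information_scope(a, np.arange(7)))


# ---------------------------------------------------------------------------
# Spectral power

class TestPsdPower:
    def _epoch(self, data, fs=500.0):
        rec = gn.Recording(data=data, fs=fs,
                           labels=[f"c{i}" for i in range(data.shape[0])])
        return gn.GestureEpoch(label="Idle", hand="dominant", recording=rec)

    def test_all_zero_epoch(self, small_montage):
        ep = self._epoch(np.zeros((small_montage.n_channels, 1500)))
        vals = psd_power(ep, small_montage)
        assert all(v == 0.0 for v in vals.values())

    def test_amplitude_doubling_quadruples_power(self, small_montage):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((small_montage.n_channels, 2000))
        p1 = psd_power(self._epoch(x), small_montage)
        p2 = psd_power(self._epoch(2 * x), small_montage)
        for k in p1:
            assert p2[k] == pytest.approx(4 * p1[k], rel=1e-9)

    def test_tone_power_parseval(self, small_montage):
        amp = 3.0
        t = np.arange(5000) / 500.0
        x = amp * np.sin(2 * np.pi * 10.0 * t)
        data = np.tile(x, (small_montage.n_channels, 1))
        vals = psd_power(self._epoch(data), small_montage)
        for v in vals.values():
            assert v == pytest.approx(amp ** 2 / 2, rel=0.05)


# ---------------------------------------------------------------------------
# Assembly

class TestAssembly:
    def test_sixty_named_finite_features(self, epoch_features):
        names = feature_names()
        assert len(names) == 60
        assert list(epoch_features) == names
        assert all(np.isfinite(v) for v in epoch_features.values())

    def test_inventory_structure(self):
        names = feature_names()
        network = [n for n in names if not n.startswith("power.")]
        power = [n for n in names if n.startswith("power.")]
        assert len(network) == 57
        assert len(power) == 3
        for fam in SCOPED_FAMILIES:
            assert sum(n.startswith(fam + ".") for n in names) == 9
        for g in GLOBAL_FEATURES:
            assert g in names

    def test_bounded_families(self, epoch_features):
        for name, v in epoch_features.items():
            fam = name.split(".")[0]
            if fam in ("flexibility", "integration", "recruitment",
                       "transitivity", "global_efficiency"):
                assert 0.0 <= v <= 1.0, name

    def test_scope_means_match_definition_oracle(self, coupled_epoch,
                                                 small_montage):
        """Per-scope strength equals the direct definition on each layer."""
        tensor = gn.build_tensor(coupled_epoch)
        cfg = gn.CommunityConfig(repetitions=5, null_permutations=5, seed=1)
        partition, mam, _ = gn.detect_communities(tensor, cfg)
        feats = gn.assemble_features(coupled_epoch, tensor, partition, mam,
                                     small_montage)
        for cortex in ("motor", "cognition", "perception"):
            members = small_montage.scope_members(cortex, "left")
            expect = np.mean([
                np.mean([(tensor.layer(r)[i].sum() - tensor.layer(r)[i, i])
                         for i in members])
                for r in range(tensor.n_layers)])
            assert feats[f"strength.{cortex}.left"] == pytest.approx(
                expect, abs=1e-9)

    def test_time_averaged_gamma_mode(self, coupled_epoch, small_montage):
        tensor = gn.build_tensor(coupled_epoch)
        cfg = gn.CommunityConfig(repetitions=3, null_permutations=3, seed=2)
        partition, mam, _ = gn.detect_communities(tensor, cfg)
        f1 = gn.assemble_features(coupled_epoch, tensor, partition, mam,
                                  small_montage,
                                  FeatureConfig(time_averaged_gamma=True))
        assert len(f1) == 60
        mean_layer = tensor.values.mean(axis=2)
        assert f1["transitivity"] == pytest.approx(
            gn.transitivity(mean_layer))
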