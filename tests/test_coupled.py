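"""Block connectivity, staged calibration, lesioning, and staged recovery."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import hadamard

import hopaux as hx
from _oracles import staged_recovery, sign_ge


class TestSparseMask:
    def test_extreme_densities(self):
        assert not hx.sparse_mask(6, 7, 0.0, seed=0).any()
        assert hx.sparse_mask(6, 7, 1.0, seed=0).all()

    def test_interface_density_from_study_grid(self):
        mask = hx.sparse_mask(200, 1000, 0.05, seed=1)
        assert int(mask.sum()) == 10_000

    @given(density=st.sampled_from([0.03, 0.05, 0.17, 0.5]),
           seed=st.integers(0, 2 ** 16))
    def test_count_is_exact(self, density, seed):
        mask = hx.sparse_mask(40, 50, density, seed)
        assert int(mask.sum()) == round(density * 2000)

    def test_density_out_of_range(self):
        with pytest.raises(ValueError, match="density"):
            hx.sparse_mask(5, 5, 1.2, seed=0)


class TestInterfaceC:
    def test_nonzero_count_and_sign_values(self):
        C = hx.build_interface_C(200, 1000, 0.05, seed=2)
        nz = C[C != 0]
        assert nz.size == 10_000
        assert np.isin(nz, (-1, 1)).all()

    def test_determinism(self):
        a = hx.build_interface_C(20, 100, 0.1, seed=3)
        b = hx.build_interface_C(20, 100, 0.1, seed=3)
        assert np.array_equal(a, b)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            hx.build_interface_C(20, 100, 0.0, seed=0)


class TestAuxiliaryDerivation:
    def test_zero_interface_gives_constant_codes_with_warning(self, small_memories):
        with pytest.warns(UserWarning, match="all zero"):
            aug = hx.derive_auxiliary_patterns(small_memories,
                                               np.zeros((10, 200)))
        for code in aug.auxiliaries:
            assert np.all(code.values == 1)

    def test_single_connection_copies_source_neuron(self, small_memories):
        C = np.zeros((10, 200))
        C[4, 17] = 1.0
        aug = hx.derive_auxiliary_patterns(small_memories, C)
        for m, a in zip(small_memories, aug.auxiliaries):
            assert a.values[4] == m.values[17]

    def test_counts_and_lengths(self, small_memories):
        C = hx.build_interface_C(50, 200, 0.1, seed=4)
        aug = hx.derive_auxiliary_patterns(small_memories, C)
        assert len(aug) == len(small_memories)
        assert aug.n_aux == 50
        with pytest.raises(ValueError):
            hx.derive_auxiliary_patterns(small_memories, np.zeros((10, 99)))


class TestAuxiliaryWeightsAndFeedback:
    def test_auxiliary_matrix_delegates_to_hebbian_rule(self, small_memories):
        C = hx.build_interface_C(50, 200, 0.1, seed=4)
        aug = hx.derive_auxiliary_patterns(small_memories, C)
        D = hx.build_auxiliary_weights(aug.auxiliaries)
        ref = hx.hebbian_weights(aug.auxiliaries)
        assert np.array_equal(D.weights, ref.weights)
        assert np.all(np.diag(D.weights) == 0)

    def test_orthogonal_codes_are_stage4_fixed_points(self):
        H = hadamard(16).astype(np.int8)
        codes = hx.MemorySet(tuple(
            hx.MemoryPattern(H[i], label=f"a{i}") for i in range(1, 5)))
        D = hx.build_auxiliary_weights(codes)
        for code in codes:
            step = hx.update(hx.NetworkState(code.values), D)
            assert np.array_equal(step.spins, code.values)

    def test_feedback_density_zero_is_empty(self, small_memories):
        C = hx.build_interface_C(50, 200, 0.1, seed=4)
        aug = hx.derive_auxiliary_patterns(small_memories, C)
        B = hx.build_feedback_B(small_memories, aug.auxiliaries, 0.0, seed=5)
        assert not B.any()

    def test_dense_feedback_single_pair_is_outer_product(self):
        rng = np.random.default_rng(6)
        mo = hx.MemorySet((hx.MemoryPattern(
            rng.choice(np.array([-1, 1], dtype=np.int8), 12), label="o"),))
        ma = hx.MemorySet((hx.MemoryPattern(
            rng.choice(np.array([-1, 1], dtype=np.int8), 5), label="a"),))
        B = hx.build_feedback_B(mo, ma, 1.0, seed=7)
        assert np.array_equal(B, np.outer(mo[0].values, ma[0].values))

    def test_random_feedback_convention_and_bad_name(self, small_memories):
        C = hx.build_interface_C(50, 200, 0.1, seed=4)
        aug = hx.derive_auxiliary_patterns(small_memories, C)
        B = hx.build_feedback_B(small_memories, aug.auxiliaries, 0.2, seed=8,
                                weights="random")
        nz = B[B != 0]
        assert nz.size == round(0.2 * 200 * 50)
        assert np.isin(nz, (-1, 1)).all()
        with pytest.raises(ValueError, match="convention"):
            hx.build_feedback_B(small_memories, aug.auxiliaries, 0.2, seed=8,
                                weights="magic")


class TestTraining:
    def test_block_shapes_at_study_scale(self):
        ms = hx.generate_synthetic_patterns(20, 1000, 0.2, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, aug = hx.train_augmented_network(ms, n_aux=200,
                                                  density_C=0.05,
                                                  density_B=0.25, seed=2)
        assert net.A.weights.shape == (1000, 1000)
        assert net.B.shape == (1000, 200)
        assert net.C.shape == (200, 1000)
        assert net.D.weights.shape == (200, 200)
        assert net.stage == 5
        assert len(aug.auxiliaries) == 20
        assert aug.n_aux == 200

    def test_zero_feedback_density_gives_zero_block(self, small_memories):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = hx.train_augmented_network(small_memories, n_aux=50,
                                                density_C=0.1, density_B=0.0,
                                                seed=3)
        assert not net.B.any()

    def test_toy_auxiliary_codes_match_hand_computation(self):
        H = hadamard(8).astype(np.int8)
        ms = hx.MemorySet((hx.MemoryPattern(H[1], label="m1"),
                           hx.MemoryPattern(H[2], label="m2")))
        C = hx.build_interface_C(4, 8, 1.0, seed=9)
        aug = hx.derive_auxiliary_patterns(ms, C)
        for m, a in zip(ms, aug.auxiliaries):
            expected = [sign_ge(sum(float(C[i][j]) * int(m.values[j])
                                    for j in range(8))) for i in range(4)]
            assert np.array_equal(a.values, np.array(expected))


@pytest.fixture(scope="module")
def A():
    ms = hx.generate_synthetic_patterns(5, 200, 0.3, seed=3)
    return hx.hebbian_weights(ms)


class TestDamage:

    def test_no_damage_is_identity(self, A):
        out = hx.inject_damage(A, hx.DamageSpec(0.0, seed=1))
        assert np.array_equal(out.weights, A.weights)

    def test_full_damage_clears_everything(self, A):
        out = hx.inject_damage(A, hx.DamageSpec(1.0, seed=1))
        assert not out.weights.any()

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_pair_counting_and_symmetry(self, A, p):
        iu = np.triu_indices(200, k=1)
        n_pairs = int(np.count_nonzero(A.weights[iu]))
        out = hx.inject_damage(A, hx.DamageSpec(p, seed=2))
        survivors = int(np.count_nonzero(out.weights[iu]))
        assert survivors == n_pairs - round(p * n_pairs)
        assert np.array_equal(out.weights, out.weights.T)
        # input untouched
        assert np.count_nonzero(A.weights[iu]) == n_pairs

    def test_asymmetric_mode_counts_directed_entries(self, A):
        n_entries = int(np.count_nonzero(A.weights))
        out = hx.inject_damage(A, hx.DamageSpec(0.3, seed=3, symmetric=False))
        assert int(np.count_nonzero(out.weights)) == n_entries - round(0.3 * n_entries)

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            hx.DamageSpec(1.5, seed=0)


class TestRecovery:
    def test_undamaged_network_retrieves_exact_cue(self, small_net, small_memories):
        net, _ = small_net
        final, trace = hx.recover_memory(net, small_memories[0])
        assert hx.is_retrieved(final, small_memories[0])
        assert set(trace) == {"inj1", "inj2", "inj3", "inj4", "inj5"}

    def test_full_damage_without_feedback_ignores_the_cue(self, small_memories):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = hx.train_augmented_network(small_memories, n_aux=50,
                                                density_C=0.1, density_B=0.0,
                                                seed=3)
        dead = dataclasses.replace(net, A=hx.inject_damage(net.A,
                                                           hx.DamageSpec(1.0, 4)))
        final, _ = hx.recover_memory(dead, small_memories[0])
        # zero recurrent and feedback weights: g(0) = +1 everywhere
        assert np.all(final.spins == 1)
        assert not hx.is_retrieved(final, small_memories[0])

    def test_staged_trace_matches_hand_evaluation(self):
        H = hadamard(8).astype(np.int8)
        ms = hx.MemorySet((hx.MemoryPattern(H[1], label="m1"),
                           hx.MemoryPattern(H[2], label="m2")))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = hx.train_augmented_network(ms, n_aux=4, density_C=1.0,
                                                density_B=1.0, seed=10)
        damaged = dataclasses.replace(
            net, A=hx.inject_damage(net.A, hx.DamageSpec(0.25, seed=11)))
        cue = hx.corrupt_cue(ms[0], hx.NoiseSpec(0.125, seed=12))
        final, trace = hx.recover_memory(damaged, cue)
        expected = staged_recovery(damaged.A.weights, damaged.B, damaged.C,
                                   damaged.D.weights, cue.values)
        for stage, (s_o, s_a) in expected.items():
            assert np.array_equal(trace[stage]["original"], s_o), stage
            if s_a is not None:
                assert np.array_equal(trace[stage]["auxiliary"], s_a), stage
        assert np.array_equal(final.spins, expected["inj5"][0])

    def test_inactive_blocks_cannot_influence_the_trajectory(self, small_net,
                                                             small_memories):
        net, _ = small_net
        damaged = dataclasses.replace(
            net, A=hx.inject_damage(net.A, hx.DamageSpec(0.5, seed=13)))
        cue = hx.corrupt_cue(small_memories[1], hx.NoiseSpec(0.1, 14))
        _, ref = hx.recover_memory(damaged, cue)
        rng = np.random.default_rng(15)

        # feedback block B is active only in stage inj5
        scrambled_B = dataclasses.replace(
            damaged, B=rng.integers(-3, 4, size=damaged.B.shape))
        _, tr = hx.recover_memory(scrambled_B, cue)
        for stage in ("inj1", "inj2", "inj3", "inj4"):
            assert np.array_equal(tr[stage]["original"], ref[stage]["original"])
            if ref[stage]["auxiliary"] is not None:
                assert np.array_equal(tr[stage]["auxiliary"],
                                      ref[stage]["auxiliary"])

        # interface C first acts in stage inj2
        scrambled_C = dataclasses.replace(
            damaged, C=rng.integers(-3, 4, size=damaged.C.shape))
        _, tr = hx.recover_memory(scrambled_C, cue)
        assert np.array_equal(tr["inj1"]["original"], ref["inj1"]["original"])

        # auxiliary matrix D first acts in stage inj3
        scrambled_D = dataclasses.replace(
            damaged, D=hx.WeightMatrix(rng.integers(-3, 4,
                                                    size=damaged.D.weights.shape)))
        _, tr = hx.recover_memory(scrambled_D, cue)
        for stage in ("inj1", "inj2"):
            assert np.array_equal(tr[stage]["original"], ref[stage]["original"])
        assert np.array_equal(tr["inj2"]["auxiliary"], ref["inj2"]["auxiliary"])

    def test_zero_feedback_density_equals_damaged_original_alone(
            self, small_memories):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = hx.train_augmented_network(small_memories, n_aux=50,
                                                density_C=0.1, density_B=0.0,
                                                seed=3)
        damaged = dataclasses.replace(
            net, A=hx.inject_damage(net.A, hx.DamageSpec(0.6, seed=16)))
        for mu in range(len(small_memories)):
            cue = hx.corrupt_cue(small_memories[mu], hx.NoiseSpec(0.15, 17 + mu))
            final, _ = hx.recover_memory(damaged, cue)
            alone = hx.run_to_convergence(cue, damaged.A)
            assert np.array_equal(final.spins, alone.state.spins)

    def test_unclamped_mode_runs_and_retrieves_healthy_cue(self, small_net,
                                                           small_memories):
        net, _ = small_net
        final, trace = hx.recover_memory(net, small_memories[2], clamped=False)
        assert set(trace) == {"inj1", "inj2", "inj3", "inj4", "inj5"}
        assert hx.is_retrieved(final, small_memories[2])

    def test_missing_block_is_named(self, small_net):
        net, _ = small_net
        headless = dataclasses.replace(net, B=None, stage=4)
        with pytest.raises(ValueError, match="block B"):
            hx.recover_memory(headless, net.A.weights[0] * 0 + 1)


class TestSerialisation:
    def test_network_roundtrip(self, small_net, tmp_path):
        net, aug = small_net
        path = tmp_path / "net.npz"
        hx.save_network(net, aug, path)
        net2, aug2 = hx.load_network(path)
        assert np.array_equal(net2.A.weights, net.A.weights)
        assert np.array_equal(net2.B, net.B)
        assert np.array_equal(net2.C, net.C)
        assert np.array_equal(net2.D.weights, net.D.weights)
        assert net2.density_B == net.density_B
        assert aug2.originals.labels == aug.originals.labels
        assert np.array_equal(aug2.auxiliaries.matrix, aug.auxiliaries.matrix)

    def test_block_shape_validation(self):
        A = hx.hebbian_weights(np.ones((1, 6), dtype=np.int8))
        with pytest.raises(ValueError, match="C must be"):
            hx.BlockConnectivity(A=A, B=None, C=np.zeros((3, 5)), D=None,
                                 stage=2)
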