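"""Drive computations: dense vs factorized delays, segment windows, fusion."""

import numpy as np
import pytest

from snnwm import (
    DenseDelayKernel,
    FactorizedDelayKernel,
    FusionHead,
    LIFParams,
    LayerSpec,
    SpikeTrain,
    WorkingMemoryConfig,
    dense_delay_drive,
    factorized_delay_drive,
    layer_forward,
    lif_run,
    segment_drive,
    temporal_fusion,
)
from snnwm.memory_layers import layer_drive

from conftest import random_rank1_instance


def train_1d(bits):
    return SpikeTrain(np.array(bits, dtype=float)[:, None])


class TestDenseDrive:
    def test_hand_unrolled_two_delays(self):
        # W=(0.3 at d=0, 0.7 at d=1), S=[1,0,1] -> I=[0.3, 0.7, 0.3]
        kernel = DenseDelayKernel(W=np.array([[[0.3, 0.7]]]), delays=[0, 1])
        I = dense_delay_drive(train_1d([1, 0, 1]), kernel)
        np.testing.assert_allclose(I.data[:, 0], [0.3, 0.7, 0.3], atol=1e-15)

    def test_single_delay_reduces_to_classic_matmul(self, rng):
        W = rng.normal(size=(3, 2, 1))
        S = SpikeTrain((rng.random((6, 3)) < 0.5).astype(float))
        I = dense_delay_drive(S, DenseDelayKernel(W=W, delays=[0]))
        np.testing.assert_allclose(I.data, S.data @ W[:, :, 0], atol=1e-15)

    def test_zero_input_gives_zero_drive(self):
        kernel = DenseDelayKernel(W=np.ones((2, 2, 2)), delays=[0, 1])
        I = dense_delay_drive(SpikeTrain(np.zeros((4, 2))), kernel)
        assert np.all(I.data == 0)

    def test_unsorted_delays_rejected(self):
        with pytest.raises(ValueError):
            DenseDelayKernel(W=np.ones((1, 1, 2)), delays=[1, 0])


class TestFactorizedDrive:
    def test_hand_unrolled(self):
        # W1=0.5, w2=(1,2), delays {0,1}, S=[1,0,1] -> [0.5, 1.0, 0.5]
        kernel = FactorizedDelayKernel(W1=[[0.5]], w2=[1.0, 2.0], delays=[0, 1])
        I = factorized_delay_drive(train_1d([1, 0, 1]), kernel)
        np.testing.assert_allclose(I.data[:, 0], [0.5, 1.0, 0.5], atol=1e-15)

    def test_matches_dense_on_rank1_kernels(self, rng):
        # the factorized path must equal the brute-force tensor path exactly
        worst = 0.0
        for _ in range(150):
            S, kernel = random_rank1_instance(rng)
            dense = dense_delay_drive(S, kernel.to_dense())
            fact = factorized_delay_drive(S, kernel)
            worst = max(worst, np.abs(dense.data - fact.data).max())
        assert worst < 1e-10

    def test_null_temporal_taps_give_zero(self, rng):
        S, kernel = random_rank1_instance(rng)
        kernel = FactorizedDelayKernel(
            W1=kernel.W1, w2=np.zeros_like(kernel.w2), delays=kernel.delays
        )
        assert np.all(factorized_delay_drive(S, kernel).data == 0)

    def test_parameter_accounting_by_introspection(self):
        k = FactorizedDelayKernel(
            W1=np.ones((4, 3)), w2=np.ones(5), delays=np.arange(5)
        )
        assert k.n_params == 4 * 3 + 5
        assert k.to_dense().n_params == 4 * 3 * 5

    def test_linearity_superposition(self, rng):
        S1, kernel = random_rank1_instance(rng)
        T, Ni = S1.data.shape
        S2 = SpikeTrain((rng.random((T, Ni)) < 0.4).astype(float))
        both = factorized_delay_drive(
            SpikeTrain(np.maximum(0, S1.data + S2.data - S1.data * S2.data)),
            kernel,
        )
        # superposition on the real-valued extension: I(a+b) = I(a) + I(b)
        lin = (
            factorized_delay_drive(S1, kernel).data
            + factorized_delay_drive(S2, kernel).data
            - factorized_delay_drive(
                SpikeTrain(S1.data * S2.data), kernel
            ).data
        )
        np.testing.assert_allclose(both.data, lin, atol=1e-12)


class TestSegmentDrive:
    def test_hand_evaluation_window_constant(self):
        # mem_len=2, W1=1, w2=(.5,.5), S=[1,0,0,1] -> I = 0.5 everywhere
        kernel = FactorizedDelayKernel(W1=[[1.0]], w2=[0.5, 0.5], delays=[0, 1])
        I = segment_drive(train_1d([1, 0, 0, 1]), kernel, mem_len=2)
        np.testing.assert_allclose(I.data[:, 0], [0.5, 0.5, 0.5, 0.5], atol=1e-15)

    def test_uniform_taps_rectify_within_window_permutations(self, rng):
        # with equal w2, shuffling spike times inside a window leaves the
        # drive unchanged
        L, T, Ni, Nj = 4, 16, 3, 2
        kernel = FactorizedDelayKernel(
            W1=rng.normal(size=(Ni, Nj)), w2=np.full(L, 0.25), delays=np.arange(L)
        )
        s = (rng.random((T, Ni)) < 0.4).astype(float)
        base = segment_drive(SpikeTrain(s), kernel, L).data
        for _ in range(10):
            perm = s.copy()
            for m in range(T // L):
                idx = rng.permutation(L)
                perm[m * L : (m + 1) * L] = perm[m * L + idx]
            shuffled = segment_drive(SpikeTrain(perm), kernel, L).data
            np.testing.assert_allclose(shuffled, base, atol=1e-12)

    def test_mem_len_one_reduces_to_classic(self, rng):
        Ni, Nj, T = 3, 2, 8
        W1 = rng.normal(size=(Ni, Nj))
        kernel = FactorizedDelayKernel(W1=W1, w2=[1.0], delays=[0])
        S = SpikeTrain((rng.random((T, Ni)) < 0.5).astype(float))
        I = segment_drive(S, kernel, mem_len=1)
        np.testing.assert_allclose(I.data, S.data @ W1, atol=1e-15)

    def test_window_locality(self, rng):
        # drive inside window m depends only on window-m spikes
        L, T, Ni = 4, 12, 3
        kernel = FactorizedDelayKernel(
            W1=rng.normal(size=(Ni, 2)), w2=rng.normal(size=L), delays=np.arange(L)
        )
        s = (rng.random((T, Ni)) < 0.4).astype(float)
        base = segment_drive(SpikeTrain(s), kernel, L).data
        other = s.copy()
        other[L:] = (rng.random((T - L, Ni)) < 0.6).astype(float)  # windows 1,2
        perturbed = segment_drive(SpikeTrain(other), kernel, L).data
        np.testing.assert_array_equal(perturbed[:L], base[:L])

    def test_strict_mode_rejects_indivisible_T(self):
        kernel = FactorizedDelayKernel(W1=[[1.0]], w2=[0.5, 0.5], delays=[0, 1])
        with pytest.raises(ValueError, match="divisible"):
            segment_drive(train_1d([1, 0, 1]), kernel, mem_len=2)
        # permissive mode zero-pads the final short window instead
        I = segment_drive(train_1d([1, 0, 1]), kernel, 2, pad_final_window=True)
        assert I.data.shape == (3, 1)


class TestTemporalFusion:
    def test_hand_dot_product(self):
        head = FusionHead(W1=[[1.0]], w_time=[0.2, 0.3, 0.5])
        o = temporal_fusion(train_1d([1, 0, 1]), head)
        assert o[0] == pytest.approx(0.7, abs=1e-15)

    def test_uniform_weights_count_spikes(self, rng):
        s = (rng.random((6, 4)) < 0.5).astype(float)
        head = FusionHead(W1=np.ones((4, 1)), w_time=np.ones(6))
        assert temporal_fusion(SpikeTrain(s), head)[0] == s.sum()

    def test_zero_input_zero_output(self):
        head = FusionHead(W1=np.ones((2, 3)), w_time=np.ones(4))
        np.testing.assert_array_equal(
            temporal_fusion(SpikeTrain(np.zeros((4, 2))), head), np.zeros(3)
        )

    def test_uniform_taps_are_permutation_invariant(self, rng):
        s = (rng.random((8, 3)) < 0.5).astype(float)
        head = FusionHead(W1=rng.normal(size=(3, 2)), w_time=np.full(8, 0.125))
        base = temporal_fusion(SpikeTrain(s), head)
        shuffled = temporal_fusion(SpikeTrain(s[rng.permutation(8)]), head)
        np.testing.assert_allclose(shuffled, base, atol=1e-12)

    def test_length_mismatch_rejected(self):
        head = FusionHead(W1=np.ones((1, 1)), w_time=np.ones(4))
        with pytest.raises(ValueError):
            temporal_fusion(train_1d([1, 0]), head)


class TestLayerForward:
    def test_classic_dispatch_equals_lif_over_classic_drive(self, rng):
        Ni, Nj, T = 4, 3, 10
        W1 = rng.normal(size=(Ni, Nj))
        spec = LayerSpec(
            kernel=FactorizedDelayKernel.classic(W1),
            lif=LIFParams(tau=2.0, theta=0.5),
            wm=WorkingMemoryConfig(mode="classic"),
        )
        S = SpikeTrain((rng.random((T, Ni)) < 0.5).astype(float))
        got = layer_forward(S, spec)
        expected = lif_run(
            factorized_delay_drive(S, spec.kernel), spec.lif
        )
        np.testing.assert_array_equal(got.spikes.data, expected.spikes.data)
        np.testing.assert_array_equal(got.V, expected.V)

    def test_overlap_mode_is_causal(self, rng):
        # flipping a future input spike never changes past outputs
        Ni, Nj, T, L = 3, 2, 12, 4
        spec = LayerSpec(
            kernel=FactorizedDelayKernel(
                W1=rng.normal(size=(Ni, Nj)),
                w2=rng.normal(size=L),
                delays=np.arange(L),
            ),
            lif=LIFParams(tau=2.0, theta=0.5),
            wm=WorkingMemoryConfig(mode="overlap", mem_len=L),
        )
        s = (rng.random((T, Ni)) < 0.4).astype(float)
        base = layer_forward(SpikeTrain(s), spec).spikes.data
        t_cut = 6
        s2 = s.copy()
        s2[t_cut + 1 :] = 1.0 - s2[t_cut + 1 :]
        pert = layer_forward(SpikeTrain(s2), spec).spikes.data
        np.testing.assert_array_equal(pert[: t_cut + 1], base[: t_cut + 1])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            WorkingMemoryConfig(mode="bogus")

    def test_classic_layer_requires_single_zero_delay(self):
        with pytest.raises(ValueError):
            LayerSpec(
                kernel=FactorizedDelayKernel(
                    W1=np.ones((1, 1)), w2=[1.0, 1.0], delays=[0, 1]
                ),
                wm=WorkingMemoryConfig(mode="classic"),
            )

    def test_segment_dispatch(self, rng):
        Ni, Nj, T, L = 3, 2, 8, 4
        kernel = FactorizedDelayKernel(
            W1=rng.normal(size=(Ni, Nj)), w2=np.full(L, 0.25), delays=np.arange(L)
        )
        spec = LayerSpec(
            kernel=kernel,
            lif=LIFParams(tau=2.0, theta=0.5),
            wm=WorkingMemoryConfig(mode="segment", mem_len=L),
        )
        S = SpikeTrain((rng.random((T, Ni)) < 0.5).astype(float))
        np.testing.assert_array_equal(
            layer_drive(S, spec).data, segment_drive(S, kernel, L).data
        )
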