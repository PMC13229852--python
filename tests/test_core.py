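"""Forward dynamics: delayed LIF steps, readout, loss and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import delayprop as dp
from delayprop.core import NeuronState, effective_delay


class TestEffectiveDelay:
    @pytest.mark.parametrize(
        "d,D_max,expected",
        [(-12, 25, 0), (12, 25, 24), (0, 25, 12), (-100, 25, 0), (100, 25, 24)],
    )
    def test_mapping_and_clipping(self, d, D_max, expected):
        assert effective_delay(d, D_max) == expected

    @given(st.floats(-40, 40), st.integers(1, 40))
    def test_always_a_legal_buffer_index(self, d, D_max):
        eff = effective_delay(d, D_max)
        assert 0 <= eff <= D_max - 1
        assert eff.dtype == np.int64


def _single_neuron(alpha=0.6, w=None, v_th=1.0, T=10):
    sim = dp.SimParams(alpha=alpha, v_th=v_th, T=T, D_max=3)
    w = np.array([[0.0]]) if w is None else np.asarray(w, dtype=float)
    params = dp.NetworkParams(W_in=w, W_out=np.ones((2, w.shape[0])))
    return sim, params


class TestLifStep:
    def test_subthreshold_integration_hand_value(self):
        # alpha=0.6, v=0.5, weighted input 0.2 -> v'=0.5, no spike
        sim, params = _single_neuron(w=[[0.2]])
        st_ = NeuronState.zeros(params, sim)
        st_.v = np.array([0.5])
        dp.lif_step(st_, np.array([1]), params, sim)
        assert st_.v == pytest.approx([0.5])
        assert st_.z[0] == 0

    def test_soft_reset_subtracts_threshold(self):
        # alpha=0.6, v=1.5, z=1, no input -> v' = 0.9 - 1 = -0.1
        sim, params = _single_neuron()
        st_ = NeuronState.zeros(params, sim)
        st_.v = np.array([1.5])
        st_.z = np.array([1.0])
        dp.lif_step(st_, np.array([0]), params, sim)
        assert st_.v == pytest.approx([-0.1])
        assert st_.z[0] == 0

    def test_rest_is_a_fixed_point(self):
        sim, params = _single_neuron(w=[[0.4]])
        st_ = NeuronState.zeros(params, sim)
        for _ in range(8):
            dp.lif_step(st_, np.array([0]), params, sim)
        assert st_.v == pytest.approx([0.0])

    def test_spike_requires_strictly_exceeding_threshold(self):
        sim, params = _single_neuron(w=[[1.0]])
        st_ = NeuronState.zeros(params, sim)
        dp.lif_step(st_, np.array([1]), params, sim)  # v = 1.0 exactly
        assert st_.z[0] == 0

    def test_dimension_mismatch_rejected(self):
        sim, params = _single_neuron()
        st_ = NeuronState.zeros(params, sim)
        with pytest.raises(ValueError, match="channels"):
            dp.lif_step(st_, np.array([1, 0]), params, sim)

    def test_input_delay_shifts_arrival(self):
        sim = dp.SimParams(T=10, D_max=7)
        lo = -sim.delay_bound
        params = dp.NetworkParams(
            W_in=np.array([[2.0]]),
            W_out=np.ones((1, 1)),
            D_in=np.array([[lo + 4]]),
            flavor_in="synaptic",
        )
        X = np.zeros((10, 1), dtype=np.uint8)
        X[1, 0] = 1
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        # spike at t=1 delayed 4 steps influences the state update of step 5
        assert int(np.argmax(traj.z.any(axis=1))) == 5


class TestSrnnStep:
    def test_zero_recurrence_reduces_to_lif(self, rng):
        sim = dp.SimParams(T=20, D_max=5)
        ff = dp.init_network(3, 4, 2, sim, rng=1)
        rec = ff.copy()
        rec.W_rec = np.zeros((4, 4))
        rec.flavor_rec = "none"
        X = (rng.random((20, 3)) < 0.4).astype(np.uint8)
        t_ff = dp.forward_pass(dp.SpikeRaster(X), ff, sim)
        t_rec = dp.forward_pass(dp.SpikeRaster(X), rec, sim)
        np.testing.assert_array_equal(t_ff.z, t_rec.z)
        np.testing.assert_allclose(t_ff.y, t_rec.y)

    def test_missing_recurrent_weights_rejected(self):
        sim, params = _single_neuron()
        with pytest.raises(ValueError, match="W_rec"):
            dp.srnn_step(NeuronState.zeros(params, sim), np.array([0]), params, sim)

    def test_no_delay_recurrence_uses_previous_spike(self):
        # neuron 1 driven purely by neuron 0's spike through z[t-1] recurrence
        sim = dp.SimParams(alpha=0.6, T=8, D_max=5)
        lo = -sim.delay_bound
        params = dp.NetworkParams(
            W_in=np.array([[2.0], [0.0]]),
            W_out=np.ones((1, 2)),
            W_rec=np.array([[0.0, 0.0], [1.5, 0.0]]),
            D_rec=np.full((2, 2), lo),
            flavor_rec="synaptic",
        )
        X = np.zeros((8, 1), dtype=np.uint8)
        X[0, 0] = 1
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        assert traj.z[0, 0] == 1  # driver fires at state 1
        # consumer sees z[t-1] one update later: fires at state 3
        assert int(np.argmax(traj.z[:, 1])) == 2

    @pytest.mark.parametrize("extra_delay", [0, 2, 4])
    def test_loop_period_grows_with_recurrent_delay(self, extra_delay):
        # two-neuron loop, off-diagonal 1.5*v_th, single seed spike:
        # self-sustained alternating firing whose period grows with the delay
        sim = dp.SimParams(alpha=0.6, T=40, D_max=11)
        lo = -sim.delay_bound
        params = dp.NetworkParams(
            W_in=np.array([[2.0], [0.0]]),
            W_out=np.ones((1, 2)),
            W_rec=np.array([[0.0, 1.5], [1.5, 0.0]]),
            D_rec=np.full((2, 2), lo + extra_delay),
            flavor_rec="synaptic",
        )
        X = np.zeros((40, 1), dtype=np.uint8)
        X[0, 0] = 1
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        fire0 = np.flatnonzero(traj.z[:, 0])
        assert len(fire0) >= 3
        periods = np.diff(fire0)
        assert np.all(periods == periods[0])
        assert periods[0] == 2 * (2 + extra_delay)


class TestReadout:
    def test_pure_decay_without_spikes(self):
        sim = dp.SimParams(kappa=0.9, T=5, D_max=3)
        params = dp.NetworkParams(W_in=np.zeros((1, 1)), W_out=np.array([[1.0]]))
        st_ = NeuronState.zeros(params, sim)
        st_.y = np.array([2.0])
        for _ in range(3):
            dp.readout_step(st_, params, sim)
        assert st_.y == pytest.approx([2.0 * 0.9**3])

    def test_single_spike_geometric_tail(self):
        # z=1 at the first step only: y^t = kappa^(t-1)
        sim = dp.SimParams(kappa=0.99, T=30, D_max=3)
        params = dp.NetworkParams(W_in=np.array([[2.0]]), W_out=np.array([[1.0]]))
        X = np.zeros((30, 1), dtype=np.uint8)
        X[0, 0] = 1
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        t = np.arange(1, 31)
        np.testing.assert_allclose(traj.y[:, 0], 0.99 ** (t - 1), rtol=1e-12)

    def test_near_integrator_limit_grows_linearly(self):
        sim = dp.SimParams(kappa=1 - 1e-9, T=50, D_max=3)
        params = dp.NetworkParams(W_in=np.array([[2.0]]), W_out=np.array([[1.0]]))
        X = np.ones((50, 1), dtype=np.uint8)  # constant drive -> constant z
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        z_steady = traj.z[5:, 0]
        assert z_steady.all()
        increments = np.diff(traj.y[5:, 0])
        np.testing.assert_allclose(increments, 1.0, rtol=1e-6)


class TestForwardPass:
    def test_zero_readout_gives_uniform_softmax_and_log_k_loss(self):
        sim = dp.SimParams(T=1, D_max=3)
        params = dp.NetworkParams(W_in=np.zeros((4, 2)), W_out=np.zeros((20, 4)))
        X = np.zeros((1, 2), dtype=np.uint8)
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim, label=7)
        np.testing.assert_allclose(traj.pi, 1 / 20)
        assert traj.loss == pytest.approx(np.log(20), abs=1e-12)

    def test_hand_computed_two_class_loss(self):
        sim = dp.SimParams(alpha=0.6, kappa=0.5, T=2, D_max=3)
        params = dp.NetworkParams(
            W_in=np.array([[2.0], [2.0]]), W_out=np.array([[1.0, 0.0], [0.0, -1.0]])
        )
        X = np.ones((2, 1), dtype=np.uint8)
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim, label=0)
        # hand trace: z = 1 each step for both neurons;
        # y^1 = (1, -1); y^2 = (1.5, -1.5)
        np.testing.assert_allclose(traj.y, [[1, -1], [1.5, -1.5]])
        expected = -np.log(np.exp(1) / (np.exp(1) + np.exp(-1))) - np.log(
            np.exp(1.5) / (np.exp(1.5) + np.exp(-1.5))
        )
        assert traj.loss == pytest.approx(expected, rel=1e-12)
        assert traj.pred == 0

    def test_sharpening_readout_reduces_loss_of_correct_class(self):
        # the true class has the largest readout at every step, so doubling
        # W_out sharpens every softmax row toward it and the loss drops
        sim = dp.SimParams(T=6, D_max=3)
        params = dp.NetworkParams(
            W_in=np.array([[2.0], [2.0]]), W_out=np.array([[1.0, 0.5], [-0.5, -1.0]])
        )
        raster = dp.SpikeRaster(np.ones((6, 1), dtype=np.uint8))
        loss1 = dp.forward_pass(raster, params, sim, label=0).loss
        sharp = params.copy()
        sharp.W_out *= 2.0
        loss2 = dp.forward_pass(raster, sharp, sim, label=0).loss
        assert loss2 < loss1

    def test_label_out_of_range_rejected(self, net_factory):
        sim, params, raster, _ = net_factory()
        with pytest.raises(ValueError, match="label"):
            dp.forward_pass(raster, params, sim, label=99)

    def test_softmax_rows_normalized(self, net_factory):
        sim, params, raster, label = net_factory(weight_scale=3.0)
        traj = dp.forward_pass(raster, params, sim, label=label)
        np.testing.assert_allclose(traj.pi.sum(axis=1), 1.0, atol=1e-12)
        assert set(np.unique(traj.z)) <= {0.0, 1.0}

    def test_never_spiking_membrane_is_geometric_convolution(self, rng):
        # with an unreachable threshold the membrane is the causal
        # geometric convolution of the delayed weighted inputs
        sim = dp.SimParams(alpha=0.7, v_th=1e9, T=25, D_max=7)
        params = dp.init_network(3, 2, 2, sim, flavor_in="synaptic", rng=2)
        X = (rng.random((25, 3)) < 0.4).astype(np.uint8)
        traj = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        eff = params.eff_in(sim.D_max)
        Xpad = np.vstack([np.zeros((sim.D_max, 3)), X])
        for j in range(2):
            for T_chk in (10, 25):
                expected = 0.0
                for s in range(T_chk):
                    drive = sum(
                        params.W_in[j, i] * Xpad[sim.D_max + s - eff[j, i], i]
                        for i in range(3)
                    )
                    expected += sim.alpha ** (T_chk - 1 - s) * drive
                assert traj.v[T_chk - 1, j] == pytest.approx(expected, rel=1e-12)

    def test_masked_synapses_never_contribute(self, rng):
        sim = dp.SimParams(T=20, D_max=5)
        params = dp.init_network(6, 4, 2, sim, flavor_in="synaptic", density=0.5, rng=3)
        assert params.mask_in is not None and (params.W_in[params.mask_in == 0] == 0).all()
        # zeroing the masked delay entries too must leave dynamics unchanged
        alt = params.copy()
        alt.D_in = np.where(params.mask_in == 1, params.D_in, 0.0)
        X = (rng.random((20, 6)) < 0.5).astype(np.uint8)
        t1 = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        t2 = dp.forward_pass(dp.SpikeRaster(X), alt, sim)
        np.testing.assert_allclose(t1.v, t2.v)

    @given(st.integers(0, 2**31 - 1), st.integers(5, 25))
    def test_markov_chunked_simulation_matches_single_run(self, seed, split):
        rng = np.random.default_rng(seed)
        sim = dp.SimParams(T=30, D_max=7)
        params = dp.init_network(
            4, 3, 2, sim, flavor_in="axonal", flavor_rec="synaptic", recurrent=True, rng=rng
        )
        params.W_in *= 3
        params.W_rec *= 3
        X = (rng.random((30, 4)) < 0.3).astype(np.uint8)
        full = dp.forward_pass(dp.SpikeRaster(X), params, sim)
        state = NeuronState.zeros(params, sim)
        first = dp.forward_pass(dp.SpikeRaster(X[:split]), params, sim, state=state)
        second = dp.forward_pass(dp.SpikeRaster(X[split:]), params, sim, state=state)
        np.testing.assert_array_equal(np.vstack([first.z, second.z]), full.z)
        np.testing.assert_allclose(np.vstack([first.y, second.y]), full.y, rtol=1e-12)


class TestSerialization:
    def test_raster_roundtrip(self, tmp_path, rng):
        X = (rng.random((12, 3)) < 0.5).astype(np.uint8)
        raster = dp.SpikeRaster(X, dt=10.0, label=4)
        path = tmp_path / "raster.npz"
        raster.save(path)
        back = dp.SpikeRaster.load(path)
        np.testing.assert_array_equal(back.spikes, X)
        assert back.dt == 10.0 and back.label == 4

    def test_nonbinary_raster_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dp.SpikeRaster(np.array([[0, 2]]))

    def test_checkpoint_roundtrip(self, tmp_path):
        sim = dp.SimParams(T=12, D_max=5)
        params = dp.init_network(
            3, 4, 2, sim, flavor_in="synaptic", flavor_rec="axonal",
            recurrent=True, density=0.7, rng=5,
        )
        path = tmp_path / "model.npz"
        dp.save_checkpoint(path, params, sim, rng=np.random.default_rng(9))
        back, sim2, rng2 = dp.load_checkpoint(path, with_rng=True)
        assert sim2 == sim
        np.testing.assert_array_equal(back.W_in, params.W_in)
        np.testing.assert_array_equal(back.D_in, params.D_in)
        np.testing.assert_array_equal(back.mask_in, params.mask_in)
        assert back.flavor_in == "synaptic" and back.flavor_rec == "axonal"
        assert rng2.integers(1000) == np.random.default_rng(9).integers(1000)
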