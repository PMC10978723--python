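import numpy as np
import pytest

from spikenav import (
    ActionNetwork,
    AlphaFilter,
    RingGeometry,
    init_feedforward,
    lateral_weight,
    lateral_weight_matrix,
    lif_step,
)
from spikenav.config import LIFCfg, RingCfg


class TestLateralWeights:
    def test_shared_form_worked_values(self):
        # diagonal: excitatory term vanishes, -400/40
        assert lateral_weight(3, 3) == pytest.approx(-10.0)
        # nearest neighbour at 9 degrees
        expected = -10.0 + 1.25 * np.exp(20.0 * (np.cos(np.deg2rad(9)) - 1.0))
        assert lateral_weight(1, 0) == pytest.approx(expected)
        assert lateral_weight(1, 0) == pytest.approx(-9.0228, abs=1e-4)
        # opposite side of the ring: kernel ~ e^-40
        assert lateral_weight(20, 0) == pytest.approx(-10.0, abs=1e-6)

    def test_matrix_is_circulant(self):
        w = lateral_weight_matrix(RingCfg())
        for shift in (1, 7, 19):
            assert np.allclose(w, np.roll(np.roll(w, shift, 0), shift, 1))

    def test_matrix_matches_scalar_in_shared_form(self):
        w = lateral_weight_matrix(40, exc_per_synapse=False, gain=1.0)
        for j, k in [(0, 0), (5, 3), (0, 20), (39, 0)]:
            assert w[j, k] == pytest.approx(lateral_weight(j, k))

    def test_production_form_has_positive_local_lobe(self):
        """The calibrated convention must excite nearest neighbours net of
        the shared inhibition, else no bump can form."""
        w = lateral_weight_matrix(RingCfg())
        assert w[0, 1] > 0  # net local excitation
        assert w[0, 20] < 0  # global inhibition far away
        assert w[0, 0] < 0  # shared self-inhibition

    def test_literal_kernel_is_astronomical(self):
        w = lateral_weight_matrix(40, form="literal", exc_per_synapse=False, gain=1.0)
        assert w[0, 1] > 1e7


class TestFeedforwardInit:
    def test_moments_and_bounds(self, rng):
        w = init_feedforward(441, 40, rng)
        assert w.mean() == pytest.approx(30.0, abs=0.1)
        assert w.std() == pytest.approx(5.0, abs=0.1)
        assert w.min() >= 0.0 and w.max() <= 60.0

    def test_truncation_respects_custom_bounds(self, rng):
        w = init_feedforward(100, 10, rng, mean=1.0, sd=5.0, wmin=0.0, wmax=2.0)
        assert w.min() >= 0.0 and w.max() <= 2.0


class TestAlphaFilter:
    def test_silent_filter_decays_to_zero(self):
        f = AlphaFilter(1, tau_ms=5.0)
        f.add(np.array([2.0]))
        for _ in range(100_000):
            f.step(1e-4)
        assert f.current[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_spike_peaks_at_tau_with_weight_amplitude(self):
        f = AlphaFilter(1, tau_ms=5.0)
        w = 3.7
        f.add(np.array([w]))
        currents = [f.step(1e-4)[0] for _ in range(2000)]
        k_peak = int(np.argmax(currents))
        assert (k_peak + 1) * 0.1 == pytest.approx(5.0)  # ms
        assert currents[k_peak] == pytest.approx(w, rel=1e-9)

    def test_linearity_of_two_spikes(self):
        one = AlphaFilter(1, 5.0)
        one.add(np.array([1.0]))
        resp1 = np.array([one.step(1e-4)[0] for _ in range(300)])

        two = AlphaFilter(1, 5.0)
        two.add(np.array([1.0]))
        out = []
        for k in range(300):
            if k == 100:
                two.add(np.array([1.0]))
            out.append(two.step(1e-4)[0])
        expected = resp1.copy()
        expected[100:] += resp1[:200]
        assert np.allclose(out, expected, rtol=1e-12)


class TestLIF:
    def test_relaxation_to_rest(self):
        p = LIFCfg()
        v = np.array([-60.0])
        ref = np.zeros(1, dtype=int)
        for _ in range(100):  # 10 ms = one tau_m
            v, ref, _ = lif_step(v, ref, np.zeros(1), p, 1e-4)
        assert v[0] == pytest.approx(-70.0 + 10.0 * np.exp(-1.0), rel=1e-9)

    def test_subthreshold_fixed_point(self):
        p = LIFCfg()
        v = np.array([p.E_L])
        ref = np.zeros(1, dtype=int)
        spiked_any = False
        for _ in range(20_000):  # 2 s at constant 250 pA
            v, ref, s = lif_step(v, ref, np.array([250.0]), p, 1e-4)
            spiked_any |= bool(s[0])
        assert not spiked_any
        assert v[0] == pytest.approx(-60.0, rel=1e-6)  # E_L + I tau_m / C_m

    def test_periodic_firing_matches_closed_form_isi(self):
        p = LIFCfg()
        dt = 1e-4
        v = np.array([p.E_L])
        ref = np.zeros(1, dtype=int)
        spike_steps = []
        for k in range(30_000):
            v, ref, s = lif_step(v, ref, np.array([500.0]), p, dt)
            if s[0]:
                spike_steps.append(k)
        isis = np.diff(spike_steps) * dt * 1e3  # ms
        v_inf = p.E_L + 500.0 * p.tau_m / p.C_m  # -50 mV
        closed = p.t_ref + p.tau_m * np.log(
            (v_inf - p.V_reset) / (v_inf - p.V_th)
        )
        assert len(isis) > 100
        assert np.all(np.abs(isis - closed) <= 2 * dt * 1e3)

    def test_refractory_holds_reset_for_t_ref(self):
        p = LIFCfg()
        v = np.array([p.V_th + 1.0])
        ref = np.zeros(1, dtype=int)
        v, ref, s = lif_step(v, ref, np.zeros(1), p, 1e-4)
        assert s[0] and v[0] == p.V_reset
        for _ in range(20):  # 2 ms
            v, ref, s = lif_step(v, ref, np.full(1, 1e5), p, 1e-4)
            assert not s[0] and v[0] == p.V_reset
        # released afterwards: huge current now fires it
        v, ref, s = lif_step(v, ref, np.full(1, 1e5), p, 1e-4)
        assert s[0]


def _drive_pattern(n_inputs, k, period=20):
    """Deterministic input raster: input cell i spikes every `period` steps,
    staggered by cell index, shifted by k cells.  The stagger (7) times the
    ring size (40) is a multiple of the period, so shifting the cell index
    is exactly a rotation of the raster."""
    def spikes_at(step):
        out = np.zeros(n_inputs, dtype=bool)
        out[(step + np.arange(n_inputs) * 7 + k * 7) % period == 0] = True
        return out
    return spikes_at


class TestActionNetwork:
    def test_silent_without_input(self, baseline_cfg):
        net = ActionNetwork(baseline_cfg.ring, baseline_cfg.lif)
        w = np.zeros((10, 40))
        for _ in range(10_000):
            spikes = net.step(np.zeros(10, dtype=bool), w, 1e-4)
            assert not spikes.any()

    def test_localized_drive_forms_contiguous_bump(self, baseline_cfg, rng):
        """Strong feedforward drive peaked on one direction activates one
        contiguous arc of the ring and silences the rest."""
        net = ActionNetwork(baseline_cfg.ring, baseline_cfg.lif)
        geom = RingGeometry(40)
        # one input per action neuron (weights diagonal); input rates peaked
        # on the direction of neuron 12 with a broad angular profile
        w = np.diag(np.full(40, 60.0))
        rates = 3500.0 * np.exp(2.0 * (np.cos(geom.theta - geom.theta[12]) - 1.0))
        counts = np.zeros(40)
        for step in range(20_000):
            in_spk = rng.random(40) < rates * 1e-4
            counts += net.step(in_spk, w, 1e-4)
        active = counts > 0.05 * counts.max()
        assert active[12]
        # active set is one circular arc
        transitions = np.sum(active != np.roll(active, 1)) // 2
        assert transitions == 1
        # silencing: far side of the ring is quiet
        assert counts[32] < 0.1 * counts[12]

    def test_rotating_drive_rotates_spikes(self, baseline_cfg):
        """Ring symmetry: shifting the (deterministic) input pattern by k
        cells shifts the output spike pattern by exactly k neurons."""
        k_shift = 9
        geom = RingGeometry(40)
        kern = np.exp(20.0 * (np.cos(geom.theta[:, None] - geom.theta[None, :]) - 1.0))
        w = 30.0 + 30.0 * kern  # circulant feedforward tuning

        raster_a = _drive_pattern(40, 0)
        raster_b = _drive_pattern(40, k_shift)
        net_a = ActionNetwork(baseline_cfg.ring, baseline_cfg.lif)
        net_b = ActionNetwork(baseline_cfg.ring, baseline_cfg.lif)
        spikes_a, spikes_b = [], []
        for step in range(5000):
            spikes_a.append(net_a.step(raster_a(step), w, 1e-4))
            spikes_b.append(net_b.step(raster_b(step), w, 1e-4))
        spikes_a = np.array(spikes_a)
        spikes_b = np.array(spikes_b)
        assert spikes_a.sum() > 50  # the probe actually drives spiking
        assert np.array_equal(np.roll(spikes_a, -k_shift, axis=1), spikes_b)
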