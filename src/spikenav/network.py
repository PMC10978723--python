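"""Ring-attractor action-selection network of 40 LIF neurons.

Each neuron codes one allocentric movement direction; the preferred
directions tile 360 degrees.  Fixed lateral weights implement
excite-your-neighbours / inhibit-everyone connectivity, so a localised
activity bump forms and selects the movement direction.  Feedforward input
arrives from place cells (plastic weights) and boundary cells (fixed
repulsive weights); every synapse injects an alpha-shaped postsynaptic
current whose peak amplitude in pA equals the weight.

Units: membrane quantities mV / pF / pA, time constants ms; the public step
functions take dt in seconds and convert internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LIFCfg, RingCfg

__all__ = [
    "RingGeometry",
    "lateral_weight",
    "lateral_weight_matrix",
    "init_feedforward",
    "AlphaFilter",
    "lif_step",
    "ActionNetwork",
]


@dataclass(frozen=True)
class RingGeometry:
    """Preferred directions theta_j = j * 360/N and their unit vectors."""

    n_neurons: int = 40

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_neurons) / self.n_neurons

    @property
    def unit_vectors(self) -> np.ndarray:
        th = self.theta
        return np.column_stack([np.cos(th), np.sin(th)])


def lateral_weight(
    j: int,
    k: int,
    n_neurons: int = 40,
    w_inh: float = -400.0,
    w_exc: float = 50.0,
    zeta: float = 20.0,
    form: str = "normalized",
    exc_per_synapse: bool = False,
    gain: float = 1.0,
) -> float:
    """Lateral weight from neuron k onto neuron j.

    The connectivity is  gain * (w_inh/N + w_exc_scale * (1 - delta_jk) * K)
    with K an angular kernel peaked at equal preferred directions: the
    ``normalized`` von-Mises kernel ``exp(zeta*(cos(dtheta) - 1))`` (peak 1,
    the default) or the ``literal`` kernel ``exp(zeta*cos(dtheta))``, which
    at zeta = 20 produces astronomically large excitation and is kept only
    for comparison.  With the defaults (shared division of both terms,
    gain 1) this is the connectivity equation as printed; the *production*
    network (:func:`lateral_weight_matrix` built from a
    :class:`~spikenav.config.RingCfg`) uses per-synapse excitation and a
    calibrated gain, without which no activity bump can form — see the
    methods note.
    """
    if form not in ("normalized", "literal"):
        raise ValueError(f"unknown kernel form {form!r}")
    dtheta = 2.0 * np.pi * (j - k) / n_neurons
    if j % n_neurons == k % n_neurons:
        exc = 0.0
    elif form == "normalized":
        exc = np.exp(zeta * (np.cos(dtheta) - 1.0))
    else:
        exc = np.exp(zeta * np.cos(dtheta))
    exc_div = 1.0 if exc_per_synapse else n_neurons
    return gain * (w_inh / n_neurons + (w_exc / exc_div) * exc)


def lateral_weight_matrix(ring: RingCfg | RingGeometry | int = 40, **kw) -> np.ndarray:
    """Full (N, N) lateral weight matrix; circulant by construction.

    Accepts a :class:`~spikenav.config.RingCfg` (production defaults:
    per-synapse excitation, calibrated gain), a :class:`RingGeometry`, or a
    plain neuron count, with keyword overrides ``w_inh`` / ``w_exc`` /
    ``zeta`` / ``form`` / ``exc_per_synapse`` / ``gain``.  Entry [j, k] is
    the weight from presynaptic k onto postsynaptic j.
    """
    if isinstance(ring, RingCfg):
        n = ring.n_neurons
        params = dict(
            w_inh=ring.w_inh,
            w_exc=ring.w_exc,
            zeta=ring.zeta,
            form=ring.kernel_form,
            exc_per_synapse=ring.exc_per_synapse,
            gain=ring.lateral_gain,
        )
    elif isinstance(ring, RingGeometry):
        n = ring.n_neurons
        params = {}
    else:
        n = int(ring)
        params = {}
    params.update(kw)
    w_inh = params.get("w_inh", -400.0)
    w_exc = params.get("w_exc", 50.0)
    zeta = params.get("zeta", 20.0)
    form = params.get("form", "normalized")
    exc_per_synapse = params.get("exc_per_synapse", True)
    gain = params.get("gain", 4.0)
    if form not in ("normalized", "literal"):
        raise ValueError(f"unknown kernel form {form!r}")
    jj, kk = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dtheta = 2.0 * np.pi * (jj - kk) / n
    if form == "normalized":
        kern = np.exp(zeta * (np.cos(dtheta) - 1.0))
    else:
        kern = np.exp(zeta * np.cos(dtheta))
    exc_div = 1.0 if exc_per_synapse else float(n)
    w = gain * (w_inh / n + (w_exc / exc_div) * (1.0 - np.eye(n)) * kern)
    return w


def init_feedforward(
    n_inputs: int,
    n_neurons: int,
    rng: np.random.Generator,
    mean: float = 30.0,
    sd: float = 5.0,
    wmin: float = 0.0,
    wmax: float = 60.0,
) -> np.ndarray:
    """Initial plastic weights ~ Normal(mean, sd), truncated to [wmin, wmax].

    The bounds sit 6 standard deviations from the mean under the defaults, so
    truncation is essentially never exercised.
    """
    w = rng.normal(mean, sd, size=(n_inputs, n_neurons))
    return np.clip(w, wmin, wmax)


class AlphaFilter:
    """Bank of alpha-function synaptic current filters (one per neuron).

    A spike of weight w injects the current  i(t) = w * (e/tau) * t *
    exp(-t/tau), which peaks at exactly w pA at t = tau.  Implemented as two
    coupled linear state variables propagated exactly over each step, so the
    impulse response is the analytic alpha function sampled on the grid.
    """

    def __init__(self, n: int, tau_ms: float):
        self.tau = float(tau_ms)  # ms
        self.y1 = np.zeros(n)
        self.y2 = np.zeros(n)  # the current, pA

    def add(self, weighted_impulses: np.ndarray) -> None:
        """Deliver spikes: ``weighted_impulses`` is the summed weight (pA of
        eventual peak current) arriving at each neuron this step."""
        self.y1 += np.asarray(weighted_impulses, float) * (np.e / self.tau)

    def step(self, dt: float) -> np.ndarray:
        """Advance by dt seconds; returns the current (pA) after the step."""
        dt_ms = dt * 1e3
        decay = np.exp(-dt_ms / self.tau)
        self.y2 = decay * (self.y2 + dt_ms * self.y1)
        self.y1 = self.y1 * decay
        return self.y2

    @property
    def current(self) -> np.ndarray:
        return self.y2


def lif_step(
    v: np.ndarray,
    refractory_steps: np.ndarray,
    I_total: np.ndarray,
    params: LIFCfg,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential-Euler update of the leaky integrate-and-fire membrane.

    dv/dt = (E_L - v)/tau_m + I/C_m, integrated exactly under the
    piecewise-constant-current assumption:  v -> v_inf + (v - v_inf) *
    exp(-dt/tau_m) with v_inf = E_L + I*tau_m/C_m.  On crossing V_th the
    neuron spikes, resets to V_reset and holds there for t_ref.

    Arrays are updated out-of-place; returns (v, refractory_steps, spiked).
    """
    v = np.asarray(v, float).copy()
    refractory_steps = np.asarray(refractory_steps).copy()
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential")
    dt_ms = dt * 1e3
    ref_total = int(round(params.t_ref / dt_ms))
    in_ref = refractory_steps > 0
    v_inf = params.E_L + np.asarray(I_total, float) * params.tau_m / params.C_m
    decay = np.exp(-dt_ms / params.tau_m)
    v_new = v_inf + (v - v_inf) * decay
    v_new = np.maximum(v_new, params.V_min)
    v_new[in_ref] = params.V_reset
    refractory_steps[in_ref] -= 1
    spiked = (~in_ref) & (v_new >= params.V_th)
    v_new[spiked] = params.V_reset
    refractory_steps[spiked] = ref_total
    return v_new, refractory_steps, spiked


class ActionNetwork:
    """Stateful ring-attractor network stepped at the global dt.

    Per step: (1) feedforward input spikes, weighted by the feedforward
    matrix, and lateral spikes from the *previous* step (one-dt transmission
    delay), are delivered into the excitatory/inhibitory alpha filters by the
    sign of the weight; (2) the filters and membranes advance one step;
    (3) the new spikes are recorded for the readout, plasticity, and the next
    step's lateral input.  State persists across trials by design.
    """

    def __init__(self, ring_cfg: RingCfg, lif_cfg: LIFCfg):
        n = ring_cfg.n_neurons
        self.geometry = RingGeometry(n)
        self.lif = lif_cfg
        self.w_lat = lateral_weight_matrix(ring_cfg)  # property: splits by sign
        self.v = np.full(n, lif_cfg.E_L)
        self.refractory = np.zeros(n, dtype=np.int64)
        self.exc = AlphaFilter(n, lif_cfg.tau_syn_ex)
        self.inh = AlphaFilter(n, lif_cfg.tau_syn_in)
        self.prev_spikes = np.zeros(n, dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.geometry.n_neurons

    def _split_lateral(self) -> None:
        """Per-synapse sign routing: positive lateral weights feed the
        excitatory alpha filter, negative ones the inhibitory filter."""
        self._w_lat_pos = np.where(self.w_lat > 0.0, self.w_lat, 0.0)
        self._w_lat_neg = np.where(self.w_lat > 0.0, 0.0, self.w_lat)

    @property
    def w_lat(self) -> np.ndarray:
        return self._w_lat

    @w_lat.setter
    def w_lat(self, value: np.ndarray) -> None:
        self._w_lat = np.asarray(value, float)
        self._split_lateral()

    def step(self, input_spikes: np.ndarray, w_fwd: np.ndarray, dt: float) -> np.ndarray:
        """Advance one step; returns the boolean spike vector."""
        input_spikes = np.asarray(input_spikes, dtype=bool)
        drive = input_spikes.astype(float) @ w_fwd  # (n_neurons,), all >= 0
        self.exc.add(drive + self._w_lat_pos[:, self.prev_spikes].sum(axis=1))
        self.inh.add(self._w_lat_neg[:, self.prev_spikes].sum(axis=1))
        i_exc = self.exc.step(dt)
        i_inh = self.inh.step(dt)
        I_total = i_exc + i_inh + self.lif.I_e
        self.v, self.refractory, spiked = lif_step(
            self.v, self.refractory, I_total, self.lif, dt
        )
        self.prev_spikes = spiked
        return spiked
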