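"""Motor readout: action spikes -> agent displacement; policy maps.

The movement vector is the exponentially discounted, direction-weighted sum
of recent action-neuron spikes,

    a(t) = s * sum_j sum_{t_j <= t} exp(-(t - t_j)/tau_a) * a_j ,

maintained incrementally as one decaying 2-vector accumulator and applied as
the per-step displacement.  With s = 1e-4 m per spike and tau_a = 0.5 ms the
agent crosses the arena on the timescale of seconds when the bump is active.

This module also defines the fixed boundary-cell projection (cosine-shaped
weights toward the arena centre, so walls and corners repel) and the policy
map used to visualise what the feedforward weights encode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import Arena
from .inputs import PlaceCellPopulation, place_rate
from .network import RingGeometry

__all__ = [
    "ReadoutParams",
    "MovementAccumulator",
    "movement_vector_explicit",
    "boundary_projection",
    "boundary_weight_matrix",
    "policy_map",
]


@dataclass(frozen=True)
class ReadoutParams:
    step_size: float = 1e-4  # metres per spike
    tau_a: float = 0.5  # ms

    def __post_init__(self):
        if self.step_size <= 0 or self.tau_a <= 0:
            raise ValueError("step_size and tau_a must be positive")


class MovementAccumulator:
    """Incremental evaluation of the discounted spike sum.

    Per step: decay by exp(-dt/tau_a), then add s * a_j for every neuron j
    that spiked this step (a spike at the current instant contributes its
    full step size).  The accumulator itself is the displacement applied
    this step.
    """

    def __init__(self, ring: RingGeometry, params: ReadoutParams):
        self.params = params
        self.unit_vectors = ring.unit_vectors
        self.m = np.zeros(2)

    def step(self, spikes: np.ndarray, dt: float) -> np.ndarray:
        self.m = self.m * np.exp(-dt * 1e3 / self.params.tau_a)
        if np.any(spikes):
            self.m = self.m + self.params.step_size * self.unit_vectors[spikes].sum(axis=0)
        return self.m


def movement_vector_explicit(
    spike_times: np.ndarray,
    spike_neurons: np.ndarray,
    t: float,
    ring: RingGeometry,
    params: ReadoutParams,
) -> np.ndarray:
    """Direct evaluation of the discounted double sum at time t (seconds).

    O(n_spikes); the incremental accumulator is the production path, this
    explicit form exists for verification and one-off queries.
    """
    spike_times = np.asarray(spike_times, float)
    spike_neurons = np.asarray(spike_neurons, int)
    mask = spike_times <= t
    if not np.any(mask):
        return np.zeros(2)
    w = np.exp(-(t - spike_times[mask]) * 1e3 / params.tau_a)
    vecs = ring.unit_vectors[spike_neurons[mask]]
    return params.step_size * (w @ vecs)


def boundary_projection(
    bc_center: np.ndarray,
    ring: RingGeometry,
    w_max: float = 60.0,
) -> np.ndarray:
    """Fixed weight row from one boundary cell onto the ring.

    phi is the direction from the cell's centre toward the arena centre; the
    weight onto neuron j is w_max * max(0, cos(theta_j - phi)): inward
    directions are driven, outward directions get nothing.
    """
    bc_center = np.asarray(bc_center, float)
    phi = np.arctan2(-bc_center[1], -bc_center[0])
    return w_max * np.maximum(0.0, np.cos(ring.theta - phi))


def boundary_weight_matrix(
    bc_centers: np.ndarray, ring: RingGeometry, w_max: float = 60.0
) -> np.ndarray:
    """(8, N) fixed projection matrix of all boundary cells (non-plastic)."""
    return np.vstack([boundary_projection(c, ring, w_max) for c in bc_centers])


def policy_map(
    w_fwd_place: np.ndarray,
    pop: PlaceCellPopulation,
    grid: np.ndarray,
    ring: RingGeometry | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Preferred movement direction encoded by the weights at each location.

    At location x the policy vector is  sum_j a_j * (sum_i w_ij *
    rate_i(x)) — each action neuron's unit vector weighted by the total
    place-cell input it would receive there.  ``grid`` is (M, 2); returns
    (M, 2) vectors, optionally normalised to unit length for quiver display.
    """
    if ring is None:
        ring = RingGeometry(w_fwd_place.shape[1])
    rates = place_rate(pop, np.asarray(grid, float))  # (M, N_pc)
    drive = rates @ w_fwd_place  # (M, n_neurons)
    vecs = drive @ ring.unit_vectors  # (M, 2)
    if normalize:
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vecs = np.where(norms > 0, vecs / norms, 0.0)
    return vecs
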