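"""Closed-loop experiment driver: inputs -> network -> readout -> arena -> STDP.

Each 0.1 ms step samples Poisson input spikes at the agent's position, feeds
them through the plastic feedforward weights into the ring attractor,
converts action spikes into a displacement, moves the agent (wall-clamped),
and accumulates STDP eligibility.  On goal entry a single dopamine impulse
converts eligibility into weight change; otherwise nothing is written to the
weights.  Membrane, synaptic, readout and eligibility state all persist
across the 30 trials of a repetition, so consecutive trials start from
different network states even when weights are unchanged.

The production inner loop is a numba kernel (`_trial_kernel`); a pure
numpy/object composition of the module-level operations
(:meth:`Simulation.run_trial_reference`) consumes the identical RNG stream
and is used to cross-validate the kernel on short horizons.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from . import metrics
from .config import Config, repetition_seed
from .environment import (
    Arena,
    GoalZone,
    TrialRecord,
    classify_trial,
    reset_trial,
    apply_displacement,
    in_goal,
)
from .inputs import (
    BoundaryCellPopulation,
    PlaceCellPopulation,
    boundary_rate,
    place_rate,
)
from .network import ActionNetwork, RingGeometry, init_feedforward
from .plasticity import EligibilityTraces, apply_reward
from .readout import MovementAccumulator, ReadoutParams, boundary_weight_matrix

__all__ = [
    "SimulationState",
    "Simulation",
    "RepetitionResult",
    "PerformanceSummary",
    "run_repetition",
    "summarize",
    "sweep",
    "sweep_axis_points",
]


# --------------------------------------------------------------------------
# fused trial kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _trial_kernel(
    # geometry / task
    half, goal_x, goal_y, goal_r2, dt,
    n_steps_max,
    # place cells (separable lattice: index i = iy*n_side + ix)
    grid, n_side, eta, sigma,
    # boundary cells
    bc_cx, bc_cy, bc_hwx, bc_hwy, bc_eta,
    # synapses
    W, w_lat,
    # LIF constants (mV / pA / pF / ms)
    E_L, V_th, V_reset, I_e, tau_m, C_m, ref_steps,
    em, es_e, es_i, k_e, k_i, dt_ms,
    # readout
    ax, ay, step_size, ea,
    # plasticity
    A_plus, ep, ec,
    # persistent state (mutated in place)
    pos, v, refc, y1e, y2e, y1i, y2i, prev_sp, mvec,
    C, pre_tr, post_tr,
    # rng + trajectory buffer
    rng, traj, traj_every,
):
    n_pc = n_side * n_side
    n_in = W.shape[0]
    n_as = W.shape[1]
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    etadt = eta * dt
    bcdt = bc_eta * dt

    g = 1.0  # running eligibility decay folded into C on exit
    entered = False
    blown = False
    steps_done = 0
    traj_n = 0

    rx = np.empty(n_side)
    ry = np.empty(n_side)
    in_spk = np.empty(n_in, np.bool_)
    spk = np.zeros(n_as, np.bool_)

    for k in range(n_steps_max):
        # ---- input spikes at the current position
        u = rng.random(n_in)
        for i in range(n_side):
            dx = pos[0] - grid[i]
            rx[i] = math.exp(-dx * dx * inv2s2)
            dy = pos[1] - grid[i]
            ry[i] = math.exp(-dy * dy * inv2s2)
        idx = 0
        for iy in range(n_side):
            py = etadt * ry[iy]
            for ix in range(n_side):
                in_spk[idx] = u[idx] < py * rx[ix]
                idx += 1
        for b in range(8):
            inside = (
                abs(pos[0] - bc_cx[b]) <= bc_hwx[b]
                and abs(pos[1] - bc_cy[b]) <= bc_hwy[b]
            )
            in_spk[n_pc + b] = inside and (u[n_pc + b] < bcdt)

        # ---- deliver feedforward impulses (weights are nonnegative)
        for i in range(n_in):
            if in_spk[i]:
                for j in range(n_as):
                    y1e[j] += W[i, j] * k_e

        # ---- deliver lateral spikes from the previous step (one-dt delay)
        for kk in range(n_as):
            if prev_sp[kk]:
                for j in range(n_as):
                    w = w_lat[j, kk]
                    if w > 0.0:
                        y1e[j] += w * k_e
                    else:
                        y1i[j] += w * k_i

        # ---- advance alpha filters (exact propagator)
        for j in range(n_as):
            y2e[j] = es_e * (y2e[j] + dt_ms * y1e[j])
            y1e[j] *= es_e
            y2i[j] = es_i * (y2i[j] + dt_ms * y1i[j])
            y1i[j] *= es_i

        # ---- LIF membranes
        n_spk = 0
        for j in range(n_as):
            if refc[j] > 0:
                refc[j] -= 1
                v[j] = V_reset
                spk[j] = False
            else:
                I = y2e[j] + y2i[j] + I_e
                vinf = E_L + I * tau_m / C_m
                vj = vinf + (v[j] - vinf) * em
                if vj >= V_th:
                    spk[j] = True
                    v[j] = V_reset
                    refc[j] = ref_steps
                    n_spk += 1
                else:
                    spk[j] = False
                    v[j] = vj

        # ---- readout and movement
        mvec[0] *= ea
        mvec[1] *= ea
        if n_spk > 0:
            for j in range(n_as):
                if spk[j]:
                    mvec[0] += step_size * ax[j]
                    mvec[1] += step_size * ay[j]
        pos[0] += mvec[0]
        pos[1] += mvec[1]
        if pos[0] > half:
            pos[0] = half
        elif pos[0] < -half:
            pos[0] = -half
        if pos[1] > half:
            pos[1] = half
        elif pos[1] < -half:
            pos[1] = -half
        if not (math.isfinite(pos[0]) and math.isfinite(pos[1])):
            blown = True
            steps_done = k + 1
            break

        # ---- eligibility traces (place rows only); see EligibilityTraces
        # for the pairing-order convention this mirrors
        g *= ec
        amp = A_plus / g
        for i in range(n_pc):
            pre_tr[i] *= ep
        for j in range(n_as):
            post_tr[j] *= ep
        for i in range(n_pc):
            if in_spk[i]:
                pre_tr[i] += 1.0
        for i in range(n_pc):
            if in_spk[i]:
                for j in range(n_as):
                    C[i, j] += amp * post_tr[j]
        if n_spk > 0:
            for j in range(n_as):
                if spk[j]:
                    for i in range(n_pc):
                        C[i, j] += amp * pre_tr[i]
                    post_tr[j] += 1.0

        for j in range(n_as):
            prev_sp[j] = spk[j]

        # ---- trajectory subsampling
        if (k + 1) % traj_every == 0 and traj_n < traj.shape[0]:
            traj[traj_n, 0] = (k + 1) * dt
            traj[traj_n, 1] = pos[0]
            traj[traj_n, 2] = pos[1]
            traj_n += 1

        # ---- goal test on the post-move position
        dxg = pos[0] - goal_x
        dyg = pos[1] - goal_y
        steps_done = k + 1
        if dxg * dxg + dyg * dyg <= goal_r2:
            entered = True
            break

    # fold the running decay into the eligibility matrix
    for i in range(n_pc):
        for j in range(n_as):
            C[i, j] *= g
    return steps_done, entered, blown, traj_n


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Everything that persists across the trials of one repetition."""

    W: np.ndarray  # (n_inputs, n_as) feedforward weights, pA
    v: np.ndarray
    refractory: np.ndarray
    y1e: np.ndarray
    y2e: np.ndarray
    y1i: np.ndarray
    y2i: np.ndarray
    prev_spikes: np.ndarray
    mvec: np.ndarray
    eligibility: np.ndarray  # (n_pc, n_as)
    pre_trace: np.ndarray
    post_trace: np.ndarray

    def copy(self) -> "SimulationState":
        return SimulationState(
            **{f.name: getattr(self, f.name).copy() for f in dataclasses.fields(self)}
        )


@dataclass
class RepetitionResult:
    records: list
    W: np.ndarray
    blown_up: bool = False
    #: per-trial copies of the feedforward matrix (only when requested)
    weight_snapshots: list | None = None

    @property
    def latencies(self) -> np.ndarray:
        return np.array([r.duration for r in self.records])

    @property
    def successes(self) -> np.ndarray:
        return np.array([r.success for r in self.records])


@dataclass
class PerformanceSummary:
    """Latency / hit-rate summary over repetitions (the study's two
    performance measures)."""

    latency_per_trial: np.ndarray  # mean over repetitions, per trial
    hit_rate_per_trial: np.ndarray
    mean_latency: float
    hit_rate: float
    asymptotic_latency: float  # pooled over the last `asymptotic_window` trials
    asymptotic_hit_rate: float
    n_repetitions: int
    asymptotic_window: int = 10


# --------------------------------------------------------------------------
# simulation driver
# --------------------------------------------------------------------------

class Simulation:
    """One fully assembled model: populations, network constants, task."""

    def __init__(self, cfg: Config):
        cfg.validate()
        self.cfg = cfg
        self.arena = Arena(cfg.arena.side)
        self.goal = GoalZone(np.asarray(cfg.goal.center), cfg.goal.radius)
        self.place = PlaceCellPopulation.from_grid(
            cfg.place.n_side, self.arena, cfg.place.sigma, cfg.place.target_center_rate
        )
        self.boundary = BoundaryCellPopulation.from_arena(
            self.arena, cfg.boundary.eta, cfg.boundary.wall_hw, cfg.boundary.corner_hw
        )
        self.ring = RingGeometry(cfg.ring.n_neurons)
        self.w_boundary = boundary_weight_matrix(
            self.boundary.centers, self.ring, cfg.boundary.w_max
        )
        # reuse ActionNetwork for its lateral matrix; per-repetition state is
        # carried in SimulationState arrays
        self.w_lat = ActionNetwork(cfg.ring, cfg.lif).w_lat
        self.n_pc = self.place.n_cells
        self.n_inputs = self.n_pc + self.boundary.n_cells
        if self.place.eta * cfg.sim.dt > 1.0 or cfg.boundary.eta * cfg.sim.dt > 1.0:
            raise ValueError("rate*dt exceeds 1; decrease sim.dt")

    # -- state ------------------------------------------------------------

    def new_state(self, rng: np.random.Generator) -> SimulationState:
        """Fresh repetition state: random plastic weights, resting network."""
        cfg = self.cfg
        n_as = self.ring.n_neurons
        w_place = init_feedforward(
            self.n_pc, n_as, rng, cfg.ff.init_mean, cfg.ff.init_sd, cfg.ff.wmin, cfg.ff.wmax
        )
        W = np.vstack([w_place, self.w_boundary])
        return SimulationState(
            W=W,
            v=np.full(n_as, cfg.lif.E_L),
            refractory=np.zeros(n_as, dtype=np.int64),
            y1e=np.zeros(n_as),
            y2e=np.zeros(n_as),
            y1i=np.zeros(n_as),
            y2i=np.zeros(n_as),
            prev_spikes=np.zeros(n_as, dtype=bool),
            mvec=np.zeros(2),
            eligibility=np.zeros((self.n_pc, n_as)),
            pre_trace=np.zeros(self.n_pc),
            post_trace=np.zeros(n_as),
        )

    # -- production trial (numba) ----------------------------------------

    def run_trial(
        self,
        state: SimulationState,
        rng: np.random.Generator,
        trial_index: int = 0,
        traj_every: int = 100,
        max_steps: int | None = None,
    ) -> TrialRecord:
        cfg = self.cfg
        dt = cfg.sim.dt
        dt_ms = dt * 1e3
        lif = cfg.lif
        n_steps_max = int(round(cfg.trial.timeout / dt))
        if max_steps is not None:
            n_steps_max = min(n_steps_max, max_steps)
        grid = np.linspace(-self.arena.half, self.arena.half, cfg.place.n_side)
        traj = np.empty((n_steps_max // traj_every + 2, 3))
        pos = np.zeros(2)

        steps, entered, blown, traj_n = _trial_kernel(
            self.arena.half,
            self.goal.center[0],
            self.goal.center[1],
            self.goal.radius**2,
            dt,
            n_steps_max,
            grid,
            cfg.place.n_side,
            self.place.eta,
            self.place.sigma,
            np.ascontiguousarray(self.boundary.centers[:, 0]),
            np.ascontiguousarray(self.boundary.centers[:, 1]),
            np.ascontiguousarray(self.boundary.half_widths[:, 0]),
            np.ascontiguousarray(self.boundary.half_widths[:, 1]),
            self.boundary.eta,
            state.W,
            self.w_lat,
            lif.E_L,
            lif.V_th,
            lif.V_reset,
            lif.I_e,
            lif.tau_m,
            lif.C_m,
            int(round(lif.t_ref / dt_ms)),
            math.exp(-dt_ms / lif.tau_m),
            math.exp(-dt_ms / lif.tau_syn_ex),
            math.exp(-dt_ms / lif.tau_syn_in),
            math.e / lif.tau_syn_ex,
            math.e / lif.tau_syn_in,
            dt_ms,
            np.ascontiguousarray(self.ring.unit_vectors[:, 0]),
            np.ascontiguousarray(self.ring.unit_vectors[:, 1]),
            cfg.readout.step_size,
            math.exp(-dt_ms / cfg.readout.tau_a),
            cfg.plasticity.A_plus,
            math.exp(-dt_ms / cfg.plasticity.tau_plus),
            math.exp(-dt_ms / cfg.plasticity.tau_c),
            pos,
            state.v,
            state.refractory,
            state.y1e,
            state.y2e,
            state.y1i,
            state.y2i,
            state.prev_spikes,
            state.mvec,
            state.eligibility,
            state.pre_trace,
            state.post_trace,
            rng,
            traj,
            traj_every,
        )
        duration = steps * dt
        if blown:
            raise FloatingPointError("agent position became non-finite")
        reward_time = None
        if entered:
            reward_time = duration
            # single dopamine impulse: event-exact conversion of eligibility
            state.W[: self.n_pc] = apply_reward(
                state.W[: self.n_pc], state.eligibility, cfg.plasticity
            )
        trajectory = np.vstack([traj[:traj_n], [[duration, pos[0], pos[1]]]])
        outcome = classify_trial(
            duration, entered, cfg.trial.timeout, cfg.trial.success_threshold
        )
        return TrialRecord(
            trial_index=trial_index,
            duration=duration,
            outcome=outcome,
            trajectory=trajectory,
            reward_time=reward_time,
        )

    # -- reference trial (module composition, same RNG stream) ------------

    def run_trial_reference(
        self,
        state: SimulationState,
        rng: np.random.Generator,
        trial_index: int = 0,
        max_steps: int | None = None,
        raster: dict | None = None,
    ) -> tuple[TrialRecord, np.ndarray]:
        """Slow trial driver composing the tested module operations.

        Draws the same per-step random vector as the kernel, so with a
        cloned RNG both paths follow the same spike realisation.  Returns
        (record, positions) with the position after every step.  Intended
        for verification on short horizons.

        If ``raster`` is a dict it is filled with spike rasters: keys
        ``input`` and ``action``, each an (n_spikes, 2) array of
        (cell_id, spike_time_s), suitable for delimited-text dumping.
        """
        cfg = self.cfg
        dt = cfg.sim.dt
        n_steps_max = int(round(cfg.trial.timeout / dt))
        if max_steps is not None:
            n_steps_max = min(n_steps_max, max_steps)

        net = ActionNetwork(cfg.ring, cfg.lif)
        net.v = state.v.copy()
        net.refractory = state.refractory.copy()
        net.exc.y1, net.exc.y2 = state.y1e.copy(), state.y2e.copy()
        net.inh.y1, net.inh.y2 = state.y1i.copy(), state.y2i.copy()
        net.prev_spikes = state.prev_spikes.copy()

        mover = MovementAccumulator(
            self.ring, ReadoutParams(cfg.readout.step_size, cfg.readout.tau_a)
        )
        mover.m = state.mvec.copy()

        elig = EligibilityTraces(self.n_pc, self.ring.n_neurons, cfg.plasticity)
        elig.c = state.eligibility.copy()
        elig.pre_trace = state.pre_trace.copy()
        elig.post_trace = state.post_trace.copy()

        agent = reset_trial(self.arena)
        positions = np.empty((n_steps_max, 2))
        entered = False
        steps = 0
        raster_in: list = []
        raster_as: list = []
        for k in range(n_steps_max):
            u = rng.random(self.n_inputs)
            rates = np.concatenate(
                [
                    place_rate(self.place, agent.position),
                    boundary_rate(self.boundary, agent.position),
                ]
            )
            in_spk = u < rates * dt
            spikes = net.step(in_spk, state.W, dt)
            if raster is not None:
                t_now = (k + 1) * dt
                raster_in.extend((i, t_now) for i in np.where(in_spk)[0])
                raster_as.extend((j, t_now) for j in np.where(spikes)[0])
            a = mover.step(spikes, dt)
            agent = apply_displacement(agent, a, dt, self.arena)
            elig.step(in_spk[: self.n_pc], spikes, dt)
            positions[k] = agent.position
            steps = k + 1
            if in_goal(agent, self.goal):
                entered = True
                break

        # write persistent state back
        state.v, state.refractory = net.v, net.refractory
        state.y1e, state.y2e = net.exc.y1, net.exc.y2
        state.y1i, state.y2i = net.inh.y1, net.inh.y2
        state.prev_spikes = net.prev_spikes
        state.mvec = mover.m
        state.eligibility = elig.c
        state.pre_trace = elig.pre_trace
        state.post_trace = elig.post_trace

        if raster is not None:
            raster["input"] = np.array(raster_in, dtype=float).reshape(-1, 2)
            raster["action"] = np.array(raster_as, dtype=float).reshape(-1, 2)

        duration = steps * dt
        reward_time = None
        if entered:
            reward_time = duration
            state.W[: self.n_pc] = apply_reward(
                state.W[: self.n_pc], state.eligibility, cfg.plasticity
            )
        outcome = classify_trial(
            min(duration, cfg.trial.timeout), entered,
            cfg.trial.timeout, cfg.trial.success_threshold,
        )
        record = TrialRecord(
            trial_index=trial_index,
            duration=duration,
            outcome=outcome,
            trajectory=np.column_stack(
                [np.arange(1, steps + 1) * dt, positions[:steps]]
            ),
            reward_time=reward_time,
        )
        return record, positions[:steps]


def run_repetition(
    cfg: Config,
    seed: int,
    n_trials: int | None = None,
    traj_every: int = 100,
    snapshot_weights: bool = False,
) -> RepetitionResult:
    """One repetition: fresh random weights, ``n_trials`` chained trials.

    All randomness (weight init, then every input spike) comes from one
    seeded stream, so a (config, seed) pair reproduces byte-identically.
    Numerical blow-up in a trial flags the repetition instead of crashing.
    ``snapshot_weights`` stores a copy of the feedforward matrix after each
    trial.
    """
    sim = Simulation(cfg)
    if n_trials is None:
        n_trials = cfg.trial.n_trials
    rng = np.random.default_rng(seed)
    state = sim.new_state(rng)
    records = []
    snaps: list | None = [] if snapshot_weights else None
    try:
        for t in range(n_trials):
            records.append(sim.run_trial(state, rng, trial_index=t, traj_every=traj_every))
            if snaps is not None:
                snaps.append(state.W.copy())
    except FloatingPointError:
        return RepetitionResult(
            records=records, W=state.W, blown_up=True, weight_snapshots=snaps
        )
    return RepetitionResult(records=records, W=state.W, weight_snapshots=snaps)


def summarize(
    repetitions: list, asymptotic_window: int = 10
) -> PerformanceSummary:
    """Escape latency and hit rate, per trial and pooled.

    Latency of a failed trial is its full (timed-out) duration.  Asymptotic
    values pool the last ``asymptotic_window`` trials of every repetition.
    """
    reps = [r for r in repetitions if not getattr(r, "blown_up", False)]
    if not reps:
        raise ValueError("no usable repetitions")
    lat = np.vstack([r.latencies for r in reps])  # (reps, trials)
    suc = np.vstack([r.successes for r in reps])
    w = min(asymptotic_window, lat.shape[1])
    return PerformanceSummary(
        latency_per_trial=lat.mean(axis=0),
        hit_rate_per_trial=suc.mean(axis=0),
        mean_latency=float(lat.mean()),
        hit_rate=float(suc.mean()),
        asymptotic_latency=float(lat[:, -w:].mean()),
        asymptotic_hit_rate=float(suc[:, -w:].mean()),
        n_repetitions=len(reps),
        asymptotic_window=w,
    )


# --------------------------------------------------------------------------
# parameter sweeps
# --------------------------------------------------------------------------

_DEFAULT_AXES = {
    # odd lattice sides; the full study spans 3..101
    "n": [3, 5, 7, 9, 11, 15, 21, 31, 41, 61, 81, 101],
    "sigma": [0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.8, 1.1, 1.4],
    "coverage": [5, 7, 9, 13, 21, 35, 61, 101],
}


def sweep_axis_points(
    axis: str,
    values: list | None = None,
    baseline_n_side: int = 21,
    baseline_sigma: float = 0.2,
) -> list[tuple[int, float]]:
    """(n_side, sigma) pairs for one sweep axis.

    * ``n``: vary lattice side at fixed sigma;
    * ``sigma``: vary field size at fixed lattice;
    * ``coverage``: co-scale so N*sigma^2 stays at its baseline value
      (17.64 m^2 under the defaults), i.e. sigma = n_base*sigma_base/n.

    Even lattice sides are skipped (a field must sit on the start position).
    """
    if axis not in _DEFAULT_AXES:
        raise ValueError(f"axis must be one of {sorted(_DEFAULT_AXES)}")
    if values is None:
        values = _DEFAULT_AXES[axis]
    pts = []
    const = baseline_n_side * baseline_sigma  # sqrt of the coverage index
    for val in values:
        if axis == "sigma":
            pts.append((baseline_n_side, float(val)))
        else:
            n_side = int(val)
            if n_side % 2 == 0 or n_side < 3:
                continue  # infeasible lattice: skip
            if axis == "n":
                pts.append((n_side, baseline_sigma))
            else:
                pts.append((n_side, const / n_side))
    return pts


def sweep(
    cfg: Config,
    axis: str,
    radii: tuple = (0.1, 0.15, 0.2, 0.3),
    values: list | None = None,
    n_repetitions: int | None = None,
    asymptotic_window: int = 10,
    progress: bool = False,
) -> pd.DataFrame:
    """Cross one place-cell axis with the goal radii; returns a tidy table.

    One row per (population, radius): population geometry, the normalised
    peak rate, the three coding metrics, and asymptotic performance.
    """
    if n_repetitions is None:
        n_repetitions = cfg.experiment.n_repetitions
    arena = Arena(cfg.arena.side)
    rows = []
    for n_side, sigma in sweep_axis_points(
        axis, values, cfg.place.n_side, cfg.place.sigma
    ):
        pop = PlaceCellPopulation.from_grid(
            n_side, arena, sigma, cfg.place.target_center_rate
        )
        ov = metrics.overlap_index(pop)
        cov = metrics.coverage_index(pop.n_cells, sigma)
        min_f = metrics.min_fisher_on_path(
            pop, np.zeros(2), np.asarray(cfg.goal.center)
        )
        for r in radii:
            point_cfg = _with_point(cfg, n_side, sigma, r)
            reps = [
                run_repetition(point_cfg, repetition_seed(cfg.experiment.base_seed, i))
                for i in range(n_repetitions)
            ]
            summ = summarize(reps, asymptotic_window)
            rows.append(
                {
                    "n_pc": pop.n_cells,
                    "n_side": n_side,
                    "sigma_pc": sigma,
                    "eta_pc": pop.eta,
                    "goal_radius": r,
                    "overlap_index": ov,
                    "coverage_index": cov,
                    "log2_min_fisher": float(np.log2(min_f)) if min_f > 0 else -np.inf,
                    "latency": summ.asymptotic_latency,
                    "hit_rate": summ.asymptotic_hit_rate,
                }
            )
            if progress:
                print(
                    f"n={pop.n_cells} sigma={sigma:.3g} r={r}: "
                    f"latency={summ.asymptotic_latency:.2f}s "
                    f"hit={summ.asymptotic_hit_rate:.2f}"
                )
    return pd.DataFrame(rows)


def _with_point(cfg: Config, n_side: int, sigma: float, radius: float) -> Config:
    """Copy of ``cfg`` with one sweep point's place/goal parameters."""
    import copy

    out = copy.deepcopy(cfg)
    out.place.n_side = n_side
    out.place.sigma = sigma
    out.goal.radius = radius
    return out.validate()
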