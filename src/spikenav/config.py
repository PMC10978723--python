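"""Configuration handling: defaults, YAML loading, validation, seeds.

Every tunable of the simulation lives in one nested dataclass tree whose
defaults are the baseline study conditions: a 2.4 m square arena, a hidden
goal of radius 0.2 m offset (0.5, 0.5) m from the centre, a 21 x 21 grid of
Gaussian place cells with sigma = 0.2 m normalised to a 3500 Hz summed rate
at the centre, 40 ring-attractor action neurons, and reward-gated symmetric
STDP.  Units follow the conventions of the neuron/plasticity parameter
tables: membrane quantities in mV/pF/pA, time constants in ms; arena
quantities in metres and seconds.  The global step is ``sim.dt`` seconds.

Unknown keys in a config file are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "SimCfg",
    "ArenaCfg",
    "GoalCfg",
    "TrialCfg",
    "PlaceCfg",
    "BoundaryCfg",
    "RingCfg",
    "FeedforwardCfg",
    "LIFCfg",
    "ReadoutCfg",
    "PlasticityCfg",
    "ExperimentCfg",
    "Config",
    "load_config",
    "dump_config",
    "config_to_dict",
    "repetition_seed",
    "run_manifest",
]


class ConfigError(ValueError):
    """Raised when a configuration document is malformed or inconsistent."""


@dataclass
class SimCfg:
    #: global integration step in seconds (0.1 ms)
    dt: float = 1e-4


@dataclass
class ArenaCfg:
    #: side length of the square arena in metres; the arena is centred on (0, 0)
    side: float = 2.4


@dataclass
class GoalCfg:
    #: goal-zone centre in metres, as an offset from the arena centre
    center: tuple[float, float] = (0.5, 0.5)
    #: goal-zone radius in metres
    radius: float = 0.2


@dataclass
class TrialCfg:
    #: hard timeout in seconds; a trial never runs longer
    timeout: float = 5.0
    #: a trial is successful only if the goal is entered before this time (s)
    success_threshold: float = 4.5
    #: trials per repetition
    n_trials: int = 30


@dataclass
class PlaceCfg:
    #: place-field centres form an n_side x n_side lattice (odd, >= 3)
    n_side: int = 21
    #: shared field size sigma in metres
    sigma: float = 0.2
    #: summed population rate at the arena centre used to set the peak rate (Hz)
    target_center_rate: float = 3500.0


@dataclass
class BoundaryCfg:
    #: peak rate of the 8 boundary cells (Hz)
    eta: float = 200.0
    #: half-width of the wall strips perpendicular to the wall (m); the strip
    #: spans the full wall in the other direction
    wall_hw: float = 0.1
    #: half-width of the square corner fields (m)
    corner_hw: float = 0.15
    #: peak weight of the fixed inward (repulsive) projection onto the ring
    w_max: float = 60.0


@dataclass
class RingCfg:
    n_neurons: int = 40
    #: global inhibition strength (shared, divided by n_neurons)
    w_inh: float = -400.0
    #: local excitation strength (divided by n_neurons)
    w_exc: float = 50.0
    #: concentration of the angular kernel
    zeta: float = 20.0
    #: "normalized" (von-Mises kernel with peak 1, the default) or "literal"
    kernel_form: str = "normalized"
    #: if True (default) the excitatory kernel acts at per-synapse strength
    #: (w_exc * K); if False it is additionally divided by n_neurons like the
    #: inhibitory term, which leaves lateral coupling too weak to break the
    #: uniform firing state (see the methods note on the bump condition)
    exc_per_synapse: bool = True
    #: overall gain on the lateral matrix, calibrated once from the
    #: requirement that inhibition from the activity bump silences the
    #: off-bump neurons at the 3500 Hz feedforward operating point
    lateral_gain: float = 4.0


@dataclass
class FeedforwardCfg:
    #: initial plastic weights ~ Normal(mean, sd) truncated to [wmin, wmax]
    init_mean: float = 30.0
    init_sd: float = 5.0
    wmin: float = 0.0
    wmax: float = 60.0


@dataclass
class LIFCfg:
    """Leaky integrate-and-fire parameters (mV / pF / ms / pA)."""

    E_L: float = -70.0
    C_m: float = 250.0
    tau_m: float = 10.0
    t_ref: float = 2.0
    V_th: float = -55.0
    V_reset: float = -70.0
    tau_syn_ex: float = 5.0
    tau_syn_in: float = 5.0
    I_e: float = 0.0
    V_min: float = -math.inf


@dataclass
class ReadoutCfg:
    #: displacement per action-neuron spike (m)
    step_size: float = 1e-4
    #: decay constant of the movement accumulator (ms)
    tau_a: float = 0.5


@dataclass
class PlasticityCfg:
    """Reward-gated symmetric STDP parameters (ms where a time constant)."""

    A_plus: float = 0.002
    tau_plus: float = 20.0
    tau_c: float = 200.0
    tau_n: float = 0.1
    b: float = 0.0
    Wmin: float = 0.0
    Wmax: float = 60.0


@dataclass
class ExperimentCfg:
    #: repetitions per condition.  The full study conditions use 100; the
    #: package default is a reduced 10 so a condition runs on one CPU in
    #: minutes (full fidelity is a config change away).
    n_repetitions: int = 10
    base_seed: int = 12345


@dataclass
class Config:
    sim: SimCfg = field(default_factory=SimCfg)
    arena: ArenaCfg = field(default_factory=ArenaCfg)
    goal: GoalCfg = field(default_factory=GoalCfg)
    trial: TrialCfg = field(default_factory=TrialCfg)
    place: PlaceCfg = field(default_factory=PlaceCfg)
    boundary: BoundaryCfg = field(default_factory=BoundaryCfg)
    ring: RingCfg = field(default_factory=RingCfg)
    ff: FeedforwardCfg = field(default_factory=FeedforwardCfg)
    lif: LIFCfg = field(default_factory=LIFCfg)
    readout: ReadoutCfg = field(default_factory=ReadoutCfg)
    plasticity: PlasticityCfg = field(default_factory=PlasticityCfg)
    experiment: ExperimentCfg = field(default_factory=ExperimentCfg)

    def validate(self) -> "Config":
        """Check cross-field invariants; return self for chaining."""
        if self.sim.dt <= 0:
            raise ConfigError("sim.dt must be positive (seconds)")
        if self.arena.side <= 0:
            raise ConfigError("arena.side must be positive (metres)")
        if self.place.n_side < 3 or self.place.n_side % 2 == 0:
            raise ConfigError(
                "place.n_side must be odd and >= 3 so a place field sits on "
                f"the start position (got {self.place.n_side})"
            )
        if self.place.sigma <= 0:
            raise ConfigError("place.sigma must be positive (metres)")
        if self.goal.radius <= 0:
            raise ConfigError("goal.radius must be positive (metres)")
        half = self.arena.side / 2.0
        cx, cy = self.goal.center
        if abs(cx) + self.goal.radius > half or abs(cy) + self.goal.radius > half:
            raise ConfigError("goal disk must lie fully inside the arena")
        if not (0 < self.trial.success_threshold <= self.trial.timeout):
            raise ConfigError(
                "trial.success_threshold must lie in (0, trial.timeout]"
            )
        if self.ring.kernel_form not in ("normalized", "literal"):
            raise ConfigError(
                "ring.kernel_form must be 'normalized' or 'literal' "
                f"(got {self.ring.kernel_form!r})"
            )
        if not (self.ff.wmin <= self.ff.init_mean <= self.ff.wmax):
            raise ConfigError("ff.init_mean must lie within [wmin, wmax]")
        if self.lif.V_reset > self.lif.V_th:
            raise ConfigError("lif.V_reset must not exceed lif.V_th")
        dt_ms = self.sim.dt * 1e3
        for name, tau in [
            ("lif.tau_m", self.lif.tau_m),
            ("lif.tau_syn_ex", self.lif.tau_syn_ex),
            ("lif.tau_syn_in", self.lif.tau_syn_in),
            ("readout.tau_a", self.readout.tau_a),
            ("plasticity.tau_plus", self.plasticity.tau_plus),
            ("plasticity.tau_c", self.plasticity.tau_c),
            ("plasticity.tau_n", self.plasticity.tau_n),
        ]:
            if tau < 5.0 * dt_ms:
                warnings.warn(
                    f"{name} = {tau} ms is below 5*dt = {5 * dt_ms} ms; "
                    "per-step integration of this variable is coarse "
                    "(the dopamine transient is handled event-exactly)",
                    stacklevel=2,
                )
        return self


def _merge(obj: Any, data: dict, prefix: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            known = ", ".join(sorted(fields))
            raise ConfigError(
                f"unknown config key '{prefix}{key}' (known: {known})"
            )
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"'{prefix}{key}' must be a mapping")
            _merge(current, value, prefix=f"{prefix}{key}.")
        else:
            if key == "center":
                value = tuple(float(v) for v in value)
            elif isinstance(current, bool):
                value = bool(value)
            elif isinstance(current, int) and not isinstance(value, bool):
                if isinstance(value, float) and not value.is_integer():
                    raise ConfigError(f"'{prefix}{key}' must be an integer")
                value = int(value)
            elif isinstance(current, float):
                if isinstance(value, str) and value in (".inf", "-.inf", "inf", "-inf"):
                    value = float(value.replace(".", ""))
                value = float(value)
            setattr(obj, key, value)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Build a validated :class:`Config` from an optional YAML file.

    An empty or missing document yields the full baseline defaults.  Keys not
    present in the schema raise :class:`ConfigError` naming the offending key.
    ``overrides`` (a nested dict) is applied after the file.
    """
    cfg = Config()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"top level of {path} must be a mapping")
        _merge(cfg, data, prefix="")
    if overrides:
        _merge(cfg, overrides, prefix="")
    return cfg.validate()


def config_to_dict(cfg: Config) -> dict:
    d = dataclasses.asdict(cfg)
    d["goal"]["center"] = list(d["goal"]["center"])
    return d


def dump_config(cfg: Config, path: str | Path | None = None) -> str:
    """Serialise a config to YAML; load(dump(cfg)) round-trips."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def repetition_seed(base_seed: int, repetition_id: int) -> int:
    """Deterministic per-repetition seed: one RNG stream per repetition."""
    return int(base_seed) + int(repetition_id)


def run_manifest(cfg: Config, n_repetitions: int, outputs: list[str]) -> dict:
    """Metadata sufficient to reproduce a run byte-identically."""
    doc = dump_config(cfg)
    return {
        "config_sha256": hashlib.sha256(doc.encode()).hexdigest(),
        "base_seed": cfg.experiment.base_seed,
        "repetition_seeds": [
            repetition_seed(cfg.experiment.base_seed, r) for r in range(n_repetitions)
        ],
        "outputs": list(outputs),
    }
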