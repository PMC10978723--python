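"""Spatial input layer: Gaussian place cells and rectangular boundary cells.

Place cells are laid out on a uniform square lattice spanning the arena
(including the borders), all sharing one field size ``sigma`` and one peak
rate ``eta``.  The peak rate is not free: it is set so that the *summed*
population rate at the arena centre equals a target (3500 Hz under baseline
conditions), which keeps the total feedforward drive onto the action network
comparable as cell number and field size are varied.

Eight boundary cells fire at a fixed rate inside rectangular fields hugging
the four walls and four corners; their projection onto the action network
(defined in :mod:`spikenav.readout`) repels the agent inward.

All cells are inhomogeneous Poisson sources, sampled per step as Bernoulli
events with probability rate*dt (exact to O(dt^2) at dt = 0.1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import Arena

__all__ = [
    "PlaceCellPopulation",
    "BoundaryCellPopulation",
    "make_place_grid",
    "place_rate",
    "normalize_peak_rate",
    "boundary_rate",
    "sample_spikes",
    "active_input_budget",
]


def make_place_grid(n_side: int, arena: Arena) -> np.ndarray:
    """Centres of an ``n_side`` x ``n_side`` lattice spanning the arena.

    The lattice includes the borders, so the spacing is side/(n_side - 1)
    and — because ``n_side`` is odd — one centre sits exactly on the arena
    centre, where the agent starts every trial.

    Returns an (n_side**2, 2) array ordered with x varying fastest.
    """
    if n_side < 3 or n_side % 2 == 0:
        raise ValueError(
            f"n_side must be odd and >= 3 (got {n_side}); an odd count puts "
            "a place field on the start position"
        )
    coords = np.linspace(-arena.half, arena.half, n_side)
    xx, yy = np.meshgrid(coords, coords)  # row = y, column = x
    return np.column_stack([xx.ravel(), yy.ravel()])


def normalize_peak_rate(
    centers: np.ndarray,
    sigma: float,
    target_sum: float = 3500.0,
    at: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Peak rate eta such that the summed population rate at ``at`` is
    ``target_sum`` Hz.

    The Gaussian lattice sum is strictly positive, so a solution always
    exists; eta is never capped.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    d2 = np.sum((np.asarray(centers, float) - np.asarray(at, float)) ** 2, axis=1)
    s = float(np.sum(np.exp(-d2 / (2.0 * sigma**2))))
    return target_sum / s


@dataclass(frozen=True)
class PlaceCellPopulation:
    """Uniform lattice of Gaussian place cells with shared sigma and eta."""

    centers: np.ndarray  # (N, 2) metres
    sigma: float  # metres
    eta: float  # Hz
    n_side: int

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")

    @classmethod
    def from_grid(
        cls,
        n_side: int,
        arena: Arena,
        sigma: float,
        target_center_rate: float = 3500.0,
        eta: float | None = None,
    ) -> "PlaceCellPopulation":
        """Build the lattice population; unless ``eta`` is given explicitly,
        the peak rate is set by the centre-rate normalisation."""
        centers = make_place_grid(n_side, arena)
        if eta is None:
            eta = normalize_peak_rate(centers, sigma, target_center_rate)
        return cls(centers=centers, sigma=sigma, eta=eta, n_side=n_side)

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    @property
    def spacing(self) -> float:
        """Lattice spacing d (metres)."""
        xs = np.unique(self.centers[:, 0])
        return float(xs[1] - xs[0])


def place_rate(pop: PlaceCellPopulation, x: np.ndarray) -> np.ndarray:
    """Gaussian firing-rate map of every place cell at position(s) ``x``.

    ``x`` may be a single 2-vector (returns shape (N,)) or an (M, 2) batch
    (returns (M, N)).  Rates lie in (0, eta].
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = x[None, :] if single else x
    d2 = np.sum((pts[:, None, :] - pop.centers[None, :, :]) ** 2, axis=2)
    rates = pop.eta * np.exp(-d2 / (2.0 * pop.sigma**2))
    return rates[0] if single else rates


@dataclass(frozen=True)
class BoundaryCellPopulation:
    """Eight rectangular boundary cells: four wall strips, four corners."""

    centers: np.ndarray  # (8, 2) metres
    half_widths: np.ndarray  # (8, 2) metres
    eta: float  # Hz

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "half_widths", np.asarray(self.half_widths, dtype=float))
        if self.centers.shape != (8, 2) or self.half_widths.shape != (8, 2):
            raise ValueError("exactly 8 boundary cells with (8, 2) geometry arrays")

    @classmethod
    def from_arena(
        cls,
        arena: Arena,
        eta: float = 200.0,
        wall_hw: float = 0.1,
        corner_hw: float = 0.15,
    ) -> "BoundaryCellPopulation":
        """Wall cells are strips along each wall (full wall length, narrow
        perpendicular extent ``wall_hw``); corner cells are squares of
        half-width ``corner_hw``."""
        h = arena.half
        centers = np.array(
            [
                [h, 0.0],  # east wall
                [-h, 0.0],  # west wall
                [0.0, h],  # north wall
                [0.0, -h],  # south wall
                [h, h],
                [-h, h],
                [-h, -h],
                [h, -h],
            ]
        )
        half_widths = np.array(
            [
                [wall_hw, h],
                [wall_hw, h],
                [h, wall_hw],
                [h, wall_hw],
                [corner_hw, corner_hw],
                [corner_hw, corner_hw],
                [corner_hw, corner_hw],
                [corner_hw, corner_hw],
            ]
        )
        return cls(centers=centers, half_widths=half_widths, eta=eta)

    @property
    def n_cells(self) -> int:
        return 8


def boundary_rate(pop: BoundaryCellPopulation, x: np.ndarray) -> np.ndarray:
    """Rectangular rate map: eta inside a cell's box (edges inclusive), else 0."""
    x = np.asarray(x, dtype=float)
    inside = np.all(np.abs(x[None, :] - pop.centers) <= pop.half_widths, axis=1)
    return np.where(inside, pop.eta, 0.0)


def sample_spikes(rates: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """One Bernoulli draw per cell with p = rate*dt (Poisson at small dt).

    Raises if any rate*dt exceeds 1, which signals a step too coarse for the
    Bernoulli approximation.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    p = rates * dt
    if np.any(p > 1.0):
        raise ValueError(
            f"rate*dt reaches {p.max():.3g} > 1; decrease dt for valid sampling"
        )
    return rng.random(rates.shape) < p


def active_input_budget(
    n_cells: int = 10_000,
    active_percent: int = 25,
    coverage_percent: int = 15,
    rate_hz: int = 10,
) -> tuple[int, int]:
    """Back-of-envelope input budget for a downstream neuron.

    Of ``n_cells`` afferent place cells, ``active_percent`` % have a field in
    the current environment and each field covers ``coverage_percent`` % of
    its area, so ``n_cells * active% * coverage%`` cells are co-active at any
    moment; at ``rate_hz`` each, the total afferent rate follows.  Integer
    arithmetic throughout.

    Returns (n_active, total_rate_hz): (375, 3750) under the defaults, the
    biological counterpart of the model's 3500 Hz centre-rate target.
    """
    n_active = n_cells * active_percent * coverage_percent // 10_000
    return n_active, n_active * rate_hz
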