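"""Spatial-coding efficiency measures of the place-cell population.

Three summaries quantify how a lattice of Gaussian place fields encodes
position:

* **overlap index** — the rate of a cell evaluated at its nearest
  neighbour's field centre, normalised by the peak rate:
  exp(-d^2 / (2 sigma^2)) for lattice spacing d.  Ranges over (0, 1),
  independent of the peak rate; measures field redundancy.
* **coverage index** — N * sigma^2 (m^2), a proxy for total field area.
* **Fisher information** — for independent Poisson cells with Gaussian
  tuning, the 2x2 Fisher matrix at x has the closed form

      J(x) = (1/sigma^4) * sum_i (x - x_i) (x - x_i)^T * rate_i(x)

  (units m^-2 per unit observation time).  The scalar summary is the mean
  of the diagonal; navigation performance tracks the *minimum* of this
  scalar along the straight start-to-goal path, because sparse populations
  leave low-information gaps between fields.
"""

from __future__ import annotations

import numpy as np

from .inputs import PlaceCellPopulation, place_rate

__all__ = [
    "overlap_index",
    "coverage_index",
    "fisher_matrix",
    "fisher_scalar",
    "fisher_scalar_at",
    "min_fisher_on_path",
]


def _lattice_spacing(pop: PlaceCellPopulation) -> float:
    """Spacing of the uniform lattice; raises if centres are not uniform."""
    xs = np.unique(np.round(pop.centers[:, 0], 12))
    ys = np.unique(np.round(pop.centers[:, 1], 12))
    if len(xs) < 2:
        raise ValueError("overlap index needs at least 2 distinct field columns")
    dx = np.diff(xs)
    dy = np.diff(ys)
    if not (np.allclose(dx, dx[0], rtol=1e-9) and np.allclose(dy, dy[0], rtol=1e-9)
            and np.isclose(dx[0], dy[0], rtol=1e-9)):
        raise ValueError("overlap index is defined only for a uniform square lattice")
    return float(dx[0])


def overlap_index(pop: PlaceCellPopulation) -> float:
    """Rate at the nearest neighbouring field centre over the peak rate.

    Evaluated through the actual rate map (so it is exp(-d^2/(2 sigma^2))
    by construction) and independent of the peak rate eta.
    """
    d = _lattice_spacing(pop)
    # evaluate cell at a neighbour centre d away through the rate map itself
    i_center = int(np.argmin(np.sum(pop.centers**2, axis=1)))
    x_neighbor = pop.centers[i_center] + np.array([d, 0.0])
    rate = place_rate(pop, x_neighbor)[i_center]
    return float(rate / pop.eta)


def coverage_index(n_cells: int, sigma: float) -> float:
    """N * sigma^2 in m^2 — the population's field-area proxy."""
    if n_cells < 1 or sigma <= 0:
        raise ValueError("need n_cells >= 1 and sigma > 0")
    return n_cells * sigma**2


def fisher_matrix(pop: PlaceCellPopulation, x: np.ndarray) -> np.ndarray:
    """Closed-form 2x2 Fisher information matrix at position x (m^-2)."""
    x = np.asarray(x, dtype=float)
    diff = x[None, :] - pop.centers  # (N, 2)
    rates = place_rate(pop, x)  # (N,)
    outer = diff[:, :, None] * diff[:, None, :]  # (N, 2, 2)
    return np.sum(outer * rates[:, None, None], axis=0) / pop.sigma**4


def fisher_scalar(J: np.ndarray) -> float:
    """Mean of the diagonal of the (symmetric) Fisher matrix."""
    J = np.asarray(J, dtype=float)
    if not np.allclose(J, J.T, rtol=1e-8, atol=1e-8):
        raise ValueError("Fisher matrix must be symmetric")
    return float(np.trace(J) / J.shape[0])


def fisher_scalar_at(pop: PlaceCellPopulation, x: np.ndarray) -> float:
    return fisher_scalar(fisher_matrix(pop, x))


def min_fisher_on_path(
    pop: PlaceCellPopulation,
    start: np.ndarray,
    goal_center: np.ndarray,
    n_samples: int = 100,
) -> float:
    """Minimum scalar Fisher information on the closed segment
    [start, goal_center], sampled at ``n_samples`` evenly spaced points
    (endpoints included)."""
    if n_samples < 2:
        raise ValueError("need at least 2 path samples")
    start = np.asarray(start, float)
    goal_center = np.asarray(goal_center, float)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + ts[:, None] * (goal_center - start)[None, :]
    diff = pts[:, None, :] - pop.centers[None, :, :]  # (M, N, 2)
    rates = place_rate(pop, pts)  # (M, N)
    d2 = np.sum(diff**2, axis=2)  # |x - x_i|^2; trace of the outer product
    scalars = np.sum(d2 * rates, axis=1) / (2.0 * pop.sigma**4)
    return float(np.min(scalars))
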