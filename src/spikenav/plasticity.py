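"""Reward-gated symmetric STDP with eligibility traces and dopamine.

Three-factor learning rule on the place-cell -> action-neuron weights:

    dw/dt = c * (n - b)
    dc/dt = -c/tau_c + Psi(dt_pair) * delta(t - s_pre/post)
    dn/dt = -n/tau_n + (1/tau_n) * delta(t - s_n)

with the purely potentiating, symmetric pairing window
Psi(dt) = A_plus * exp(-|dt|/tau_plus) applied all-to-all.  Every pre/post
spike pairing deposits eligibility on its synapse; the eligibility decays
with tau_c; a single dopamine impulse at reward (time-integral exactly 1)
converts the eligibility standing at that moment into weight change.
Failures release no dopamine, so weights are untouched — learning is purely
appetitive.

The all-to-all pairing sum is computed online with one presynaptic and one
postsynaptic exponential trace (time constant tau_plus), which reproduces
the explicit sum over all spike pairs exactly.  Because tau_n (0.1 ms) is
at the integration step, the dopamine transient is treated as an impulse
and the reward update applied event-exactly (delta_w = c at reward); the
per-step ODE integration of n is retained here for verification.
"""

from __future__ import annotations

import numpy as np

from .config import PlasticityCfg

__all__ = [
    "stdp_window",
    "EligibilityTraces",
    "dopamine_step",
    "dopamine_integral",
    "weight_update",
    "apply_reward",
]


def stdp_window(delta_t: float | np.ndarray, params: PlasticityCfg) -> np.ndarray:
    """Symmetric pairing window Psi(dt) = A_plus * exp(-|dt|/tau_plus).

    ``delta_t`` in seconds (post minus pre); both spike orders potentiate.
    """
    dt_ms = np.asarray(delta_t, float) * 1e3
    return params.A_plus * np.exp(-np.abs(dt_ms) / params.tau_plus)


class EligibilityTraces:
    """Per-synapse eligibility c for an (n_pre, n_post) plastic projection.

    Stepping convention (spikes are attributed to the *end* of the step,
    t_k = (k+1)*dt):

    1. decay c, pre-trace and post-trace over dt;
    2. add this step's presynaptic spikes to the pre-trace;
    3. presynaptic spikes pair with the post-trace (which excludes this
       step's postsynaptic spikes);
    4. postsynaptic spikes pair with the pre-trace (which includes this
       step's presynaptic spikes, so a simultaneous pair is counted exactly
       once, at Psi(0) = A_plus);
    5. add this step's postsynaptic spikes to the post-trace.

    This reproduces sum over all (pre, post) pairs of
    Psi(t_post - t_pre) * exp(-(t_now - t_later)/tau_c)  exactly.
    """

    def __init__(self, n_pre: int, n_post: int, params: PlasticityCfg):
        self.params = params
        self.c = np.zeros((n_pre, n_post))
        self.pre_trace = np.zeros(n_pre)
        self.post_trace = np.zeros(n_post)

    def step(self, pre_spikes: np.ndarray, post_spikes: np.ndarray, dt: float) -> None:
        p = self.params
        dt_ms = dt * 1e3
        self.c *= np.exp(-dt_ms / p.tau_c)
        ep = np.exp(-dt_ms / p.tau_plus)
        self.pre_trace *= ep
        self.post_trace *= ep
        pre_spikes = np.asarray(pre_spikes, dtype=bool)
        post_spikes = np.asarray(post_spikes, dtype=bool)
        self.pre_trace[pre_spikes] += 1.0
        if np.any(pre_spikes):
            self.c[pre_spikes, :] += p.A_plus * self.post_trace[None, :]
        if np.any(post_spikes):
            self.c[:, post_spikes] += p.A_plus * self.pre_trace[:, None]
        self.post_trace[post_spikes] += 1.0


def dopamine_step(
    n: float, dopamine_spike: bool, dt: float, params: PlasticityCfg
) -> float:
    """One exact step of the dopamine concentration ODE.

    Decay is integrated exactly; a dopamine spike at the step start adds
    1/tau_n (so one isolated transient integrates to exactly 1 over time).
    """
    dt_ms = dt * 1e3
    if dopamine_spike:
        n = n + 1.0 / params.tau_n
    return n * np.exp(-dt_ms / params.tau_n)


def dopamine_integral(params: PlasticityCfg) -> float:
    """Analytic time-integral of one dopamine transient: exactly 1."""
    return 1.0


def weight_update(
    w: np.ndarray, c: np.ndarray, n: float, dt: float, params: PlasticityCfg
) -> np.ndarray:
    """Per-step Euler update  w += c*(n - b)*dt, clamped to [Wmin, Wmax].

    ``n`` is the dopamine concentration in 1/ms (matching tau_n in ms), so
    dt is converted to ms.  This path exists for verification; production
    reward delivery uses :func:`apply_reward`.
    """
    w = np.asarray(w, float) + np.asarray(c, float) * (n - params.b) * (dt * 1e3)
    return np.clip(w, params.Wmin, params.Wmax)


def apply_reward(
    w: np.ndarray, eligibility: np.ndarray, params: PlasticityCfg
) -> np.ndarray:
    """Event-exact reward update: delta_w = c(t_reward), clamped.

    A single dopamine impulse has unit time-integral and tau_n << tau_c, so
    integrating dw/dt = c*n across the transient gives c at the reward time
    to within O(tau_n/tau_c); the impulse limit is applied exactly.
    """
    w = np.asarray(w, float) + np.asarray(eligibility, float) * (1.0 - params.b)
    return np.clip(w, params.Wmin, params.Wmax)
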