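# Methods

`spikenav` simulates an embodied agent that learns a watermaze-style
navigation task with a spiking neural network, and quantifies how the
efficiency of the spatial code in its inputs shapes navigation performance.
This note documents the model, the numerical choices, and the places where
the design was genuinely open.

## Task

The agent lives in a 2.4 m x 2.4 m square arena centred on the origin and
starts every trial at the centre.  A hidden circular goal zone (radius
`goal.radius`, default 0.2 m; centre offset (0.5, 0.5) m) ends the trial on
entry and delivers reward; otherwise the trial times out at 5 s.  A trial
counts as *successful* only if the goal was entered before 4.5 s — in
practice trials either succeed within ~3 s or not at all, so the band
between 4.5 and 5 s is almost empty and is classified as failure.  One
*repetition* is 30 consecutive trials with persistent network state and a
fresh random weight initialisation; performance is summarised by the escape
latency (trial duration, averaged over repetitions) and the hit rate
(fraction of successful trials).  Asymptotic performance pools the last 10
trials (the trial window is not prescribed anywhere; 10 is this package's
choice).

## Input layer

`N_PC = n_side^2` place cells (n_side odd, so one field sits on the start
position) tile the arena on a uniform square lattice *including the
borders*: spacing d = 2.4/(n_side - 1).  Cell i fires as an inhomogeneous
Poisson process with the isotropic Gaussian rate map

    rate_i(x) = eta * exp(-|x - x_i|^2 / (2 sigma^2)),

sampled per 0.1 ms step as a Bernoulli event with p = rate*dt (exact to
O(dt^2)).  The shared peak rate eta is not free: it is set so the summed
population rate at the arena centre equals `place.target_center_rate`
(3500 Hz), which keeps the total drive onto the decision network comparable
across populations.  Under the baseline (n_side = 21, sigma = 0.2 m) this
normalisation yields eta ≈ 200 Hz; the border-spanning lattice is what
makes those two published numbers consistent (an interior-margin lattice
does not reproduce them).

Eight boundary cells fire at `boundary.eta` (200 Hz) inside rectangles
hugging the walls (strips of half-widths 0.1 m x 1.2 m) and corners
(squares of half-width 0.15 m).  Their geometry and rates are not
prescribed anywhere; the defaults are this package's choices, exposed in
config.  Each boundary cell projects non-plastically onto the ring with
cosine-rectified weights peaked on the direction from the cell toward the
arena centre (`boundary.w_max * max(0, cos(theta_j - phi_i))`), so walls
and corners repel the agent inward.  The functional form is likewise an
invented default satisfying the qualitative repulsion contract.

## Decision network

Forty leaky integrate-and-fire neurons (parameters in `lif.*`: E_L = -70 mV,
C_m = 250 pF, tau_m = 10 ms, t_ref = 2 ms, V_th = -55 mV, V_reset = -70 mV,
alpha-function synapses with tau_syn = 5 ms) form a ring over movement
directions theta_j = j*9°.  Synaptic weights are postsynaptic-current
amplitudes: a spike through weight w injects an alpha current peaking at
w pA at t = tau_syn after the spike.  Feedforward weights from place cells
are plastic, initialised Normal(30, 5) truncated to [0, 60]; boundary rows
are fixed.  Lateral connectivity excites neighbours through a von-Mises
kernel K = exp(zeta (cos dtheta - 1)) (zeta = 20) and inhibits globally.

### The lateral magnitude convention (open design point)

The connectivity is published as w_inh/N + (w_exc/N)(1-delta) e^{zeta cos}
with w_inh = -400, w_exc = 50, zeta = 20.  Taken literally the excitatory
kernel reaches e^20 ~ 5e8, which is not a usable synaptic amplitude, so
some normalisation is clearly implied but not stated.  The bounded
von-Mises reading divided by N on both terms gives -10 pA of shared
inhibition and at most +1.25 pA of local excitation per spike — and under
that convention *no activity bump can exist*: the mean feedforward drive at
the 3500 Hz operating point is

    I_ff = 3500 Hz * 30 pA * e * tau_syn ≈ 1.43 nA,

against a rheobase of (V_th - E_L) C_m / tau_m = 375 pA, and a bump firing
R_bump ≤ ~2500 spikes/s can contribute at most |w_inh|/N * R_bump * e *
tau_syn ≈ 340 pA of inhibition — it can never silence the losers, and the
ring settles into uniform asynchronous firing whose movement read-out
cancels (verified in simulation: all neurons ~120 Hz, net displacement
~0.05 m in 2 s).

`spikenav` therefore resolves the convention as follows, keeping the
published structure, ratios and kernel:

* the excitatory kernel acts at per-synapse strength, w_exc * K
  (`ring.exc_per_synapse`, default true).  The kernel already localises the
  excitation to a few neighbours; dividing it by N as well is what makes it
  ineffective;
* one overall gain `ring.lateral_gain` (default 4.0) multiplies the lateral
  matrix.  It is calibrated once, analytically, from the silencing
  condition  g * |w_inh|/N * R_bump * e * tau_syn > I_ff - I_rheobase,
  which gives g > ~3.9 at R_bump = 2000 spikes/s; the smallest sufficient
  integer gain is used.

With this convention the nearest-neighbour lateral weight is net positive
(+116 pA against -40 pA of shared inhibition at the default gain), a single
contiguous arc of the ring is active while the rest is silenced, and the
agent moves at ~1 m/s with direction persistence on the 0.1-1 s scale.
The equation-as-printed shared form remains available
(`exc_per_synapse: false, lateral_gain: 1`), as does the literal kernel
(`kernel_form: literal`), for comparison.

The movement vector is the discounted direction sum
a(t) = s * sum_j sum_{t_j<=t} exp(-(t-t_j)/tau_a) a_j with s = 1e-4 m and
tau_a = 0.5 ms, maintained as one decaying accumulator and applied as the
per-step displacement; walls clamp the position per axis (the agent slides,
it does not bounce — the wall rule is not prescribed).  Lateral spikes are
delivered with a one-step (0.1 ms) transmission delay; positive weights
feed the excitatory alpha filter and negative ones the inhibitory filter,
synapse by synapse.  Membranes integrate by exponential Euler, which is
exact for piecewise-constant current over a step.  Network state is *not*
reset between trials: trial t+1 starts from the exact state at the end of
trial t, which varies the initial condition across trials and is the only
source of across-trial behavioural variability after an unsuccessful trial.

## Plasticity

Place-to-ring weights learn by a three-factor rule: a purely potentiating,
symmetric pairing window Psi(dt) = A+ exp(-|dt|/tau+) (A+ = 0.002,
tau+ = 20 ms) deposits eligibility c on each synapse for every pre/post
spike pair (all-to-all, computed online with one exponential trace per
place cell and per action neuron — this reproduces the explicit pair sum
exactly); c decays with tau_c = 200 ms; a dopamine transient n with
tau_n = 0.1 ms and unit time-integral converts eligibility into weight
change dw/dt = c (n - b), with baseline b = 0.  Weights clamp to [0, 60]
after each update.  Because tau_n equals the integration step, the
transient is treated as an impulse and the reward update is applied
event-exactly: delta_w = c(t_reward) on goal entry (the per-step ODE
integration of n is retained in the code for verification).  Failures
release no dopamine, so unsuccessful trials leave the weights bit-identical
— learning is purely appetitive.  Eligibility, like all state, persists
(and decays) across trial boundaries.

## Coding metrics

For a lattice population the **overlap index** exp(-d^2 / (2 sigma^2))
measures field redundancy (rate at the nearest neighbouring centre over the
peak rate; independent of eta).  The **coverage index** N sigma^2 (17.64 m^2
at baseline) is the field-area proxy held constant on the co-scaling sweep
axis.  The **Fisher information** of the population, for independent
Poisson cells with Gaussian tuning, has the closed form

    J(x) = sigma^-4 * sum_i (x - x_i)(x - x_i)^T rate_i(x),

summarised by the mean of the diagonal; navigation correlates with the
*minimum* of this scalar along the straight start-goal segment (100 evenly
spaced samples, endpoints included — the sampling density is this package's
choice), because sparse populations leave low-information gaps.  In the
dense-lattice limit with centre-rate normalisation the scalar tends to
R/sigma^2 (e.g. 87,500 m^-2 at sigma = 0.2), which makes it invariant to
cell number under the normalisation and inversely proportional to sigma^2 —
the properties the sweep figures rest on.  For presentation the binary
logarithm of the path minimum is reported.

## Problem sizes and reproducibility

The full study conditions average 100 repetitions per parameter set; the
package default (`experiment.n_repetitions`) is 10, which this package's
tests use throughout — direction-only assertions (learning effect,
goal-size monotonicity, overlap u-shape) are stable at that size under the
deterministic seeding, while absolute latencies retain visible sampling
noise.  Repetition r always uses seed base_seed + r for every source of
randomness (weight initialisation and all Poisson sampling from one
stream), so any (config, seed) pair reproduces bit-identically.  The inner
closed loop runs as a single compiled kernel (numba) over 0.1 ms steps
(50,000 steps per timed-out trial); a pure-numpy composition of the
module-level operations consumes the identical RNG stream and is compared
against the kernel in the tests.

## What the generator does and does not emulate

Inputs are ideal Poisson place and boundary cells with stationary, noise-
free tuning; there is no path integration, no head-direction system, no
obstacle, no temporal coding (phase precession, theta), and no across-cell
heterogeneity in peak rate or field size.  Conclusions from passing tests
therefore concern the closed-loop consequences of population-code geometry
(cell number, field size, overlap, Fisher information), not the biology of
individual place fields.  Known limitations: the lateral magnitude
convention is a reconstruction (documented above) rather than a published
fact; boundary-cell geometry is invented; and with 40 discrete directions
and an exponential readout kernel the agent's movements have limited
angular resolution, which bounds achievable latency from below.
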