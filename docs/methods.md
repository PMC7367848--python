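# Methods

## Network model

Time is discretized in steps of `dt` (default 1 ms). The recurrent
population holds `n_rec` neurons, of which the last `n_adaptive` carry an
adaptive threshold; inputs arrive on `n_in` binary channels and `n_out`
non-spiking leaky readouts integrate the network spikes.

Per step, with decay factors `α = exp(-dt/τ_m)`, `ρ = exp(-dt/τ_a)`,
`κ = exp(-dt/τ_out)`:

```
v_j'  = α v_j + Σ_i W_rec_ji z_i + Σ_i W_in_ji x_i' - z_j v_th
a_j'  = ρ a_j + z_j                      (adaptive rows only)
A_j'  = v_th + β a_j'
z_j'  = H(v_j' - A_j')                   (0 while refractory)
y_k'  = κ y_k + Σ_j W_out_kj z_j' + b_k
```

Conventions that the equations leave open and that we fixed once:

* **Firing**: spike iff `v ≥ A` (threshold inclusive), so tests can be
  bit-exact.
* **Reset**: the soft reset subtracts the constant `v_th` for ALIF rows
  too; the dynamic threshold enters only the firing condition.
* **Refractoriness**: a countdown of `n_refractory` steps (default 3 at
  1 ms) during which the spike output and the surrogate derivative are
  forced to zero while `v` and `a` continue to evolve.
* **Transmission delay**: one step by default; a larger integer delay
  shifts the presynaptic index consistently in the simulation, the
  eligibility filters, and the backward pass.
* **Initial conditions**: `v`, `a`, `y` start at configurable constants
  (zero by default).
* **Initialization**: zero-mean Gaussians with std `gain/√fan_in`; the
  recurrent diagonal is held at zero everywhere (no autapses).

The surrogate (pseudo-)derivative of the threshold crossing is
triangular: `ψ = (γ_pd/v_th) max(0, 1 - |v - A|/v_th)` with dampening
`γ_pd = 0.3`, and exactly 0 during refractoriness.

## Eligibility traces

Each synapse carries an eligibility vector with a membrane component
`ε_v` — the α-filtered (delayed) presynaptic spike train, shared by all
postsynaptic targets — and, for adaptive rows, a slow component

```
ε_a' = ψ_prev ε_v_prev + (ρ - ψ_prev β) ε_a
e    = ψ (ε_v - β ε_a)
```

The slow component is explicitly zeroed for non-adaptive rows (it would
be multiplied by β = 0 anyway). A simplified variant drops the `-ψβ`
correction, leaving a plain ρ-filtered trace of post-pre pairings; its
deviation from the full recursion is bounded by `ψβ/(1-ρ)` relative to
the drive, which the tests verify numerically.

**Index contract.** The recursions above mix adjacent time indices; the
contract we fixed is: the trace at recording step `t` uses `ψ` at `t`,
the presynaptic filter updated with the spike from `t - delay` (inputs:
`t`), and `ψ`/filter values from `t-1` inside the slow component. The
arbiter is `brute_force_eligibility`, which evaluates the explicit
sum-of-products definition (chained 2×2 state Jacobians applied to the
direct weight sensitivity) in quadratic time; the recursive traces match
it to ≤1e-12 at every synapse and step, which removes any ambiguity the
recursive notation leaves.

## Learning rules

Supervised updates accumulate `-η L_j ē_ji` per step, where
`ē = F_κ(e)` and the learning signal broadcasts the masked readout error
through feedback weights `B`: `L_j = Σ_k B_jk (y_k - y*_k)` (regression)
or `(π_k - π*_k)` with `π = softmax(y)` (classification). Feedback modes:

* `symmetric` — `B = W_out^T`, recomputed from the current readout
  weights at every batch;
* `random` — `B` drawn once with the same statistics as `W_out` and
  frozen (broadcast alignment);
* `adaptive` — random initialization, but every readout update is
  mirrored onto `B`.

Readout weights follow their exact gradient: `ΔW_out = -η Σ err_k z̄_j`
with `z̄ = F_κ(z)`, and the bias uses the κ-filtered unit kernel
`F_κ(1)` as its "trace". The commonly printed simplification `Δb = -η Σ
err` is exact only for κ = 0; we keep the exact form because the package
certifies the readout gradient against the oracle.

Updates are accumulated over a batch of trials (default 64) and applied
once per batch, divided by the batch size. Plain SGD is the default
optimizer; momentum and adaptive-moment (Adam) variants are available in
the learning configuration. An optional firing-rate regularizer
`c_reg/2 Σ_j (f_j - f_target)²` (rates in Hz, computed over the batch)
contributes its exact gradient through the *unfiltered* trace sum, since
it acts on the spikes directly rather than through the readout.

## BPTT oracle

The oracle backpropagates through the unrolled *surrogate* graph: `ψ`
stands in for the non-existent derivative of the Heaviside, and the
reset term is treated as constant — the same two conventions the forward
traces use, so the equivalence statement is well posed. The backward
recursion over the two-component hidden state `(v, a)` uses the
within-neuron Jacobian `[[α, 0], [ψ, ρ - ψβ]]`, the spike sensitivity
`[ψ, -βψ]`, and cross-neuron terms through `W_rec` at the transmission
delay. Everything runs in float64.

Three identities are certified on randomized small networks (mixed
LIF/ALIF, both losses, spiking trajectories):

1. `Σ_t (dE/dz_j^t) e_ji^t` equals the backward-pass gradient on every
   weight block (relative deviation ~1e-15, tolerance 1e-8);
2. recursive traces equal the brute-force definition (≤1e-12);
3. with `W_rec = 0`, the full symmetric online update equals the exact
   gradient (~1e-16, tolerance 1e-10), including the interchange of the
   κ-filter between future errors and past traces.

**Finite differences.** The spiking system is flat almost everywhere, so
finite differences on it cannot probe the surrogate gradient. The
gradient check therefore runs on a *relaxed* twin network in which the
spike is replaced by the antiderivative of the triangular ψ (a smooth
amplitude in [0, γ_pd]), with no reset and no refractoriness. On that
system the backward pass is the exact gradient; central differences
match it with second-order convergence. A guard rejects trajectories
that come within a margin of the surrogate's curvature kinks (threshold
crossing or saturation edges), where FD loses its order.

## Reward-based variant

The network drives K policy readouts (softmax policy) and one value
readout. With TD error `δ^t = r^t + γV^{t+1} - V^t` (terminal
`V^{T+1} = 0`), recurrent and input weights follow
`ΔW = -η Σ_t δ^t F_γ(L^t ē^t)` with
`L_j = -c_V B_j^V + Σ_k B_jk^π (π_k - 1_{a=k})`; the policy term is zero
at steps where no action is committed. The two heads follow the mirrored
updates built from `z̄` and the bias kernel. Head feedback defaults to
symmetric. TD errors are settled with a one-step lag online (each step's
δ needs the next step's value estimate). An episode-length schedule with
`η ∝ 1/length` is provided for stability over long horizons; the toy
environments have fixed episode lengths, so the default training uses a
single phase.

## Synthetic tasks

**Cue accumulation.** Seven brief cues, each independently left/right
(p = 0.5), drive 10-channel Poisson groups inside an early cue window;
a 10-channel recall group fires during a terminal recall window, where
alone the loss mask is active; the target is the majority side. Full
scale: 2250 ms trial, 1050 ms cue window (100 ms cues, 50 ms gaps),
150 ms recall, cues at 40 Hz over 1 Hz background. The *reduced* preset
compresses time five-fold (450/210/50 ms, 20 ms cues, 10 ms gaps) and
scales the cue/recall rate five-fold (200 Hz) so the expected spike
count per cue is preserved; the adaptation constant scales with it
(τ_a = 400 ms against τ_a = 2000 ms at full scale). What the generator
does *not* emulate: correlated noise, cue-position jitter, or any
sensory preprocessing — passing tests show temporal credit assignment
over the programmed delays, not robustness to realistic sensory
statistics.

**Pattern regression.** A frozen Poisson raster (20 channels, 50 Hz)
replayed every trial; the target is a fixed sum of 3 sinusoids with
frequencies in 0.5–5 Hz and random amplitudes/phases.

**Catch.** A 5×5 grid; a ball falls one row per step from a uniformly
random column; the paddle (start: center) moves one cell per step;
reward ±1 exactly once, at the bottom row. Observations are one-hot
spike groups (ball column, paddle column, ball row), each held for
`steps_per_cell` simulation steps (3 in the trained configuration). The
random-policy baseline is computed exactly by enumerating all
(spawn, action-sequence) pairs, and per-spawn achievability by the same
enumeration.

## Problem sizes and training settings

Chosen as the package's default desk-scale experiments:

* Gradient identities: 20 random networks, `n_rec ≤ 8`, `T ≤ 25` — runs
  in seconds.
* Cue accumulation: 100 neurons (50 LIF + 50 ALIF), random e-prop,
  Adam, η = 5e-3 for 300 batches of 32 then 1e-3 for 150 with tail
  (Polyak) averaging of the final iterates, rate regularization
  `c_reg = 1e-4` toward 10 Hz, `v_th = 0.6`. The weak regularizer keeps
  the trained network near 15 Hz; a ten-fold stronger one pins rates at
  the target but measurably caps task accuracy, and without any
  regularizer rates drift to 60–100 Hz. The all-LIF control uses matched
  parameters with `n_adaptive = 0` (its accuracy stays flat at chance
  from the first iterations on, so the control run uses a somewhat
  shorter schedule). Held-out accuracy is measured on 512 fresh trials.
* Catch: LSNN of 64 neurons (16 adaptive), γ = 0.98, `c_V = 0.5`,
  η = 3e-3, 600–900 batches of 32 episodes; evaluation on 500 frozen
  episodes against the enumerated baseline.
* Bandit estimator check: 2×10⁴–10⁵ one-step episodes with frozen
  weights.

## Known limitations

* Gradients ignore the reset term and refractory gating (both treated as
  constants), consistently in the traces and the oracle; reset-aware
  eligibility vectors are out of scope.
* The learning-signal approximation drops cross-neuron error paths by
  construction; tasks that require error flow through downstream hidden
  spiking layers will not be learned by the symmetric variant.
* The trainer's float32 fast path makes training runs reproducible
  per-platform but not bit-portable across BLAS builds; all certificates
  run in float64.
* Episodic training assumes equal-length episodes within a batch (true
  for the bundled environments).
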