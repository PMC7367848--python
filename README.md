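# eprop — online gradient learning for recurrent spiking networks

Recurrent spiking neural networks (RSNNs) are the standard abstraction for
cortical circuits, but training them with backpropagation through time
(BPTT) requires unrolling the network and propagating errors backwards —
something neither brains nor neuromorphic chips can do. This package
implements **e-prop** (eligibility propagation): a strictly online,
biologically plausible learning rule in which every synapse maintains a
forward-running *eligibility trace* and combines it with a top-down
*learning signal* broadcast from the readout errors.

The mathematical core is the re-factorization of the loss gradient

```
dE/dW_ji  =  Σ_t  (dE/dz_j^t) · e_ji^t
```

where `z_j^t` are the binary spikes of neuron *j* and the eligibility
trace `e_ji^t` collects — forward in time — every locally computable
factor of the gradient. For leaky integrate-and-fire (LIF) neurons the
trace is the membrane-filtered presynaptic spike train times the
surrogate derivative ψ of the postsynaptic threshold crossing; for
adaptive-threshold (ALIF) neurons it gains a slow component that decays
with the adaptation time constant τ_a and carries gradient information
across seconds. Replacing the unavailable total derivative `dE/dz` by the
instantaneous readout error broadcast through feedback weights `B` gives
the online rule

```
ΔW_ji = -η Σ_t  [ Σ_k B_jk (y_k^t - y*_k^t) ] · ē_ji^t,     ē = F_κ(e)
```

with three feedback variants (`symmetric`, `random`, `adaptive`), plus a
reward-based actor-critic variant in which a temporal-difference error
δ^t multiplies a discount-filtered trace, `ΔW = -η Σ_t δ^t F_γ(L^t ē^t)`.

What makes the package a *tested* implementation rather than a demo is
the built-in **BPTT oracle**: an exact backward pass through the
surrogate-differentiable unrolled graph. On small random networks the
package certifies, to near machine precision, that

* the trace-based gradient with ideal learning signals equals the BPTT
  gradient (the exactness identity),
* the recursive eligibility computation equals its brute-force
  sum-of-products definition,
* with no recurrent connections, symmetric e-prop *is* gradient descent.

## Worked example

Verify the gradient identities and train a small recurrent network of 50
LIF + 50 ALIF neurons on the cue-accumulation task (seven brief left/right
cues early in the trial, decision requested only in a late recall window):

```bash
$ eprop check-gradients --seed 1
gradient_identity_max_rel_dev: 6.338e-16 (tolerance 1e-08) ok
eligibility_recursion_max_abs_dev: 1.776e-15 (tolerance 1e-12) ok
feedforward_exactness_max_rel_dev: 4.158e-16 (tolerance 1e-08) ok

$ eprop train-supervised --task cue_accumulation --mode random \
      --preset reduced --seed 1 --iterations 150 --batch-size 32
...
[ 149] loss=20.4636 mean_rate=14.8424 accuracy=0.8125 heldout_loss=14.5526 heldout_mean_rate=15.4908 heldout_accuracy=0.8828
```

The first block reports the maximum deviation between the online
computation and the exact BPTT gradients over randomized networks —
around 1e-15, i.e. the identity holds to float64 round-off. The training
run shows the network learning a task whose errors arise only in the last
50 ms of a 450 ms trial: held-out accuracy climbs from chance (0.5) to
~0.88 after 150 weight updates, with a mean firing rate near 15 Hz (a
sparse-firing, not rate-coded, regime); the longer two-phase schedule in
`eprop.presets` reaches ~0.92. The same run with an all-LIF network
stays near chance — the slow eligibility component of the adapting
neurons is what bridges the delay.

For the reward-based variant:

```bash
eprop train-rl --seed 1 --batches 600
```

trains an actor-critic agent on a toy "catch" grid (a falling ball must
be intercepted by a paddle; a single ±1 reward per episode) and prints
the final mean return against the exactly enumerated random-policy
baseline.

## Layout

| module | contents |
| --- | --- |
| `eprop.config` | `NetworkConfig`, derived decay constants |
| `eprop.dynamics` | LIF/ALIF step operations, trial simulation, recordings |
| `eprop.eligibility` | eligibility vectors/traces, brute-force definitional oracle |
| `eprop.learning` | learning signals, feedback modes, supervised trainer |
| `eprop.oracle` | BPTT backward pass, ideal-signal gradients, finite-difference check |
| `eprop.rl` | actor-critic rule, TD errors, episode schedule, trainer |
| `eprop.tasks` | cue accumulation, pattern regression, catch environment |
| `eprop.verify` / `presets` | randomized identity sweeps; the canonical desk-scale experiments |
| `eprop.cli` / `io` / `experiment` | command line, serialization, experiment configs |
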