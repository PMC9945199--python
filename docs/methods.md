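# Methods

## Model

A feedforward stack of dense layers of Spike Response Model neurons in
discrete time, bins `n = 0 … T−1`.  Per layer: `a[n] = W s_in[n]`,
`z[n] = (ε ∗ a)[n]`, `u[n] = z[n] + (ν ∗ s)[n−1]`, `s[n] = 1{u[n] ≥ θ}`.
Assumptions and conventions:

- State at `n < 0` is zero; kernels are truncated at the horizon `T` (exact
  for the finite convolution sums involved).
- The threshold comparison is `u ≥ θ`: exact equality fires.
- The reset is "soft": each output spike subtracts a `θ·α^k` trace from the
  future membrane potential (for LIF kernels).  There is no clamp to zero
  and no refractory mechanism beyond the reset kernel.
- At most one spike per neuron per bin; the membrane is not re-examined
  within a bin after a spike.
- The reset acts with a one-bin delay: the reset contribution at bin `n`
  involves output spikes up to bin `n−1` only.  The backward recursion for
  σ uses the same convention (`(ν ∗ σ_m)[n−1]`).
- Only dense linear layers are provided; the weight matrix slot of a layer
  is the single extension point for other linear maps.
- Gradients are taken with respect to weights only (not α, θ, or kernel
  shapes), and only first-order.

Two forward implementations exist and agree to float64 round-off: a
convolutional reference (any kernel pair, O(T²) per neuron) and an O(T)
state-space recursion `u[n] = α u[n−1] + a[n] − c s[n−1]` valid for
geometric kernels (`c = θ` for LIF/IF, `c = 0` for a zero reset kernel).
The convolutional path is the semantic reference; the recurrent path is
what the trainer and the unrolled-graph oracle use.

## Backward passes

Three algorithms share the forward pass and the e / weight-gradient
formulas (`e[n] = d_next[n]·W_next`, `∂L/∂W = Σ_n d[n] s_in[n]ᵀ`) and
differ only in how `d = ∂L/∂a` is obtained:

- **exodus** (exact): the within-layer Jacobian σ from the
  forward-substitution recursion (generic kernels, O(T²)–O(T³), reference
  path with a documented memory ceiling of T ≤ 256) or, for geometric
  kernels, the O(T) backward recursion
  `d[n] = e[n]f'[n] + d[n+1](α − θf'[n])`.  The recursion was validated
  against the literal double sum over σ and against the literal
  ζ-product sum before being adopted; that chain is kept as tests.
- **slayer**: identical pipeline with σ truncated to its diagonal —
  equivalently the reset kernel set to zero in the backward pass.  Its fast
  path is the same recursion with reset strength 0, so running the exact
  pass on a network whose reset kernel *is* the zero kernel reproduces
  SLAYER bit-for-bit (same low-level kernels, same arithmetic).
- **bptt**: a hand-written reverse-mode sweep over the fully unrolled
  time × layer graph (reverse in time, top-down in layers per bin), sharing
  no backward code with the exodus path.  It is the ground truth for the
  equivalence claim.  Finite differences of the true loss would not be a
  valid oracle: surrogate gradients deliberately differ from the derivative
  of the discontinuous spike function, so the oracle differentiates the
  same surrogate-relaxed graph, applying `f'(u[n])` to every occurrence of
  `s[n]` — the downstream path and the reset path alike.  The reset-path
  term is exactly what the slayer pass drops.

The surrogate derivative is evaluated once, during the forward pass, and
cached (`LayerCache.f_prime`); every backward pass consumes the cached
values, so the three algorithms are guaranteed to see identical `f'`.

One convention worth noting: `GradientSet.e` stores the *downstream-path*
derivative `d_next·W` (the quantity that propagates between layers).  The
total derivative of the loss with respect to a layer's spikes additionally
contains the within-layer reset path; that part is absorbed into σ (or the
d recursion) rather than into e, so e, d and the weight gradients are
directly comparable across all three algorithms.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 1.0 (IF) in examples | per-bin membrane decay `exp(−Δ/τ)`; 1 = no leak, the regime where reset effects are largest |
| `theta` | 1.0 | firing threshold, sets the membrane scale |
| surrogate family | exponential | `scale·exp(−width·|u−θ|)`; smooth, strictly positive, peaked at threshold |
| surrogate `width` | 1.0 | decay of the surrogate away from threshold, in units of θ |
| surrogate `scale` | 1.0 | global multiplier ("gradient scale"); swept in the stability experiment; `scale = 0` is allowed and zeroes every backward pass |
| weight init | N(0, 3/√fan_in) | large enough that sparse binary input drives spiking in every layer at initialization |
| optimizer | plain SGD, lr 1e-3, batch 16 | no schedules, momentum or tricks, so trajectory differences isolate the gradient algorithm |
| loss | sum-over-time cross-entropy | logits = per-class spike counts; gradient constant over bins |

The `fast_sigmoid` (`scale/(1+width·|u−θ|)²`), `piecewise_linear`
(`scale·max(0, 1−width·|u−θ|)`, compact support) and `constant` families
are also provided; `constant` makes the reset-propagation products
closed-form and is used for analysis and testing.

The max-over-time readout is defined here as the per-class maximum over
time of the ε-filtered output trace; the softmax residual is routed through
the earliest arg-max bin of each class's trace and spread backward by ε.
This is one concrete choice among several plausible "max-over-time"
definitions and is documented as such.

## Synthetic data

The generators emulate event-sensor recordings after time binning: binary
rasters, tens of channels, ~100 bins.  The study task (`latency_order`,
2 classes, 20 channels, T = 100, 200 train / 100 test) gives each of two
fixed sub-populations one elevated-rate burst window (rate 0.6 in a 20-bin
window, background 0.02); the class only swaps which population bursts
first.  Per-neuron expected spike counts are therefore identical across
classes by construction — a counts-only linear classifier is at chance and
the task is solvable only through temporal processing.  `poisson_rate` and
`burst_position` variants are provided for rate-coded and onset-coded
controls.  All randomness flows through one explicit seeded generator.

What the generator does **not** emulate: spatial correlations of real
sensors, per-sample timing jitter of the burst windows, refractory
structure in the input statistics, and realistic class counts.  Passing
tests on these tasks demonstrate the gradient algebra and the qualitative
optimization behavior, not performance on real neuromorphic benchmarks.

## Numerical choices

- All gradient-path arithmetic in float64; spikes stored as 0/1 int8.
- σ / χ / ζ are materialized as dense `(T, T, N)` tensors only on the
  reference paths (capped at T ≤ 256); the fast paths never form them.
- Gradients for a batch are averaged over samples.
- Arg-max ties in the max-over-time readout resolve to the earliest bin
  (numpy argmax convention).
- Non-finite losses or gradients during training raise (or, in the
  experiment driver, truncate and flag the run) — never silently continue.
- Operation-count instrumentation (`OpCounter`) tallies scalar
  multiply-accumulates actually executed by the fast d recursion, so the
  O(T) claim is checked as a count ratio, not wall clock.

## The stability experiment, and a known limitation

The experiment trains the same 5-layer IF stack (identical data, seeds and
initial weights per arm) for a short stretch of SGD with the exact and the
diagonal-approximation gradients at surrogate scales {0.01, 0.1, 1, 10},
logging per-layer weight-gradient two-norms each step; the summary
statistic is the first-layer/last-layer norm ratio, median over seeds.

At scale 1, dropping the reset correction inflates the ratio by orders of
magnitude relative to the exact pass — the depth-amplification the exact
gradients avoid.  At scale 0.01 both algorithms' first-layer gradients
collapse (vanishing regime).

At scale 10 with the width-1 exponential surrogate, however, *both*
algorithms blow up, and the exact one faster: spiking IF neurons dwell near
threshold through entire burst windows, so the reset-propagation factors
`α − θf'` have magnitude ≈ 9 over many consecutive bins and their products
dominate.  This is an intrinsic property of the exact gradients in this
regime — the unrolled-graph oracle returns the same exploding values to
float64 round-off — and corresponds to the known failure mode of
reset-aware gradients when the surrogate exceeds `α/θ` over a wide
membrane range.  The package treats surrogate scales of that magnitude as
outside the usable regime of *either* algorithm rather than as evidence
about their relative stability; the stability advantage of the exact pass
is the scale ≤ 1 comparison.

Other known limitations: recurrent architectures are out of scope (the
within-layer IFT construction relies on feedforward structure across
layers); the fast paths require the diagonal surrogate Jacobian that
elementwise surrogates provide; convolutional layers and axonal delays are
not implemented.

## Problem sizes

The randomized verification suites use stacks of 1–3 layers with at most 8
neurons per layer and horizons up to 32 bins (100 configurations for the
gradient-equivalence and closed-form checks, 50 for the decay bound); the
stability sweep uses the 5-layer, 100-bin task with 5 seeds and 15 SGD
steps per arm; the training demonstration uses the 200-sample task for 12
epochs.  These sizes were chosen so that every reported quantity is
recomputed from scratch in well under a minute each on a single CPU while
exercising every code path (both σ paths, both d paths, all three backward
algorithms, leaky and non-leaky neurons, two surrogate families).
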