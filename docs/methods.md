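# Methods

`dispcomm` simulates the experimental evolution of displaced communication:
sender/receiver agent pairs forage on a one-dimensional circular world and
can evolve to communicate the location of remote food through a signaling
channel that only works inside a shared nest.  This note documents the
model, its parameters, the numerical choices, and what the reduced-scale
experiments used by the test suite do and do not show.

## World model

The environment is the perimeter of a circle, a single angular coordinate
normalized to `[-π, π)`.  A nest (the communication area) is the arc of
length π/2 centered on 0.  Five foraging sites of length π/4 are centered on
π/2, 3π/4, π, −3π/4 and −π/2; since adjacent centers are π/4 apart, the
sites tile a contiguous 5π/8-per-side band on the half of the circle
opposite the nest.  Arcs are half-open (`[center − ℓ/2, center + ℓ/2)`),
closed at the lower edge, so adjacent sites are disjoint by construction.
The centering convention (arcs centered on, rather than starting at, the
listed positions) is the package's choice; it is the only reading that
makes the five sites both contiguous and non-overlapping.

A trial lasts 100 discrete time steps.  Both agents start at position 0
(inside the nest) and move at most π/9 radians per step in either
direction; they are points and cannot collide.  In each of the five trials
of an evaluation, food occupies one site (each site exactly once, order
randomized).  Only the sender can detect food (a binary floor sensor); only
the receiver is scored.  The receiver perceives the sender's emitted signal
amplitude (continuous in [0, 1]) exactly when both agents are inside the
nest, and zero otherwise — multiplicative gating, so the perceived
amplitude never exceeds the emitted one.

Per trial, performance is 0.01 per time step the receiver spends on the
food site during the last 20 steps, so at most 0.2 per trial and 1.0 over
five trials.  A receiver "found food" in a trial when it was on the food
site for at least 15 of those 20 steps (equivalently, p_T ≥ 0.15).

A structural consequence worth noting: a receiver whose behavior does not
depend on food location traverses the same trajectory in all five trials,
and because each site holds food exactly once, its five-trial total is at
most 20 scored steps — performance 0.2.  Exceeding 0.2 therefore *requires*
food-dependent receiver behavior, i.e. communication.  This makes 0.2 a
sharp ceiling for the no-communication treatment rather than a mere
empirical plateau.

## Neural controllers

Each agent is a continuous-time recurrent neural network (CTRNN) with 3
input neurons (sine and cosine of its own position plus a role-specific
channel: the food sensor for senders, the perceived amplitude for
receivers), 5 fully recurrent hidden neurons, and 2 motor outputs (plus a
third, signal-amplitude output for senders).  Speed is
`|y_a − y_b| · π/9` and direction is the sign of `y_a − y_b` (+1 on an
exact tie, where speed is zero anyway).  The |difference| of two sigmoid
activations lies in (0, 1), so multiplying by the speed bound π/9 is the
natural scaling; the bound is approached but never attained exactly.

Every parameter is one gene in [0, 1]: weights map linearly to [−4, 4],
biases to [−2, 2], and time constants to [0.1, 1.0].  With all neurons
(including inputs) carrying a bias and a time constant, genome lengths are
15 + 25 + 15 + 11 + 11 = 77 (sender) and 15 + 25 + 10 + 10 + 10 = 70
(receiver).  Input neurons integrate the raw sensory value as their drive —
this uses every encoded parameter and is consistent with the bias and
time-constant gene counts; a pass-through alternative would leave the
input-neuron genes dead.

State integration is the standard leaky CTRNN Euler step with α = 0.1:

    s_i(t) = s_i(t−1) + (α / τ_i) · (Σ_j W_ji y_j − s_i(t−1)),
    y_i(t) = σ(s_i(t) + θ_i).

Within a step, layers update in order (input → hidden → output); hidden
recurrence uses the previous step's hidden activations.  At every trial
start all internal states are reset to zero (so y = σ(θ)), making the five
food placements exchangeable; no state carries over between trials.

A τ-multiplicative variant, `integration="printed"`
(`s = α·τ·(drive − s)`), is retained as a sensitivity switch.  It is not
the default for a mechanistic reason: with α·τ ≤ 0.1 the previous state
enters the update only through the term `−α·τ·s(t−1)`, so state is
forgotten within one step, every layer attenuates its drive by a factor
≤ 0.1, and the linearized recurrent gain is below 1 everywhere — the
network is a contraction with an end-to-end sensory gain of order 10⁻³ and
no memory.  Displaced communication requires remembering a signal after
leaving the nest; under the τ-multiplicative form no desk-scale run ever
produced a single pair above the 0.2 ceiling, while under the leaky form
communication evolves readily.  Both forms are implemented and tested; the
switch is part of `EvolutionConfig`.

## Trial semantics

Within a time step: the sender senses and updates its network, producing
this step's emitted amplitude; perception is computed from this step's
positions and emission; the receiver senses and updates; both agents then
move.  Logged positions are those occupied during the step.  Because the
sender receives no information about the receiver, its trajectory and
emission are autonomous given the food site; the receiver-side probes
exploit this by replaying logged sender streams exactly.

Treatments:

* **communication** — free signaling.
* **no_communication** — the perceived signal is clamped to zero (the
  emitted signal is still recorded).
* **constrained_sender** — the sender's motion is overridden to full speed
  π/9, counterclockwise (period 18 steps per revolution); its signal output
  remains network-controlled.  This removes all between-trial variation in
  nest-arrival time and nest residence, leaving amplitude as the only
  usable channel.  The specific speed/direction values are the package's
  choice (only "fixed velocity, same direction" is prescribed); full speed
  guarantees several nest transits per 100-step trial.

## Probes

Probes are post-hoc counterfactuals applied to evolved pairs; control and
probe evaluations share the food order so the manipulation is the only
difference, and every probe's null version (zero shift, fixed amplitude
equal to an already-constant emission, mean replay of identical emissions)
reproduces the control bit-for-bit.

* **fixed_amplitude** — the emitted amplitude is clamped to a constant;
  gating (and hence onset/duration information) is untouched.
* **mean_amplitude_replay** — each trial is re-run feeding the receiver the
  across-trial mean amplitude at each step (gated by the logged sender
  positions and the live receiver position); the stream is identical in all
  trials, removing amplitude-borne information only.
* **onset_shift** — the receiver's perception timeline is delayed by the
  pair's own mean absolute between-trial onset difference, rounded to whole
  steps.  Applied as a delay (the sign is not prescribed by the shift's
  definition); pairs with fewer than two measurable onsets are excluded as
  inapplicable.
* **duration_lock** — the sender is frozen in place upon its first
  *re-entry* into the nest.  Both agents start inside the nest, so a
  literal "once entered" rule would freeze every sender at step 1 and
  destroy the onset channel too; arming the lock only after the sender has
  left once isolates the duration channel, which is the probe's purpose.

**Onset-delay** is the step at which the receiver first perceives a signal
above a threshold (default 1e-6; sigmoid outputs are never exactly zero,
and 0.05 is a documented sensitivity alternative).  Because the trial
starts with both agents co-present in the nest, a perception episode
already in progress at step 1 is skipped and the start of the next episode
is used; that episode begins when the sender returns from the food site,
which is the food-dependent event the statistic is meant to capture.

## Evolution

Populations hold n sender/receiver pairs (1'000 at full scale).  Genes are
initialized uniformly in [0, 1].  Each generation: every pair is evaluated
over five trials (food order re-randomized per pair per generation);
senders and receivers are selected in separate tournament streams of size
10, sampling with replacement, each individual scored by its pair's total;
offspring genes mutate independently with probability μ/G (μ = 0.5, G the
genome length, so the expected mutation count per genome is 0.5 for both
roles); mutated genes are redrawn from a normal centered on the current
value with sd 0.1 and reflected into [0, 1]; offspring are randomly
re-paired.  No crossover, no elitism, non-overlapping generations.
Gene-centered Gaussian mutation is the standard evolutionary-computation
reading of gene "replacement from a normal distribution" and preserves
gradualism; a mid-centered (0.5) alternative and lifetime (fixed) pairing
are config options.

All randomness flows through five named streams (init, food, selection,
mutation, pairing) spawned from one master seed, so runs are bit-for-bit
reproducible, including across checkpoint/resume, and toggling one
stochastic component leaves the others' draws unchanged.

Per-pair totals are multiples of 0.01 and are stored per generation as
exact centi-performance integers; the best pair's per-trial onset-delays
are recorded (optionally all pairs') for the milestone analyses.

## Analysis statistics

* **Success histogram** — receivers binned by the number of trials (0–5)
  in which they found food.
* **Signal variation S′** — for one sender, the mean over the 100 steps of
  the ordered-pair sum of |amplitude differences| between trials with
  coefficient 2/(|T|(|T|−1)); this equals exactly twice the mean unordered
  pairwise difference (the coefficient is kept as defined, and the factor
  of two is verified against a brute-force unordered-pair oracle).  When
  restricted to food-found trials, senders with fewer than two eligible
  trials are excluded and counted.
* **Milestones** — the first generation whose per-pair performances are
  significantly above 0.2 (one-sided Wilcoxon signed-rank, P < 0.01; the
  test choice is the package's, matching the nonparametric style of the
  treatment contrasts), and the first generation with between-trial
  onset-delay variation (best-performing pair's onset spread > 1 step by
  default; population-median aggregation is a config option).  Early
  generations can show spurious onset variation from random behavior, so
  the milestone is a noisy leading indicator at small population sizes.
* **Treatment and probe contrasts** — two-sided Mann–Whitney U on per-pair
  totals (probe vs control within a population, or treatment vs treatment
  across populations); milestone association via Pearson correlation.

## Scales, problem sizes, and what the tests show

The full-scale experiment (40 populations × 25'000 generations × 1'000
pairs per treatment) is cluster work; the package runs it, checkpointed,
via the `paper_full` preset.  The test suite and the acceptance script use
the documented `desk_small` preset — 10 replicate populations × 500
generations × 100 pairs — chosen as the package's standard reduced scale.
At that scale:

* the no-communication treatment reaches its exact 0.2 ceiling;
* communication populations cross 0.2 early (typically within tens of
  generations) but have climbed only a little above it by generation 500,
  so magnitude-level results (the ≈0.47 final performance, the ≈0.005 vs
  ≈0.185 amplitude-variation contrast, the per-population probe counts)
  are full-scale quantities that reduced-scale runs bound only
  directionally;
* the constrained treatment's crossing is strongly delayed or absent
  within 500 generations, giving the directional version of the
  "amplitude-based communication is slower to evolve" result.

The simulator itself is deterministic given genomes and food order; there
is no sensory or motor noise.  What passing reduced-scale tests show is
that the implemented mechanism produces the qualitative phenomena
(ceiling, communication onset, ordering of treatments); they do not
certify full-scale magnitudes.

## Numerical choices

* Angles are normalized with `mod` arithmetic to `[-π, π)`; +π and −π
  label the same point and the site centered on π is handled wrap-aware.
* Population-scale evaluation runs in a compiled (numba) kernel that
  mirrors the reference single-pair path operation for operation; their
  agreement, and the agreement of the vectorized network update with a
  naive per-neuron loop, is tested to 1e-12.
* Motor tie-break: direction +1 at an exactly zero output difference
  (inert, since the speed is then zero).
* Tournament ties resolve to the first maximal candidate, which is uniform
  over tied individuals because candidate order is i.i.d.
* Mutation reflection folds values into [0, 1] as a triangle wave,
  avoiding boundary pile-up.

## Known limitations

* The onset-variation milestone depends on an aggregation rule (best pair
  vs population median) and a threshold; both are exposed in config, and
  at small population sizes the statistic is noisy.
* Probe contrasts assume the evolved communication is strong enough for a
  per-population Mann–Whitney test to resolve; at reduced scale many
  populations are near the detection floor.
* No energy costs, noise, or more than one pair per trial; these are
  outside the model.
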