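# Methods

## Model

The network couples a 1D visual layer (180 azimuth-coding neurons, 1° per
neuron) with a 2D auditory layer (180 azimuths × 40 frequencies, five
neurons per octave). Both layers are rings: every distance between neuron
indices is circular, `d(i1, i2) = min(|i1 - i2|, N - |i1 - i2|)`, which
removes border effects. Neuron activity is a normalized firing rate in
[0, 1] obeying `tau_y dy/dt = -y + F(u)` with the logistic activation
`F(u) = 1 / (1 + exp(-s (u - theta)))`.

The net input of a neuron sums three terms:

* **external drive** — a stimulus filtered by the neuron's receptive field:
  a circular Gaussian over azimuth for the visual layer (width `sigma_p_v`),
  a separable circular Gaussian over azimuth × frequency for the auditory
  layer (widths `sigma_p_a`, `sigma_f_a`);
* **lateral input** — Mexican-hat connectivity stored as separate
  excitatory and inhibitory components, each a Gaussian of circular index
  distance (`Lex0 > Lin0`, `sigma_ex < sigma_in`), with self-synapses
  excluded in both components;
* **cross-modal input** — two scalars: each auditory neuron receives
  `W_av y_v(i)` from the visual neuron at its azimuth; each visual neuron
  receives `W_va Σ_j y_a(i, j)` from its auditory column
  (`W_va ≈ W_av / N_f` so the two directions carry comparable drive).

All defaults are the model's basal parameter set (`ModelConfig`); widths
are dimensionless index distances, intensities arbitrary units, times ms.

### Plasticity

During adaptation, the lateral synapses of both layers follow a
potentiation Hebbian rule gated by postsynaptic activity: nothing changes
unless the postsynaptic neuron exceeds `theta_post = 0.5` (half of
saturation). Excitatory weights grow with learning factor
`alpha_ex0 (Lmax - Lex)` so they saturate at `Lmax` (set to the basal peak
strength); inhibitory weights shrink with factor `alpha_in0 Lin` so they
cannot cross zero. After every integration step, the incoming weights of
each postsynaptic neuron are rescaled — separately per component — so their
sums stay at the basal values (population normalization). Because the gate
is postsynaptic, reciprocal synapses between two co-active neurons with
unequal activities modify asymmetrically, which is what ultimately remaps
the trained region toward the visual side. Cross-modal weights and
self-entries never change.

## Numerical choices

* **Integration** — explicit synchronous Euler, `dt = 1 ms` with
  `tau_y = 3 ms`. The step size matters only in two places: the activity
  trajectory sampled by learning, and path selection near marginal
  attractors (below); all untrained steady states are `dt`-independent
  fixed points of `y = F(u(y))`. The package treats one integration step
  per millisecond as the model's native discretization (activation
  snapshots and protocol durations are naturally expressed in whole
  milliseconds) and the adaptation protocol as 1000 such steps with
  learning applied every step, from the very first (no warm-up; the
  network starts from the null state).
* **Steady state** — largest per-step activity change below `1e-6`, with a
  cap `t_max = 1500 ms` (flagged, never silent, if hit). Untrained runs
  converge within ~60–120 ms; trained-network tests can need several
  hundred ms because adaptation places the test activation near a slowly
  developing secondary attractor at the formerly visual position.
* **Synapse storage** — the auditory lateral matrices
  (`7200 × 7200` per component if dense) are kept in factored form: the
  untrained connectivity is separable and circulant (lateral input = two
  small matrix products), and explicit incoming-weight rows are
  materialised only for neurons touched by learning (~150 rows in the
  standard adaptations). An optional support cutoff
  (`kernel_cutoff_sigmas`) truncates the windows; the default is *no*
  truncation, because although the basal Gaussians are negligible beyond
  4 sigma, the Hebbian potentiation term does not decay with distance and
  clipping it measurably inflates aftereffects. A literal dense-matrix
  backend (`ventnet.dense`) serves as an oracle on small grids; the test
  suite verifies bit-level (1e-10) agreement of basal weights, dynamics
  and full 1000-step learning between the two.
* **Decoding floor** — the logistic activation never reaches zero: every
  neuron rests at `F(0) ≈ 7.5e-4`. The barycenter decoder treats activity
  at or below `1e-3` (0.1 % of saturation, just above that silent level)
  as silence. Without this, the stimulus-independent pedestal of ~7000
  silent neurons drags every decoded position toward mid-ring by a few
  tenths of a degree and produces a spurious visual shift an order of
  magnitude larger than the model's true visual capture. The floor affects
  decoding only; dynamics and learning always use the raw activities.
* **Barycenters on linear indices** — all protocols place stimuli
  mid-ring; a warning fires if >1 % of decoded mass sits within 5 indices
  of the seam.
* **Half-max width** — one-sided: degrees from the peak of the azimuthal
  tuning curve to the first half-peak crossing (linear interpolation), with
  a full-width variant available. The azimuthal "response span" checks use
  a 10 %-of-peak floor, i.e. where a plotted curve visually reaches zero.
* **Generalization bandwidth** — octave distance from the adaptation
  frequency at which the aftereffect first falls below a floor (default
  0.5°), scanning distances in ascending order and taking the largest
  shift among tones at equal distance.

## Design decisions that were genuinely open

* **Frequency anchor** — the grid's absolute frequencies are fixed by
  placing 1.1 kHz at index 17, giving ~104 Hz–23 kHz coverage of every
  frequency the protocols use; off-grid frequencies resolve to the nearest
  index and report the residual in octaves.
* **Circular frequency axis** — the wrap applies to the frequency
  dimension as well as azimuth, following the model's generic circular
  distance. This is biologically odd (the lowest and highest frequencies,
  8 octaves apart, become neighbours) but follows from applying the
  model's single circular-distance convention to every dimension;
  with default widths it only affects pairs more than 20 indices apart and
  none of the standard protocols place activation near the frequency seam.
* **Visual-layer learning rule** — the 1D layer reuses the 2D rule with
  the frequency dimension collapsed; `Lmax_v` and the visual basal sums
  play the corresponding roles.
* **Update order per learning step** — dynamics step, then Hebbian deltas
  from the new activities, then normalization of `L + dL`.

## What the simulations emulate — and what they do not

All inputs are generated internally; there is no empirical data anywhere in
the pipeline. Stimuli are idealized flashes and pure tones expressed
directly as Gaussian receptive-field drives with noiseless, deterministic
dynamics. Consequently the tests demonstrate the *mechanism* — visual bias
of sound localization, Hebbian remapping, intensity-gated frequency
generalization — not quantitative fits to psychophysical data: real
observers show trial-to-trial variability, intensity in arbitrary units has
no calibrated dB correspondence, and the spatial map is functional rather
than anatomical.

## Known limitations

* The 17/17 aftereffect sits near a bifurcation of the trained network:
  its converged value varies by ~0.3° across reasonable Euler steps
  (1.34° at `dt = 0.1` to 1.63° at `dt = 1`), unlike every other measured
  quantity. Quantitative claims about that single point should be treated
  as step-size-sensitive.
* After a strong adaptation (intensity ≥ 19) a small residual aftereffect
  (~0.2°) survives at two octaves' distance rather than vanishing
  completely; the residual is robust to step size, decoding floor and
  kernel support.
* The azimuthal tuning width expansion between probe intensities 10 and 25
  measures 5.5° with the one-sided half-max convention and 11.0° with the
  full-width one; intermediate values require a convention the half-max
  definition does not pin down.
* Barycenter decoding is linear, not circular; protocols that place
  activation near the azimuth seam would need the circular-mean variant
  that the package deliberately does not implement.
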