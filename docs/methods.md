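# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
show.

## The liquid

The ionic liquid space is a quantized 2D voltage field. One step of the
update is, in order: external injection → diffusion/leak → dendritic
pre-activation → k-winner-take-all firing → intrinsic-plasticity threshold
update → axonal feedback. Consequences of this ordering:

- pre-activations read the *current* step's post-diffusion voltages;
- feedback spikes deposited by this step's winners first diffuse on the
  next step;
- with exactly `k` winners the threshold update `ν_i += η (x_i − k/N)` sums
  to zero, so `Σ_i ν_i` is an exact invariant of any run (we test it to
  1e-9 absolute over hundreds of steps).

**Diffusion.** The 8-neighbor update uses a synchronous (Jacobi-style)
scheme. Boundary bins exchange only with in-grid neighbors (zero-flux), the
simplest choice that keeps the `β = 0` update exactly conservative; the
global sum scales by `(1 − β)` per step in general. The transfer
coefficient is capped at `α ≤ 1/8` so the one-step update is a convex
combination of neighborhood values (no overshoot); defaults `α = 0.1`,
`β = 0.05`.

**Neurons.** Pre-activation is memoryless in `p` (an optional leaky
accumulator `p_decay` exists but is off by default — the grid itself is the
only memory). Thresholds start at 0 and may go negative. k-WTA ties break
deterministically toward the lowest neuron index; this makes silent,
symmetric liquids cycle through neurons in index order, which is convenient
for hand-traced tests. There is no refractory mechanism beyond the
threshold raise.

**Topology.** Neurons form a regular centered lattice. Terminal lengths are
drawn uniformly from annuli expressed in lattice-spacing units by default
(a dendrite of length 2 in a 100-bin grid with spacing 4 reaches ~8 bins);
a `bins` unit is available for small grids where lattice units would push
annuli off-grid. Dendrite weights default to `1/D` (uniform, normalized) so
the drive scale is independent of `D`; a uniform-random mode exists.
Multiple terminals may share a bin. GA perturbation clips to the grid and
does not re-impose the original length annulus, so terminals may drift
outside it over generations; we accept the drift as part of the search
space.

## Spike data and distances

Spike trains are event-time lists in ms. The train distance replaces each
spike with a Gaussian kernel (pdf-normalized, `σ = 5 ms` default) and takes
the L2 distance of the filtered functions, evaluated in closed form via
pairwise Gaussian product integrals; we verify it against dense quadrature
to 1e-6.

For the input-distance protocol we report a *relative* normalization,
`d = ‖f_u − f_v‖ / (‖f_u‖ + ‖f_v‖) ∈ [0, 1]`: 0 means identical trains and
values near 1 mean disjoint bursts, so targets like 0.1 / 0.3 are
meaningful fractions of full independence regardless of duration, rate or
kernel width. (Normalizing by duration instead would tie the target scale
to the kernel convention and the train length; independent 20 Hz Poisson
pairs concentrate near d ≈ 0.6–0.8 on our scale.) Distance-matched pairs
are produced by partially resampling one train — a fraction `q` of spikes
is replaced by fresh uniform times — and bisecting `q` until the distance
lands within tolerance; pure rejection over independent pairs cannot reach
small targets.

## Calibration of unstated scales

The voltage scale of injections is the one place where the model's
qualitative behavior depends on an otherwise arbitrary constant. The
threshold step `η = 0.2` only means something relative to the dendritic
drive: if injected voltages are small (gain ~1 for unit-intensity spikes),
thresholds dominate pre-activations, the winner rotation is pure
homeostatic round-robin, and the state carries no input information. The
experiment drivers therefore use an injection gain of 20 voltage units per
spike, putting dendritic drive at O(1)–O(10) — input-driven competition
with the homeostatic term still active as a slow equalizer. Axonal spikes
deposit 1.0 (feedback perturbs but does not dominate). Library-level
defaults stay neutral (`gain = 1.0`) and every scale is a config knob.

Time discretization for spike-driven experiments uses 20 ms per step —
twice the 10 ms jitter SD of the generalization task, so timing noise is
mostly sub-bin — together with anti-aliased injection (each spike's charge
split linearly between its two adjacent steps, preserving total charge and
making injections vary smoothly under small time shifts). Readout rates are
averaged over the stimulus window plus an equally long input-free settling
window, letting the liquid's fading memory of the whole sample enter the
features. These choices were fixed once for all experiments.

## The synthetic experiments

**Generalization (headline number).** 80 base patterns of 4 Poisson trains
(20 Hz, 200 ms); 20 random binary labelings; 500 jittered training and 200
jittered test samples (σ = 10 ms); liquid of 25 neurons in a 20×20 grid
(`k = 1`); least-squares readout on rate vectors, sign decision. Mean test
correctness lands around 0.67–0.69 depending on seed. Two effects bound it:
the least-squares geometry ceiling for 80 arbitrary binary labels in 25
dimensions (~0.75 even with noiseless features), and residual jitter noise
(within-pattern rate scatter at roughly a third of the between-pattern
spacing). A quarter of topology draws are noticeably worse filters than the
rest — random liquids vary, which is the motivation for evolving them.

**Separation ordering.** 200 train pairs per target distance (0.1 and 0.3,
500 ms, 20 Hz) through one liquid; summed state distance is compared
one-sidedly (Mann-Whitney, α = 0.01). The effect is large: mean state
distance roughly doubles from d = 0.1 to d = 0.3.

**Homeostasis.** Under stationary Poisson drive, every neuron's firing rate
converges to within ±50% of `k/N` after a few thousand steps (typically
within ±10%); the intrinsic-plasticity integrator suppresses any neuron
that fires persistently above target regardless of drive scale.

**Evolution.** The toy task has two input channels in opposite halves of a
16×16 grid, classes distinguished by which channel is briskly active. From
a deliberately blind start (all dendrites stacked in one corner, chance
fitness 0.5) the elitist GA recovers above-chance fitness within ~12
generations of population 8. Elitism makes the best-fitness history
non-decreasing by construction. The 70/30 stratified split is drawn once
per GA run so fitness differences between individuals reflect topology
only.

## What the synthetic data does not show

The generator produces homogeneous Poisson channels and Gaussian timing
jitter. Real event streams (camera events, cochlear channels) have strong
rate non-stationarity, channel correlations and burst structure that these
tasks do not emulate; passing them shows the machinery is correct and the
liquid is input-sensitive at these scales, not that any particular
real-world accuracy would be reached. Image-scale mapping (e.g. 34×34
sources into a 100×100 grid) is implemented and tested for its contracts
(one-to-one, regional, seeded) but no image dataset is bundled.

## Numerical notes and limitations

- All randomness flows through `numpy` Generators; experiment drivers fan a
  single seed out to named sub-seeds, so components can be re-seeded
  independently.
- k-WTA uses a stable sort; with heavily tied pre-activations the lowest
  indices win, which biases degenerate liquids toward low-index neurons (by
  design, for reproducibility). A seeded-random tie-break is not provided.
- Problem sizes in the test suite are chosen to keep the whole suite in
  tens of seconds: the full-size liquid (625 neurons, 100×100 bins) is
  exercised for sparsity and gene accounting, while statistical properties
  run on the 25-neuron liquid.
- The GA evaluates ~`population × generations` liquid runs per data sample;
  it is intended for small topologies and demonstrations, not large-scale
  search.
- 3D liquids, inhibitory synapses, within-run synaptic learning, and
  external dataset loaders are out of scope.
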