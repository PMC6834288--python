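# Methods

`anisonet` implements a generative connectivity rule for spiking networks on
a two-dimensional torus, a simulator for the resulting dynamics, and the
analysis stack used to characterize the spatio-temporal activity sequences
(STAS) the rule produces. This note documents the model, the numerical
choices, and the places where the package had to make a decision the
published description leaves open.

## Network model

Neurons sit on a regular square grid folded into a torus (all distances are
minimal-image; the unit of distance is one grid point throughout — no
physical length scale is introduced). Two model families are built:

- **I-network** — 10,000 inhibitory neurons on a 100×100 grid. Each neuron
  makes exactly 1,000 outgoing connections (10%); the radial displacement of
  each connection is drawn from a Gamma distribution with shape κ = 4 and
  scale θ = 3 (a non-monotonic, ring-like profile peaking near 9 grid
  points) with a uniform angle. Recurrent weight −10 pA (unitary IPSP
  −0.22 mV), delay 1 ms.
- **EI-network** — 14,400 excitatory neurons on 120×120 and 3,600 inhibitory
  neurons on 60×60 (4:1). Every neuron projects to exactly 720 excitatory
  and 180 inhibitory targets (5%). Displacements are isotropic Gaussians.
  The space constants are given in units of the *target* grid so that each
  projection class has a consistent physical extent across the two sheet
  resolutions: excitatory projections σ = 9 onto the E-sheet and 4.5 onto
  the I-sheet; inhibitory projections σ = 12 and 6. (The alternative
  reading of the projection-class labels, with inhibition narrower than
  excitation, destabilizes the model — excitatory rates run away to >100 Hz
  — and is rejected on that ground.) Excitatory weight +10 pA; inhibitory
  weight −g·J_E with g = 8 (−1.76 mV unitary IPSP).

Multiple edges between a pair are permitted and arise naturally from the
local profile; self-connections are rejected and redrawn, so the out-degree
is exact by construction. Sampled offsets that round to the origin are also
redrawn (a zero offset is not a connection at any shift). Cross-population
projections map the source position into target-grid coordinates before
sampling.

### Anisotropy

Each neuron can carry a preferred direction φ, quantized to the eight grid
directions k·π/4. Anisotropy is implemented by translating the neuron's
whole sampled connectivity cloud by `s` grid points along φ before rounding
and wrapping (s = 0, 1, or 2; shift s = 0 reproduces the isotropic network
exactly). In EI-networks only E→E projections are shifted. Four spatial
layouts of φ are supported: **symmetric** (no φ, no shift), **random**
(i.i.d. uniform over the 8 directions), **homogeneous** (one direction for
all neurons), and **perlin** (spatially correlated, below).

A structural consequence worth noting: with the Γ ring profile, shifting
the cloud along φ increases connection probability along φ at distances
beyond the profile mode and increases it *opposite* to φ below the mode
(near-field probability roughly doubles on one side and falls by the same
absolute amount on the other). The mirrored increase/decrease pair and its
magnitude are what the symmetric-vs-homogeneous comparison
(`connectivity_change`) verifies.

### The Perlin direction field

The correlated field is produced by interpolating coarse-grid noise: a p×p
coarse lattice (p = N / perlin_scale, e.g. 5×5 for the I-network at scale
20) is filled with i.i.d. angles from U[0, 2π); their unit vectors are
interpolated to the N×N grid with smoothstep-weighted bilinear
interpolation, periodic in both dimensions (a circular quantity cannot be
interpolated linearly); the interpolated angle is then quantized to the
eight directions with *equal-occupancy* bins — neurons are ranked by angle
and split into eight equal groups — so the direction marginal over the
network is exactly uniform, which is a stated property of this
configuration and of the random configuration it generalizes. Whether the
original field was quantized before or after interpolation is not
documented; quantize-after is used here. A 1×1 coarse lattice carries no
spatial variation and degenerates to a constant (homogeneous-like) field.

Alternative constructions were evaluated (plain scalar interpolation of the
angle values; classical gradient noise rank-mapped to the 8 directions) and
produce respectively much larger and much smaller coherent domains; the
adopted construction reproduces the published structural dichotomy
(feedforward paths: always present for homogeneous, never for
symmetric/random, intermediate for Perlin) but its I-network Perlin
path probability settles near 0.8 rather than the published ≈0.66 (see
Limitations).

## Neuron and synapse model

Leaky integrate-and-fire neurons: C_m = 250 pF, g_L = 25 nS (τ_m = 10 ms),
E_L = V_reset = −70 mV, V_th = −55 mV, absolute refractory period 2 ms.
Synapses are alpha-shaped current transients with τ_syn = 5 ms for both
signs and delay 1 ms. The kernel is peak-normalized,
I(t) = J · e · (t/τ) · exp(−t/τ), so the amplitude parameter J equals the
peak current; with the parameters above J = 10 pA yields a unitary PSP of
0.2214 mV, matching the published 0.22 mV calibration (the printed transient
without the factor e would give 0.13 mV and is inconsistent with that
calibration). `calibrate_weight` inverts the (linear) J → PSP-peak map.

External drive is Gaussian white noise current: an independent value
μ + σξ is drawn per neuron per integration step (s.d. exactly σ, no
1/√dt scaling), held for `noise_dt_ms` (default one step). Defaults:
μ = 700 pA, σ = 100 pA (I-network); μ = 350 pA, σ = 100 pA (EI-network).

### Integration

The coupled linear subsystem (membrane + two-stage alpha filter) is
advanced by its exact propagator at dt = 0.1 ms; external current is held
constant within a step. Because both synapse classes share one time
constant, a single signed filter per neuron suffices. Threshold crossings
are detected on the grid; the spike time is the end of the step; delivery
uses a ring buffer of delay/dt slots. During the refractory period the
membrane is clamped at V_reset while synaptic state keeps evolving.
Initial state is v = E_L (a uniform-random option in [V_reset, V_th) is
available); every analysis discards a 200 ms transient. For constant input
the one-step update matches the analytic solution to machine precision, and
DC-driven firing matches the closed-form LIF rate to within one step of
period quantization (both are tested).

## Sequence analysis

Spikes are points in (x, y, t/time_rescale) and clustered with DBSCAN
(scikit-learn) in sliding 1 s windows overlapping by 0.9 s; clusters from
overlapping windows are merged when they share member spikes (Jaccard
overlap > 0.5, or containment). Defaults: eps = 3, time rescale 20,
minPts = 25 for I-networks; eps = 3.5, rescale 4, minPts = 10 for
EI-networks. minPts and the exact EI values within their published ranges
are supervised choices, exposed in the configuration. The torus metric is
realized by embedding each periodic axis on a ring of equal circumference;
at eps-scale distances chord and arc differ by < 0.01%, and the pipeline is
tested against DBSCAN on the exact wrapped-distance matrix.

Each cluster's bump trajectory is a sequence of torus-aware centroids
(circular mean per axis) in short time bins — 10 ms for velocity traces,
50 ms for sequence qualification — unwrapped with minimal-image increments
so seam crossings stay continuous. Movement direction α_t, its wrapped
change dα ∈ (−π, π], and speed follow from consecutive centroids.

A cluster qualifies as a STAS when its centroid travels ≥ 7 grid points
net, lives ≥ 150 ms, and moves with directional persistence ≥ 0.8 (mean
resultant of step directions over 50 ms bins). The persistence term is the
package's operationalization of "moving bump" vs "bump jittering around a
fixed location": a long-lived jittering bump random-walks a comparable net
distance, but with near-zero persistence. With these defaults, full-size
symmetric and random networks yield zero qualifying sequences while Perlin
and homogeneous networks yield them in every second of activity, with a
wide margin on both sides.

For regimes where all bumps drift coherently (homogeneous fields, large
shifts) the package also provides a cluster-free estimator,
`flow_velocity`: the mean argmax displacement of the wrapped FFT
cross-correlation between activity frames 40 ms apart. It is robust to the
cluster fragmentation that fast drift causes at the published DBSCAN
settings, and is used for the shift-ordering checks.

## Spectral analysis

Population rate = spike counts of a neuron selection (all, 100 random, or
a 10×10 region) in 5 ms bins (200 Hz), z-scored. Welch spectra use a Hann
window, segments of min(length, 1024) samples with 50% overlap, zero-padded
to nfft = 4096, constant detrend (segment length is otherwise undocumented;
peak location is insensitive to it). Spectrograms use 200 ms epochs
advancing by 150 ms. Peak frequency is the band-restricted argmax.

## Feedforward-path discovery

From 64 neurons in an 8×8 block, iterate 50 times: count connections (with
multiplicity) from the current group restricted to the recurrent
anisotropy-carrying class (E→E, or I→I in the I-network), keep the 64
most-targeted neurons (ties broken by ascending id — the published rule
does not specify tie handling). Group centroids are torus-aware; the
effective length is the minimal-image distance between the first and last
centroid, except that when the path's unwrapped extent exceeds half the
torus the unwrapped distance is reported instead — otherwise a homogeneous
path that drifts a full torus circumference would alias back to zero. A
path with effective length > 16 (half the 12 + 8 + 12 = 32 diameter of the
start block's combined connection region) counts as an effective
feedforward pathway; pFF is the qualifying fraction over 100 uniformly
random seeded start blocks.

## Eigenvalue spectra

The signed, multiplicity-weighted adjacency submatrix of 1,000 randomly
sampled neurons (weights in unitary-PSP millivolts; binary available) is
diagonalized densely. The informative statistic is the imaginary spread of
the large-magnitude eigenvalues outside the random-matrix bulk: near zero
for the symmetric layout, growing through random and Perlin to homogeneous.

## Evoked-sequence protocol

Fifty neighboring excitatory neurons receive +500 pA DC for 50 ms, 20
trials, 1 s apart (the inter-trial interval is not published; 1 s is the
default), on top of the background drive. A trial is evoked when the
stimulated set fires ≥ 10 spikes inside some 10 ms sub-window within 50 ms
of onset and no such cluster occurred in the 50 ms before ("clustered
spikes" is not quantified in the source; K = 10 per 10 ms is the default,
configurable). Probability = C_e/20; reaction time = first stimulated
spike after onset; lifespan = first-to-last spike of the evoked episode
(until a gap > 10 ms).

## Problem sizes used by the checks

The acceptance script and the acceptance tests build the full-size models
(10,000- and 18,000-neuron networks) and simulate 3.2 s per spectral
measurement and 1.7–4.2 s per ordering measurement, with a 200 ms discard;
the structural pFF measurements use the full 100 starts × 50 steps.
Orderings over Perlin scales pool two field realizations of 4 s each.
Unit tests use 20×20 to 60×60 networks; angular statistics of the Γ
profile are always tested on the full 100×100 grid because smaller tori
wrap the profile's tail.

## Known limitations

- **I-network Perlin pFF.** Every field construction consistent with the
  published description yields either ≈0.8 (interpolated-value fields,
  including the adopted one) or ≈0.45 (rank-mapped gradient noise) for the
  I-network at scale 20, against a published ≈0.66; the EI value ≈0.84 and
  the homogeneous/symmetric extremes (1.0 / 0) reproduce exactly. The
  original noise generator (a third-party library plus an undocumented
  mapping from noise values to directions) is not recoverable from the
  text; the dichotomy and ordering are robust, the I-network midpoint is
  not.
- **Oscillation frequencies.** The I-network rhythm sits at 74–83 Hz
  (noise-convention dependent) against a published ≈60 Hz, and the
  EI-network rhythm at 21–24 Hz against ≈30 Hz; the low-frequency EI peak
  at 12–14 Hz is reproduced. Both collective frequencies are emergent and
  sensitive to the external-drive discretization, which the source
  describes only as Gaussian white noise; the published parameter tables
  pin every other lever (weights, time constants, delays, degrees).
- **Synthetic fixtures** (moving Gaussian bumps, sinusoid-rate Poisson
  populations) validate estimator correctness with known ground truth;
  they do not emulate bump birth/death dynamics, interactions between
  sequences, or rate inhomogeneity of the real model, so estimator tests
  passing on fixtures bound estimator error, not model realism.
- Velocity traces use 10 ms centroid bins, a reconciliation: the published
  1 s analysis windows cannot resolve the sub-second velocity structure
  the velocity figures show.
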