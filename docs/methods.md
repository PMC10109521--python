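# Methods

## The coupling model

GPLA operates on two normalizations of the same spike-triggered sum of the
band-limited complex analytic LFP.  In `plv` mode each entry of the coupling
matrix is the mean phasor over a unit's spikes (`1/N` normalization, modulus
bounded by 1, invariant to LFP amplitude).  In `c` mode the analytic signal
itself is summed and scaled by `1/sqrt(N)`; this keeps amplitude information
and — the essential point — normalizes the entry's null variance to one when
the LFP has been whitened, which is what lets random-matrix theory describe
the null spectrum.  Both are flat sums over all spikes of all trials, so
concatenating trials and summing per-trial contributions are identical by
construction.

Spike times are stored as integer sample indices into the LFP; continuous
times are rounded to the nearest sample with half-sample ties going to the
earlier sample.  Units below a configurable minimum total spike count
(default 50) are excluded from the matrix, and a unit with zero spikes
yields a flagged missing value, never 0, since 0 asserts "no locking".

## Preprocessing

Band-limiting uses a zero-phase (forward–backward) order-4 Butterworth
filter followed by the Hilbert transform.  The filter family and order are
deliberate defaults, exposed in the API, since phase estimates are only as
good as the band-pass is narrow while temporal dynamics must survive; a
margin of 3 cycles of the band's lower edge (configurable) is discarded at
each trial end before coupling sums, which removes filter and Hilbert edge
artifacts.

Reduced-rank whitening first eigendecomposes the covariance of all trials
concatenated and keeps the smallest rank explaining 99% of variance
(configurable), then whitens each trial with its own truncated
eigendecomposition, making every whitened trial's covariance exactly the
identity on the retained components.  Eigenvalue ties are broken by original
channel index and each eigenvector's global phase is fixed by making its
largest-modulus entry real positive.  The unwhitening operator is the
least-squares map from whitened back to raw channels, fitted on the
concatenated trials; it is exact for a single trial at full rank, and
otherwise a compromise across trials (the per-trial whitening operators
differ), which is why the round-trip identity is only guaranteed for
single-epoch data.  Whitening is optional: it is required by the analytic
significance test and is undone on the LFP vector afterwards for
interpretation in channel space.

## Conventions

The SVD's common phase ambiguity is resolved by rotating both singular
vectors by the negative phase of the mean LFP-vector coefficient; `Phi_d`
(mean LFP phase minus mean spike phase) is computed on the rotated SVD
vectors *before* unwhitening or rescaling.  A consequence worth noting:
multiplying the coupling matrix by a global phase `e^{i theta}` leaves the
convention-rotated LFP vector invariant, shifts `Phi_d` by exactly `theta`,
and rotates the spike vector by `e^{-i theta}` — so the deterministic object
on the spike side is the vector in its own phase gauge,
`v e^{i Phi_d}`.  In `c` mode the spike vector is finally divided entrywise
by `sqrt(N_m)` and renormalized, undoing the per-unit weighting by firing
rate.  The alternative laminar-recording sign convention (fixing the sign of
peri-somatic channels instead of the mean LFP phase) is documented but not
implemented.

## Significance

*Surrogates.*  Interval jitter partitions each trial into windows (default:
one period of the band's center frequency, anchored at t = 0, last partial
window kept) and redraws each spike uniformly within its window, preserving
per-window per-unit counts.  Group-preserved jitter draws one circular shift
per window shared by all units, preserving relative spike timing across the
ensemble.  The p-value uses the add-one formula
`(1 + #{gPLV_surr >= gPLV_obs}) / (1 + n_surr)` so it can never be zero, and
one seeded generator drives the whole test.

*Analytic test.*  With whitening and `c` normalization the null coupling
matrix is asymptotically iid standard complex Gaussian, so the squared
singular values of `C` scaled by `1/n_u` follow the Marchenko–Pastur law
with ratio `alpha_eff = n_c_eff / n_u`.  The scaling of the test statistic
is `S = (1/n_u) C C^H` — chosen so that the null bulk edge is
`theta_DET = (1 + sqrt(alpha_eff))^2` and the gPLV criterion reads
`gPLV > sqrt(n_u theta_DET)`; this choice was validated against sampled iid
complex Gaussian matrices and against the null false-positive benchmark
below.  The number of coupled populations is estimated by walking the
squared singular values from the top and stopping at the first one below the
edge.

A practical caveat discovered while validating the population-count
benchmark: per-trial whitening decorrelates each trial in its *own*
eigenbasis, and when several oscillatory components carry nearly equal
power, those bases rotate arbitrarily between trials, decohering planted
coupling components that are summed across trials.  The multi-assembly
benchmarks therefore use one continuous epoch (the default of the
multi-population generator), where per-trial and global whitening coincide.

## Synthetic study conditions

All benchmark data follow one recipe: oscillatory components (constant or
Tukey-windowed envelope, random initial phase per trial) mixed linearly onto
channels with Gaussian weights plus white noise, and inhomogeneous Poisson
units with rate `lambda0 (1 + kappa * env * cos(phi - phi0))`, clipped at
zero.  For a constant-envelope oscillation the ground-truth PLV of such a
unit is `(kappa/2) e^{i phi0}`, which anchors the coupling-strength scale:
0 is no coupling, 1 is maximal sinusoidal modulation.

The default conditions, fixed a priori from the planted-singular-value
arithmetic (`d_signal^2 ~ n_assembly * N_spikes * kappa^2 / 4` versus the MP
edge `n_u * theta_DET`):

* multi-assembly benchmark — 100 units, 100 channels, 2/5 of units coupled,
  assemblies partitioning the coupled units across frequencies spread in
  11–15.5 Hz, base rate 20 Hz, one 120 s epoch at 200 Hz sampling, channel
  noise sigma 1;
* detection-sensitivity sweep — same layout with one assembly, base rate
  40 Hz (multi-unit-like) and a 400 s epoch, so that a strength of 0.05
  plants a singular value about twice the null edge;
* transient-oscillation scenarios — one channel, 18 units, 5 Hz oscillation
  with a Tukey envelope over the middle half of each 6 s trial, 25 trials,
  base rate 12 Hz, kappa 0.8; the weak-unit comparison of gPLV against
  per-unit and pooled PLV uses 3 units, kappa 0.4, 5 trials of 3 s, and
  19-surrogate tests at the 5% level.

What these generators do *not* emulate: spike-waveform leakage into
high-frequency LFP, non-Poisson firing (bursting, refractoriness),
non-stationary rates beyond the oscillation envelope, and volume-conduction
channel correlations beyond the linear mixing.  Passing benchmarks therefore
validate the estimator and its null calibration, not robustness to these
real-data effects.

## Neural mass and field models

The interpretation layer is a linearized two-population (E/I) rate model:
first-order membranes `tau dV/dt = -V + (synaptic currents) + eta`, sigmoid
rate functions linearized at the operating point, per-connection synaptic
kernels (instantaneous or alpha, `(t/tau_s) e^{-t/tau_s}`) and pure delays.
The mass variant solves the 2x2 frequency-domain system exactly and reports
phases of the E and I rates relative to a chosen LFP proxy (recurrent EPSP,
IPSP, or the exogenous drive).  Two named configurations bracket the
oscillogenesis question: membrane dynamics only (PING-capable; E–I phase
difference monotone in frequency, no sign change) versus added delayed
alpha-synapse I–I coupling (ING; the E–I lead–lag relation reverses across
the frequency axis).  The I–I parameters (nu_II = 3, tau_s = 6 ms, delay
3 ms) were chosen once to place that reversal inside 1–180 Hz.

The spatial variant puts both populations on a square electrode grid
(extent 1.2 cm, spacing 800 µm), couples E populations horizontally with an
exponentially decaying, row-normalized kernel (scale r0 = 440 µm), keeps
inhibition local, and drives the array with a synchronous excitatory input
whose spatial amplitude is a Gaussian (sigma 1.4 mm) and whose time course
is rectified band-limited noise (low-passed at 30 Hz so its power lies in
the analysis bands).  Sigmoid rates use `Q sigma(4 chi (V - V_th) / Q)`, so
`chi` is the maximum slope; the four inhibition presets vary `chi_I` and
`V_th_I` only.  The I→E connection carries an alpha synapse (15 ms) and an
8 ms delay — the lag that lets strong recurrent inhibition pull response
phases back toward the input focus.  Integration is forward Euler with
`dt <= tau/20` (guarded), box-filter downsampling to 250 Hz, and one
excitatory Poisson unit per node.

The low-frequency spatial response to a localized input is a convolution
with `k(x) = e^{-|x| a(f)}`,
`a^2 = (1/r0^2)[1 + nu_EI nu_IE - nu_EE - i 2 pi tau f (2 nu_EI nu_IE -
nu_EE)]` with gain-scaled couplings evaluated at the input-free equilibrium
(found by damped fixed-point iteration).  `Im[a] > 0` means outward
propagation from the input focus, `Im[a] < 0` a wave converging back onto
it; across the four presets `Im[a]` falls monotonically from positive
(weak) to negative (strong).

Known limitation: with the Table-of-parameters couplings under this sigmoid
convention, the equilibrium E–I loop gain is at most about 0.67, which caps
the converging-wave phase contrast across the array at roughly 0.2 rad.
That is at the spike-estimation noise floor for desk-scale recordings, so
while the strong-inhibition preset's phase–modulus regression slope is
negative, its significance is marginal (p ≈ 0.07 in the committed
configuration); the corresponding acceptance check is left failing rather
than tuning the model.  The band-peak contrast (weak: lowest band; strong:
the 3–5 Hz resonance band) and the `Im[a]` signs are robust.  Sensitivity
to the linearization point is real: under strong drive the I population
operates on a steeper part of its sigmoid, raising the loop gain above the
input-free value.

## Numerical choices

* SVD phase fixed solely by the zero-mean-LFP-phase convention; spectra
  sorted descending by `numpy.linalg.svd`.
* Mean-LFP-vector modulus below `1e-15` of the largest coefficient: rotation
  skipped and flagged.
* Von Mises fits use the ML estimator with concentration capped at `1e6`;
  resultant length below `1e-9` returns kappa 0 with a uniformity flag.
* Phase–modulus regression unwraps phases about their circular mean before
  ordinary least squares; all-equal moduli return a flagged degenerate fit.
* Whitening refuses rank-deficient trials below the retained rank;
  zero-variance input is an error.
* Jitter windows are anchored at the trial start; the last partial window is
  kept and jittered within its own span.
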