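# gpla — generalized phase locking analysis

`gpla` quantifies the coupling between *populations* of spiking neurons and
*multi-channel* local field potentials (LFPs).  Classical spike–field
coupling measures such as the phase-locking value (PLV) treat one unit and
one LFP channel at a time; with modern probes recording hundreds of units and
channels, the resulting matrix of pairwise couplings is unwieldy and its
individual entries are noisy.  GPLA summarizes that matrix with a single
dimensionality reduction:

1. Band-pass each LFP channel in the frequency band of interest and take its
   complex analytic signal `L_f(t) = a_f(t) e^{i phi_f(t)}` (Hilbert
   transform).
2. For every (channel *n*, unit *m*) pair, sum the analytic signal over the
   unit's spike times.  Two normalizations are available:
   `PLV_{nm} = (1/N_m) Σ_j e^{i phi_n(t_j)}` or
   `c_{nm} = (1/sqrt(N_m)) Σ_j L_n(t_j)`.
3. Decompose the resulting complex coupling matrix `C = U D V^H`.

The leading singular value `d_1` is the **generalized phase-locking value
(gPLV)**; the corresponding singular vectors are the **LFP vector** (one
complex weight per channel) and the **spike vector** (one per unit).  Each
coefficient's modulus measures how strongly that channel/unit participates in
the dominant coupling pattern, and its phase measures relative timing.  The
common phase ambiguity is fixed by rotating both vectors so the mean LFP
vector phase is zero; the residual mean spike-vector phase `Phi_d` is then
the overall spike–LFP phase shift.

Two significance tests are provided:

* **Surrogate tests** — spikes are redrawn uniformly within windows matched
  to the analysis band (interval jitter), or all units are circularly
  shifted together per window (group-preserved jitter); the observed gPLV is
  compared with the surrogate distribution.
* **Analytic test** — after reduced-rank whitening of the LFP and with the
  `1/sqrt(N)` normalization, the null coupling matrix has asymptotically iid
  standard complex Gaussian entries, so its squared singular values follow
  the Marchenko–Pastur law.  Coupling is declared significant when
  `gPLV^2 / n_u` exceeds the deterministic edge
  `theta_DET = (1 + sqrt(n_c_eff / n_u))^2`; counting the singular values
  above the edge estimates the number of independently coupled populations.
  This runs in milliseconds regardless of the number of units.

The package also ships the synthetic benchmarks used to validate these tests
(phase-locked Poisson spike trains on oscillation-mixture LFPs) and
linearized two-population neural mass / neural field models that give the
GPLA features a biophysical reading (E–I phase lags across frequency,
spatial phase gradients controlled by recurrent inhibition).

## Worked example

Simulate 18 units firing in three clusters at distinct phases of a 5 Hz
transient oscillation, then analyze and test:

```bash
$ gpla simulate --preset three_clusters --seed 7 --out demo
wrote demo/lfp.h5, demo/spikes.csv

$ gpla run --lfp demo/lfp.h5 --spikes demo/spikes.csv \
      --band 3 7 --mode plv --min-spikes 20 --out demo_out
band 3-7 Hz: gPLV=0.9813 Phi_d=+0.703 rad

$ gpla test --lfp demo/lfp.h5 --spikes demo/spikes.csv \
      --band 3 7 --method surrogate --n-surrogates 99 --seed 7 \
      --out demo_test
band 3-7 Hz: gPLV=0.9813 significant=True (p=0.0100)
```

With one LFP channel and 18 units, a gPLV of 0.98 (normalized by its maximum
`sqrt(n_c * n_s) = sqrt(18)`: 0.23) reflects strong locking spread over
three phase clusters; `Phi_d = +0.70 rad` is the mean phase by which spiking
leads the oscillation; the surrogate p-value of 0.01 (the smallest value 99
surrogates can yield) confirms significance.  The spike-vector coefficients
written to `demo_out/gpla_3-7Hz.h5` separate the three clusters by phase.

The same steps are available as a library:

```python
import numpy as np
from gpla import synthetic, RunConfig, run_pipeline

lfp, spikes, truth = synthetic.gen_scenario("three_clusters",
                                            rng=np.random.default_rng(7))
cfg = RunConfig(bands=[(3.0, 7.0)], mode="plv", min_spikes=20,
                sig_method="surrogate", n_surrogates=99, seed=7)
(result, report), = run_pipeline(cfg, lfp, spikes)
print(result.gplv, result.phi_d, report.p_value)
```

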