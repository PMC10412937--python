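# laminarfp

Bilateral laminar field-potential analysis for hippocampal (and other
layered) multichannel recordings: blind separation of pathway-specific
field-potential generators, and a battery of coupling, causality and
event-level analyses between homotopic left/right probes or between
generators on the same side.

## Who this is for

Electrophysiologists with paired laminar probe recordings (e.g. two
32-site silicon probes in the left and right dorsal hippocampus) who want
to move from raw depth profiles of voltage to pathway-resolved statements
like "the medial perforant-path input is bilaterally coherent in the delta
band, the Schaffer input shares individual gamma waves across hemispheres,
and neither drives the other with a measurable lag".

## The model

The potential at electrode *m* is modelled as an instantaneous linear
mixture of *N* generators,

    u_m(t) = Σ_n V_mn s_n(t),

where the columns of the mixing matrix **V** (the *voltage loadings*) are
depth profiles that identify synaptic pathways, and s_n(t) are generator
time courses. PCA pre-reduction followed by ICA estimates both factors;
generators below 1% relative variance are rejected; left/right profiles
are matched by correlation distance (< 0.2) with average-linkage
clustering.

On top of the separated generators the package computes:

- **CSD** — 1-D current-source density, `-(σ/h²)(u_{m-1} - 2u_m + u_{m+1})`,
  which cancels volume-conducted (channel-constant) contributions;
- **lagged cross-correlation** `R = C12/√(C11 C22)` with surrogate
  significance for the peak;
- **spectral coherence** `C_xy(f) = |P_xy|²/(P_xx P_yy)` with per-frequency
  thresholds from 1000 phase-randomization surrogates (α = 0.05);
- **windowed Pearson histograms** at Δt ∈ {1, 0.1, 0.01} s — long windows
  track envelopes, short windows track individual waves;
- **pairwise Granger causality** (temporal and spectral), 250 Hz, 5 s
  windows, 80% overlap, order 12, block-resampling surrogates with a
  normal-approximation threshold;
- **pulse-template deconvolution** of gamma waves,
  `s(t) = Σ w_k f(t-τ_k; δ_k)` with `f(t;δ) = H(t)(t/δ²)e^(-t²/2δ²)`,
  bilateral pairing at ≥ 70% support overlap, and amplitude covariation of
  the paired waves.

A synthetic-data generator (`laminarfp.synth`) produces bilateral
recordings with known mixing matrices, event lists and coupling structure,
so every stage is testable against ground truth.

## Worked example

```python
from laminarfp import (simulate_scene, run_ica, match_profiles,
                       coherence_with_significance, downsample)

rec, truth = simulate_scene(duration=60.0, fs=1000.0, seed=3)

left = run_ica(rec.left, n_components=6, seed=7)
right = run_ica(rec.right, n_components=6, seed=8)
match = match_profiles(left.mixing, right.mixing, threshold=0.2)
print("matched pairs:", [(i, j, round(d, 3)) for i, j, d in match.pairs])

# the highest-variance generator (index 0 on each side)
i, j, _ = next(p for p in match.pairs if p[0] == 0)
x = downsample(left.timecourses[i], 250.0, fs=1000.0)
y = downsample(right.timecourses[j], 250.0, fs=1000.0)
coh = coherence_with_significance(x, y, 250.0, n_surrogates=1000, seed=0)
band = (coh.freqs >= 1) & (coh.freqs <= 4)
print("delta-band coherence %.2f, significant fraction %.2f"
      % (coh.coherence[band].mean(), coh.significant[band].mean()))
```

Output:

```
matched pairs: [(1, 1, 0.0), (0, 0, 0.0), (2, 2, 0.0), (3, 3, 0.0), (4, 4, 0.001), (5, 5, 0.001)]
delta-band coherence 0.66, significant fraction 1.00
```

All six generator profiles match across hemispheres essentially exactly
(correlation distances ≪ 0.2), and the highest-variance generator — the
Schaffer-like one, whose gamma waves are 90% bilaterally paired in this
scene — shows strongly significant delta-band coherence.

A command-line interface mirrors the library
(`laminarfp simulate | preprocess | separate | csd | couple | granger |
deconv | run-all`).

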