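# normcoh

Normative abnormality scoring of spectral coherence between two
brain-region time series.

## The problem

Resting-state fMRI studies often ask whether the functional coupling
between two regions — here the posterior cingulate cortex (PCC, a core
default-mode-network node) and the dorsal anterior cingulate cortex
(dACC) — differs between a clinical group and controls. Correlation
collapses that coupling to one number; *spectral coherence* resolves it
by frequency, which matters because resting-state networks have
distinct spectral signatures and clinical effects can be band-limited.
And rather than training a two-class classifier (which presumes the
groups are separable and biases the analysis toward discrimination),
this package scores each subject by how *atypical* their coherence
spectrum is relative to a pooled sample — a normative, unsupervised
analysis suited to heterogeneous clinical populations.

## The method

For each subject with region signals x_t, y_t (T samples, sampling
interval dt; z-normalized to mean 0, variance 1):

1. **Parametric coherence.** Fit a bivariate VAR(p),
   `z_t = B_1 z_{t-1} + ... + B_p z_{t-p} + e_t`, by the multivariate
   Yule-Walker equations, with p chosen per subject by AIC over 1–10.
   The model-implied spectral matrix is
   `S(f) = A(f)^{-1} Σ A(f)^{-H}`, `A(f) = I − Σ_k B_k e^{−i2πf·dt·k}`,
   and the feature vector is the magnitude-squared coherence
   `C(f) = |S_xy|² / (S_xx S_yy) ∈ [0,1]` at 125 equally spaced
   frequencies up to the Nyquist limit (0.25 Hz at TR = 2 s).
2. **Abnormality index.** Train a ν-one-class SVM (RBF kernel,
   γ = 1/125, ν = 0.5) on the *pooled* features of both groups and
   score every subject in-sample: `index = ρ − Σ_i α_i k(x_i, v)`, the
   negated decision score. Pooling keeps the analysis symmetric in the
   groups; ν bounds the fraction of training subjects flagged abnormal.
3. **Group comparison.** One-tailed Mann-Whitney U on the indices
   (case group expected greater), plus sex (Mann-Whitney) and age
   (quadratic-regression F-test) confound checks.
4. **Relevance curve.** Retrain with each frequency excluded in turn;
   the relevance of frequency j is the *drop* in between-group median
   separation it causes, `Δ_full − Δ_(−j)`.

A synthetic cohort generator produces bivariate series with known,
group-specific, band-limited coupling (see `docs/methods.md`) so the
whole pipeline is testable without any imaging data.

## Worked example

A cohort of 21 + 21 subjects (T = 197 samples, TR = 2 s) whose groups
differ only in the 0.01–0.05 Hz band — the case group's coupling there
is reduced on average and much more heterogeneous:

```python
import normcoh as nc

manifest, series = nc.generate_cohort(nc.single_band_contrast(seed=0))
result = nc.run_pipeline(nc.PipelineConfig(), manifest, series=series)
print(result.comparisons[0])
```

Running `python examples/06_full_pipeline.py` prints:

```
contrast case_vs_control:
  U = 322, one-tailed p = 0.0055
  medians: case +0.0282, control -0.0029
  relevance peak: 0.038 Hz
  confounds: sex p = 0.103, age p = 0.263
```

The case group's median abnormality index is significantly greater
(p = 0.0055): its heterogeneous coupling makes its members atypical
within the pooled sample. The relevance curve peaks at 0.038 Hz —
inside the only band where the groups actually differ — while sex and
age show no effect, as expected since neither influenced the generator.
The other `examples/` scripts walk through each stage (simulation,
coherence features, indices, relevance, comparison) one at a time.

A thin CLI mirrors the pipeline for shell use:

```sh
normcoh simulate --out cohort --seed 0
normcoh run-all --manifest cohort/manifest.csv --out results
```

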