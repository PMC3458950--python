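"""Which frequencies carry the group difference?

Retrains the mixed-group one-class SVM 125 times, each time excluding
one frequency's coherence value, and records the drop in the
between-group median separation of the abnormality indices.  On a
cohort whose coupling differs only within 0.01-0.05 Hz, the relevance
curve should peak inside that band.
"""

import warnings

import normcoh as nc

spec = nc.single_band_contrast(seed=0)
manifest, series = nc.generate_cohort(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    features, _, _ = nc.pipeline.extract_features(manifest, nc.PipelineConfig(), series)

X = features.iloc[:, 1:].to_numpy()
g = manifest.group.to_numpy()
grid = nc.default_grid(2.0, 125)
curve = nc.leave_one_frequency_out(X[g == "case"], X[g == "control"], grid)

print(f"baseline separation (case median - control median): "
      f"{curve.baseline_separation:+.4f}")
print(f"relevance peak at {curve.peak_frequency:.3f} Hz "
      f"(perturbed band: 0.01-0.05 Hz)")
in_band = (grid >= 0.01) & (grid <= 0.05)
print(f"mean relevance inside band : {curve.relevance[in_band].mean():+.2e}")
print(f"mean relevance outside band: {curve.relevance[~in_band].mean():+.2e}")
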