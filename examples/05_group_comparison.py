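"""Rank-based comparison of abnormality indices, with confound checks.

The hypothesis is directional (case subjects are more abnormal, i.e.
greater median index), so the Mann-Whitney test is one-tailed.  Sex is
checked with a two-tailed Mann-Whitney test and age with a quadratic
regression F-test on the pooled indices.
"""

import warnings

import numpy as np

import normcoh as nc

spec = nc.single_band_contrast(seed=0)
manifest, series = nc.generate_cohort(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    features, _, _ = nc.pipeline.extract_features(manifest, nc.PipelineConfig(), series)

X = features.iloc[:, 1:].to_numpy()
g = manifest.group.to_numpy()
results, _ = nc.mixed_group_protocol(
    X[g == "case"], X[g == "control"], group_names=("case", "control")
)
idx = np.array([r.index for r in results])
case = idx[: (g == "case").sum()]
ctrl = idx[(g == "case").sum():]

rep = nc.mann_whitney_one_tailed(case, ctrl, "a-greater", contrast="case-vs-control")
print(f"{rep.contrast}: U = {rep.u_statistic:.0f}, one-tailed p = {rep.p_value:.4f}")
print(f"medians: case {rep.median_a:+.4f}  control {rep.median_b:+.4f}")

print(f"sex effect (two-tailed MW) p = {nc.sex_effect_test(idx, manifest.sex):.3f}")
print(f"age effect (quadratic F)   p = {nc.age_effect_quadratic(idx, manifest.age):.3f}")
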