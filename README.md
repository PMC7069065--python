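# msnkit

Morphometric similarity networks (MSNs) estimate the mesoscale organization of
an individual cortex as the similarity between regions' anatomical profiles.
For each subject, every cortical region of the 68-region Desikan–Killiany
atlas carries a vector of morphometric features — up to ten of them, spanning
T1w-derived macrostructure (cortical thickness CT, surface area SA,
gray-matter volume GM, mean/Gaussian curvature MC/GC, folding and curvature
indices FI/CI), the T1w/T2w-ratio myelin proxy, and DWI microstructure (FA,
MD). Each feature is z-scored across the 68 regions (raw units span six
orders of magnitude), and the network edge between regions *i* and *j* is the
Pearson correlation of their z-scored feature vectors.

`msnkit` implements the full comparison of three nested acquisition models —
**msn10** (T1w + T1w/T2w + DWI), **msn8** (T1w + T1w/T2w), **msn7** (T1w only)
— for users asking whether clinically feasible, reduced-acquisition MSNs
approximate the multimodal network:

- proportional density thresholding (retain the k = round(d·n(n−1)/2)
  strongest edges so all compared networks have equal edge counts), nodal and
  graph strength;
- similarity statistics: all-edge and mutually-nonzero-edge Pearson
  correlation, the Mantel statistic (with optional permutation p), the binary
  edge-replication proportion Σ(xᵢ≠0 & yᵢ≠0)/Σ(xᵢ≠0), and paired-t effect
  sizes r = √(t²/(t²+df));
- reliability studies: hierarchical intermodel comparison (full model as
  reference), test-retest, and subject-vs-group-average congruence;
- cognition prediction: nodal strength residualized for age, sex and
  age×sex, then PLS1 regression with the component count selected by the
  cross-validated Q² = 1 − PRESS/TSS over repeated 9-fold CV (zero components
  = intercept-only is a first-class outcome), a stratified-bin training
  variant, and BCa-bootstrapped predictor weights;
- a synthetic-cohort generator with shared cohort structure,
  modality-grouped noise, tunable test-retest reliability ρ and tunable
  brain–behavior coupling β, standing in for restricted MRI data so every
  stage is testable end to end.

## Worked example

```python
import numpy as np
from msnkit import (CohortConfig, generate_cohort, run_intermodel)

cohort = generate_cohort(CohortConfig(n_subjects=100, seed=1))
records, summary = run_intermodel(cohort, densities=[0.4])
peak = summary.query("statistic == 'r_all'").set_index("contrast")
for contrast, row in peak.iterrows():
    print(f"{contrast}: {row['mean']:.3f} +/- {row['sd']:.3f}")
```

prints

```
msn10_vs_msn7: 0.799 +/- 0.025
msn10_vs_msn8: 0.875 +/- 0.019
```

i.e. at 40% density the 8-feature network's edge weights correlate r ≈ 0.88
with the full 10-feature network and the T1w-only network r ≈ 0.80 — the
hierarchical ordering expected when dropping an imaging modality removes
information. The numbered drivers under `analysis/` run each study stage and
print the corresponding summaries (`01` simulates and writes a cohort, `02`
intermodel similarity and graph strength, `03` test-retest, `04`
subject-vs-group, `05` cognition PLS, `06` the full orchestrated pipeline
with a checksummed manifest).

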