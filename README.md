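# adsubtype

Subtyping Alzheimer's disease from MRI visual rating scales, and
characterizing the subtypes — for neuroimaging and biostatistics researchers
who want the whole workflow reproducible on synthetic data.

## The problem

AD is heterogeneous: neuropathology and MRI studies repeatedly find a
*typical* form (atrophy in both the medial temporal lobe and the association
cortex), a *limbic-predominant* form (medial temporal atrophy only), a
*hippocampal-sparing* form (cortical atrophy with spared medial temporal
lobe), and patients with *no visible atrophy*. Sophisticated image-analysis
pipelines can find these subtypes, but clinics rate scans with quick ordinal
visual scales. This package implements subtyping directly from three such
scales:

* **MTA** (Scheltens, 0–4 per hemisphere) — medial temporal lobe atrophy,
* **PA** (Koedam, 0–3) — posterior/parietal atrophy,
* **GCA-F** (Pasquier frontal subscale, 0–3) — frontal atrophy.

Left/right MTA are averaged; the composite is abnormal at the age-banded
cutoffs **≥1.5 / ≥1.5 / ≥2 / ≥2.5** for ages 45–64 / 65–74 / 75–84 / 85–94,
while PA and GCA-F are abnormal at **≥1** regardless of age. The decision
rule is then:

| MTA abnormal | cortex (PA or GCA-F) abnormal | label |
|---|---|---|
| yes | yes | typical |
| yes | no  | limbic-predominant |
| no  | yes | hippocampal-sparing |
| no  | no  | no-atrophy |

Around the classifier sits the full characterization toolkit: AVLT
memory-component profiling with −1.5 SD impairment flags, backward multiple
regression with **general dominance analysis** (Shapley decomposition of R²
over all predictor subsets) and bootstrap stability screening, longitudinal
**random-intercept mixed models** for CDR/MMSE slopes with pairwise slope
contrasts, random-forest group discriminability with analytic chance error,
weighted κ rater reliability, and Benjamini–Hochberg FDR correction — plus a
seeded synthetic cohort generator that reproduces the statistical structure
of the motivating ADNI-1 sample (group sizes 230/100/33/35/30, demographics,
standardized memory-model coefficients, trajectory slopes), so every stage
runs and validates without restricted data.

## Worked example

```python
import numpy as np
from adsubtype import (VisualRatings, classify_subtype, CohortSpec,
                       generate_longitudinal, TrajectoryModel)

# one patient, age 70: abnormal MTA (mean 2.0 >= 1.5) + abnormal PA
print(classify_subtype(VisualRatings(2, 2, 1, 0), age=70).value)

# parameter recovery: simulate 5 groups x 500 subjects at visits 0/1/2 years
# with per-group CDR slopes (0.03, 0.29, 0.28, 0.16, 0.14), then refit
groups = ["HC", "typical", "limbic_predominant", "hippocampal_sparing", "no_atrophy"]
spec = CohortSpec(group_sizes={g: 500 for g in groups}, seed=7)
fit = TrajectoryModel(generate_longitudinal(spec), "cdr").fit()
print(fit.group_slopes().round(3))
```

prints

```
typical
                     slope     se
group
HC                   0.023  0.005
typical              0.293  0.005
limbic_predominant   0.266  0.005
hippocampal_sparing  0.158  0.005
no_atrophy           0.145  0.005
```

i.e. the mixed model recovers each generating slope to within a few
thousandths of a CDR point per year (each estimate sits within ~2 standard
errors of its true value). `fit.slope_contrasts()` adds pairwise Wald tests
with BH adjustment, and `fit.compare_quadratic()` tests whether progression
accelerates (a likelihood-ratio test of the quadratic time terms).

The same objects drive a CLI:

```bash
subtype simulate --seed 7 --out sim/
subtype classify --in sim/cross_section.csv --out labels.csv
subtype trajectories --in sim/longitudinal.csv --outcome cdr
subtype run --config run.yaml      # full pipeline, one reproducible run
```

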