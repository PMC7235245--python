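# ithkit

Multi-region intratumor-heterogeneity (ITH) analysis: somatic copy-number
(SCNA) calling from SNP-array BAF/LRR signals, purity-adjusted DNA
methylation, an unbiased ITH index with a principled variance model, weighted
survival association, and joint genetic/epigenetic tumor phylogenies — with a
ground-truth synthetic cohort generator that makes every stage testable.

## The problem

When a tumor is sampled in several regions, the genomic differences among
those regions measure intratumor heterogeneity, a quantity repeatedly linked
to prognosis. The obvious index — the fraction of the genome altered in *some
but not all* samples — grows mechanically with the number of samples taken,
so patients biopsied more often look more heterogeneous, and anything
correlated with sampling intensity (tumor size, study site) confounds the
association with outcome.

`ithkit` implements the **average pairwise ITH index (APITH)**. For a patient
with *k* tumor samples and pairwise distance *d<sub>ij</sub>*,

```
APITH = 2 / (k(k-1)) · Σ_{i<j} d_ij
```

a U-statistic whose expectation is free of *k*. Distances are the proportion
of probes with different copy-number status (SCNA) or the Euclidean distance
of purity-adjusted beta values (methylation). The variance of APITH *does*
shrink with *k*:

```
Var(APITH | k) = σ²_d / m + 4(k-2)·c / (k(k-1)),   m = k(k-1)/2
```

where σ²_d is the variance of one pairwise distance and c the covariance of
two distances sharing a sample. Both are estimated from the cohort by pooled
method of moments, and the resulting inverse-variance weights feed a weighted
Cox proportional-hazards model, giving patients with better-measured APITH
more influence. See `docs/methods.md` for the full model description.

Intended users: statistical-genomics and cancer-evolution researchers working
with multi-region SNP-array / methylation-array data, and methodologists who
need a reproducible test bed for ITH estimators.

## Worked example

Simulate a 200-patient multi-region cohort with known clonal ground truth,
compute per-patient SCNA APITH with inverse-variance weights, and test the
association with overall survival:

```python
import numpy as np
from ithkit import assoc, ith
from ithkit.scna import CopyNumberProfile
from ithkit.simdata import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(n_patients=200, n_probes=8000, seed=7))

results, dmats = [], []
for pat in cohort.patients:  # here: distances from the true status tracks
    profiles = [CopyNumberProfile(s, pat.true_status[i], pat.true_status[i] * 0 + 2)
                for i, s in enumerate(pat.sample_ids)]
    dm = ith.scna_distance_matrix(profiles)
    dmats.append(dm)
    results.append(ith.ApithResult(pat.patient_id, dm.k, ith.apith(dm), dm.metric))

model = ith.estimate_variance_model(dmats)
results = ith.apith_weights(results, model)
print(f"mean APITH = {np.mean([r.apith for r in results]):.3f}")
print(f"sigma2_d = {model.sigma2_d:.4f}, c = {model.c:.4f}")

clin = cohort.clinical.assign(apith=[r.apith for r in results])
fit = assoc.fit_cox(clin, weights=[r.weight for r in results])
print(f"HR per sd APITH = {fit.hr:.2f} (95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), "
      f"p = {fit.p:.3g}, n = {fit.n}")
```

Output:

```
mean APITH = 0.132
sigma2_d = 0.0195, c = 0.0019
HR per sd APITH = 1.33 (95% CI 1.10-1.62), p = 0.00303, n = 200
```

The mean APITH of 0.132 says that two regions of the same tumor differ in
copy-number status at about 13% of probes on average. The cohort was
generated with a hazard ratio of 1.5 per 0.153 units of true APITH; this
cohort's own APITH spread is smaller (sd ≈ 0.12), so the true effect per
*sample* standard deviation is ≈ 1.36 — the weighted fit recovers 1.33 with a
covering confidence interval. `sigma2_d` and `c` are the two moments of the
variance model; patients with more samples get proportionally larger weights.

The same steps are available from the shell: `ithkit simulate`,
`ithkit scna-call`, `ithkit meth`, `ithkit apith`, `ithkit survival`,
`ithkit tree` (see `--help` on each).

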