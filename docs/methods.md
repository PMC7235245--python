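# Methods

`ithkit` quantifies intratumor heterogeneity (ITH) from multi-region tumor
sampling and relates it to clinical outcome. This note records the models the
package implements, the defaults it ships with, and the design decisions that
were genuinely open.

## The APITH index

For a patient with `k` tumor samples and a pairwise distance `d_ij` between
samples `i` and `j`,

    APITH = 2 / (k(k-1)) * sum_{i<j} d_ij ,

the average distance over all sample pairs. Because APITH is a U-statistic of
degree 2, its expectation does not depend on `k` when samples are exchangeable
within a patient. This is the property that makes cross-patient comparison
valid: the older "naive" index — the fraction of the genome disrupted by SCNAs
not shared by *all* samples — grows mechanically with `k` (more samples, more
chances for an alteration to be private), which both biases comparisons and
opens the door to confounding by whatever drives the number of samples taken.

Distances supported:

* **SCNA**: proportion of probes whose 4-level copy-number status
  (DEL / LOH / NEUTRAL / AMP) differs between two samples, optionally within a
  probe subset (e.g. driver-gene regions).
* **Methylation**: Euclidean distance between purity-adjusted beta vectors
  over a chosen probe set; the "scaled" variant divides by sqrt(#probes)
  (root-mean-square difference) so regions of different size are comparable.

## Variance of APITH and inverse-variance weights

While the expectation of APITH is free of `k`, its variance is not. Writing
`sigma2_d = Var(d_ij)` and `c = Cov(d_ij, d_il)` for two pairs sharing one
sample, the U-statistic decomposition over `m = k(k-1)/2` pairs gives

    Var(APITH | k) = sigma2_d / m + 4 (k-2) c / (k (k-1)) .

Both moments are estimated by pooled method of moments from within-patient
*centered* distances (centering removes each patient's mean level, so no
assumption on the distribution of true ITH across patients is needed). Under
the exchangeable working model `d_ij = mu + a_i + a_j + e_ij`:

    E[S1] = (k-1)(k-2) sa2 + (m-1) se2        S1 = sum of squared residuals
    E[S2] = N_s (k-4)/k sa2 - (k-2) se2       S2 = shared-sample cross products

with `N_s = k(k-1)(k-2)/2`, `sigma2_d = 2 sa2 + se2`, `c = sa2`. These
equations are summed over patients and solved. Identifiability: at `k = 3` the
two equations are collinear (residuals sum to zero and every pair-of-pairs
shares a sample), so separating `c` from pair noise requires at least one
patient with `k >= 4`; otherwise the estimator falls back to `c = 0` with a
warning. Weights for the survival models are `1 / Var(APITH | k)`, normalized
to mean 1 (so rescaling all distances, or all weights, changes nothing).

A delete-one jackknife is provided as a cross-check. The plain Tukey jackknife
of a pairwise average is *provably* upward-biased: its pair-noise component is
inflated by `2(k-1)/(k-2)` (a factor 4 at k = 3). The default implementation
therefore solves the jackknife value together with the within-patient sum of
squares for the two variance components and evaluates the exact variance; this
corrected estimator is unbiased for `k >= 4`. At `k = 3` no within-patient
estimator can be unbiased (the two observable moments are both proportional to
`sa2 + se2`, whereas the target is `(4 sa2 + se2)/3`), so the conservative
uncorrected value is returned with a warning.

## SCNA calling

Extensively rearranged tumor genomes make joint BAF+LRR segmentation fragile,
so segmentation uses BAF alone and LRR only for classification:

1. **Segmentation** — the mirrored signal `|BAF - 0.5|` of heterozygous
   probes is segmented per chromosome by exact penalized least-squares
   changepoint search (PELT). The penalty defaults to `2 * sigma^2 * 3 log n`;
   sigma is estimated from lag-1 differences of the mirrored signal, where
   segment-level shifts cancel, using the half-normal folding constant 0.5308
   (the mirrored noise in balanced regions is half-normal, not normal).
   Segments with fewer than `min_probes` (default 15) heterozygous probes are
   merged into the more similar neighbor.
2. **"Different from 0.5"** — a segment is allelically imbalanced when its
   mean mirrored BAF exceeds `sigma*sqrt(2/pi) + 3*sigma/sqrt(min_probes)`,
   i.e. the expected mean of a balanced segment plus three standard errors.
3. **Classification** — each imbalanced segment's LRR values are compared to
   the pooled LRR of balanced segments by a two-sided pooled t-test with
   Benjamini-Hochberg adjustment across segments: significantly higher → AMP,
   lower → DEL, otherwise copy-neutral LOH. Two safeguards make this usable
   on heavily rearranged genomes: (i) the reference excludes balanced segments
   whose mean LRR is an outlier (beyond 3 MAD, minimum band 0.1) — a
   homozygous deletion in an impure sample has BAF exactly 0.5 (all allelic
   signal comes from contaminating normal DNA) and would otherwise drag the
   reference down and cascade LOH→AMP errors; (ii) a minimum practical effect
   of 0.1 LRR accompanies the t-test, because on multi-hundred-probe segments
   statistical significance is reached at offsets (~0.005) far below any
   genuine copy change (a single-copy gain at purity 0.5 shifts LRR by ~0.17).
4. **Copy number** — `CN = round(2 * 2^(LRR/gamma))` with `gamma = 0.55`,
   floored at 0, optionally corrected for known purity
   (`CN = (CN_mix - 2(1-pi))/pi`). Driver events: oncogene with max CN >= 4
   (amplification), tumor suppressor with min CN = 0 (deletion).

Known limitation: copy-zero segments in impure samples are invisible to
BAF-only segmentation (step 2 classifies them NEUTRAL). This is intrinsic to
the method, not the implementation; the simulator makes homozygous deletions
focal (60–120 probes) for the same reason they are focal in real tumors.

## Methylation processing

Observed tumor betas are modelled as a purity-weighted linear mixture,
`beta_obs = pi*beta_tumor + (1-pi)*beta_normal`; `adjust_purity` inverts it
and clips to [0, 1]. Purity is an input (the simulator's truth, or a value
estimated upstream); estimating purity from 450K data is out of scope. Tumors
without a matched normal use the per-probe mean over all normals. All
downstream methylation analyses consume adjusted betas.

* **Probe selection**: top-n or top-fraction by across-tumor-sample variance,
  ties broken by probe id.
* **CIMP**: average-linkage Euclidean hierarchical clustering of tumor samples
  on the 5000 most variable promoter CpG-island probes, cut into two groups; a
  group is CIMP-H when its mean promoter-island beta exceeds the normal mean
  by at least `min_delta` (default 0.05 — the margin makes "tumors identical
  to normals" come out all CIMP-L; the underlying phenotype has no published
  quantitative threshold, so the cut is an operationalization).
* **Driver methylation**: per driver gene, mean beta over promoter-island
  probes; an event is `|mean_tumor - mean_normal| >= 0.3`, direction recorded.

## Survival association

Cox proportional-hazards fits (lifelines) of overall survival or distant
metastasis on APITH, adjusted for stage, age and smoking; Efron tie handling.
With weights, the weighted partial likelihood is maximized and a robust
sandwich variance reported. APITH enters per standard deviation by default
(per-unit optional). Kaplan-Meier curves are stratified at the median APITH,
with the group test from the (weighted) Cox model on the high/low indicator
and an optional restriction to patients with at least `min_k` samples.

## Phylogenies

Per-patient trees are distance-based balanced minimum evolution: neighbor
joining (scikit-bio) provides the starting topology, nearest-neighbor
interchange hill-climbing on Pauplin's balanced tree length refines it, and
branch lengths are OLS estimates clamped at 0. SCNA and methylation matrices
combine into the consensus distance
`d0_ij = 0.5 (d1_ij / max d1 + d2_ij / max d2)` (SCNA term alone for pairs
without methylation). Congruence between data types is the Spearman
correlation of pooled within-patient pairs (never cross-patient), with a
Mantel-style within-patient label permutation test (exhaustive enumeration for
a single small patient); tree-vs-tree similarity is Robinson-Foulds, raw and
normalized by `2(n-3)`.

## The synthetic cohort generator

Each patient is a random rooted clone tree: the founder carries public events,
each descendant clone adds private events at Poisson rates. SCNA events are
non-overlapping segments in states DEL(1), homozygous DEL(0, focal), LOH(2;0),
AMP(3;2+1) or AMP(4;3+1); methylation events shift a probe block toward 1 by
`beta + delta(1-beta)` or toward 0 by `beta(1-delta)`, which keeps expected
betas inside [0, 1] for any baseline. Samples draw a clone uniformly
(exchangeable by default; an option correlates `k` with tree divergence to
study confounding), a purity in [0.6, 0.9], and observe:

* BAF centered at `(pi*nB + (1-pi)) / (pi*CN + 2(1-pi))` with random allele
  orientation, Gaussian noise sd 0.03, clipped to [0, 1]; homozygous probes
  sit at 0/1 and carry no allelic signal.
* LRR centered at `gamma * log2((pi*CN + 2(1-pi))/2)`, noise sd 0.15.
* Beta as the purity mixture plus noise sd 0.02.

Defaults emulate the conditions of multi-region lung adenocarcinoma studies:
2–11 samples per patient, purity 0.6–0.9, and clone counts (1–7) and
private-branch event loads calibrated so the cohort's true SCNA APITH
distribution matches values observed in such cohorts (simulated mean 0.18,
sd 0.12, including zero-ITH single-clone tumors). The probe grid defaults to 20,000
probes (not a full array); APITH is a proportion and scale-free in probe
count, so tests use 4,000–8,000-probe grids for speed — the methods are
identical at every scale. Survival times are exponential under a proportional
hazards model whose linear predictor contains the *true* APITH (per reference
sd 0.153) plus stage, age and smoking effects; censoring is independent
(administrative at 120 months plus uniform dropout).

For large replicated survival studies the package uses a distance-level
generator: `mu_p ~ Gamma(mean 0.184, sd 0.153)` across patients and
`d_ij = max(0, mu_p + a_i + a_j + e_ij)` with `sd(a) = 0.03`,
`sd(e) = 0.05` — exactly the exchangeable model the variance machinery
assumes, with measurement error that shrinks in `k` so weighting matters.
What the simulator does **not** emulate: real genome coordinates, probe-level
correlation structure of arrays, subclonal mixtures within one sample
(samples are pure draws of one clone plus normal contamination), SNV
read-level data, and informative censoring. Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to every artifact of real arrays.

## Numerical choices and degenerate inputs

* Distance matrices must be symmetric, nonnegative, zero-diagonal; NA probes
  are dropped pairwise with the denominator reduced.
* APITH requires `k >= 2`; public/private labels require `>= 2` samples;
  clustering requires `>= 3`; trees require `>= 3` leaves.
* Variance estimates are clamped at 0; weights are normalized to mean 1 and
  floored at 1e-12 variance.
* Negative OLS branch lengths are clamped to 0; NNI stops at the first pass
  with no improvement (cap 20 rounds).
* The somatic-variant filter is strict/inclusive exactly as stated: alt > 3,
  depth > 2 in both tissues, VAF >= 0.1.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale by design:
4,000–20,000-probe grids, 25–300-patient cohorts, 200–2,000 simulation
replicates. These sizes were chosen so the full suite completes on a single
CPU while keeping Monte-Carlo error well inside the asserted tolerances.
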