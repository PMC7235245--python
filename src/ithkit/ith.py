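"""The average pairwise ITH index (APITH) and its variance model.

For a patient with k multi-region tumor samples and pairwise distances d_ij,

    APITH = 2 / (k(k-1)) * sum_{i<j} d_ij

i.e. the mean distance over all sample pairs. Its expectation does not depend
on k (it is a U-statistic of degree 2 under within-patient exchangeability),
unlike the "naive" ITH index (fraction of the genome disrupted by SCNAs not
shared by all samples), which grows with k.

The variance of APITH does depend on k. Writing sigma2_d = Var(d_ij) and
c = Cov(d_ij, d_il) for two pairs sharing one sample, the U-statistic
decomposition over m = k(k-1)/2 pairs gives

    Var(APITH | k) = sigma2_d / m + 4 (k-2) c / (k (k-1)).

(sigma2_d, c) are estimated by pooled method of moments from within-patient
centered distances across the cohort, and inverse-variance weights derived
from the formula feed the weighted survival models in :mod:`ithkit.assoc`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import STATUS_NEUTRAL
from .scna import CopyNumberProfile

__all__ = [
    "PairwiseDistances",
    "ApithResult",
    "VarianceModel",
    "scna_distance",
    "methylation_distance",
    "scna_distance_matrix",
    "methylation_distance_matrix",
    "apith",
    "naive_ith",
    "estimate_variance_model",
    "apith_variance",
    "apith_jackknife_variance",
    "apith_weights",
    "region_apith",
    "classify_public_private",
    "filter_somatic_variants",
]


@dataclass
class PairwiseDistances:
    """Symmetric pairwise distance matrix over one patient's samples."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "scna_proportion"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def pairs(self) -> np.ndarray:
        iu = np.triu_indices(self.k, 1)
        return self.values[iu]


@dataclass
class ApithResult:
    patient_id: str
    k: int
    apith: float
    metric: str
    variance: float = np.nan
    weight: float = np.nan


@dataclass
class VarianceModel:
    """Second-moment structure of a single pairwise distance.

    ``sigma2_d`` is Var(d_ij); ``c`` is Cov(d_ij, d_il) for pairs sharing one
    sample (pairs sharing no sample are uncorrelated under exchangeability).
    """

    sigma2_d: float
    c: float
    method: str = "method_of_moments"

    def __post_init__(self) -> None:
        if self.sigma2_d < 0:
            raise ValueError("sigma2_d must be >= 0")
        if abs(self.c) > self.sigma2_d + 1e-12:
            raise ValueError("|c| cannot exceed sigma2_d")


# ---------------------------------------------------------------------------
# distances


def _resolve_subset(n: int, subset) -> np.ndarray:
    if subset is None:
        return np.arange(n)
    subset = np.asarray(subset)
    if subset.dtype == bool:
        return np.flatnonzero(subset)
    return subset


def scna_distance(
    p1: CopyNumberProfile, p2: CopyNumberProfile, probe_subset=None
) -> float:
    """Proportion of probes with different 4-level copy-number status.

    NA status (coded < 0) in either profile is dropped pairwise, reducing the
    denominator.
    """
    if len(p1.status) != len(p2.status):
        raise ValueError("profiles are on different probe sets")
    idx = _resolve_subset(len(p1.status), probe_subset)
    a, b = p1.status[idx], p2.status[idx]
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no probes in common after NA removal")
    return float(np.mean(a[ok] != b[ok]))


def methylation_distance(
    b1: np.ndarray, b2: np.ndarray, probe_subset=None, scaled: bool = False
) -> float:
    """Euclidean distance between beta vectors over a probe subset.

    ``scaled=True`` divides by sqrt(p) (root-mean-square difference), making
    distances comparable across genomic regions with different probe counts.
    """
    b1 = np.asarray(b1, float)
    b2 = np.asarray(b2, float)
    if b1.shape != b2.shape:
        raise ValueError("beta vectors are on different probe sets")
    idx = _resolve_subset(b1.size, probe_subset)
    if idx.size == 0:
        raise ValueError("empty probe subset")
    x, y = b1[idx], b2[idx]
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("no probes in common after NA removal")
    diff = x[ok] - y[ok]
    d = float(np.sqrt(np.sum(diff**2)))
    return d / np.sqrt(ok.sum()) if scaled else d


def scna_distance_matrix(
    profiles: list[CopyNumberProfile], probe_subset=None
) -> PairwiseDistances:
    k = len(profiles)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = scna_distance(profiles[i], profiles[j], probe_subset)
    return PairwiseDistances([p.sample_id for p in profiles], d, "scna_proportion")


def methylation_distance_matrix(
    beta: pd.DataFrame, probe_subset=None, scaled: bool = False
) -> PairwiseDistances:
    """Pairwise methylation distances for a probes-by-samples beta matrix."""
    ids = list(beta.columns)
    k = len(ids)
    mat = beta.to_numpy()
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = methylation_distance(
                mat[:, i], mat[:, j], probe_subset, scaled=scaled
            )
    metric = "methylation_rms" if scaled else "methylation_euclidean"
    return PairwiseDistances(ids, d, metric)


# ---------------------------------------------------------------------------
# the index


def apith(d: PairwiseDistances | np.ndarray) -> float:
    """Average pairwise ITH: mean of the k(k-1)/2 upper-triangle distances."""
    values = d.values if isinstance(d, PairwiseDistances) else np.asarray(d, float)
    k = values.shape[0]
    if k < 2:
        raise ValueError("APITH undefined for fewer than 2 samples")
    iu = np.triu_indices(k, 1)
    return float(values[iu].mean())


def naive_ith(
    profiles: list[CopyNumberProfile], denominator: str = "genome"
) -> float:
    """Fraction of the genome disrupted by private SCNAs.

    A probe counts as private when it is non-NEUTRAL in at least one sample
    but does not carry an identical non-NEUTRAL status in all samples. With
    ``denominator="genome"`` (default) the fraction is over all probes; with
    ``"disrupted"`` it is over probes non-NEUTRAL in at least one sample.
    """
    if len(profiles) < 2:
        raise ValueError("naive ITH requires >= 2 samples")
    status = np.vstack([p.status for p in profiles])
    disrupted = (status != STATUS_NEUTRAL).any(axis=0)
    shared = (status == status[0]).all(axis=0) & (status[0] != STATUS_NEUTRAL)
    private = disrupted & ~shared
    if denominator == "genome":
        return float(private.mean())
    if denominator == "disrupted":
        total = disrupted.sum()
        return float(private.sum() / total) if total else 0.0
    raise ValueError("denominator must be 'genome' or 'disrupted'")


# ---------------------------------------------------------------------------
# variance model


def _moment_coefficients(k: int) -> tuple[float, float, float, float]:
    """Coefficients of (sigma_a^2, sigma_e^2) in E[S1] and E[S2].

    Under d_ij = mu + a_i + a_j + e_ij with Var(a) = sigma_a^2,
    Var(e) = sigma_e^2, and r_ij = d_ij - mean(d):

        E[S1] = E[sum r_ij^2]            = (k-1)(k-2) sa2 + (m-1) se2
        E[S2] = E[sum_{share} r_ij r_il] = N_s (k-4)/k sa2 - (k-2) se2

    with m = k(k-1)/2 pairs and N_s = k(k-1)(k-2)/2 unordered pair-of-pairs
    sharing exactly one sample.
    """
    m = k * (k - 1) / 2
    n_s = k * (k - 1) * (k - 2) / 2
    a1 = (k - 1) * (k - 2)
    b1 = m - 1
    a2 = n_s * (k - 4) / k
    b2 = -(k - 2)
    return a1, b1, a2, b2


def _patient_moments(d: np.ndarray) -> tuple[float, float, int]:
    """Observed S1, S2 for one patient's distance matrix."""
    k = d.shape[0]
    iu = np.triu_indices(k, 1)
    vals = d[iu]
    r = vals - vals.mean()
    rmat = np.zeros((k, k))
    rmat[iu] = r
    rmat = rmat + rmat.T
    s1 = float(np.sum(r**2))
    # sum over unordered pair-of-pairs sharing exactly one sample:
    # sum_i (row_i sum)^2 counts, for each shared sample i, 2*sum_{j<l} r_ij r_il
    # plus the diagonal sum_j r_ij^2 (= 2*S1 over all i)
    row_sums = rmat.sum(axis=1)
    s2 = float((np.sum(row_sums**2) - 2.0 * s1) / 2.0)
    return s1, s2, k


def estimate_variance_model(
    distance_matrices: list[np.ndarray | PairwiseDistances],
) -> VarianceModel:
    """Pooled method-of-moments estimate of (sigma2_d, c) across patients.

    Within-patient centered sums of squares (S1) and shared-sample cross
    products (S2) are pooled and solved against their expectations. Patients
    with k = 2 contribute nothing (their single residual is identically 0);
    separating the shared-sample covariance from pair noise requires at least
    one patient with k >= 4 (at k = 3 the two moment equations are collinear
    because residuals sum to zero). When no such patient exists, c is set to 0
    with a warning and sigma2_d falls back to the pooled variance of all
    distances around their patient means.
    """
    mats = [
        d.values if isinstance(d, PairwiseDistances) else np.asarray(d, float)
        for d in distance_matrices
    ]
    A = np.zeros((2, 2))
    b = np.zeros(2)
    informative = False
    for d in mats:
        k = d.shape[0]
        if k < 3:
            continue
        if k >= 4:
            informative = True
        s1, s2, _ = _patient_moments(d)
        a1, b1, a2, b2 = _moment_coefficients(k)
        A[0] += (a1, b1)
        A[1] += (a2, b2)
        b += (s1, s2)

    if not informative:
        warnings.warn(
            "no patient with k >= 4: shared-sample covariance c is not "
            "identifiable; falling back to c = 0"
        )
        pooled = []
        for d in mats:
            k = d.shape[0]
            if k < 2:
                continue
            iu = np.triu_indices(k, 1)
            pooled.append(d[iu] - d[iu].mean())
        allr = np.concatenate(pooled) if pooled else np.array([0.0])
        sigma2 = float(np.var(allr, ddof=0)) if allr.size > 1 else 0.0
        return VarianceModel(sigma2_d=max(sigma2, 1e-12), c=0.0, method="fallback_c0")

    sa2, se2 = np.linalg.solve(A, b)
    sa2 = max(float(sa2), 0.0)
    se2 = max(float(se2), 0.0)
    sigma2_d = 2.0 * sa2 + se2
    if sigma2_d <= 0:
        sigma2_d, sa2 = 1e-12, 0.0
    return VarianceModel(sigma2_d=sigma2_d, c=sa2)


def apith_variance(k: int, model: VarianceModel) -> float:
    """Var(APITH | k) from the U-statistic decomposition over k(k-1)/2 pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    m = k * (k - 1) / 2
    return model.sigma2_d / m + 4.0 * (k - 2) * model.c / (k * (k - 1))


def apith_jackknife_variance(
    d: PairwiseDistances | np.ndarray, corrected: bool = True
) -> float:
    """Delete-one-sample jackknife variance of APITH.

    The classic Tukey value ``(k-1)/k * sum (APITH_(-i) - mean)^2``
    (``corrected=False``) is upward-biased for a pairwise average: under the
    exchangeable model d_ij = mu + a_i + a_j + e_ij its expectation is
    ``4 sa2/k + 4 se2/(k(k-2))`` while the true variance is
    ``4 sa2/k + 2 se2/(k(k-1))`` — the pair-noise term is inflated by
    2(k-1)/(k-2). The default corrects this by solving the jackknife value
    together with the within-patient centered sum of squares for (sa2, se2)
    and evaluating the exact variance; the corrected estimate is unbiased and
    serves as a model-free cross-check of :func:`apith_variance`.
    """
    values = d.values if isinstance(d, PairwiseDistances) else np.asarray(d, float)
    k = values.shape[0]
    if k < 3:
        raise ValueError("jackknife needs k >= 3")
    loo = []
    for i in range(k):
        keep = np.delete(np.arange(k), i)
        loo.append(apith(values[np.ix_(keep, keep)]))
    loo = np.asarray(loo)
    v_jack = float((k - 1) / k * np.sum((loo - loo.mean()) ** 2))
    if not corrected:
        return v_jack
    if k == 3:
        # with three samples the jackknife and the centered sum of squares
        # carry the same single moment (residuals sum to zero), so the
        # pair-noise inflation cannot be separated; return the conservative
        # uncorrected value
        warnings.warn("k=3: jackknife bias correction unidentifiable; returning Tukey value")
        return v_jack
    m = k * (k - 1) / 2
    iu = np.triu_indices(k, 1)
    r = values[iu] - values[iu].mean()
    s1 = float(np.sum(r**2))
    # E[v_jack] = 4 sa2/k + 4 se2/(k(k-2)); E[S1] = (k-1)(k-2) sa2 + (m-1) se2
    A = np.array(
        [[4.0 / k, 4.0 / (k * (k - 2))], [(k - 1) * (k - 2), m - 1]]
    )
    sa2, se2 = np.linalg.solve(A, np.array([v_jack, s1]))
    # no clamping: per-patient estimates are noisy but unbiased in the mean
    return float(4.0 * sa2 / k + 2.0 * se2 / (k * (k - 1)))


def apith_weights(
    results: list[ApithResult], model: VarianceModel
) -> list[ApithResult]:
    """Attach Var(APITH | k) and inverse-variance weights (normalized to mean 1)."""
    variances = np.array([apith_variance(r.k, model) for r in results])
    variances = np.maximum(variances, 1e-12)
    w = 1.0 / variances
    w = w / w.mean()
    out = []
    for r, v, wi in zip(results, variances, w):
        out.append(
            ApithResult(r.patient_id, r.k, r.apith, r.metric, variance=float(v), weight=float(wi))
        )
    return out


# ---------------------------------------------------------------------------
# region-restricted methylation ITH


def region_apith(
    beta_by_patient: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    region_col: str,
    top_fraction: float = 0.10,
    min_probes: int = 10,
) -> pd.DataFrame:
    """Per-patient methylation APITH within each genomic region.

    ``region_col`` selects the annotation vocabulary ("cpg_context",
    "gene_context" or "driver_class"). Within each region the top
    ``top_fraction`` most variable probes (variance pooled over all tumor
    samples) are kept, pairwise root-mean-square distances computed, and
    APITH taken per patient. Regions with fewer than ``min_probes`` probes
    are skipped with a warning.
    """
    ann = annotation.reset_index(drop=True)
    all_beta = pd.concat(beta_by_patient.values(), axis=1)
    rows = []
    for region, sub in ann.groupby(region_col, sort=True):
        idx = sub.index.to_numpy()
        if idx.size < min_probes:
            warnings.warn(f"region {region!r} has <{min_probes} probes; skipped")
            continue
        region_beta = all_beta.iloc[idx]
        select_idx = _top_variable_positions(region_beta, top_fraction)
        probe_idx = idx[select_idx]
        for pid, beta in beta_by_patient.items():
            if beta.shape[1] < 2:
                continue
            dm = methylation_distance_matrix(beta, probe_subset=probe_idx, scaled=True)
            rows.append((pid, region, dm.k, apith(dm)))
    return pd.DataFrame(rows, columns=["patient_id", "region", "k", "apith"])


def _top_variable_positions(beta: pd.DataFrame, fraction: float) -> np.ndarray:
    var = beta.var(axis=1, ddof=1).to_numpy()
    n = max(1, int(round(fraction * len(var))))
    order = np.lexsort((np.arange(len(var)), -var))
    return np.sort(order[:n])


def region_apith_ttest(
    table: pd.DataFrame, region_a: str, region_b: str
) -> tuple[float, float]:
    """Unpaired two-sided t-test of per-patient APITH between two regions."""
    a = table.loc[table["region"] == region_a, "apith"]
    b = table.loc[table["region"] == region_b, "apith"]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# public/private events and somatic-variant filtering


def classify_public_private(events: pd.DataFrame) -> pd.DataFrame:
    """Label events public (present in all of a patient's samples) or private.

    ``events`` needs columns patient_id, sample_id, event_id, present (0/1).
    Patients with a single sample are rejected (the labels are undefined).
    """
    required = {"patient_id", "sample_id", "event_id", "present"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    rows = []
    for pid, sub in events.groupby("patient_id", sort=True):
        n_samples = sub["sample_id"].nunique()
        if n_samples < 2:
            raise ValueError(f"patient {pid} has one sample; public/private undefined")
        for eid, esub in sub.groupby("event_id", sort=True):
            carriers = esub.loc[esub["present"] == 1, "sample_id"].nunique()
            if carriers == 0:
                continue
            label = "public" if carriers == n_samples else "private"
            rows.append((pid, eid, carriers, n_samples, label))
    return pd.DataFrame(
        rows, columns=["patient_id", "event_id", "n_carriers", "n_samples", "label"]
    )


def filter_somatic_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep variants with alt count > 3, coverage > 2 in both tumor and
    normal, and VAF >= 0.1 (thresholds strict/inclusive exactly as stated)."""
    required = {"alt_count", "depth_tumor", "depth_normal", "vaf"}
    if not required.issubset(variants.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    keep = (
        (variants["alt_count"] > 3)
        & (variants["depth_tumor"] > 2)
        & (variants["depth_normal"] > 2)
        & (variants["vaf"] >= 0.1)
    )
    return variants.loc[keep].reset_index(drop=True)
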