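"""Purity-adjusted methylation processing.

Observed tumor-sample betas are modelled as a purity-weighted linear mixture
of tumor-cell and normal-tissue methylation; :func:`adjust_purity` inverts the
mixture so downstream analyses work on tumor-cell betas. The module also
selects most-variable probe sets, classifies samples into CIMP-H / CIMP-L by
hierarchical clustering of promoter-island probes, and calls candidate driver
methylation events from tumor-vs-normal beta differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .constants import PROMOTER_CONTEXTS

__all__ = [
    "MethylationProfile",
    "adjust_purity",
    "adjust_purity_matrix",
    "impute_normal_reference",
    "select_top_variable",
    "promoter_island_probes",
    "call_cimp",
    "call_driver_methylation",
]


@dataclass
class MethylationProfile:
    """Per-probe beta values with sample purity."""

    sample_id: str
    beta: np.ndarray
    purity: float = 1.0
    tissue: str = "tumor"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.tissue == "tumor" and not 0 < self.purity <= 1:
            raise ValueError("tumor purity must lie in (0, 1]")


def adjust_purity(beta_obs: np.ndarray, beta_normal: np.ndarray, purity: float) -> np.ndarray:
    """Recover tumor-cell betas from the observed tumor/normal mixture.

    Inverts ``beta_obs = purity*beta_tumor + (1-purity)*beta_normal``:

        beta_tumor = (beta_obs - (1-purity)*beta_normal) / purity

    clipped to [0, 1]. With ``purity=1`` this is the identity.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    beta_obs = np.asarray(beta_obs, float)
    beta_normal = np.asarray(beta_normal, float)
    if beta_obs.shape != beta_normal.shape:
        raise ValueError("observed and normal beta vectors must align")
    return np.clip((beta_obs - (1.0 - purity) * beta_normal) / purity, 0.0, 1.0)


def impute_normal_reference(normal_betas: np.ndarray) -> np.ndarray:
    """Per-probe mean over all normal samples (columns = samples), used when a
    tumor lacks its matched normal."""
    normal_betas = np.atleast_2d(np.asarray(normal_betas, float))
    return np.nanmean(normal_betas, axis=0)


def adjust_purity_matrix(
    beta: pd.DataFrame,
    purity: pd.Series,
    beta_normal_ref: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Column-wise :func:`adjust_purity` for a probes-by-samples beta matrix."""
    normal = np.asarray(beta_normal_ref, float)
    out = {}
    for sample in beta.columns:
        out[sample] = adjust_purity(beta[sample].to_numpy(), normal, float(purity[sample]))
    return pd.DataFrame(out, index=beta.index)


def select_top_variable(beta_matrix: pd.DataFrame, n: int | float) -> pd.Index:
    """Probes ranked by across-sample variance; return the top ``n``.

    ``n`` may be an integer count or a fraction in (0, 1); ties are broken by
    probe id order. Requires at least two samples.
    """
    if beta_matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to rank variances")
    if 0 < n < 1:
        n = max(1, int(round(n * len(beta_matrix))))
    n = int(n)
    if n > len(beta_matrix):
        warnings.warn("n exceeds probe count; returning all probes")
        n = len(beta_matrix)
    var = beta_matrix.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "pid": beta_matrix.index}).sort_values(
        ["var", "pid"], ascending=[False, True], kind="mergesort"
    )
    return pd.Index(order.index[:n])


def promoter_island_probes(annotation: pd.DataFrame) -> np.ndarray:
    """Boolean mask of probes in CpG islands within gene promoter regions."""
    return (
        (annotation["cpg_context"] == "island")
        & annotation["gene_context"].isin(PROMOTER_CONTEXTS)
    ).to_numpy()


def call_cimp(
    beta_tumor: pd.DataFrame,
    beta_normal: pd.DataFrame,
    annotation: pd.DataFrame,
    n_probes: int = 5000,
    min_delta: float = 0.05,
    linkage_method: str = "average",
) -> pd.Series:
    """CIMP-H / CIMP-L labels per tumor sample.

    Hierarchical clustering (average linkage, Euclidean) of tumor samples on
    the ``n_probes`` most variable promoter CpG-island probes, cut into two
    groups. A group is CIMP-H when its mean promoter-island beta exceeds the
    normal-tissue mean by at least ``min_delta``; otherwise CIMP-L. Labels may
    legitimately differ between samples of the same tumor.
    """
    if beta_tumor.shape[1] < 3:
        raise ValueError("clustering needs >= 3 tumor samples")
    if beta_normal.shape[1] < 1:
        raise ValueError("at least one normal sample required for orientation")
    mask = promoter_island_probes(annotation)
    sub = beta_tumor.loc[mask]
    sub_norm = beta_normal.loc[mask]
    top = select_top_variable(sub, min(n_probes, len(sub)))
    x = sub.loc[top].to_numpy().T  # samples x probes
    z = linkage(x, method=linkage_method, metric="euclidean")
    groups = fcluster(z, t=2, criterion="maxclust")
    normal_mean = float(sub_norm.loc[top].to_numpy().mean())
    labels = {}
    for g in np.unique(groups):
        gmean = float(x[groups == g].mean())
        labels[g] = "CIMP-H" if gmean - normal_mean >= min_delta else "CIMP-L"
    return pd.Series(
        [labels[g] for g in groups], index=beta_tumor.columns, name="cimp"
    )


def call_driver_methylation(
    beta_tumor: pd.DataFrame,
    beta_normal_ref: np.ndarray | pd.Series,
    annotation: pd.DataFrame,
    cutoff: float = 0.3,
) -> pd.DataFrame:
    """Candidate driver methylation events per driver gene per sample.

    For each oncogene/TSG, betas are averaged over its promoter CpG-island
    probes; an event is called when |mean_tumor - mean_normal| >= ``cutoff``
    (0.3 by default), with the direction (hyper/hypo) recorded.
    """
    ann = annotation.reset_index(drop=True)
    mask = promoter_island_probes(ann)
    drivers = ann[mask & ann["driver_class"].isin(["oncogene", "TSG"])]
    normal = np.asarray(beta_normal_ref, float)
    rows = []
    for gene, sub in drivers.groupby("gene", sort=True):
        idx = sub.index.to_numpy()
        if idx.size == 0:
            warnings.warn(f"gene {gene} has no promoter-island probes; skipped")
            continue
        norm_mean = float(normal[idx].mean())
        for sample in beta_tumor.columns:
            tumor_mean = float(beta_tumor[sample].to_numpy()[idx].mean())
            delta = tumor_mean - norm_mean
            if abs(delta) >= cutoff:
                rows.append(
                    (
                        sample,
                        gene,
                        "hyper" if delta > 0 else "hypo",
                        round(delta, 6),
                    )
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "direction", "delta_beta"])
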