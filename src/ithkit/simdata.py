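"""Synthetic multi-region tumor cohorts with known clonal ground truth.

Each patient is generated from a random rooted clone tree. The founder clone
carries "public" events (present in every tumor sample); descendant clones add
private somatic copy-number alterations (SCNAs) and DNA-methylation shifts.
Tumor samples are purity-weighted mixtures of one tumor clone and normal
tissue, observed through SNP-array signals (B-allele frequency and log R
ratio) and 450K-style methylation beta values. Survival times follow a
proportional-hazards model whose linear predictor includes the patient's true
average pairwise ITH (APITH), so that association machinery downstream can be
validated against a known hazard ratio.

Two generators are provided:

* probe-level (:func:`simulate_clone_tree`, :func:`simulate_patient`,
  :func:`simulate_cohort`) — full BAF/LRR/beta tracks, used to test SCNA
  calling, methylation processing and phylogenies;
* distance-level (:func:`simulate_apith_cohort`) — draws pairwise distances
  directly from the exchangeable model d_ij = mu + a_i + a_j + e_ij, which is
  the exact sampling model under which the APITH variance formula holds; used
  for large survival-association simulations where probe tracks would be
  wasteful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm as _norm

from .constants import STATUS_AMP, STATUS_DEL, STATUS_LOH, STATUS_NEUTRAL

__all__ = [
    "SimConfig",
    "ScnaEvent",
    "MethEvent",
    "CloneTree",
    "PatientSimulation",
    "Cohort",
    "make_annotation",
    "normal_beta_profile",
    "simulate_clone_tree",
    "clone_scna_profile",
    "clone_beta_profile",
    "simulate_patient",
    "simulate_cohort",
    "simulate_apith_cohort",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """All knobs of the cohort generator; ``seed`` fixes the full stream.

    Defaults emulate the study conditions of a multi-region lung
    adenocarcinoma cohort: 2-11 tumor samples per patient, SNP-array plus
    450K-style methylation readout, tumor purity 0.6-0.9, and a hazard that
    increases with true SCNA APITH.
    """

    n_patients: int = 80
    k_min: int = 2
    k_max: int = 11
    n_probes: int = 20_000
    n_chromosomes: int = 22
    het_fraction: float = 0.33

    # clone tree / event process; defaults calibrated so the cohort's true
    # SCNA APITH distribution lands near the emulated study (mean ~0.18)
    n_clones_min: int = 1
    n_clones_max: int = 7
    founder_scna_events: int = 4
    branch_scna_rate: float = 7.0
    founder_meth_events: int = 8
    branch_meth_rate: float = 4.0
    seg_len_min: int = 300
    seg_len_max: int = 2000
    meth_event_len: int = 40
    meth_delta_min: float = 0.2
    meth_delta_max: float = 0.5

    # assay noise and purity
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    beta_noise_sd: float = 0.02
    purity_min: float = 0.6
    purity_max: float = 0.9
    lrr_gamma: float = 0.55

    # outcome model
    baseline_hazard: float = 0.012  # events per month
    log_hr_per_sd: float = float(np.log(1.5))
    apith_sd_ref: float = 0.153  # reference spread used to scale the effect
    followup_months: float = 120.0
    dropout_max_months: float = 240.0
    correlate_k_with_ith: float = 0.0  # >0 links large k to high true APITH

    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if not 0 < self.purity_min <= self.purity_max <= 1:
            raise ValueError("purity range must satisfy 0 < min <= max <= 1")
        for name in ("branch_scna_rate", "branch_meth_rate", "baseline_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# annotation


def make_annotation(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Build a synthetic probe annotation table.

    Probes tile ``n_chromosomes`` chromosomes with sorted positions. Genes are
    laid down as blocks of probes with promoter / body / 3'UTR structure
    separated by intergenic gaps; ~2% of genes are labelled oncogenes and ~2%
    tumor suppressors. CpG context is biased so promoters are island-rich and
    gene bodies open-sea-rich, mirroring 450K design.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_probes
    per_chrom = n // config.n_chromosomes
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    start = 0
    for c in range(config.n_chromosomes):
        stop = n if c == config.n_chromosomes - 1 else start + per_chrom
        chrom[start:stop] = f"chr{c + 1}"
        pos[start:stop] = 10_000 + 5_000 * np.arange(stop - start)
        start = stop

    gene_context = np.full(n, "intergenic", dtype=object)
    gene = np.full(n, "", dtype=object)
    driver = np.full(n, "other", dtype=object)
    block = ["TSS1500", "TSS1500", "TSS200", "TSS200", "5'UTR", "first-exon"] + [
        "body"
    ] * 7 + ["3'UTR", "3'UTR"]
    gid = 0
    i = 0
    while i < n:
        gid += 1
        name = f"GENE{gid:05d}"
        glen = min(len(block), n - i)
        gene_context[i : i + glen] = block[:glen]
        gene[i : i + glen] = name
        r = rng.random()
        if r < 0.02:
            driver[i : i + glen] = "oncogene"
        elif r < 0.04:
            driver[i : i + glen] = "TSG"
        i += glen + int(rng.integers(3, 8))  # intergenic gap

    # CpG context, promoter-biased islands
    cpg = np.empty(n, dtype=object)
    u = rng.random(n)
    promoter = np.isin(gene_context, ["TSS1500", "TSS200", "5'UTR", "first-exon"])
    p_island = np.where(promoter, 0.65, 0.18)
    p_shore = 0.2
    p_shelf = 0.1
    cpg[u < p_island] = "island"
    cpg[(u >= p_island) & (u < p_island + p_shore)] = "shore"
    cpg[(u >= p_island + p_shore) & (u < p_island + p_shore + p_shelf)] = "shelf"
    cpg[u >= p_island + p_shore + p_shelf] = "open-sea"
    orientation = np.where(
        np.isin(cpg, ["shore", "shelf"]), rng.choice(["N", "S"], size=n), ""
    )

    is_het = rng.random(n) < config.het_fraction
    return pd.DataFrame(
        {
            "probe_id": [f"P{j:06d}" for j in range(n)],
            "chrom": chrom,
            "pos": pos,
            "is_het": is_het,
            "cpg_context": cpg,
            "cpg_orientation": orientation,
            "gene_context": gene_context,
            "gene": gene,
            "driver_class": driver,
        }
    )


def normal_beta_profile(annotation: pd.DataFrame, seed: int) -> np.ndarray:
    """Baseline (normal tissue) beta per probe: islands unmethylated,
    open-sea methylated, shores/shelves intermediate."""
    rng = np.random.default_rng(seed)
    n = len(annotation)
    beta = np.empty(n)
    ctx = annotation["cpg_context"].to_numpy()
    masks = {
        "island": rng.beta(2.0, 18.0, n),
        "shore": rng.beta(5.0, 7.0, n),
        "shelf": rng.beta(6.0, 5.0, n),
        "open-sea": rng.beta(12.0, 4.0, n),
    }
    for name, draw in masks.items():
        sel = ctx == name
        beta[sel] = draw[sel]
    return beta


# ---------------------------------------------------------------------------
# clone trees


@dataclass(frozen=True)
class ScnaEvent:
    """One copy-number event on a contiguous probe range [start, end)."""

    start: int
    end: int
    status: int  # STATUS_* code
    cn: int  # total copy number
    n_a: int  # major-allele copies
    n_b: int  # minor-allele copies


@dataclass(frozen=True)
class MethEvent:
    """A methylation shift on a contiguous probe block.

    ``hyper`` events move betas toward 1 by ``beta' = beta + delta*(1-beta)``;
    hypo events toward 0 by ``beta' = beta*(1-delta)``. Both keep expected
    betas strictly inside [0, 1] for any baseline.
    """

    start: int
    end: int
    delta: float
    hyper: bool


@dataclass
class CloneTree:
    """Rooted clone tree; clone 0 is the founder (its events are public)."""

    clones: list[int]
    parent: dict[int, int | None]
    scna_events: dict[int, list[ScnaEvent]]
    meth_events: dict[int, list[MethEvent]]
    n_probes: int

    def path_to_root(self, clone: int) -> list[int]:
        path = [clone]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def validate(self) -> None:
        if 0 not in self.clones:
            raise ValueError("founder clone 0 missing")
        for c in self.clones:
            if c != 0 and self.parent[c] not in self.clones:
                raise ValueError(f"clone {c} has unknown parent")
            seen = set()
            node: int | None = c
            while node is not None:
                if node in seen:
                    raise ValueError("cycle in clone tree")
                seen.add(node)
                node = self.parent[node]
        for events in self.scna_events.values():
            for ev in events:
                if not (0 <= ev.start < ev.end <= self.n_probes):
                    raise ValueError("event outside probe range")
        for events in self.meth_events.values():
            for ev in events:
                if not (0 <= ev.start < ev.end <= self.n_probes):
                    raise ValueError("event outside probe range")
                if not 0 < ev.delta < 1:
                    raise ValueError("delta must lie in (0, 1)")


_SCNA_STATES = [
    # (status, cn, nA, nB, probability)
    (STATUS_DEL, 1, 1, 0, 0.30),
    (STATUS_DEL, 0, 0, 0, 0.05),  # homozygous deletion
    (STATUS_LOH, 2, 2, 0, 0.30),
    (STATUS_AMP, 3, 2, 1, 0.20),
    (STATUS_AMP, 4, 3, 1, 0.15),
]


def _draw_scna_event(rng: np.random.Generator, config: SimConfig, occupied: np.ndarray) -> ScnaEvent | None:
    """Draw one non-overlapping SCNA segment; None if no room after retries."""
    probs = np.array([s[-1] for s in _SCNA_STATES])
    for _ in range(200):
        status, cn, na, nb, _ = _SCNA_STATES[rng.choice(len(_SCNA_STATES), p=probs)]
        if cn == 0:
            # homozygous deletions are focal
            length = int(rng.integers(60, 121))
        else:
            length = int(rng.integers(config.seg_len_min, config.seg_len_max + 1))
        start = int(rng.integers(0, max(1, config.n_probes - length)))
        end = min(start + length, config.n_probes)
        if occupied[start:end].any():
            continue
        occupied[start:end] = True
        return ScnaEvent(start, end, status, cn, na, nb)
    return None


def _draw_meth_event(rng: np.random.Generator, config: SimConfig, occupied: np.ndarray) -> MethEvent | None:
    for _ in range(200):
        length = config.meth_event_len
        start = int(rng.integers(0, max(1, config.n_probes - length)))
        end = min(start + length, config.n_probes)
        if occupied[start:end].any():
            continue
        occupied[start:end] = True
        delta = float(rng.uniform(config.meth_delta_min, config.meth_delta_max))
        return MethEvent(start, end, delta, hyper=bool(rng.random() < 0.5))
    return None


def simulate_clone_tree(n_clones: int, config: SimConfig, seed: int) -> CloneTree:
    """Random rooted clone tree with founder (public) and branch (private) events.

    Each non-founder clone attaches to a uniformly chosen earlier clone and
    draws Poisson-distributed numbers of private SCNA and methylation events.
    Event probe ranges never overlap across the whole tree, so every probe's
    ground-truth state in any clone is determined by a single event.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    clones = list(range(n_clones))
    parent: dict[int, int | None] = {0: None}
    for c in range(1, n_clones):
        parent[c] = int(rng.integers(0, c))

    occupied_scna = np.zeros(config.n_probes, dtype=bool)
    occupied_meth = np.zeros(config.n_probes, dtype=bool)
    scna_events: dict[int, list[ScnaEvent]] = {c: [] for c in clones}
    meth_events: dict[int, list[MethEvent]] = {c: [] for c in clones}

    for c in clones:
        if c == 0:
            n_scna = config.founder_scna_events
            n_meth = config.founder_meth_events
        else:
            n_scna = int(rng.poisson(config.branch_scna_rate))
            n_meth = int(rng.poisson(config.branch_meth_rate))
        for _ in range(n_scna):
            ev = _draw_scna_event(rng, config, occupied_scna)
            if ev is not None:
                scna_events[c].append(ev)
        for _ in range(n_meth):
            ev = _draw_meth_event(rng, config, occupied_meth)
            if ev is not None:
                meth_events[c].append(ev)

    tree = CloneTree(clones, parent, scna_events, meth_events, config.n_probes)
    tree.validate()
    return tree


def clone_scna_profile(tree: CloneTree, clone: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free SCNA state of one clone: (status, cn, nA, nB) per probe."""
    n = tree.n_probes
    status = np.full(n, STATUS_NEUTRAL, dtype=np.int8)
    cn = np.full(n, 2, dtype=np.int16)
    na = np.ones(n, dtype=np.int16)
    nb = np.ones(n, dtype=np.int16)
    for c in tree.path_to_root(clone):
        for ev in tree.scna_events[c]:
            status[ev.start : ev.end] = ev.status
            cn[ev.start : ev.end] = ev.cn
            na[ev.start : ev.end] = ev.n_a
            nb[ev.start : ev.end] = ev.n_b
    return status, cn, na, nb


def clone_beta_profile(tree: CloneTree, clone: int, beta_normal: np.ndarray) -> np.ndarray:
    """Noise-free tumor beta of one clone given the normal baseline."""
    beta = beta_normal.copy()
    for c in tree.path_to_root(clone):
        for ev in tree.meth_events[c]:
            seg = beta[ev.start : ev.end]
            if ev.hyper:
                beta[ev.start : ev.end] = seg + ev.delta * (1.0 - seg)
            else:
                beta[ev.start : ev.end] = seg * (1.0 - ev.delta)
    return beta


# ---------------------------------------------------------------------------
# patients


@dataclass
class PatientSimulation:
    """Ground truth and observed tracks for one simulated patient."""

    patient_id: str
    tree: CloneTree
    sample_ids: list[str]
    clone_of_sample: list[int]
    purity: np.ndarray  # (k,)
    baf: np.ndarray  # (k, n_probes)
    lrr: np.ndarray
    beta_obs: np.ndarray
    beta_normal_obs: np.ndarray  # matched normal methylation, with noise
    true_status: np.ndarray  # (k, n_probes) int8
    true_beta: np.ndarray  # (k, n_probes) clone betas, noise-free
    true_distance: dict[str, np.ndarray]  # metric -> (k, k)
    true_apith: dict[str, float]

    @property
    def k(self) -> int:
        return len(self.sample_ids)


def _true_distances(true_status: np.ndarray, true_beta: np.ndarray) -> dict[str, np.ndarray]:
    k = true_status.shape[0]
    n = true_status.shape[1]
    d_scna = np.zeros((k, k))
    d_meth = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d_scna[i, j] = d_scna[j, i] = np.mean(true_status[i] != true_status[j])
            rms = float(np.sqrt(np.mean((true_beta[i] - true_beta[j]) ** 2)))
            d_meth[i, j] = d_meth[j, i] = rms
    return {"scna_proportion": d_scna, "methylation_rms": d_meth}


def _apith_of(d: np.ndarray) -> float:
    k = d.shape[0]
    iu = np.triu_indices(k, 1)
    return float(d[iu].mean())


def simulate_patient(
    tree: CloneTree,
    k: int,
    config: SimConfig,
    seed: int,
    annotation: pd.DataFrame | None = None,
    beta_normal: np.ndarray | None = None,
    patient_id: str = "PT0001",
) -> PatientSimulation:
    """Simulate ``k`` multi-region tumor samples from one clone tree.

    Each sample is drawn from a single clone (uniform over clones) and mixed
    with normal tissue at purity pi ~ U(purity_min, purity_max):

    * heterozygous-probe BAF centers at ``(pi*nB + (1-pi)) / (pi*cn + 2(1-pi))``
      with random allele orientation (mirrored around 0.5);
    * LRR centers at ``gamma * log2((pi*cn + 2(1-pi)) / 2)``;
    * observed beta = pi*beta_clone + (1-pi)*beta_normal + noise.

    True pairwise distances are recorded from the noise-free clone profiles.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (ITH is undefined from one sample)")
    tree.validate()
    rng = np.random.default_rng(seed)
    if annotation is None:
        annotation = make_annotation(config)
    if beta_normal is None:
        beta_normal = normal_beta_profile(annotation, config.seed + 1)
    n = config.n_probes
    het = annotation["is_het"].to_numpy()

    clone_status = {}
    clone_beta = {}
    for c in tree.clones:
        clone_status[c] = clone_scna_profile(tree, c)
        clone_beta[c] = clone_beta_profile(tree, c, beta_normal)

    clone_of = [int(rng.integers(0, len(tree.clones))) for _ in range(k)]
    purity = rng.uniform(config.purity_min, config.purity_max, size=k)
    if not np.all((purity > 0) & (purity <= 1)):
        raise ValueError("purity must lie in (0, 1]")

    # allele orientation per probe shared across samples (array genotype fixed)
    b_is_minor = rng.random(n) < 0.5
    hom_b = rng.random(n) < 0.5  # homozygous probes split between AA and BB

    baf = np.empty((k, n))
    lrr = np.empty((k, n))
    beta_obs = np.empty((k, n))
    true_status = np.empty((k, n), dtype=np.int8)
    true_beta = np.empty((k, n))

    for s in range(k):
        status, cn, na, nb = clone_status[clone_of[s]]
        pi = purity[s]
        # floor keeps homozygous deletions finite (residual normal/stromal DNA)
        cn_mix = np.maximum(pi * cn + 2.0 * (1.0 - pi), 0.05)
        # heterozygous: one allele is "B"; orientation mirrors BAF around 0.5
        b_copies = np.where(b_is_minor, nb, na)
        baf_mean = (pi * b_copies + (1.0 - pi)) / cn_mix
        baf_s = baf_mean + rng.normal(0.0, config.baf_noise_sd, n)
        # homozygous probes carry no allelic signal
        baf_hom = np.where(hom_b, 1.0, 0.0) + rng.normal(0.0, config.baf_noise_sd, n)
        baf[s] = np.clip(np.where(het, baf_s, baf_hom), 0.0, 1.0)
        lrr[s] = config.lrr_gamma * np.log2(cn_mix / 2.0) + rng.normal(
            0.0, config.lrr_noise_sd, n
        )
        bt = clone_beta[clone_of[s]]
        mixed = pi * bt + (1.0 - pi) * beta_normal
        beta_obs[s] = np.clip(mixed + rng.normal(0.0, config.beta_noise_sd, n), 0.0, 1.0)
        true_status[s] = status
        true_beta[s] = bt

    beta_normal_obs = np.clip(
        beta_normal + rng.normal(0.0, config.beta_noise_sd, n), 0.0, 1.0
    )

    true_distance = _true_distances(true_status, true_beta)
    true_apith = {m: _apith_of(d) for m, d in true_distance.items()}
    sample_ids = [f"{patient_id}_S{s + 1:02d}" for s in range(k)]
    return PatientSimulation(
        patient_id=patient_id,
        tree=tree,
        sample_ids=sample_ids,
        clone_of_sample=clone_of,
        purity=purity,
        baf=baf,
        lrr=lrr,
        beta_obs=beta_obs,
        beta_normal_obs=beta_normal_obs,
        true_status=true_status,
        true_beta=true_beta,
        true_distance=true_distance,
        true_apith=true_apith,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    config: SimConfig
    annotation: pd.DataFrame
    beta_normal: np.ndarray
    patients: list[PatientSimulation]
    clinical: pd.DataFrame


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(65.0, 8.0, n), 1),
            "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.3, 0.3, 0.1]),
            "smoking": rng.choice([0, 1, 2], size=n, p=[0.2, 0.4, 0.4]),
        }
    )


def _survival_from_linpred(
    rng: np.random.Generator, lp: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under proportional hazards + independent censoring."""
    n = lp.shape[0]
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.minimum(
        config.followup_months, rng.uniform(0.0, config.dropout_max_months, n)
    )
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # survival times strictly positive
    return time, event


def simulate_cohort(config: SimConfig) -> Cohort:
    """Full probe-level cohort: per-patient trees, tracks and a clinical table.

    The hazard's linear predictor is
    ``log_hr_per_sd * trueAPITH/apith_sd_ref + 0.015*(age-65) + 0.25*(stage-2)
    + 0.15*smoking`` for overall survival; the metastasis endpoint uses half
    the ITH effect.
    """
    rng = np.random.default_rng(config.seed)
    annotation = make_annotation(config)
    beta_normal = normal_beta_profile(annotation, config.seed + 1)
    patients = []
    for p in range(config.n_patients):
        pid = f"PT{p + 1:04d}"
        n_clones = int(rng.integers(config.n_clones_min, config.n_clones_max + 1))
        tree = simulate_clone_tree(n_clones, config, seed=int(rng.integers(2**31)))
        # expected divergence of the tree (mean pairwise clone distance) drives
        # the optional k<->ITH confounding: a Gaussian-copula blend between an
        # independent draw of k and the tree's divergence rank
        profiles = [clone_scna_profile(tree, c)[0] for c in tree.clones]
        if len(profiles) > 1:
            div = float(
                np.mean(
                    [
                        np.mean(profiles[i] != profiles[j])
                        for i in range(len(profiles))
                        for j in range(i + 1, len(profiles))
                    ]
                )
            )
        else:
            div = 0.0
        rho = config.correlate_k_with_ith
        z = rho * (div / 0.15) + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal()
        u = float(_norm.cdf(z)) if rho > 0 else float(rng.random())
        k = config.k_min + int(u * (config.k_max - config.k_min + 1))
        k = min(k, config.k_max)
        patients.append(
            simulate_patient(
                tree,
                k,
                config,
                seed=int(rng.integers(2**31)),
                annotation=annotation,
                beta_normal=beta_normal,
                patient_id=pid,
            )
        )

    apith_true = np.array([p.true_apith["scna_proportion"] for p in patients])
    cov = _draw_covariates(rng, config.n_patients)
    z = apith_true / config.apith_sd_ref
    lp = (
        config.log_hr_per_sd * z
        + 0.015 * (cov["age"].to_numpy() - 65.0)
        + 0.25 * (cov["stage"].to_numpy() - 2.0)
        + 0.15 * cov["smoking"].to_numpy()
    )
    time, event = _survival_from_linpred(rng, lp, config)
    t_met, met = _survival_from_linpred(rng, 0.5 * lp, config)
    clinical = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "time": np.round(time, 3),
            "event": event,
            "time_metastasis": np.round(t_met, 3),
            "metastasis": met,
            "stage": cov["stage"],
            "age": cov["age"],
            "smoking": cov["smoking"],
            "k": [p.k for p in patients],
            "true_apith_scna": apith_true,
        }
    )
    return Cohort(config, annotation, beta_normal, patients, clinical)


# ---------------------------------------------------------------------------
# distance-level cohorts (for survival-association simulations)


def simulate_apith_cohort(
    n_patients: int = 300,
    k_min: int = 2,
    k_max: int = 8,
    mu_mean: float = 0.184,
    mu_sd: float = 0.153,
    sigma_a: float = 0.03,
    sigma_e: float = 0.05,
    log_hr_per_sd: float = float(np.log(1.5)),
    baseline_hazard: float = 0.012,
    followup_months: float = 120.0,
    dropout_max_months: float = 240.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Cohort drawn directly at the pairwise-distance level.

    For patient p with true ITH level mu_p ~ Gamma(mean ``mu_mean``, sd
    ``mu_sd``), each of k_p exchangeable samples gets a latent effect
    a_i ~ N(0, sigma_a^2) and every pair an independent e_ij ~ N(0, sigma_e^2):

        d_ij = max(0, mu_p + a_i + a_j + e_ij)

    Observed APITH is the mean of the d_ij; the hazard depends on the *true*
    mu_p (per sd = ``mu_sd``), so fitted models face realistic measurement
    error that shrinks with k. Returns the clinical/APITH table and the list
    of per-patient distance matrices (inputs for the variance model).
    """
    rng = np.random.default_rng(seed)
    shape = (mu_mean / mu_sd) ** 2
    scale = mu_sd**2 / mu_mean
    mu = rng.gamma(shape, scale, n_patients)
    ks = rng.integers(k_min, k_max + 1, n_patients)

    apith_obs = np.empty(n_patients)
    dmats: list[np.ndarray] = []
    for p in range(n_patients):
        k = int(ks[p])
        a = rng.normal(0.0, sigma_a, k)
        d = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        e = rng.normal(0.0, sigma_e, len(iu[0]))
        vals = np.maximum(mu[p] + a[iu[0]] + a[iu[1]] + e, 0.0)
        d[iu] = vals
        d = d + d.T
        dmats.append(d)
        apith_obs[p] = vals.mean()

    cov = _draw_covariates(rng, n_patients)
    lp = (
        log_hr_per_sd * mu / mu_sd
        + 0.015 * (cov["age"].to_numpy() - 65.0)
        + 0.25 * (cov["stage"].to_numpy() - 2.0)
        + 0.15 * cov["smoking"].to_numpy()
    )
    cfg = SimConfig(
        baseline_hazard=baseline_hazard,
        followup_months=followup_months,
        dropout_max_months=dropout_max_months,
    )
    time, event = _survival_from_linpred(rng, lp, cfg)
    table = pd.DataFrame(
        {
            "patient_id": [f"PT{p + 1:04d}" for p in range(n_patients)],
            "k": ks,
            "apith": apith_obs,
            "true_apith": mu,
            "time": time,
            "event": event,
            "stage": cov["stage"],
            "age": cov["age"],
            "smoking": cov["smoking"],
        }
    )
    return table, dmats
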