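"""Plain-text readers/writers for the pipeline's tabular formats.

Formats: per-sample probe TSV (probe_id, chrom, pos, LRR, BAF); beta matrix
TSV (rows probes, columns samples); clinical CSV; segments as BED-like TSV;
probe-status matrix TSV (codes 0=DEL, 1=LOH, 2=NEUTRAL, 3=AMP); per-patient
APITH CSV; ground-truth JSON; Newick trees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import STATUS_LABELS
from .scna import CopyNumberProfile, Segment
from .simdata import Cohort, PatientSimulation


def write_probe_tsv(path, annotation: pd.DataFrame, lrr: np.ndarray, baf: np.ndarray) -> None:
    df = annotation[["probe_id", "chrom", "pos"]].copy()
    df["LRR"] = np.round(lrr, 5)
    df["BAF"] = np.round(baf, 5)
    df.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos", "LRR", "BAF"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe TSV needs columns {sorted(required)}")
    return df


def write_beta_tsv(path, beta: pd.DataFrame) -> None:
    beta.round(5).to_csv(path, sep="\t", index_label="probe_id")


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_annotation_tsv(path, annotation: pd.DataFrame) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_tsv(path, segments: list[Segment], annotation: pd.DataFrame) -> None:
    """BED-like: chrom, start, end (0-based half-open genomic), status, CN, p_adj."""
    pos = annotation["pos"].to_numpy()
    rows = []
    for s in segments:
        rows.append(
            (
                s.chrom,
                int(pos[s.start]) - 1,
                int(pos[s.end - 1]),
                STATUS_LABELS[s.status],
                s.cn,
                f"{s.p_adj:.4g}",
            )
        )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "status", "cn", "p_adj"]
    ).to_csv(path, sep="\t", index=False)


def write_status_matrix_tsv(path, profiles: list[CopyNumberProfile], annotation: pd.DataFrame) -> None:
    df = pd.DataFrame(
        {p.sample_id: p.status for p in profiles},
        index=annotation["probe_id"],
    )
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_status_matrix_tsv(path) -> list[CopyNumberProfile]:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return [
        CopyNumberProfile(c, df[c].to_numpy(), np.full(len(df), -1)) for c in df.columns
    ]


def write_apith_csv(path, results) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "metric": r.metric,
                "k": r.k,
                "apith": r.apith,
                "variance": r.variance,
                "weight": r.weight,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def read_apith_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_newick(path, tree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a simulated cohort: probe TSVs, beta matrix, clinical CSV,
    annotation and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation_tsv(out / "annotation.tsv", cohort.annotation)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)

    betas = {}
    truth = {}
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        for s, sid in enumerate(p.sample_ids):
            write_probe_tsv(pdir / f"{sid}.tsv", cohort.annotation, p.lrr[s], p.baf[s])
            betas[sid] = p.beta_obs[s]
        betas[f"{p.patient_id}_N"] = p.beta_normal_obs
        truth[p.patient_id] = _truth_json(p)
    beta = pd.DataFrame(betas, index=cohort.annotation["probe_id"])
    write_beta_tsv(out / "beta.tsv", beta)
    purity = pd.DataFrame(
        {
            "sample_id": [s for p in cohort.patients for s in p.sample_ids],
            "patient_id": [p.patient_id for p in cohort.patients for _ in p.sample_ids],
            "purity": np.concatenate([p.purity for p in cohort.patients]),
        }
    )
    purity.to_csv(out / "purity.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def _truth_json(p: PatientSimulation) -> dict:
    return {
        "k": p.k,
        "sample_ids": p.sample_ids,
        "clone_of_sample": [int(c) for c in p.clone_of_sample],
        "purity": [round(float(x), 4) for x in p.purity],
        "clone_parents": {str(c): p.tree.parent[c] for c in p.tree.clones},
        "true_apith": {m: round(float(v), 6) for m, v in p.true_apith.items()},
        "true_distance": {
            m: np.round(d, 6).tolist() for m, d in p.true_distance.items()
        },
    }
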