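"""Cohort persistence: HDF5 arrays plus delimited side tables.

Layout of the HDF5 container::

    /connectomes   (S, T, N, N) float32   symmetric Fisher-Z matrices
    /activation    (S, T, V)    float32
    /structure     (S, 2, R)    float64   [volume, thickness]
    /partition     (N,)         int       node -> network id
    /outcomes      (S, D)       float64   NaN where behavior is missing
    /demographics  (S, 3)       float64   age, sex, education

Demographics, outcomes and the node partition are additionally written
as CSV next to the container when a directory is given, for inspection
with ordinary table tools.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data_model import EdgeIndex
from .synthetic_cohort import CohortConfig, GroundTruth, SyntheticCohort

__all__ = ["save_cohort", "load_cohort"]


def save_cohort(cohort: SyntheticCohort, path, csv_dir=None) -> Path:
    """Write a cohort to an HDF5 container (and optional CSV side tables)."""
    path = Path(path)
    cfg = cohort.config
    S, T = cfg.n_subjects, cfg.n_tasks
    N = cfg.n_nodes
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("connectomes", shape=(S, T, N, N), dtype="f4",
                                chunks=(1, T, N, N))
        for s in range(S):
            mats = np.empty((T, N, N), dtype=np.float32)
            for t in range(T):
                mats[t] = cohort.connectome(s, t)
            dset[s] = mats
        f.create_dataset("activation", data=cohort.activation, dtype="f4")
        structure = np.stack([cohort.structure_volume, cohort.structure_thickness], axis=1)
        f.create_dataset("structure", data=structure)
        f.create_dataset("partition", data=cohort.ground_truth.network_partition)
        f.create_dataset("outcomes", data=cohort.outcomes.to_numpy(dtype=float))
        f.create_dataset("demographics",
                         data=cohort.demographics[["age", "sex", "education"]].to_numpy())
        f.attrs["config"] = json.dumps(asdict(cfg))
        f.attrs["domain_names"] = list(cohort.domain_names)
        f.attrs["task_domain"] = cohort.task_domain.tolist()
        gt = f.create_group("ground_truth")
        gt.create_dataset("subject_factors", data=cohort.ground_truth.subject_factors)
        for (modality, domain), pattern in cohort.ground_truth.planted_patterns.items():
            gt.create_dataset(f"pattern/{modality}/{domain}", data=pattern)
        gt.attrs["covariate_coefficients"] = json.dumps(
            {k: float(v) for k, v in cohort.ground_truth.covariate_coefficients.items()}
        )
    if csv_dir is not None:
        csv_dir = Path(csv_dir)
        csv_dir.mkdir(parents=True, exist_ok=True)
        cohort.demographics.to_csv(csv_dir / "demographics.csv")
        cohort.outcomes.to_csv(csv_dir / "outcomes.csv")
        pd.DataFrame({
            "node_id": np.arange(N),
            "network_id": cohort.ground_truth.network_partition,
        }).to_csv(csv_dir / "partition.csv", index=False)
    return path


def load_cohort(path) -> SyntheticCohort:
    """Read a cohort written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        cfg = CohortConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in json.loads(f.attrs["config"]).items()})
        domain_names = [str(d) for d in f.attrs["domain_names"]]
        task_domain = np.asarray(f.attrs["task_domain"], dtype=int)
        index = EdgeIndex(cfg.n_nodes)
        mats = f["connectomes"]
        S, T = cfg.n_subjects, cfg.n_tasks
        edges = np.empty((S, T, len(index)), dtype=np.float32)
        for s in range(S):
            block = mats[s]
            edges[s] = block[:, index.rows, index.cols]
        activation = f["activation"][()]
        structure = f["structure"][()]
        partition = f["partition"][()]
        outcomes = pd.DataFrame(f["outcomes"][()],
                                index=pd.RangeIndex(S, name="subject"),
                                columns=domain_names)
        demographics = pd.DataFrame(f["demographics"][()],
                                    index=pd.RangeIndex(S, name="subject"),
                                    columns=["age", "sex", "education"])
        patterns = {}
        gt_grp = f["ground_truth"]
        for modality in gt_grp["pattern"]:
            for domain in gt_grp[f"pattern/{modality}"]:
                patterns[(modality, domain)] = gt_grp[f"pattern/{modality}/{domain}"][()]
        ground_truth = GroundTruth(
            planted_patterns=patterns,
            covariate_coefficients=json.loads(gt_grp.attrs["covariate_coefficients"]),
            network_partition=partition,
            subject_factors=gt_grp["subject_factors"][()],
        )
    return SyntheticCohort(
        config=cfg,
        demographics=demographics,
        outcomes=outcomes,
        connectivity_edges=edges,
        activation=activation,
        structure_volume=structure[:, 0, :],
        structure_thickness=structure[:, 1, :],
        ground_truth=ground_truth,
        edge_index=index,
        task_domain=task_domain,
    )
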