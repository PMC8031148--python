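"""Common feature-space containers for multimodal brain data.

Every modality (task functional connectomes, voxel activation maps,
structural ROI features) is reshaped into the same two-dimensional
``variables x observations`` layout before any group-level modelling.
One column is one subject-task (task level) or one subject (after
within-subject averaging).  This module owns that conversion: edge
vectorization of symmetric Fisher-Z connectivity matrices, the
conjunction mask over subjects, structural z-scoring, stacking, and
within-subject averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EdgeIndex",
    "ObservationArray",
    "vectorize_connectome",
    "devectorize_edges",
    "conjunction_mask",
    "build_structural_vector",
    "stack_observations",
    "average_within_subject",
]


class EdgeIndex:
    """Fixed ordering of the unique node pairs (i, j), i < j, of a connectome.

    The ordering is row-major over the upper triangle: (0,1), (0,2), ...,
    (0,n-1), (1,2), ...  The same index object must be used to vectorize
    connectomes, to interpret edge patterns, and to coarse-grain them, so
    that edge positions always mean the same node pair.
    """

    def __init__(self, n_nodes: int):
        if n_nodes < 2:
            raise ValueError("EdgeIndex requires at least 2 nodes")
        self.n_nodes = int(n_nodes)
        self.rows, self.cols = np.triu_indices(self.n_nodes, k=1)

    def __len__(self) -> int:
        return self.rows.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"EdgeIndex(n_nodes={self.n_nodes}, n_edges={len(self)})"

    @property
    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of node pairs in index order."""
        return np.column_stack([self.rows, self.cols])

    def vectorize(self, matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
        """Extract the upper-triangle edge vector of a symmetric matrix."""
        matrix = np.asarray(matrix)
        if matrix.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{self.n_nodes} nodes"
            )
        finite = np.isfinite(matrix) & np.isfinite(matrix.T)
        if np.any(np.abs((matrix - matrix.T)[finite]) > atol):
            raise ValueError("connectome matrix is not symmetric")
        return matrix[self.rows, self.cols]

    def devectorize(self, edges: np.ndarray) -> np.ndarray:
        """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
        edges = np.asarray(edges)
        if edges.shape != (len(self),):
            raise ValueError(
                f"edge vector length {edges.shape} does not match "
                f"{len(self)} edges"
            )
        out = np.zeros((self.n_nodes, self.n_nodes), dtype=edges.dtype)
        out[self.rows, self.cols] = edges
        out[self.cols, self.rows] = edges
        return out


def vectorize_connectome(connectome: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Vectorize a symmetric Fisher-Z connectivity matrix to edge order.

    Missing edges (NaN in the matrix) stay NaN in the vector and are
    resolved later by :func:`conjunction_mask`.
    """
    return index.vectorize(connectome)


def devectorize_edges(edges: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Inverse of :func:`vectorize_connectome`."""
    return index.devectorize(edges)


def conjunction_mask(edge_vectors) -> np.ndarray:
    """Edges present (finite) for *every* subject.

    Parameters
    ----------
    edge_vectors : sequence of 1-D arrays, or 2-D array (subjects x edges)

    Returns
    -------
    boolean mask over edges, True where no subject is missing the edge.
    """
    arr = np.asarray(edge_vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("edge_vectors must be a list of equal-length vectors")
    mask = np.all(np.isfinite(arr), axis=0)
    if not mask.any():
        raise ValueError("conjunction mask is empty: no edge present in all subjects")
    return mask


def build_structural_vector(volume: np.ndarray, thickness: np.ndarray) -> np.ndarray:
    """Concatenate within-subject z-scored ROI volume and thickness.

    Volume and thickness are incommensurate, so each block is z-scored
    across its ROIs within the subject before concatenation (volume
    first).  With 68 cortical ROIs this yields the 136-element structural
    feature vector.
    """
    volume = np.asarray(volume, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if volume.ndim != 1 or thickness.ndim != 1 or volume.size != thickness.size:
        raise ValueError("volume and thickness must be 1-D and equal length")
    out = []
    for name, block in (("volume", volume), ("thickness", thickness)):
        sd = block.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"{name} block has zero variance; z-score undefined")
        out.append((block - block.mean()) / sd)
    return np.concatenate(out)


@dataclass
class ObservationArray:
    """A variables x observations matrix with observation labels.

    ``values[v, o]`` is variable ``v`` measured in observation ``o``; an
    observation is one subject-task pair (task level) or one subject
    (after within-subject averaging).  Columns are ordered by
    (subject, task) as produced by :func:`stack_observations`.
    """

    values: np.ndarray
    subjects: np.ndarray
    tasks: np.ndarray | None = None
    domains: np.ndarray | None = None
    modality: str = ""
    variable_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (variables x observations)")
        self.subjects = np.asarray(self.subjects)
        if self.subjects.size != self.n_observations:
            raise ValueError("one subject label required per observation")
        for name in ("tasks", "domains"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.size != self.n_observations:
                    raise ValueError(f"{name} labels must match observation count")
                setattr(self, name, lab)

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_observations(self) -> int:
        return self.values.shape[1]

    def labels(self) -> pd.DataFrame:
        """Observation labels as a DataFrame (one row per column)."""
        data = {"subject": self.subjects}
        if self.tasks is not None:
            data["task"] = self.tasks
        if self.domains is not None:
            data["domain"] = self.domains
        return pd.DataFrame(data)

    def column(self, subject, task=None) -> np.ndarray:
        """Retrieve the column for one (subject, task) observation."""
        sel = self.subjects == subject
        if task is not None:
            if self.tasks is None:
                raise ValueError("array has no task labels")
            sel &= self.tasks == task
        idx = np.flatnonzero(sel)
        if idx.size != 1:
            raise KeyError(f"expected one column for ({subject}, {task}), found {idx.size}")
        return self.values[:, idx[0]]

    def restrict_domain(self, domain) -> "ObservationArray":
        """Keep only the observations of one cognitive domain."""
        if self.domains is None:
            raise ValueError("array has no domain labels")
        sel = self.domains == domain
        if not sel.any():
            raise KeyError(f"no observations for domain {domain!r}")
        return ObservationArray(
            values=self.values[:, sel],
            subjects=self.subjects[sel],
            tasks=None if self.tasks is None else self.tasks[sel],
            domains=self.domains[sel],
            modality=self.modality,
            variable_ids=self.variable_ids,
        )


def stack_observations(
    vectors,
    subjects,
    tasks=None,
    domains=None,
    modality: str = "",
    variable_ids=None,
) -> ObservationArray:
    """Stack per-observation feature vectors into a variables x observations array.

    Columns are sorted by (subject, task) with a stable sort, so the
    layout is deterministic regardless of input order.
    """
    mat = np.column_stack([np.asarray(v, dtype=float) for v in vectors])
    subjects = np.asarray(subjects)
    if subjects.size != mat.shape[1]:
        raise ValueError("subject labels must match the number of vectors")
    tasks_arr = None if tasks is None else np.asarray(tasks)
    if tasks_arr is not None and tasks_arr.size != mat.shape[1]:
        raise ValueError("task labels must match the number of vectors")
    keys = (tasks_arr, subjects) if tasks_arr is not None else (subjects,)
    order = np.lexsort(keys)  # last key (subject) is primary
    return ObservationArray(
        values=mat[:, order],
        subjects=subjects[order],
        tasks=None if tasks_arr is None else tasks_arr[order],
        domains=None if domains is None else np.asarray(domains)[order],
        modality=modality,
        variable_ids=variable_ids,
    )


def average_within_subject(
    arr: ObservationArray,
    outcomes: pd.DataFrame | pd.Series,
    domain=None,
) -> tuple[ObservationArray, np.ndarray]:
    """Average task-level observations within subject for one domain.

    Returns a subject-level ObservationArray (one column per subject,
    subjects in sorted order) and the aligned outcome vector for the
    requested domain.  Subjects with a missing outcome are *retained*
    in the array — their brain data still informs the PCA — and carry
    NaN in the outcome vector, which downstream regression excludes.
    """
    if domain is not None:
        arr = arr.restrict_domain(domain)
    if arr.domains is not None and np.unique(arr.domains).size > 1:
        raise ValueError("array spans multiple domains; pass `domain` to select one")

    subject_ids = np.unique(arr.subjects)
    cols = np.empty((arr.n_variables, subject_ids.size), dtype=float)
    for k, s in enumerate(subject_ids):
        sel = arr.subjects == s
        if not sel.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"subject {s!r} has no observations in this domain")
        cols[:, k] = arr.values[:, sel].mean(axis=1)

    if isinstance(outcomes, pd.DataFrame):
        if domain is None:
            raise ValueError("domain required to pick the outcome column")
        y_series = outcomes[domain]
    else:
        y_series = outcomes
    y = y_series.reindex(subject_ids).to_numpy(dtype=float)

    averaged = ObservationArray(
        values=cols,
        subjects=subject_ids,
        tasks=None,
        domains=None if domain is None else np.full(subject_ids.size, domain, dtype=object),
        modality=arr.modality,
        variable_ids=arr.variable_ids,
    )
    return averaged, y
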