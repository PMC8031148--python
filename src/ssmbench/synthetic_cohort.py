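"""Synthetic multimodal cohort with planted brain-behavior ground truth.

The generator emulates the data layout of a 240-subject aging cohort
performing 12 in-scanner tasks in 4 cognitive domains (episodic memory,
fluid reasoning, perceptual speed, vocabulary): per subject-task
Fisher-Z functional connectomes on a 264-node / 14-network parcellation,
voxel-like activation maps, 68-ROI volume and thickness vectors, and
demographics (age, sex, education) correlated with the outcomes.

The generative model is deliberately linear.  Each subject carries one
latent ability factor per domain; every modality expresses that factor
along a planted unit-norm pattern, on top of a fixed group mean, a
subject-level trait component (stable across tasks), task-specific
structure, and observation noise.  Outcomes are the standardized factor
plus demographic effects plus noise, with the noise variance set so
that the factor accounts for a configurable fraction (the per-domain
SNR) of the outcome variance.  Because everything planted is known, the
whole prediction pipeline can be tested for parameter recovery.

Connectivity is generated directly in Fisher-Z edge space: the
prediction framework consumes Fisher-Z matrices, so no per-subject
time-series simulation is needed for the main pipeline (a separate ROI
time-series generator exists as a fixture for the QC stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .data_model import EdgeIndex, ObservationArray, average_within_subject

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "DOMAIN_NAMES",
    "generate_cohort",
    "generate_node_timeseries",
]

DOMAIN_NAMES = ("MEM", "FLUID", "SPEED", "VOCAB")

# Cohort demographics the generator is matched to: age 51.10 +- 16.40
# (range 21-80), education 16.24 +- 2.37 years (range 9-24), 110 of 240
# male.  Sex is coded 0 = female, 1 = male.
AGE_MEAN, AGE_SD, AGE_RANGE = 51.10, 16.40, (21.0, 80.0)
EDU_MEAN, EDU_SD, EDU_RANGE = 16.24, 2.37, (9.0, 24.0)
MALE_FRACTION = 110 / 240


@dataclass
class CohortConfig:
    """Design constants and noise levels of a synthetic cohort.

    ``snr_per_domain`` is the fraction of each outcome's variance
    carried by the latent brain factor (0 = pure noise + demographics).
    ``trait_variance_fc``/``trait_variance_act`` are the per-feature
    variances of the stable between-subject component; connectivity is
    given the larger trait share, which flattens its group variance
    spectrum relative to activation.
    """

    n_subjects: int = 240
    n_domains: int = 4
    tasks_per_domain: int = 3
    n_nodes: int = 264
    n_networks: int = 14
    n_voxels: int = 2_000          # desk-scale default; nominal grid is 24,595
    n_rois: int = 68
    snr_per_domain: tuple = (0.3, 0.3, 0.3, 0.3)
    trait_variance_fc: float = 0.02
    trait_variance_act: float = 0.005
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.2, "sex": 0.1, "education": 0.15}
    )
    missing_behavior_fraction: float = 0.05
    seed: int = 0

    # secondary noise/structure knobs (held fixed across the test suite)
    state_noise_fc: float = 0.25       # per-edge observation noise, Fisher-Z units
    state_noise_act: float = 0.5       # per-voxel observation noise
    fc_base_mean: float = 0.1          # group-mean Fisher-Z connectome level
    fc_base_sd: float = 0.1
    task_amplitude_fc: float = 0.05    # task-specific edge modulation
    task_amplitude_act: float = 1.0    # task-specific activation topography
    pattern_amplitude_fc: float = 1.0  # planted-direction loading of the factor
    pattern_amplitude_act: float = 1.0
    pattern_amplitude_struct: float = 0.5
    struct_noise: float = 0.3

    def __post_init__(self):
        for name in ("n_subjects", "n_domains", "tasks_per_domain", "n_nodes",
                     "n_networks", "n_voxels", "n_rois"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_networks > self.n_nodes:
            raise ValueError("cannot have more networks than nodes")
        if not 0 <= self.missing_behavior_fraction <= 1:
            raise ValueError("missing_behavior_fraction must lie in [0, 1]")
        if np.isscalar(self.snr_per_domain):
            self.snr_per_domain = (float(self.snr_per_domain),) * self.n_domains
        self.snr_per_domain = tuple(float(s) for s in self.snr_per_domain)
        if len(self.snr_per_domain) != self.n_domains:
            raise ValueError("snr_per_domain needs one value per domain")
        if any(not 0 <= s < 1 for s in self.snr_per_domain):
            raise ValueError("snr values must lie in [0, 1)")
        for v in (self.trait_variance_fc, self.trait_variance_act):
            if v < 0:
                raise ValueError("trait variances must be nonnegative")

    @property
    def n_tasks(self) -> int:
        return self.n_domains * self.tasks_per_domain

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def domain_names(self) -> tuple:
        base = list(DOMAIN_NAMES[: self.n_domains])
        base += [f"DOM{i + 1}" for i in range(len(base), self.n_domains)]
        return tuple(base)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    planted_patterns: dict        # (modality, domain) -> unit-norm variable vector
    covariate_coefficients: dict  # covariate -> effect on each standardized outcome
    network_partition: np.ndarray  # node -> network id
    subject_factors: np.ndarray    # (subjects, domains) latent ability factors


@dataclass
class SyntheticCohort:
    """A generated cohort, held in edge-vector form for connectivity."""

    config: CohortConfig
    demographics: pd.DataFrame
    outcomes: pd.DataFrame
    connectivity_edges: np.ndarray   # (subjects, tasks, edges) float32, Fisher-Z
    activation: np.ndarray           # (subjects, tasks, voxels) float32
    structure_volume: np.ndarray     # (subjects, rois) raw units
    structure_thickness: np.ndarray  # (subjects, rois)
    ground_truth: GroundTruth
    edge_index: EdgeIndex
    task_domain: np.ndarray          # task index -> domain index

    @property
    def domain_names(self) -> tuple:
        return self.config.domain_names

    @property
    def subject_ids(self) -> np.ndarray:
        return self.demographics.index.to_numpy()

    def connectome(self, subject: int, task: int) -> np.ndarray:
        """Full symmetric zero-diagonal Fisher-Z matrix of one observation."""
        return self.edge_index.devectorize(
            self.connectivity_edges[subject, task].astype(float)
        )

    def covariates(self, subjects=None) -> np.ndarray:
        """(n, 3) raw covariate matrix in the order age, education, sex."""
        demo = self.demographics if subjects is None else self.demographics.loc[subjects]
        return demo[["age", "education", "sex"]].to_numpy(dtype=float)

    def structural_array(self) -> ObservationArray:
        """One 2*n_rois z-scored structural vector per subject."""
        from .data_model import build_structural_vector

        vecs = [
            build_structural_vector(self.structure_volume[s], self.structure_thickness[s])
            for s in range(self.config.n_subjects)
        ]
        return ObservationArray(
            values=np.column_stack(vecs),
            subjects=self.subject_ids,
            modality="struct",
        )

    def task_array(self, modality: str) -> ObservationArray:
        """Task-level variables x (subjects*tasks) array for fc or act."""
        if modality == "fc":
            data = self.connectivity_edges
        elif modality == "act":
            data = self.activation
        else:
            raise ValueError("task-level arrays exist for modalities 'fc' and 'act'")
        S, T, V = data.shape
        names = self.domain_names
        # column order (subject-major, task-minor) matches stack_observations
        values = np.ascontiguousarray(
            data.astype(np.float32).transpose(2, 0, 1).reshape(V, S * T)
        )
        subjects = np.repeat(self.subject_ids, T)
        tasks = np.tile(np.arange(T), S)
        domains = np.array([names[d] for d in self.task_domain], dtype=object)[tasks]
        return ObservationArray(values=values, subjects=subjects, tasks=tasks,
                                domains=domains, modality=modality)

    def domain_data(self, modality: str, domain: str):
        """Subject-level (ObservationArray, outcome vector) for one domain.

        Connectivity and activation are averaged over the domain's tasks
        within subject; structure is subject-level already and is paired
        with the domain's outcome directly.
        """
        if modality == "struct":
            arr = self.structural_array()
            y = self.outcomes[domain].reindex(arr.subjects).to_numpy(dtype=float)
            return arr, y
        return average_within_subject(self.task_array(modality), self.outcomes, domain)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _zscore(x):
    return (x - x.mean()) / x.std()


def _unit(v):
    return v / np.linalg.norm(v)


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a full cohort from a config (deterministic given the seed)."""
    if config is None:
        config = CohortConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S, T, D = cfg.n_subjects, cfg.n_tasks, cfg.n_domains
    E, V, R = cfg.n_edges, cfg.n_voxels, cfg.n_rois
    names = cfg.domain_names
    task_domain = np.repeat(np.arange(D), cfg.tasks_per_domain)

    # node -> network partition: contiguous, near-equal blocks
    partition = np.concatenate([
        np.full(len(block), k)
        for k, block in enumerate(np.array_split(np.arange(cfg.n_nodes), cfg.n_networks))
    ])

    # demographics
    age = _truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=S)
    education = _truncated_normal(rng, EDU_MEAN, EDU_SD, *EDU_RANGE, size=S)
    sex = np.zeros(S)
    sex[: round(S * MALE_FRACTION)] = 1.0
    rng.shuffle(sex)
    demographics = pd.DataFrame(
        {"age": age, "sex": sex, "education": education},
        index=pd.RangeIndex(S, name="subject"),
    )
    cov_z = np.column_stack([_zscore(age), _zscore(sex), _zscore(education)])

    # latent per-domain ability factors and planted patterns
    g = rng.standard_normal((S, D))
    patterns = {}
    for d in range(D):
        patterns[("fc", names[d])] = _unit(rng.standard_normal(E))
        patterns[("act", names[d])] = _unit(rng.standard_normal(V))
        p_struct = rng.standard_normal(2 * R)
        # keep each block mean-free so within-subject z-scoring preserves it
        p_struct[:R] -= p_struct[:R].mean()
        p_struct[R:] -= p_struct[R:].mean()
        patterns[("struct", names[d])] = _unit(p_struct)

    # functional connectivity, generated directly in Fisher-Z edge space
    fc_base = rng.normal(cfg.fc_base_mean, cfg.fc_base_sd, E).astype(np.float32)
    fc_task = rng.normal(0.0, cfg.task_amplitude_fc, (T, E)).astype(np.float32)
    fc_trait = (np.sqrt(cfg.trait_variance_fc)
                * rng.standard_normal((S, E), dtype=np.float32))
    fc = rng.standard_normal((S, T, E), dtype=np.float32)
    fc *= cfg.state_noise_fc
    for t in range(T):
        d = task_domain[t]
        planted = cfg.pattern_amplitude_fc * np.outer(g[:, d], patterns[("fc", names[d])])
        fc[:, t, :] += fc_base + fc_task[t] + planted.astype(np.float32)
    fc += fc_trait[:, None, :]

    # voxel activation: distinct mean topography per task
    act_task = rng.normal(0.0, cfg.task_amplitude_act, (T, V)).astype(np.float32)
    act_trait = (np.sqrt(cfg.trait_variance_act)
                 * rng.standard_normal((S, V), dtype=np.float32))
    act = rng.standard_normal((S, T, V), dtype=np.float32)
    act *= cfg.state_noise_act
    for t in range(T):
        d = task_domain[t]
        planted = cfg.pattern_amplitude_act * np.outer(g[:, d], patterns[("act", names[d])])
        act[:, t, :] += act_task[t] + planted.astype(np.float32)
    act += act_trait[:, None, :]

    # structure: fixed ROI profiles plus subject noise plus planted signal
    base_vol = np.clip(rng.normal(5.0, 1.0, R), 0.5, None)
    base_thick = np.clip(rng.normal(2.5, 0.3, R), 0.5, None)
    vol = base_vol + cfg.struct_noise * rng.standard_normal((S, R))
    thick = base_thick + 0.5 * cfg.struct_noise * rng.standard_normal((S, R))
    for d in range(D):
        p = patterns[("struct", names[d])]
        vol += cfg.pattern_amplitude_struct * np.outer(g[:, d], p[:R])
        thick += cfg.pattern_amplitude_struct * np.outer(g[:, d], p[R:])

    # outcomes: standardized factor + demographic effects + calibrated noise
    coef = np.array([cfg.covariate_effects.get(k, 0.0)
                     for k in ("age", "sex", "education")])
    cov_part = cov_z @ coef
    v_cov = float(cov_part.var())
    outcomes = np.empty((S, D))
    for d in range(D):
        snr = cfg.snr_per_domain[d]
        eps_var = 1.0 - snr - v_cov
        if eps_var <= 0:
            raise ValueError(
                f"snr {snr} plus covariate variance {v_cov:.3f} exceeds the "
                "unit outcome variance; reduce one of them"
            )
        outcomes[:, d] = (np.sqrt(snr) * _zscore(g[:, d]) + cov_part
                          + np.sqrt(eps_var) * rng.standard_normal(S))
    outcomes_df = pd.DataFrame(outcomes, index=demographics.index, columns=list(names))

    n_missing = round(cfg.missing_behavior_fraction * S)
    if n_missing:
        missing = rng.choice(S, size=n_missing, replace=False)
        outcomes_df.iloc[missing] = np.nan

    return SyntheticCohort(
        config=cfg,
        demographics=demographics,
        outcomes=outcomes_df,
        connectivity_edges=fc,
        activation=act,
        structure_volume=vol,
        structure_thickness=thick,
        ground_truth=GroundTruth(
            planted_patterns=patterns,
            covariate_coefficients={k: v for k, v in zip(("age", "sex", "education"), coef)},
            network_partition=partition,
            subject_factors=g,
        ),
        edge_index=EdgeIndex(cfg.n_nodes),
        task_domain=task_domain,
    )


def generate_node_timeseries(
    n_frames: int,
    n_nodes: int,
    motion_spikes=None,
    seed: int | None = None,
    corr: np.ndarray | None = None,
    tr_s: float = 2.0,
    mean: float = 1000.0,
    amplitude: float = 2.0,
):
    """Band-limited correlated ROI series plus motion parameters.

    A fixture for the QC stage: node signals are white noise band-pass
    filtered to 0.01-0.08 Hz, mixed to a known inter-node correlation
    matrix, and offset to a positive baseline.  Motion is a slow small
    random walk (FD well below 0.5 mm); each entry of ``motion_spikes``
    — ``(frame, magnitude_mm)`` — adds a sustained x-translation step at
    that frame, so FD exceeds the magnitude exactly there.

    Returns ``(timeseries, motion, true_corr)`` with shapes
    (frames, nodes), (frames, 6), (nodes, nodes).
    """
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    rng = np.random.default_rng(seed)

    if corr is None:
        loadings = 0.6 * rng.standard_normal((n_nodes, 3))
        cov = loadings @ loadings.T + np.eye(n_nodes)
        dd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(dd, dd)
    else:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (n_nodes, n_nodes):
            raise ValueError("corr must be (n_nodes, n_nodes)")

    pad = 100
    white = rng.standard_normal((n_frames + 2 * pad, n_nodes))
    sos = signal.butter(4, [0.01, 0.08], btype="bandpass", fs=1.0 / tr_s, output="sos")
    slow = signal.sosfiltfilt(sos, white, axis=0)[pad:pad + n_frames]
    slow = (slow - slow.mean(axis=0)) / slow.std(axis=0)
    mixed = slow @ np.linalg.cholesky(corr).T
    ts = mean + amplitude * mixed

    motion = np.cumsum(rng.normal(0.0, 0.002, (n_frames, 6)), axis=0)
    motion[:, 3:] *= 0.01  # rotations in radians, far smaller than translations
    if motion_spikes:
        for frame, magnitude in motion_spikes:
            if not 1 <= frame < n_frames:
                raise ValueError(f"spike frame {frame} outside [1, {n_frames - 1}]")
            motion[frame:, 0] += magnitude
    return ts, motion, corr
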