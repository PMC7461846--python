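"""Regime-switching synthetic cohorts with class differences only in dynamics.

The generator emulates the one property the surrogate argument hinges on:
multivariate signals whose covariance switches between a small set of hidden
states, where two classes of subjects visit the *same* states with the
*same* stationary occupancy but at different speeds (mean dwell times).  By
construction the classes share their time-averaged (static) covariance, so a
static-connectivity feature carries no class information — any classifier
that separates the classes must be reading temporal structure.

State covariances are built from a designated "dynamic block" of regions:
state 0 raises the within-block correlation to ``rho``; state 1 is the
identity.  The within-block pairs are the ground-truth dynamic edges used by
the attribution-recovery and per-edge-test experiments.

A continuous trait is linearly coupled to each subject's realized state
switch rate (z-scored across the cohort) plus Gaussian noise, and nuisance
covariates (age and motion stand-ins) can be given a configurable
correlation with the trait to exercise confound regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfc import edge_indexing
from .io import CohortTable, NetworkPartition, RoiTimeSeries

__all__ = ["GeneratorSpec", "SyntheticCohort", "sample_state_path", "generate_run",
           "generate_cohort"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort: 20 regions, 300 samples at
    TR = 0.72 s, two covariance states with within-block correlation 0.8 on
    an 8-region dynamic block, slow (mean dwell 30 samples, ~22 s) vs. fast
    (4 samples, ~3 s) switching classes, mild AR(1) smoothing and
    observation noise.  The dwell contrast is chosen so that a sliding
    window shorter than the slow dwell resolves the slow class's regimes
    while averaging over the fast class's.
    """

    n_regions: int = 20
    n_samples: int = 300
    tr_seconds: float = 0.72
    n_states: int = 2
    dynamic_block: int = 8          # regions 0..dynamic_block-1 carry the dynamics
    rho: float = 0.8                # within-block correlation in state 0
    dwell_means: tuple[float, float] = (30.0, 4.0)    # per class, in samples
    ar_coef: float = 0.1            # AR(1) smoothing of the state-conditional draws
    noise_sd: float = 0.1           # additive observation noise
    trait_beta: float = 1.0         # trait = beta * z(switch rate) + noise
    trait_noise_sd: float = 1.0
    confound_strength: float = 0.3  # corr of age/motion covariates with the trait

    def __post_init__(self) -> None:
        if self.n_regions < 2 or not 2 <= self.dynamic_block <= self.n_regions:
            raise ValueError("need 2 <= dynamic_block <= n_regions")
        if self.n_states not in (1, 2):
            raise ValueError("generator supports 1 or 2 states")
        if not -1.0 / (self.dynamic_block - 1) < self.rho < 1.0:
            raise ValueError("rho outside the positive-definite range for the block")
        if any(d < 1 for d in self.dwell_means):
            raise ValueError("dwell means must be >= 1 sample")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")
        if self.noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def state_covariances(self) -> list[np.ndarray]:
        """Per-state covariance matrices; all symmetric positive definite."""
        n, b = self.n_regions, self.dynamic_block
        c0 = np.eye(n)
        c0[:b, :b] = self.rho
        np.fill_diagonal(c0, 1.0)
        if self.n_states == 1:
            return [c0]
        return [c0, np.eye(n)]

    def dynamic_edges(self) -> list[tuple[int, int]]:
        """Ground-truth edges whose correlation differs between states."""
        return [(i, j) for (i, j) in edge_indexing(self.n_regions)
                if j < self.dynamic_block]

    def node_ids(self) -> list[str]:
        return [f"n{k}" for k in range(self.n_regions)]

    def partition(self) -> NetworkPartition:
        """Two networks: the dynamic block vs. the background regions."""
        mapping = {
            nid: ("dyn" if k < self.dynamic_block else "bg")
            for k, nid in enumerate(self.node_ids())
        }
        return NetworkPartition(mapping, ["dyn", "bg"])


@dataclass
class SyntheticCohort:
    """A generated cohort: runs, latent state paths and subject metadata."""

    runs: list[RoiTimeSeries]
    state_paths: dict[str, np.ndarray]
    table: CohortTable
    dynamic_edges: list[tuple[int, int]]
    spec: GeneratorSpec

    def run_array(self) -> np.ndarray:
        """All runs stacked to shape (n_runs, T, N), in ``runs`` order."""
        return np.stack([r.values for r in self.runs], axis=0)

    @property
    def run_subjects(self) -> list[str]:
        return [r.subject_id for r in self.runs]


def sample_state_path(
    class_label: int, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Hidden state sequence for one run: a 2-state symmetric Markov chain.

    Dwell times are geometric with the class's configured mean; the
    symmetric switch probability makes the stationary occupancy 1/2 per
    state for *both* classes, which is what matches static connectivity
    across classes.
    """
    if spec.n_states == 1:
        return np.zeros(spec.n_samples, dtype=int)
    p_switch = 1.0 / spec.dwell_means[class_label]
    states = np.empty(spec.n_samples, dtype=int)
    states[0] = rng.integers(spec.n_states)
    flips = rng.random(spec.n_samples - 1) < p_switch
    for t in range(1, spec.n_samples):
        states[t] = 1 - states[t - 1] if flips[t - 1] else states[t - 1]
    return states


def generate_run(
    class_label: int,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    run_id: str = "run0",
    subject_id: str = "s0",
) -> tuple[RoiTimeSeries, np.ndarray]:
    """One run: state-conditional Gaussian draws, AR(1) smoothing, noise.

    ``x_t ~ N(0, C_state(t))`` is smoothed as
    ``y_t = a*y_{t-1} + sqrt(1-a^2)*x_t`` (variance-preserving, emulating
    hemodynamic autocorrelation) and observation noise is added.
    """
    states = sample_state_path(class_label, spec, rng)
    chols = [np.linalg.cholesky(c) for c in spec.state_covariances()]
    innovations = rng.standard_normal((spec.n_samples, spec.n_regions))
    x = np.empty_like(innovations)
    for k, chol in enumerate(chols):
        mask = states == k
        x[mask] = innovations[mask] @ chol.T
    a = spec.ar_coef
    if a > 0.0:
        y = np.empty_like(x)
        y[0] = x[0]
        scale = np.sqrt(1.0 - a * a)
        for t in range(1, spec.n_samples):
            y[t] = a * y[t - 1] + scale * x[t]
        x = y
    if spec.noise_sd > 0.0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    ts = RoiTimeSeries(
        values=x,
        tr_seconds=spec.tr_seconds,
        node_ids=spec.node_ids(),
        run_id=run_id,
        subject_id=subject_id,
    )
    return ts, states


def generate_cohort(
    n_subjects: int = 200,
    runs_per_subject: int = 1,
    spec: GeneratorSpec = GeneratorSpec(),
    seed: int = 0,
) -> SyntheticCohort:
    """A balanced two-class cohort with trait scores and nuisance covariates.

    Half the subjects get each class label (slow vs. fast switching).  The
    trait is ``beta * z(switch rate) + noise``; age and motion covariates
    are correlated with the trait at ``confound_strength``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    labels = np.array([s % 2 for s in range(n_subjects)])
    runs: list[RoiTimeSeries] = []
    state_paths: dict[str, np.ndarray] = {}
    switch_rates = np.empty(n_subjects)
    for s in range(n_subjects):
        sid = f"sub{s:04d}"
        n_switches = 0
        n_steps = 0
        for r in range(runs_per_subject):
            rid = f"{sid}_r{r}"
            ts, states = generate_run(labels[s], spec, rng, run_id=rid, subject_id=sid)
            runs.append(ts)
            state_paths[rid] = states
            n_switches += int(np.sum(states[1:] != states[:-1]))
            n_steps += spec.n_samples - 1
        switch_rates[s] = n_switches / n_steps

    z_rate = (switch_rates - switch_rates.mean()) / switch_rates.std()
    trait = spec.trait_beta * z_rate + spec.trait_noise_sd * rng.standard_normal(n_subjects)
    g = spec.confound_strength
    z_trait = (trait - trait.mean()) / (trait.std() or 1.0)
    mix = np.sqrt(max(0.0, 1.0 - g * g))
    age_z = g * z_trait + mix * rng.standard_normal(n_subjects)
    fd_z = g * z_trait + mix * rng.standard_normal(n_subjects)
    age = 28.0 + 4.0 * age_z
    mean_fd = np.exp(-2.0 + 0.4 * fd_z)          # lognormal-ish motion summary

    frame = pd.DataFrame(
        {
            "subject_id": [f"sub{s:04d}" for s in range(n_subjects)],
            "sex": labels,
            "age": age,
            "mean_fd": mean_fd,
            "run_ids": [
                ",".join(f"sub{s:04d}_r{r}" for r in range(runs_per_subject))
                for s in range(n_subjects)
            ],
            "trait": trait,
            "switch_rate": switch_rates,
        }
    )
    return SyntheticCohort(
        runs=runs,
        state_paths=state_paths,
        table=CohortTable(frame),
        dynamic_edges=spec.dynamic_edges(),
        spec=spec,
    )
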