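"""Multivariate phase randomization (MVPR) surrogates and surrogate statistics.

An MVPR surrogate multiplies the discrete Fourier transform of *every*
region's signal by ``exp(i * phi)`` with one common random phase vector
``phi`` shared across regions, then inverts the transform.  Because all
regions receive the same phases, cross-spectral phase differences — and
hence the static (full-length) correlation structure — are preserved
exactly, while any temporal ordering of connectivity states is destroyed.
That makes MVPR copies a null model for *dynamic* connectivity: anything a
model or statistic can still detect on them does not come from dynamics.

Two procedures are built on the surrogates:

* a per-edge test of whether an edge exhibits genuine dFC (observed
  windowed-variance against the surrogate null), and
* a model-level null distribution of cross-validated accuracies obtained by
  rerunning an entire training pipeline on surrogate copies of every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfc import DfcSequence, WindowSpec, sliding_window_dfc
from .io import RoiTimeSeries

__all__ = [
    "SurrogateSpec",
    "EdgeSignificance",
    "random_symmetric_phases",
    "mvpr_surrogate",
    "mvpr_surrogates",
    "edge_dfc_statistic",
    "test_edge_dfc",
    "null_accuracy_distribution",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Configuration for surrogate generation."""

    n_copies: int = 100
    seed: int = 0
    demean: bool = True

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class EdgeSignificance:
    """Per-edge dFC test result over one run."""

    edge_index: list[tuple[int, int]]
    observed: np.ndarray            # (E,)
    null: np.ndarray                # (n_copies, E)
    p_values: np.ndarray            # (E,)
    statistic_name: str
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.p_values <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        i, j = zip(*self.edge_index)
        return pd.DataFrame(
            {
                "edge_i": i,
                "edge_j": j,
                "statistic": self.observed,
                "p": self.p_values,
                "significant": self.significant,
            }
        )


def random_symmetric_phases(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random phase vector of length T with Hermitian symmetry.

    ``phi[T-k] = -phi[k]``, ``phi[0] = 0`` and, for even T, ``phi[T/2] = 0``
    — the constraints under which ``ifft(fft(x) * exp(i*phi))`` is real.
    """
    phi = np.zeros(n_samples)
    n_free = (n_samples - 1) // 2
    draw = rng.uniform(0.0, 2.0 * np.pi, size=n_free)
    phi[1 : n_free + 1] = draw
    phi[n_samples - n_free :] = -draw[::-1]
    return phi


def mvpr_surrogate(
    ts: RoiTimeSeries,
    rng: np.random.Generator | int | None = None,
    phases: np.ndarray | None = None,
    demean: bool = True,
) -> RoiTimeSeries:
    """One MVPR surrogate copy of a run.

    A single length-T phase vector is drawn (or taken from ``phases``) and
    applied to the discrete Fourier transform of every region, preserving
    each region's amplitude spectrum and all cross-spectral phase
    differences.  Signals are demeaned before the transform and their means
    restored after, so the DC component is never randomized.
    """
    x = np.asarray(ts.values, dtype=float)
    n_samples = x.shape[0]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for phase randomization")
    if phases is None:
        rng = np.random.default_rng(rng)
        phases = random_symmetric_phases(n_samples, rng)
    phases = np.asarray(phases, dtype=float)
    if phases.shape != (n_samples,):
        raise ValueError(f"phases must have shape ({n_samples},)")
    mean = x.mean(axis=0, keepdims=True) if demean else 0.0
    spectrum = np.fft.fft(x - mean, axis=0)
    inverse = np.fft.ifft(spectrum * np.exp(1j * phases)[:, None], axis=0)
    scale = max(1.0, float(np.abs(x).max()))
    if np.abs(inverse.imag).max() > 1e-9 * scale:
        raise RuntimeError(
            "inverse transform has a complex residual: phase vector is not "
            "Hermitian-symmetric"
        )
    return RoiTimeSeries(
        values=inverse.real + mean,
        tr_seconds=ts.tr_seconds,
        node_ids=list(ts.node_ids),
        run_id=f"{ts.run_id}:surr",
        subject_id=ts.subject_id,
    )


def mvpr_surrogates(ts: RoiTimeSeries, spec: SurrogateSpec) -> list[RoiTimeSeries]:
    """``spec.n_copies`` independent surrogate copies, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    return [mvpr_surrogate(ts, rng=rng, demean=spec.demean) for _ in range(spec.n_copies)]


def edge_dfc_statistic(seq: DfcSequence, statistic: str = "variance") -> np.ndarray:
    """Per-edge dynamics statistic of a windowed Fisher-z sequence.

    The default is the sample variance (ddof=1) of each edge's series:
    temporally reordered or phase-randomized signals flatten the windowed
    series, so genuine regime switching shows as excess variance.
    """
    z = seq.values
    if z.shape[0] < 2:
        raise ValueError("need at least 2 windows for a dynamics statistic")
    if statistic == "variance":
        return z.var(axis=0, ddof=1)
    if statistic == "range":
        return z.max(axis=0) - z.min(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def test_edge_dfc(
    ts: RoiTimeSeries,
    window_spec: WindowSpec,
    n_copies: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "variance",
    fdr: bool = False,
) -> EdgeSignificance:
    """Test every edge of one run for significant dFC against MVPR surrogates.

    p-values use the plus-one permutation rule
    ``p = (1 + #{null >= observed}) / (1 + n_copies)`` so p is never zero.
    With ``fdr=True`` Benjamini-Hochberg adjusted p-values are reported.
    """
    import warnings

    if n_copies < 19:
        warnings.warn(
            f"{n_copies} copies give p-resolution {1 / (n_copies + 1):.3f}, "
            "too coarse for alpha=0.05",
            UserWarning,
            stacklevel=2,
        )
    observed_seq = sliding_window_dfc(ts, window_spec)
    observed = edge_dfc_statistic(observed_seq, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty((n_copies, observed.size))
    for c in range(n_copies):
        surr = mvpr_surrogate(ts, rng=rng)
        null[c] = edge_dfc_statistic(sliding_window_dfc(surr, window_spec), statistic)
    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_copies)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    return EdgeSignificance(
        edge_index=list(observed_seq.edge_index),
        observed=observed,
        null=null,
        p_values=p,
        statistic_name=statistic,
        alpha=alpha,
    )


def null_accuracy_distribution(
    X_runs: np.ndarray,
    run_subjects: list[str],
    y: dict[str, int],
    pipeline,
    real_accuracy: float,
    n_copies: int = 20,
    tr_seconds: float = 0.72,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of CV accuracies from MVPR copies of every run.

    For each copy index every run in ``X_runs`` (shape ``(n_runs, T, N)``)
    is replaced by an independent MVPR surrogate, and ``pipeline`` — a
    callable ``(X_runs, run_subjects, y, seed) -> accuracy`` running the full
    cross-validated experiment — is re-run from scratch.  Returns the null
    accuracies and the plus-one empirical p-value of ``real_accuracy``.
    """
    X_runs = np.asarray(X_runs, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(n_copies)
    null = np.empty(n_copies)
    for c in range(n_copies):
        rng = np.random.default_rng(seeds[c])
        surr = np.empty_like(X_runs)
        for r in range(X_runs.shape[0]):
            ts = RoiTimeSeries(
                values=X_runs[r],
                tr_seconds=tr_seconds,
                node_ids=[f"n{k}" for k in range(X_runs.shape[2])],
                run_id=f"run{r}",
            )
            surr[r] = mvpr_surrogate(ts, rng=rng).values
        null[c] = pipeline(surr, run_subjects, y, int(rng.integers(2**31 - 1)))
    p = (1.0 + np.sum(null >= real_accuracy)) / (1.0 + n_copies)
    return null, p
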