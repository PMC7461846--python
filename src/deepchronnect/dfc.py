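"""Sliding-window dynamic functional connectivity (dFC).

The chronnectome representation used throughout this package: each scan run's
region-by-time signal matrix is divided into overlapping rectangular windows,
the Pearson correlation of every region pair is computed inside each window,
Fisher z-transformed (``atanh``), and the upper triangle of each correlation
matrix is vectorized.  A run therefore becomes a ``W x E`` sequence with
``W = floor((T - window) / stride) + 1`` windows and ``E = N(N-1)/2`` edges.

Edge order is row-major over the upper triangle ``(i < j)`` and is the single
edge indexing convention used by every downstream module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RoiTimeSeries

__all__ = [
    "WindowSpec",
    "DfcSequence",
    "edge_indexing",
    "edge_to_index",
    "window_count",
    "window_seconds",
    "seconds_to_samples",
    "sliding_window_dfc",
    "dfc_strength",
    "SlidingWindowConnectivity",
]

#: correlations are clipped to +/-(1 - FISHER_EPS) before atanh so duplicated
#: channels (r = +/-1 exactly) stay finite
FISHER_EPS = 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and stride in samples, TR in seconds."""

    window_samples: int
    stride_samples: int = 5
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError(f"window_samples must be >= 2, got {self.window_samples}")
        if self.stride_samples < 1:
            raise ValueError(f"stride_samples must be >= 1, got {self.stride_samples}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")


@dataclass
class DfcSequence:
    """A run's windowed-correlation sequence: ``values`` is W x E Fisher-z."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]
    window_spec: WindowSpec
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DfcSequence values must be 2-D (windows x edges)")
        if self.values.shape[1] != len(self.edge_index):
            raise ValueError(
                f"edge_index length {len(self.edge_index)} does not match "
                f"{self.values.shape[1]} edge columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DfcSequence contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def edge_indexing(n_nodes: int) -> list[tuple[int, int]]:
    """Ordered node pairs ``(i, j)`` with ``i < j``, row-major upper triangle.

    This order matches ``numpy.triu_indices(n, k=1)`` and defines the edge
    axis of every dFC matrix, attribution map and significance table.
    """
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    iu, ju = np.triu_indices(n_nodes, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def edge_to_index(i: int, j: int, n_nodes: int) -> int:
    """Position of edge ``(i, j)`` (unordered) in the vectorized upper triangle."""
    if i == j:
        raise ValueError("self-loops are not edges")
    if not (0 <= i < n_nodes and 0 <= j < n_nodes):
        raise ValueError(f"node out of range for n_nodes={n_nodes}")
    if i > j:
        i, j = j, i
    # edges before row i, plus offset inside row i
    return i * n_nodes - i * (i + 1) // 2 + (j - i - 1)


def window_count(n_samples: int, window: int, stride: int) -> int:
    """Number of half-open windows ``[k*stride, k*stride + window)`` fitting in T."""
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    if window > n_samples:
        raise ValueError(f"window ({window}) exceeds series length ({n_samples})")
    return (n_samples - window) // stride + 1


def window_seconds(spec: WindowSpec) -> float:
    """Window duration in seconds (samples times TR)."""
    return spec.window_samples * spec.tr_seconds


def seconds_to_samples(width_seconds: float, tr_seconds: float) -> int:
    """Nearest-integer sample count for a window width requested in seconds."""
    if width_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("width and TR must be positive")
    n = int(round(width_seconds / tr_seconds))
    return max(n, 2)


def _windowed_correlations(x: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Stack of per-window correlation matrices, shape (W, N, N).

    Zero-variance channels inside a window produce r = 0 for their edges
    (handled by the caller's warning); the diagonal is left untouched.
    """
    views = sliding_window_view(x, window, axis=0)[::stride]  # (W, N, window)
    views = views - views.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(views, axis=-1)  # (W, N)
    prods = np.einsum("wit,wjt->wij", views, views, optimize=True)
    denom = norms[:, :, None] * norms[:, None, :]
    zero = denom == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(zero, 0.0, prods / np.where(zero, 1.0, denom))
    return corr, bool(np.any(zero & ~np.eye(x.shape[1], dtype=bool)))


def sliding_window_dfc(ts: RoiTimeSeries, spec: WindowSpec) -> DfcSequence:
    """Compute the Fisher-z windowed-correlation sequence of one run.

    Entry ``(k, e)`` is ``atanh(clip(r, +/-(1 - 1e-7)))`` where ``r`` is the
    Pearson correlation of edge ``e``'s two region signals inside window
    ``k``.  An edge whose signal has zero variance inside a window gets
    ``z = 0`` and a warning is emitted.
    """
    x = np.asarray(ts.values, dtype=float)
    n_samples, n_nodes = x.shape
    w = window_count(n_samples, spec.window_samples, spec.stride_samples)
    corr, had_zero_variance = _windowed_correlations(
        x, spec.window_samples, spec.stride_samples
    )
    if had_zero_variance:
        warnings.warn(
            f"run {ts.run_id!r}: zero-variance signal inside at least one window; "
            "affected edges set to z=0",
            RuntimeWarning,
            stacklevel=2,
        )
    iu, ju = np.triu_indices(n_nodes, k=1)
    r = corr[:, iu, ju]
    z = np.arctanh(np.clip(r, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    assert z.shape[0] == w
    return DfcSequence(
        values=z,
        edge_index=edge_indexing(n_nodes),
        window_spec=spec,
        run_id=ts.run_id,
    )


def dfc_strength(seq: DfcSequence, strategy: str = "mean_abs") -> np.ndarray:
    """Per-edge summary strength of the windowed series (the dFC-Str feature).

    ``mean_abs`` (default) is the mean absolute Fisher-z across windows;
    ``mean`` and ``std`` are alternative collapses of the same series.
    """
    z = seq.values
    if strategy == "mean_abs":
        return np.abs(z).mean(axis=0)
    if strategy == "mean":
        return z.mean(axis=0)
    if strategy == "std":
        return z.std(axis=0, ddof=1) if z.shape[0] > 1 else np.zeros(z.shape[1])
    raise ValueError(f"unknown dFC-Str strategy {strategy!r}")


class SlidingWindowConnectivity(TransformerMixin, BaseEstimator):
    """Transformer from stacked region time series to stacked dFC sequences.

    Input ``X`` is an array of shape ``(n_runs, T, N)``; output is
    ``(n_runs, W, E)`` of Fisher-z windowed correlations.  Stateless apart
    from bookkeeping attributes set at fit time.
    """

    def __init__(
        self,
        window_samples: int = 55,
        stride_samples: int = 5,
        tr_seconds: float = 0.72,
        edge_normalization: str | None = None,
    ):
        self.window_samples = window_samples
        self.stride_samples = stride_samples
        self.tr_seconds = tr_seconds
        self.edge_normalization = edge_normalization

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.window_samples, self.stride_samples, self.tr_seconds)

    def fit(self, X, y=None):
        X = self._check(X)
        spec = self._spec()
        self.n_nodes_ = X.shape[2]
        self.n_windows_ = window_count(X.shape[1], spec.window_samples, spec.stride_samples)
        self.edge_index_ = edge_indexing(self.n_nodes_)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._check(X)
        spec = self._spec()
        out = []
        for r in range(X.shape[0]):
            ts = RoiTimeSeries(
                values=X[r],
                tr_seconds=spec.tr_seconds,
                node_ids=[f"n{k}" for k in range(X.shape[2])],
                run_id=f"run{r}",
            )
            out.append(sliding_window_dfc(ts, spec).values)
        z = np.stack(out, axis=0)
        if self.edge_normalization is None:
            return z
        if self.edge_normalization == "center":
            # remove each edge's within-run mean: the static baseline goes,
            # the fluctuation amplitude (the dynamics signal) is untouched
            return z - z.mean(axis=1, keepdims=True)
        if self.edge_normalization == "zscore":
            mu = z.mean(axis=1, keepdims=True)
            sd = z.std(axis=1, keepdims=True)
            return (z - mu) / np.where(sd == 0, 1.0, sd)
        raise ValueError(
            f"edge_normalization must be None, 'center' or 'zscore', "
            f"got {self.edge_normalization!r}"
        )

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected X of shape (n_runs, T, N)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X
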