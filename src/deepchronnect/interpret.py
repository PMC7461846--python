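"""Deconvolution-based attribution of conv features back to connection space.

A trained model's convolutional activations are projected back to the input
(edge) space through the transposed filters: for a chosen kernel scale the
pre-activation maps are rectified and each rectified activation map is
distributed back over the input windows and edges it was computed from
(a deconvnet-style reconstruction; pooling and LSTM stages are not part of
the back-projection).  The ``W x E`` reconstruction is averaged over the
window axis to give one signed strength per edge and run.

Group maps average the signed per-subject strengths across subjects *before*
taking absolute values, so edges with inconsistent signs across subjects
cancel.  Downstream summaries: percentile thresholding, intra/inter-network
aggregation, and overlap with the surrogate-based dFC significance set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import ChronnectomeNetwork, conv1d_forward, conv1d_input_gradient
from .dfc import edge_indexing
from .io import NetworkPartition

__all__ = [
    "FeatureWeightMap",
    "deconv_edge_map",
    "group_edge_map",
    "threshold_edges",
    "network_aggregate",
    "overlap_with_significant",
]


@dataclass
class FeatureWeightMap:
    """Per-edge attribution strengths (absolute group means)."""

    strengths: np.ndarray
    scales: tuple[int, ...]
    n_subjects_averaged: int

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.strengths.ndim != 1:
            raise ValueError("strengths must be a vector over edges")
        if np.any(self.strengths < 0):
            raise ValueError("strengths are absolute values and must be >= 0")


def _resolve_net(model) -> ChronnectomeNetwork:
    if isinstance(model, ChronnectomeNetwork):
        return model
    net = getattr(model, "net_", None)
    if net is None:
        raise ValueError("model must be a fitted estimator or a ChronnectomeNetwork")
    return net


def deconv_edge_map(model, dfc: np.ndarray, scale: int) -> np.ndarray:
    """Signed per-edge strength of one run at one conv scale.

    The scale's pre-activations are rectified (unless the network is
    configured linear) and pushed back through the transposed filters; the
    reconstructed ``W x E`` map is averaged over windows.
    """
    net = _resolve_net(model)
    if scale not in net.conv_kernels:
        raise ValueError(f"unknown scale {scale}; model has {net.conv_kernels}")
    x = np.asarray(dfc, dtype=net.dtype)
    if x.ndim != 2:
        raise ValueError("dfc must be a single (W, E) sequence")
    if x.shape[1] != net.n_edges:
        raise ValueError(f"{x.shape[1]} edges, model expects {net.n_edges}")
    z, _ = conv1d_forward(x[None], net.params[f"conv{scale}_w"],
                          net.params[f"conv{scale}_b"])
    act = np.maximum(z, 0.0) if net.conv_activation == "relu" else z
    recon = conv1d_input_gradient(act, net.params[f"conv{scale}_w"], x[None].shape)
    return recon[0].mean(axis=0).astype(float)


def group_edge_map(model, subject_runs: list[list[np.ndarray]],
                   scale: int | str = "mean") -> FeatureWeightMap:
    """Group-level attribution: |mean over subjects| of signed subject maps.

    ``subject_runs`` holds one list of (W, E) dFC sequences per subject; a
    subject's signed map at one scale is the mean over its runs.  For a
    single kernel ``scale`` the group strength is the absolute value of the
    across-subject mean.  With ``scale="mean"`` the per-scale group maps
    are first normalized to unit L2 norm and then averaged — the scales'
    reconstructions live on incommensurate magnitude scales, so an
    unnormalized average would be dominated by whichever scale happens to
    produce the largest activations.
    """
    net = _resolve_net(model)
    scales = net.conv_kernels if scale == "mean" else (int(scale),)
    per_scale_group = []
    for s in scales:
        subject_maps = []
        for runs in subject_runs:
            if not runs:
                raise ValueError("every subject needs at least one run")
            subject_maps.append(
                np.mean([deconv_edge_map(net, r, s) for r in runs], axis=0)
            )
        per_scale_group.append(np.abs(np.mean(subject_maps, axis=0)))
    if len(per_scale_group) == 1:
        strengths = per_scale_group[0]
    else:
        norms = [np.linalg.norm(g) or 1.0 for g in per_scale_group]
        strengths = np.mean([g / n for g, n in zip(per_scale_group, norms)], axis=0)
    return FeatureWeightMap(
        strengths=strengths,
        scales=tuple(scales),
        n_subjects_averaged=len(subject_runs),
    )


def threshold_edges(weight_map: FeatureWeightMap | np.ndarray,
                    percentile: float = 75.0) -> np.ndarray:
    """Boolean mask of edges strictly above the given percentile of strengths."""
    strengths = (weight_map.strengths if isinstance(weight_map, FeatureWeightMap)
                 else np.asarray(weight_map, dtype=float))
    if strengths.size == 0:
        raise ValueError("empty weight map")
    cut = np.percentile(strengths, percentile)
    return strengths > cut


def network_aggregate(weight_map: FeatureWeightMap | np.ndarray,
                      partition: NetworkPartition,
                      node_ids: list[str]) -> pd.DataFrame:
    """Mean strength per network pair, computed without thresholding.

    Cell (a, b) is the mean over all edges with one endpoint in network a
    and the other in b; the diagonal holds intra-network means.  A network
    with fewer than two nodes has no intra-network edges and gets NaN.
    """
    strengths = (weight_map.strengths if isinstance(weight_map, FeatureWeightMap)
                 else np.asarray(weight_map, dtype=float))
    labels = partition.labels_for(node_ids)
    n_nodes = len(node_ids)
    edges = edge_indexing(n_nodes)
    if len(edges) != strengths.size:
        raise ValueError(
            f"{strengths.size} strengths for {len(edges)} edges of {n_nodes} nodes"
        )
    nets = partition.network_labels
    sums = {(a, b): [] for ai, a in enumerate(nets) for b in nets[ai:]}
    for (i, j), w in zip(edges, strengths):
        a, b = sorted((labels[i], labels[j]), key=nets.index)
        sums[(a, b)].append(w)
    mat = pd.DataFrame(np.nan, index=nets, columns=nets, dtype=float)
    for (a, b), vals in sums.items():
        if vals:
            m = float(np.mean(vals))
            mat.loc[a, b] = m
            mat.loc[b, a] = m
    return mat


def overlap_with_significant(weight_map: FeatureWeightMap | np.ndarray,
                             significant: np.ndarray,
                             percentile: float = 75.0) -> dict:
    """Overlap between high-weight edges and edges with significant dFC.

    Returns the weight distributions for significant and non-significant
    edges and the fraction of significant edges whose weight lies strictly
    above the percentile threshold of all weights.
    """
    strengths = (weight_map.strengths if isinstance(weight_map, FeatureWeightMap)
                 else np.asarray(weight_map, dtype=float))
    significant = np.asarray(significant, dtype=bool)
    if significant.shape != strengths.shape:
        raise ValueError("significance mask length does not match edge count")
    above = threshold_edges(strengths, percentile)
    n_sig = int(significant.sum())
    fraction = float((above & significant).sum() / n_sig) if n_sig else np.nan
    return {
        "weights_significant": strengths[significant],
        "weights_nonsignificant": strengths[~significant],
        "fraction_significant_above_threshold": fraction,
        "n_significant": n_sig,
        "threshold_percentile": float(percentile),
    }
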