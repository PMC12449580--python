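"""Between-network similarity: profile distances, PCA, shared structure.

Network profiles live on wildly different scales (counts vs. fractions), so
metrics are z-scored across networks before Euclidean distance / PCA by
default; raw mode is retained for sensitivity analysis.  Shared edges between
two networks require the same unordered node pair *and* the same association
sign — an association that flips sign is not the same association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError, ValidationError
from .inference import AssociationNetwork
from .netmetrics import PROFILE_FIELDS, NetworkProfile
from .stats import OrdinationResult

logger = logging.getLogger(__name__)


@dataclass
class ProfileDistanceMatrix:
    labels: list[str]
    values: np.ndarray
    standardization: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-9) or not np.allclose(np.diag(v), 0, atol=1e-9):
            raise ValidationError("profile distance matrix must be symmetric with zero diagonal")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class SharedStructure:
    pair: tuple[str, str]
    shared_nodes: set[str]
    shared_edges: set[tuple[str, str]]  # unordered pairs with matching sign

    def __post_init__(self) -> None:
        endpoints = {v for e in self.shared_edges for v in e}
        if not endpoints <= self.shared_nodes:
            raise ValidationError("shared edge endpoints must be shared nodes")


def _profile_matrix(profiles: dict[str, NetworkProfile]) -> tuple[list[str], np.ndarray]:
    labels = list(profiles)
    mat = np.vstack([profiles[l].as_vector() for l in labels])
    if not np.all(np.isfinite(mat)):
        raise ValidationError("profiles contain non-finite entries")
    return labels, mat


def _standardize_profiles(mat: np.ndarray, standardize: str) -> tuple[np.ndarray, list[int]]:
    if standardize == "none":
        return mat, list(range(mat.shape[1]))
    if standardize != "zscore":
        raise ParameterError("standardize must be 'zscore' or 'none'")
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)  # population SD, matching the PCA standardization
    keep = np.flatnonzero(sd > 0)
    dropped = [PROFILE_FIELDS[i] for i in np.flatnonzero(sd == 0)]
    if dropped:
        logger.warning("dropping zero-variance metrics: %s", dropped)
    z = (mat[:, keep] - mu[keep]) / sd[keep]
    return z, list(keep)


def profile_distance(
    profiles: dict[str, NetworkProfile], standardize: str = "zscore"
) -> ProfileDistanceMatrix:
    """Pairwise Euclidean distance between network profiles after per-metric
    z-scoring across networks (zero-variance metrics dropped with a warning)."""
    labels, mat = _profile_matrix(profiles)
    if len(labels) < 2:
        raise ParameterError("need at least 2 profiles")
    z, _ = _standardize_profiles(mat, standardize)
    d = squareform(pdist(z, metric="euclidean"))
    return ProfileDistanceMatrix(labels, d, standardize)


def profile_pca(
    profiles: dict[str, NetworkProfile], standardize: str = "zscore"
) -> OrdinationResult:
    """Principal components of the standardized profile matrix.

    All components up to the matrix rank are retained, so pairwise Euclidean
    distances between scores reproduce :func:`profile_distance` exactly.
    """
    labels, mat = _profile_matrix(profiles)
    if len(labels) < 3:
        raise ParameterError("need at least 3 profiles for PCA")
    z, _ = _standardize_profiles(mat, standardize)
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    scores = u * s
    n = len(labels)
    evals = s**2 / (n - 1)
    total = evals.sum()
    prop = evals / total if total > 0 else np.zeros_like(evals)
    return OrdinationResult(labels, scores, evals, prop)


def shared_structure(g1: AssociationNetwork, g2: AssociationNetwork) -> SharedStructure:
    """Nodes and sign-matching edges present in both networks."""
    nodes1, nodes2 = set(g1.nodes.index), set(g2.nodes.index)
    shared_nodes = nodes1 & nodes2
    signed1 = {(a, b): s for a, b, s in g1.signed_edge_set()}
    signed2 = {(a, b): s for a, b, s in g2.signed_edge_set()}
    shared_edges = {
        pair for pair, s in signed1.items() if signed2.get(pair) == s
    }
    return SharedStructure(
        pair=("network_1", "network_2"),
        shared_nodes=shared_nodes,
        shared_edges=shared_edges,
    )


def shared_structure_report(networks: dict[str, AssociationNetwork]) -> pd.DataFrame:
    """All-pairs shared node/edge counts, TSV-ready."""
    labels = list(networks)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ss = shared_structure(networks[labels[i]], networks[labels[j]])
            rows.append(
                {
                    "network_a": labels[i],
                    "network_b": labels[j],
                    "shared_nodes": len(ss.shared_nodes),
                    "shared_edges": len(ss.shared_edges),
                }
            )
    return pd.DataFrame(rows, columns=["network_a", "network_b", "shared_nodes", "shared_edges"])
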