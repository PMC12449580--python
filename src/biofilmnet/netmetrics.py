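"""Node- and network-level metrics, module detection and hub classification.

All topological metrics are computed on the unweighted graph; edge weights
enter only through the mean absolute weight and the negative-edge fraction.
Node roles follow the canonical within-module degree z-score (Zi) versus
participation coefficient (Pi) scheme: network hubs are high in both, module
hubs high only in Zi, connectors high only in Pi, the rest peripheral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ParameterError, ValidationError
from .inference import AssociationNetwork

logger = logging.getLogger(__name__)

PROFILE_FIELDS = (
    "n_nodes",
    "n_edges",
    "edge_density",
    "mean_degree",
    "mean_betweenness",
    "transitivity",
    "modularity_Q",
    "natural_connectivity",
    "prop_negative_edges",
    "mean_abs_weight",
)


def _as_graph(g) -> nx.Graph:
    if isinstance(g, AssociationNetwork):
        return g.to_networkx()
    if isinstance(g, nx.Graph):
        return g
    raise ParameterError("expected an AssociationNetwork or networkx Graph")


@dataclass
class ModulePartition:
    assignment: dict  # node -> module id
    Q: float
    method: str
    seed: int | None

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-9 <= self.Q <= 1.0 + 1e-9):
            raise ValidationError(f"modularity Q={self.Q} outside [-0.5, 1]")

    def modules(self) -> dict:
        out: dict = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out


@dataclass
class NetworkProfile:
    """Fixed-order vector of network-level metrics for Euclidean comparison."""

    n_nodes: float
    n_edges: float
    edge_density: float
    mean_degree: float
    mean_betweenness: float
    transitivity: float
    modularity_Q: float
    natural_connectivity: float
    prop_negative_edges: float
    mean_abs_weight: float

    def as_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in PROFILE_FIELDS})

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS], dtype=float)


# ---------------------------------------------------------------------------
# Basic metrics
# ---------------------------------------------------------------------------


def basic_metrics(g) -> dict:
    """Degree/density/betweenness/transitivity and weight summaries.

    Betweenness is the normalized unweighted-shortest-path centrality averaged
    over nodes; transitivity is the global clustering coefficient
    3 * triangles / connected triples.
    """
    G = _as_graph(g)
    n, e = G.number_of_nodes(), G.number_of_edges()
    if n < 1:
        raise ParameterError("graph needs at least one node")
    weights = [d.get("weight", np.nan) for _, _, d in G.edges(data=True)]
    signs = [d.get("sign") for _, _, d in G.edges(data=True)]
    n_neg = sum(1 for s, w in zip(signs, weights) if (s == "-") or (s is None and w < 0))
    bc = nx.betweenness_centrality(G, normalized=True)
    return {
        "n_nodes": float(n),
        "n_edges": float(e),
        "edge_density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "mean_degree": 2.0 * e / n,
        "mean_betweenness": float(np.mean(list(bc.values()))),
        "transitivity": float(nx.transitivity(G)),
        "prop_negative_edges": (n_neg / e) if e else 0.0,
        "mean_abs_weight": float(np.mean(np.abs(weights))) if e and np.all(np.isfinite(weights)) else 0.0,
    }


def natural_connectivity(g) -> float:
    """Spectral robustness: ln of the average eigenvalue exponential of the
    unweighted adjacency matrix.  Zero for an edgeless graph; strictly
    increases whenever an edge is added."""
    G = _as_graph(g)
    n = G.number_of_nodes()
    if n < 1:
        raise ParameterError("graph needs at least one node")
    a = nx.to_numpy_array(G, weight=None)
    evals = np.linalg.eigvalsh(a)
    return float(logsumexp(evals) - np.log(n))


# ---------------------------------------------------------------------------
# Modules and roles
# ---------------------------------------------------------------------------


def modularity(G: nx.Graph, communities) -> float:
    """Unweighted Newman-Girvan modularity of a partition."""
    return nx.community.modularity(G, communities, weight=None)


def detect_modules(g, n_restarts: int = 10, seed: int | None = None) -> ModulePartition:
    """Greedy (Louvain-style) modularity maximisation, best of ``n_restarts``.

    Deterministic under a fixed seed.  An edgeless graph is one module with
    Q = 0 by convention.
    """
    G = _as_graph(g)
    if G.number_of_nodes() == 0:
        raise ParameterError("graph needs at least one node")
    nodes = sorted(G.nodes())
    if G.number_of_edges() == 0:
        return ModulePartition({v: 0 for v in nodes}, 0.0, "louvain", seed)
    rng = np.random.default_rng(seed)
    best_q, best_comms = -np.inf, None
    for _ in range(max(1, n_restarts)):
        comms = nx.community.louvain_communities(
            G, weight=None, seed=int(rng.integers(2**31))
        )
        q = modularity(G, comms)
        if q > best_q:
            best_q, best_comms = q, comms
    # stable module ids: order modules by their smallest member
    ordered = sorted((sorted(c) for c in best_comms), key=lambda c: c[0])
    assignment = {v: i for i, c in enumerate(ordered) for v in c}
    return ModulePartition(assignment, float(best_q), "louvain", seed)


def zi_pi(
    g,
    partition: ModulePartition,
    z_thresh: float = 2.5,
    p_thresh: float = 0.62,
) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardises a node's within-module degree against the other members
    of its module (population SD; Zi = 0 when the SD is zero).  Pi is
    1 - sum over modules of (k_i,m / k_i)^2, zero for isolated nodes.  Roles:
    network_hub (Zi and Pi high), module_hub (Zi only), connector (Pi only),
    else peripheral.
    """
    G = _as_graph(g)
    nodes = sorted(G.nodes())
    missing = [v for v in nodes if v not in partition.assignment]
    if missing:
        raise ValidationError(f"partition does not cover nodes: {missing[:5]}")
    mod_of = partition.assignment
    deg = dict(G.degree())

    within = {}
    k_by_mod = {}
    for v in nodes:
        counts: dict = {}
        for u in G.neighbors(v):
            counts[mod_of[u]] = counts.get(mod_of[u], 0) + 1
        k_by_mod[v] = counts
        within[v] = counts.get(mod_of[v], 0)

    z = {}
    for mod, members in partition.modules().items():
        vals = np.array([within[v] for v in sorted(members) if v in deg])
        mu, sd = vals.mean(), vals.std()
        for v in members:
            z[v] = (within[v] - mu) / sd if sd > 0 else 0.0

    rows = []
    bc = nx.betweenness_centrality(G, normalized=True)
    for v in nodes:
        k = deg[v]
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in k_by_mod[v].values())
        zi = z[v]
        if zi >= z_thresh and pi >= p_thresh:
            role = "network_hub"
        elif zi >= z_thresh:
            role = "module_hub"
        elif pi >= p_thresh:
            role = "connector"
        else:
            role = "peripheral"
        rows.append(
            {
                "node": v,
                "degree": k,
                "betweenness": float(bc[v]),
                "Zi": float(zi),
                "Pi": float(pi),
                "role": role,
                "module_id": mod_of[v],
            }
        )
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------


def profile(g, n_restarts: int = 10, seed: int | None = None) -> NetworkProfile:
    """Assemble all network-level metrics into the fixed-order profile."""
    G = _as_graph(g)
    base = basic_metrics(G)
    if G.number_of_edges() > 0:
        q = detect_modules(G, n_restarts=n_restarts, seed=seed).Q
    else:
        q = 0.0
    return NetworkProfile(
        n_nodes=base["n_nodes"],
        n_edges=base["n_edges"],
        edge_density=base["edge_density"],
        mean_degree=base["mean_degree"],
        mean_betweenness=base["mean_betweenness"],
        transitivity=base["transitivity"],
        modularity_Q=float(q),
        natural_connectivity=natural_connectivity(G),
        prop_negative_edges=base["prop_negative_edges"],
        mean_abs_weight=base["mean_abs_weight"],
    )


def node_role_report(g, n_restarts: int = 10, seed: int | None = None, **thresholds) -> pd.DataFrame:
    """Module detection plus Zi-Pi role table in one call."""
    part = detect_modules(g, n_restarts=n_restarts, seed=seed)
    return zi_pi(g, part, **thresholds)
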