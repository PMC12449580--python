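"""Compositionally robust sparse association network inference.

The pipeline mirrors the Meinshausen-Buhlmann flavour of SPIEC-EASI-style
inference: filter rare features, centre-log-ratio transform the counts,
estimate each feature's conditional neighbourhood by L1-penalised regression
along a regularisation path, pick the penalty by StARS stability selection on
random subsamples, and symmetrise the selected coefficient matrix into a
signed, weighted, undirected association network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .errors import EmptyResultError, ParameterError, ValidationError
from .tables_io import CountTable, FeatureTaxonomy

logger = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    """Centred log-ratio transformed abundances; every row sums to zero."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError("CLR matrix shape does not match IDs")
        if not np.all(np.isfinite(v)):
            raise ValidationError("CLR matrix has non-finite entries")
        if np.abs(v.sum(axis=1)).max() > 1e-9:
            raise ValidationError("CLR rows must sum to zero")
        self.values = v


@dataclass
class StarsResult:
    lambda_path: np.ndarray
    instability_path: np.ndarray  # monotonized D(lambda), sparsest end first
    raw_instability_path: np.ndarray
    selected_index: int
    lambda_selected: float
    instability_at_selection: float
    edge_stability: np.ndarray  # p x p edge frequencies at the selected lambda


@dataclass
class AssociationNetwork:
    """Signed weighted undirected graph over features, with inference provenance."""

    nodes: pd.DataFrame  # index feature_id; columns domain_class, mean_rel_abundance
    edges: pd.DataFrame  # columns source, target, weight, sign, stability
    lambda_selected: float
    instability_at_selection: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["source"] == e["target"]).any():
                raise ValidationError("self-edges are not allowed")
            if (e["weight"] == 0).any():
                raise ValidationError("zero-weight edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((s, t)))
            for s, t in zip(self.edges["source"], self.edges["target"])
        }

    def signed_edge_set(self) -> set[tuple[str, str, str]]:
        return {
            (*sorted((s, t)), sg)
            for s, t, sg in zip(self.edges["source"], self.edges["target"], self.edges["sign"])
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for fid, row in self.nodes.iterrows():
            g.add_node(fid, **row.to_dict())
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["source"],
                row["target"],
                weight=float(row["weight"]),
                sign=row["sign"],
                stability=float(row["stability"]),
            )
        return g

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_nodes(self, path) -> None:
        df = self.nodes.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


# ---------------------------------------------------------------------------
# Filtering and transformation
# ---------------------------------------------------------------------------


def wmc_filter(
    t: CountTable,
    min_total_reads: int = 3,
    min_mean_rel_abund: float = 0.0025,
    mode: str = "mean",
) -> CountTable:
    """Whole-microbial-community filter before network inference.

    Keeps features with at least ``min_total_reads`` reads in total and a
    relative abundance of at least ``min_mean_rel_abund`` — averaged across
    samples by default (``mode="mean"``), or required in every sample
    (``mode="min"``).
    """
    if mode not in ("mean", "min"):
        raise ParameterError("mode must be 'mean' or 'min'")
    totals = t.counts.sum(axis=0)
    rel = t.relative_abundance()
    stat = rel.mean(axis=0) if mode == "mean" else rel.min(axis=0)
    keep = (totals >= min_total_reads) & (stat >= min_mean_rel_abund)
    if keep.sum() < 3:
        raise EmptyResultError(
            f"only {int(keep.sum())} features survive the WMC filter; "
            "need at least 3 for a meaningful network"
        )
    kept = [f for f, k in zip(t.feature_ids, keep) if k]
    return t.select_features(kept)


def clr_transform(t: CountTable | np.ndarray, pseudocount: float = 1.0) -> ClrMatrix:
    """Centre-log-ratio transform: ln((x + pc) / g) with g the geometric mean
    of the pseudocounted row."""
    if isinstance(t, CountTable):
        mat, sids, fids = t.counts.astype(float), list(t.sample_ids), list(t.feature_ids)
    else:
        mat = np.asarray(t, dtype=float)
        sids = [str(i) for i in range(mat.shape[0])]
        fids = [str(j) for j in range(mat.shape[1])]
    if (mat < 0).any():
        raise ValidationError("abundances must be non-negative")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    if pseudocount == 0 and (mat == 0).any():
        raise ParameterError("pseudocount must be positive when zeros are present")
    x = mat + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(sids, fids, clr, pseudocount)


# ---------------------------------------------------------------------------
# Neighbourhood selection
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def lambda_max(values: np.ndarray) -> float:
    """Smallest penalty at which every neighbourhood regression is empty:
    max absolute cross-product / n over standardized column pairs."""
    x = _standardize(np.asarray(values, dtype=float))
    n = x.shape[0]
    g = np.abs(x.T @ x) / n
    np.fill_diagonal(g, 0.0)
    return float(g.max())


def default_lambda_path(values: np.ndarray, n_lambda: int = 30, ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty path from lambda_max to ratio*lambda_max."""
    lmax = lambda_max(values)
    if lmax <= 0:
        raise ParameterError("degenerate data: lambda_max is zero")
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _neighborhood_paths(x: np.ndarray, lambdas: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    """Coefficient matrices along the path.

    Returns B with shape (n_lambda, p, p); B[l, j, k] is the coefficient of
    feature k in the penalised regression of feature j at lambdas[l].
    """
    n, p = x.shape
    out = np.zeros((len(lambdas), p, p))
    others = np.arange(p)
    with warnings.catch_warnings():
        # the densest (smallest-penalty) end of the path may stop at max_iter;
        # those solutions are only used for instability estimates, never
        # selected when the stability criterion is active
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for j in range(p):
            mask = others != j
            # lasso_path requires decreasing alphas and returns them as given
            _, coefs, _ = lasso_path(
                x[:, mask], x[:, j], alphas=lambdas, max_iter=2000, tol=tol
            )
            out[:, j, mask] = coefs.T
    return out


def neighborhood_lasso(c: ClrMatrix, lam: float) -> np.ndarray:
    """Sparse conditional-neighbourhood estimate at a single penalty.

    Each (internally standardized) feature column is regressed on all others
    with an L1 penalty; returns the directed coefficient matrix B with
    B[j, k] the coefficient of feature k in feature j's regression.
    """
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    x = _standardize(c.values)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in CLR matrix")
    if x.shape[0] < 4:
        raise ParameterError("need at least 4 samples")
    # tight tolerance here: this single-penalty refit defines the reported
    # network, unlike the subsampled path fits used only for stability
    return _neighborhood_paths(x, np.array([lam]), tol=1e-10)[0]


def _edge_indicator(b: np.ndarray, rule: str, tol: float = 1e-10) -> np.ndarray:
    nz = np.abs(b) > tol
    return (nz | nz.T) if rule == "or" else (nz & nz.T)


def edge_instability(theta: np.ndarray) -> np.ndarray:
    """Per-edge StARS instability 2 * theta * (1 - theta) from cross-subsample
    edge frequencies theta."""
    return 2.0 * theta * (1.0 - theta)


def stars_subsample_size(n: int) -> int:
    """StARS recommendation floor(10 sqrt(n)), capped at 80% of n for the
    small group sizes typical of replicated field designs."""
    return max(4, min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n))))


def stars_select(
    c: ClrMatrix,
    lambda_path: np.ndarray | None = None,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    beta_threshold: float = 0.05,
    rule: str = "or",
    seed: int | None = None,
) -> StarsResult:
    """Stability approach to regularisation selection.

    Infers neighbourhood graphs on ``n_subsamples`` random subsamples (drawn
    without replacement) for every penalty on the path, measures total edge
    instability D(lambda) = mean over feature pairs of 2 theta (1 - theta),
    monotonises D from the sparsest end, and selects the smallest penalty
    (densest graph) whose monotonised instability stays at or below
    ``beta_threshold``.  If no penalty qualifies, the sparsest one is returned
    with a warning.
    """
    x = c.values
    n, p = x.shape
    if lambda_path is None:
        lambda_path = default_lambda_path(x)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if len(lambda_path) < 2:
        raise ParameterError("lambda path needs at least 2 values")
    if np.any(np.diff(lambda_path) >= 0):
        raise ParameterError("lambda path must be strictly descending")
    if subsample_size is None:
        subsample_size = stars_subsample_size(n)
    if subsample_size < 4 or subsample_size > n:
        raise ParameterError("subsample size out of range")

    rng = np.random.default_rng(seed)
    n_lam = len(lambda_path)
    freq = np.zeros((n_lam, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        xs = _standardize(x[idx])
        b = _neighborhood_paths(xs, lambda_path)
        for l in range(n_lam):
            freq[l] += _edge_indicator(b[l], rule)
    theta = freq / n_subsamples

    iu = np.triu_indices(p, k=1)
    d_raw = np.array([edge_instability(theta[l])[iu].mean() for l in range(n_lam)])
    d_mono = np.maximum.accumulate(d_raw)  # sparsest (largest lambda) end first

    ok = np.flatnonzero(d_mono <= beta_threshold)
    if len(ok):
        sel = int(ok[-1])  # smallest qualifying lambda = densest graph
    else:
        sel = 0
        logger.warning(
            "no penalty reaches instability <= %.3g (min %.3g); selecting sparsest",
            beta_threshold,
            float(d_mono.min()),
        )
    return StarsResult(
        lambda_path=lambda_path,
        instability_path=d_mono,
        raw_instability_path=d_raw,
        selected_index=sel,
        lambda_selected=float(lambda_path[sel]),
        instability_at_selection=float(d_mono[sel]),
        edge_stability=theta[sel],
    )


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def build_network(
    c: ClrMatrix,
    b: np.ndarray,
    rule: str = "or",
    stability: np.ndarray | None = None,
    lambda_selected: float = float("nan"),
    instability_at_selection: float = float("nan"),
    taxonomy: FeatureTaxonomy | None = None,
    rel_abundance: np.ndarray | None = None,
    params: dict | None = None,
) -> AssociationNetwork:
    """Symmetrise a coefficient matrix into a signed weighted network.

    An edge (j, k) exists when either directed coefficient is nonzero (OR
    rule, default) or when both are (AND).  Agreeing coefficients are averaged
    into the edge weight; sign conflicts are resolved by keeping the
    larger-magnitude coefficient, and counted in the log.
    """
    if rule not in ("or", "and"):
        raise ParameterError("rule must be 'or' or 'and'")
    p = len(c.feature_ids)
    if b.shape != (p, p):
        raise ValidationError("coefficient matrix shape mismatch")
    ind = _edge_indicator(b, rule)
    rows = []
    conflicts = 0
    for j in range(p):
        for k in range(j + 1, p):
            if not ind[j, k]:
                continue
            bjk, bkj = b[j, k], b[k, j]
            if bjk * bkj < 0:
                conflicts += 1
                w = bjk if abs(bjk) >= abs(bkj) else bkj
            else:
                w = 0.5 * (bjk + bkj)
            if w == 0:
                continue
            rows.append(
                {
                    "source": c.feature_ids[j],
                    "target": c.feature_ids[k],
                    "weight": float(w),
                    "sign": "+" if w > 0 else "-",
                    "stability": float(stability[j, k]) if stability is not None else np.nan,
                }
            )
    if conflicts:
        logger.info("resolved %d sign-conflicting coefficient pairs", conflicts)
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "stability"])

    if rel_abundance is None:
        rel_abundance = np.full(p, np.nan)
    domains = []
    for f in c.feature_ids:
        if taxonomy is not None and f in taxonomy.frame.index:
            domains.append(str(taxonomy.frame.loc[f, "domain_class"]))
        else:
            domains.append("unknown")
    nodes = pd.DataFrame(
        {"domain_class": domains, "mean_rel_abundance": rel_abundance},
        index=pd.Index(list(c.feature_ids), name="feature_id"),
    )
    return AssociationNetwork(
        nodes=nodes,
        edges=edges,
        lambda_selected=lambda_selected,
        instability_at_selection=instability_at_selection,
        params=params or {},
    )


def infer_association_network(
    t: CountTable,
    taxonomy: FeatureTaxonomy | None = None,
    apply_wmc_filter: bool = True,
    min_total_reads: int = 3,
    min_mean_rel_abund: float = 0.0025,
    pseudocount: float = 1.0,
    lambda_path: np.ndarray | None = None,
    n_lambda: int = 30,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    beta_threshold: float = 0.05,
    rule: str = "or",
    seed: int | None = None,
) -> AssociationNetwork:
    """End-to-end inference on one sample group: WMC filter, CLR, StARS
    selection on the penalty path, refit on the full data at the selected
    penalty, and symmetrisation."""
    if apply_wmc_filter:
        t = wmc_filter(t, min_total_reads, min_mean_rel_abund)
    c = clr_transform(t, pseudocount)
    if lambda_path is None:
        lambda_path = default_lambda_path(c.values, n_lambda=n_lambda)
    stars = stars_select(
        c,
        lambda_path=lambda_path,
        n_subsamples=n_subsamples,
        subsample_size=subsample_size,
        beta_threshold=beta_threshold,
        rule=rule,
        seed=seed,
    )
    b = neighborhood_lasso(c, stars.lambda_selected)
    rel = t.relative_abundance().mean(axis=0)
    return build_network(
        c,
        b,
        rule=rule,
        stability=stars.edge_stability,
        lambda_selected=stars.lambda_selected,
        instability_at_selection=stars.instability_at_selection,
        taxonomy=taxonomy,
        rel_abundance=rel,
        params={
            "n_subsamples": n_subsamples,
            "subsample_size": subsample_size or stars_subsample_size(t.n_samples),
            "n_lambda": len(lambda_path),
            "beta_threshold": beta_threshold,
            "rule": rule,
            "pseudocount": pseudocount,
        },
    )


def f1_score_edges(
    predicted: set[tuple[str, str]], truth: set[tuple[str, str]]
) -> float:
    """F1 of an edge set against ground truth (pairs in either order)."""
    pred = {tuple(sorted(e)) for e in predicted}
    true = {tuple(sorted(e)) for e in truth}
    tp = len(pred & true)
    if tp == 0:
        return 0.0
    precision = tp / len(pred)
    recall = tp / len(true)
    return 2 * precision * recall / (precision + recall)
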