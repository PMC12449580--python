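"""Synthetic grouped compositional count data with known association structure.

The generator emulates an in-situ host/substrate amplicon study: three host
treatments sampled on two substrates (the seaweed surface itself and an inert
proxy-biofilm filter placed next to it), plus control filters and ambient
seawater, at two timepoints with a handful of replicates each.

Counts follow a logistic-normal-multinomial model: latent log-abundances are
multivariate normal with covariance derived from a known sparse conditional
dependence graph (the ground truth for network-inference benchmarks), group
effects enter as log-scale mean shifts, sequencing depths are log-normal, and
the observed counts are multinomial draws of those depths.  Presence/absence
structure (planted cores, host-specific taxa, background prevalence) is
imposed by structural zeros applied to the composition before the multinomial
draw, because multinomial sampling alone can never guarantee absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tables_io import CountTable, FeatureTaxonomy, SampleMetadata

logger = logging.getLogger(__name__)

TOPOLOGIES = ("band", "cluster", "scale_free", "hub")

HOSTS = ("gracilaria", "fucus_serratus", "fucus_vesiculosus")

# log-scale enrichment for planted core / host-specific taxa inside their own
# groups; the baseline log-mean of a planted feature is floored at zero before
# the boost so that group-level shifts can never silence it below the read
# detection thresholds
PLANTED_BOOST = 3.0


def feature_ids(n_features: int) -> list[str]:
    return [f"ASV{i + 1:04d}" for i in range(n_features)]


# ---------------------------------------------------------------------------
# Ground-truth graphs
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthGraph:
    """Sparse signed conditional-dependence graph over features.

    ``edges`` maps ordered index pairs (i < j) to signed partial-correlation
    values.  The implied precision matrix is made strictly diagonally dominant
    (hence positive definite) and rescaled to unit diagonal; the sign of each
    planted partial correlation is preserved.
    """

    n_features: int
    edges: dict[tuple[int, int], float]
    topology: str

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i == j:
                raise ParameterError("self-edges are not allowed")
            if not (0 <= i < j < self.n_features):
                raise ParameterError(f"edge ({i},{j}) out of range / not ordered")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def precision_matrix(self) -> np.ndarray:
        p = self.n_features
        omega = np.eye(p)
        for (i, j), v in self.edges.items():
            omega[i, j] = omega[j, i] = -v  # partial corr sign(v) = -sign(omega_ij)
        # guarantee positive definiteness with the smallest diagonal shift that
        # leaves a safety margin; planted partial correlations are preserved up
        # to the final unit-diagonal rescale
        lam_min = float(np.linalg.eigvalsh(omega).min())
        if lam_min < 0.05:
            omega[np.diag_indices(p)] += 0.05 - lam_min
        d = 1.0 / np.sqrt(np.diag(omega))
        return d[:, None] * omega * d[None, :]

    def covariance_matrix(self) -> np.ndarray:
        """Inverse precision, rescaled to a correlation matrix."""
        sigma = np.linalg.inv(self.precision_matrix())
        d = 1.0 / np.sqrt(np.diag(sigma))
        return d[:, None] * sigma * d[None, :]


def make_graph(
    n_features: int,
    topology: str = "band",
    density: float = 0.04,
    seed: int = 0,
    bandwidth: int | None = None,
    n_blocks: int = 2,
) -> GroundTruthGraph:
    """Build a ground-truth graph of the requested topology.

    ``density`` is the target fraction of all feature pairs carrying an edge;
    for band graphs an explicit ``bandwidth`` overrides it.  Edge values
    (signed partial correlations) are drawn uniformly from +-[0.15, 0.35],
    which keeps recovery nontrivial but feasible at ~100 samples.
    """
    if n_features < 3:
        raise ParameterError("need at least 3 features")
    if topology not in TOPOLOGIES:
        raise ParameterError(f"unknown topology '{topology}'")
    if not (0 <= density < 1):
        raise ParameterError("density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    max_edges = n_features * (n_features - 1) // 2
    m = int(round(density * max_edges))

    pairs: list[tuple[int, int]] = []
    if topology == "band":
        if bandwidth is not None:
            if bandwidth < 0 or bandwidth >= n_features:
                raise ParameterError("bandwidth out of range")
            pairs = [
                (i, i + off)
                for off in range(1, bandwidth + 1)
                for i in range(n_features - off)
            ]
        else:
            ordered = [
                (i, i + off)
                for off in range(1, n_features)
                for i in range(n_features - off)
            ]
            pairs = ordered[:m]
    elif topology == "cluster":
        if n_blocks < 2 or n_blocks > n_features:
            raise ParameterError("n_blocks incompatible with n_features")
        block = np.arange(n_features) % n_blocks
        within = [
            (i, j)
            for i in range(n_features)
            for j in range(i + 1, n_features)
            if block[i] == block[j]
        ]
        between = [
            (i, j)
            for i in range(n_features)
            for j in range(i + 1, n_features)
            if block[i] != block[j]
        ]
        m_within = min(int(round(0.9 * m)), len(within))
        m_between = min(m - m_within, len(between))
        if m_within + m_between < m:
            raise ParameterError("density too high for cluster topology")
        pairs = [within[k] for k in rng.choice(len(within), m_within, replace=False)]
        pairs += [between[k] for k in rng.choice(len(between), m_between, replace=False)]
    elif topology == "scale_free":
        import networkx as nx

        m_attach = max(0, int(round(m / max(n_features - 1, 1))))
        if m_attach == 0:
            pairs = []
        else:
            if m_attach >= n_features:
                raise ParameterError("density too high for scale_free topology")
            g = nx.barabasi_albert_graph(n_features, m_attach, seed=int(rng.integers(2**31)))
            pairs = [tuple(sorted(e)) for e in g.edges()]
    elif topology == "hub":
        n_hubs = max(1, n_features // 10)
        hubs = list(range(n_hubs))
        others = list(range(n_hubs, n_features))
        all_pairs = [(h, o) for h in hubs for o in others]
        if m > len(all_pairs):
            raise ParameterError("density too high for hub topology")
        idx = rng.choice(len(all_pairs), m, replace=False)
        pairs = [all_pairs[k] for k in sorted(idx)]

    pairs = sorted(set(tuple(sorted(p)) for p in pairs))
    values = rng.uniform(0.15, 0.35, size=len(pairs)) * rng.choice([-1.0, 1.0], size=len(pairs))
    return GroundTruthGraph(n_features, dict(zip(pairs, values)), topology)


def truth_edge_set(graph: GroundTruthGraph) -> set[tuple[str, str]]:
    """Planted edges as ordered feature-ID pairs, for precision/recall scoring."""
    ids = feature_ids(graph.n_features)
    return {(ids[i], ids[j]) for (i, j) in graph.edges}


# ---------------------------------------------------------------------------
# Simulation design
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Everything that defines one simulated study.

    ``core_spec`` maps pooled (treatment, substrate) groups to planted-core
    feature indices (target prevalence ``core_prevalence``); the members of
    ``host_specific_spec`` are present in every sample of their host's seaweed
    and proxy-biofilm groups and structurally absent everywhere else.  When
    ``background_prevalence`` is a (low, high) interval, every other feature
    receives a per-group planted prevalence drawn uniformly from it; ``None``
    disables background dropout entirely (used for network benchmarks).
    """

    groups: list[tuple[str, str, str, int]]  # (treatment, substrate, timepoint, n_replicates)
    depth_mean: float = 20000.0
    depth_dispersion: float = 0.3
    core_spec: Mapping[tuple[str, str], Sequence[int]] = field(default_factory=dict)
    host_specific_spec: Mapping[str, Sequence[int]] = field(default_factory=dict)
    background_prevalence: tuple[float, float] | None = None
    core_prevalence: float = 0.95
    effect_size: float = 1.0
    prokaryote_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for *_rest, n in self.groups):
            raise ParameterError("replicate counts must be >= 1")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ParameterError("invalid depth parameters")
        if not (0 < self.core_prevalence <= 1):
            raise ParameterError("core_prevalence must be in (0, 1]")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        hs_all = [f for feats in self.host_specific_spec.values() for f in feats]
        if len(hs_all) != len(set(hs_all)):
            raise ParameterError("host-specific feature sets must be disjoint")


def study_design(
    seed: int = 0,
    n_features: int = 60,
    n_replicates: int = 6,
    effect_size: float = 1.0,
    core_per_group: int = 3,
    host_specific_per_host: int = 2,
) -> SimulationDesign:
    """The default full factorial design: 3 hosts x {seaweed, proxy biofilm}
    x 2 timepoints, control filters and ambient seawater, with planted cores
    and host-specific taxa."""
    groups: list[tuple[str, str, str, int]] = []
    for tp in ("exp1", "exp2"):
        for host in HOSTS:
            groups.append((host, "seaweed", tp, n_replicates))
            groups.append((host, "proxy_biofilm", tp, n_replicates))
        groups.append(("control", "control_filter", tp, n_replicates))
        groups.append(("ambient", "seawater", tp, 2))

    pooled = [(h, s) for h in HOSTS for s in ("seaweed", "proxy_biofilm")]
    pooled.append(("control", "control_filter"))
    core_spec: dict[tuple[str, str], list[int]] = {}
    nxt = 0
    for grp in pooled:
        core_spec[grp] = list(range(nxt, nxt + core_per_group))
        nxt += core_per_group
    host_specific_spec: dict[str, list[int]] = {}
    for host in HOSTS:
        host_specific_spec[host] = list(range(nxt, nxt + host_specific_per_host))
        nxt += host_specific_per_host
    if nxt > n_features:
        raise ParameterError("n_features too small for planted structure")
    return SimulationDesign(
        groups=groups,
        core_spec=core_spec,
        host_specific_spec=host_specific_spec,
        background_prevalence=(0.3, 0.8),
        effect_size=effect_size,
        seed=seed,
    )


def null_design(
    seed: int = 0,
    n_replicates: int = 6,
    depth_mean: float = 5000.0,
) -> SimulationDesign:
    """Two exchangeable treatment groups with no planted differences
    (effect_size = 0); used for type-I-error calibration."""
    groups = [
        ("gracilaria", "seaweed", "exp1", n_replicates),
        ("fucus_serratus", "seaweed", "exp1", n_replicates),
    ]
    return SimulationDesign(
        groups=groups, depth_mean=depth_mean, effect_size=0.0, seed=seed
    )


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _sample_frame(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for treatment, substrate, timepoint, n_rep in design.groups:
        for r in range(1, n_rep + 1):
            sid = f"{treatment}_{substrate}_{timepoint}_r{r}"
            # bottles pair a seaweed with its proxy filter; panels block bottles
            bottle = f"bottle_{treatment}_{r}" if substrate in ("seaweed", "proxy_biofilm") else f"bottle_{treatment}_{substrate}_{r}"
            panel = f"P{(r - 1) % 12 + 1}"
            rows.append(
                {
                    "sample_id": sid,
                    "treatment": treatment,
                    "substrate": substrate,
                    "timepoint": timepoint,
                    "panel": panel,
                    "bottle": bottle,
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.has_duplicates:
        raise ParameterError("design groups produce duplicate sample IDs")
    return df


def _taxonomy(design: SimulationDesign, n_features: int, rng: np.random.Generator) -> FeatureTaxonomy:
    ids = feature_ids(n_features)
    n_prok = int(round(design.prokaryote_fraction * n_features))
    domain = ["prokaryote"] * n_prok + ["microalga"] * (n_features - n_prok)
    phyla = ["Proteobacteria", "Bacteroidota", "Planctomycetota", "Desulfobacterota", "Myxococcota"]
    lineages, copy_numbers = [], []
    for i, d in enumerate(domain):
        if d == "prokaryote":
            ph = phyla[int(rng.integers(len(phyla)))]
            lineages.append(f"Bacteria;{ph};SynClass{i % 7};SynOrder{i % 11};SynFam{i % 13};SynGenus{i}")
            copy_numbers.append(float(rng.integers(1, 9)))
        else:
            lineages.append(f"Eukaryota;Bacillariophyta;SynClass{i % 5};SynOrder{i % 7};SynFam{i % 9};SynGenus{i}")
            copy_numbers.append(np.nan)
    frame = pd.DataFrame(
        {"domain_class": domain, "lineage": lineages, "copy_number": copy_numbers},
        index=pd.Index(ids, name="feature_id"),
    )
    return FeatureTaxonomy(frame)


def _presence_mask(
    design: SimulationDesign,
    meta: pd.DataFrame,
    n_features: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Structural presence/absence per (sample, feature)."""
    n = len(meta)
    mask = np.ones((n, n_features), dtype=bool)
    pooled = meta.groupby(["treatment", "substrate"], sort=True).groups
    positions = {sid: k for k, sid in enumerate(meta.index)}

    hs_features = {f for feats in design.host_specific_spec.values() for f in feats}
    for host, feats in sorted(design.host_specific_spec.items()):
        own = [
            positions[s]
            for (t, sub), sids in pooled.items()
            if t == host and sub in ("seaweed", "proxy_biofilm")
            for s in sids
        ]
        for f in feats:
            mask[:, f] = False
            mask[own, f] = True

    for (t, sub), sids in pooled.items():
        rows = np.array([positions[s] for s in sids])
        core = set(design.core_spec.get((t, sub), ()))
        for f in range(n_features):
            if f in hs_features:
                continue
            if f in core:
                n_present = int(round(design.core_prevalence * len(rows)))
            elif design.background_prevalence is not None:
                lo, hi = design.background_prevalence
                n_present = int(round(rng.uniform(lo, hi) * len(rows)))
            else:
                continue
            absent = rng.choice(rows, size=len(rows) - n_present, replace=False)
            mask[absent, f] = False
    return mask


def simulate_counts(
    graph: GroundTruthGraph, design: SimulationDesign
) -> tuple[CountTable, SampleMetadata, FeatureTaxonomy]:
    """Draw a full synthetic dataset from the logistic-normal-multinomial model.

    Fixed ``design.seed`` gives bit-identical output.  Sample totals equal the
    drawn sequencing depths exactly (multinomial conservation).
    """
    p = graph.n_features
    rng = np.random.default_rng(design.seed)
    meta_df = _sample_frame(design)
    tax = _taxonomy(design, p, rng)
    n = len(meta_df)

    base_mu = rng.normal(0.0, 1.0, size=p)
    # group effects: bounded log-scale mean shifts per (treatment, substrate)
    # and timepoint; bounded (uniform) rather than Gaussian so that no single
    # feature can drift into dominating the whole composition
    combos = sorted({(t, s) for t, s, _tp, _n in design.groups})
    tps = sorted({tp for _t, _s, tp, _n in design.groups})
    shift_group = {
        c: design.effect_size * rng.uniform(-1.0, 1.0, size=p) for c in combos
    }
    shift_tp = {
        tp: 0.5 * design.effect_size * rng.uniform(-1.0, 1.0, size=p) for tp in tps
    }

    boost = np.zeros((n, p))
    pos = {sid: k for k, sid in enumerate(meta_df.index)}
    pooled = meta_df.groupby(["treatment", "substrate"], sort=True).groups
    for (t, s), sids in pooled.items():
        rows = [pos[x] for x in sids]
        for f in design.core_spec.get((t, s), ()):
            boost[rows, f] += PLANTED_BOOST
        if t in design.host_specific_spec and s in ("seaweed", "proxy_biofilm"):
            for f in design.host_specific_spec[t]:
                boost[rows, f] += PLANTED_BOOST

    chol = np.linalg.cholesky(graph.covariance_matrix())
    latent = np.empty((n, p))
    for k, sid in enumerate(meta_df.index):
        row = meta_df.loc[sid]
        mu = (
            base_mu
            + shift_group[(row["treatment"], row["substrate"])]
            + shift_tp[row["timepoint"]]
        )
        planted = boost[k] > 0
        mu[planted] = np.maximum(mu[planted], 0.0) + boost[k][planted]
        latent[k] = mu + chol @ rng.standard_normal(p)

    mask = _presence_mask(design, meta_df, p, rng)
    weights = np.exp(latent) * mask
    if (weights.sum(axis=1) == 0).any():
        raise ParameterError("a sample lost all features to structural zeros")
    weights /= weights.sum(axis=1, keepdims=True)

    depths = np.maximum(
        1, np.round(rng.lognormal(np.log(design.depth_mean), design.depth_dispersion, n))
    ).astype(np.int64)
    counts = np.empty((n, p), dtype=np.int64)
    for k in range(n):
        counts[k] = rng.multinomial(depths[k], weights[k])

    table = CountTable(list(meta_df.index), feature_ids(p), counts)
    # CountTable construction may drop zero-total samples; never happens here
    # because depths >= 1, but keep metadata aligned regardless
    meta = SampleMetadata(meta_df.loc[table.sample_ids])
    return table, meta, tax


def write_truth_edges(graph: GroundTruthGraph, path) -> None:
    """Ground-truth edge list as TSV: feature_a, feature_b, sign, value."""
    ids = feature_ids(graph.n_features)
    rows = [
        {
            "feature_a": ids[i],
            "feature_b": ids[j],
            "sign": "+" if v > 0 else "-",
            "value": v,
        }
        for (i, j), v in sorted(graph.edges.items())
    ]
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "sign", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
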