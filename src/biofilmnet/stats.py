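"""Diversity and community-composition statistics.

Shannon diversity, Bray-Curtis dissimilarity, principal coordinates analysis,
PERMANOVA with label permutations (optionally restricted to strata and
optionally exact by full enumeration), the homogeneity-of-dispersion test and
pairwise PERMANOVA with multiplicity correction.

Permutation p-values follow the (1 + b) / (1 + m) convention so that p is
never zero; exact enumeration divides by the number of distinct label
arrangements instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .errors import ParameterError, ValidationError
from .tables_io import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

_MAX_EXACT = 200_000  # refuse exact enumeration beyond this many arrangements


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        self.values = v

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermanovaResult:
    factor: str
    F: float
    R2: float
    p: float
    df_between: int
    df_within: int
    n_perm: int
    p_adj: float | None = None
    comparison: tuple[str, str] | None = None


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # descending
    proportion_explained: np.ndarray


# ---------------------------------------------------------------------------
# Diversity and dissimilarity
# ---------------------------------------------------------------------------


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of one sample."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValidationError("sample total must be positive")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(t: CountTable) -> pd.Series:
    return pd.Series(
        [shannon(row) for row in t.counts], index=t.sample_ids, name="shannon"
    )


def bray_curtis(t: CountTable | np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u,v) = 1 - 2 sum_j min(u_j, v_j) / (sum u + sum v).

    Scale-dependent by definition; apply to relative abundances for a
    depth-invariant version.
    """
    if isinstance(t, CountTable):
        mat, ids = t.counts.astype(float), list(t.sample_ids)
    else:
        mat = np.asarray(t, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(mat))]
    if mat.shape[0] < 2:
        raise ParameterError("need at least 2 samples")
    if (mat.sum(axis=1) <= 0).any():
        raise ValidationError("zero-total sample in Bray-Curtis input")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric MDS: eigen-decomposition of the Gower-centred matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (non-negative) eigenvalues; negative eigenvalues are excluded from the
    coordinate space and from proportion-explained.
    """
    g = _gower_center(d.values)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(evals[0]), 1.0))
    n_pos = int((evals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(np.clip(evals[:n_axes], 0, None))
    pos_sum = evals[:n_pos].sum() if n_pos else 1.0
    prop = evals[:n_axes] / pos_sum if n_pos else np.zeros(0)
    return OrdinationResult(list(d.sample_ids), coords, evals[:n_axes], prop)


# ---------------------------------------------------------------------------
# PERMANOVA machinery
# ---------------------------------------------------------------------------


def _factor_array(m: SampleMetadata, d: DistanceMatrix, factor: str) -> np.ndarray:
    lab = m.factor(factor).reindex(d.sample_ids)
    if lab.isna().any():
        raise ValidationError("distance matrix contains samples missing from metadata")
    return lab.to_numpy(dtype=object)


def _check_groups(labels: np.ndarray) -> list[object]:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ParameterError("factor must have at least 2 levels")
    if (counts < 2).any():
        raise ParameterError("every group needs at least 2 samples")
    return list(uniq)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, groups: list) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def _permute_labels(
    labels: np.ndarray, rng: np.random.Generator, strata: np.ndarray | None
) -> np.ndarray:
    if strata is None:
        return rng.permutation(labels)
    out = labels.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


def _exact_label_arrangements(labels: np.ndarray):
    n_arr = 1
    uniq, counts = np.unique(labels, return_counts=True)
    from math import factorial

    n_arr = factorial(len(labels))
    for c in counts:
        n_arr //= factorial(int(c))
    if n_arr > _MAX_EXACT:
        raise ParameterError(
            f"{n_arr} distinct label arrangements; too many for exact enumeration"
        )
    return (np.asarray(perm, dtype=object) for perm in multiset_permutations(list(labels)))


def permanova(
    d: DistanceMatrix,
    m: SampleMetadata,
    factor: str,
    n_perm: int = 999,
    strata: str | None = None,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    ``method="exact"`` enumerates every distinct assignment of the observed
    labels (only feasible for small designs); otherwise ``n_perm`` random
    label permutations are drawn, optionally restricted within the levels of
    ``strata``.
    """
    labels = _factor_array(m, d, factor)
    groups = _check_groups(labels)
    d2 = d.values**2
    f_obs, r2 = _permanova_stats(d2, labels, groups)
    a, n = len(groups), len(labels)

    if method == "exact":
        if strata is not None:
            raise ParameterError("exact enumeration does not support strata")
        count = total = 0
        for perm in _exact_label_arrangements(labels):
            f_perm, _ = _permanova_stats(d2, perm, groups)
            count += f_perm >= f_obs - 1e-12
            total += 1
        p = count / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        strata_arr = _factor_array(m, d, strata) if strata is not None else None
        hits = 0
        for _ in range(n_perm):
            perm = _permute_labels(labels, rng, strata_arr)
            f_perm, _ = _permanova_stats(d2, perm, groups)
            hits += f_perm >= f_obs - 1e-12
        p = (1 + hits) / (1 + n_perm)

    return PermanovaResult(
        factor=factor,
        F=float(f_obs),
        R2=float(r2),
        p=float(p),
        df_between=a - 1,
        df_within=n - a,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Beta dispersion
# ---------------------------------------------------------------------------


def _dispersion_distances(d: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid in PCoA space.

    Negative-eigenvalue axes contribute with a minus sign (the imaginary-part
    convention): z_i^2 = ||real part||^2 - ||imaginary part||^2, clipped at 0.
    """
    g = _gower_center(d.values)
    evals, evecs = np.linalg.eigh(g)
    tol = 1e-10 * max(abs(evals).max(), 1.0)
    pos, neg = evals > tol, evals < -tol
    cpos = evecs[:, pos] * np.sqrt(evals[pos])
    cneg = evecs[:, neg] * np.sqrt(-evals[neg])
    z = np.empty(len(labels))
    for grp in np.unique(labels):
        idx = np.flatnonzero(labels == grp)
        dp = ((cpos[idx] - cpos[idx].mean(axis=0)) ** 2).sum(axis=1)
        dn = ((cneg[idx] - cneg[idx].mean(axis=0)) ** 2).sum(axis=1) if cneg.size else 0.0
        z[idx] = np.sqrt(np.clip(dp - dn, 0, None))
    return z


def _anova_f(z: np.ndarray, labels: np.ndarray, groups: list) -> float:
    grand = z.mean()
    ssb = ssw = 0.0
    for g in groups:
        zi = z[labels == g]
        ssb += len(zi) * (zi.mean() - grand) ** 2
        ssw += ((zi - zi.mean()) ** 2).sum()
    a, n = len(groups), len(z)
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def beta_dispersion(
    d: DistanceMatrix,
    m: SampleMetadata,
    factor: str,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResult:
    """Homogeneity-of-dispersion test: one-way F on distances to group
    centroids, with a permutation (or exact-enumeration) p-value."""
    labels = _factor_array(m, d, factor)
    groups = _check_groups(labels)
    z = _dispersion_distances(d, labels)
    f_obs = _anova_f(z, labels, groups)

    if method == "exact":
        count = total = 0
        for perm in _exact_label_arrangements(labels):
            count += _anova_f(z, perm, groups) >= f_obs - 1e-12
            total += 1
        p, n_perm = count / total, total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            hits += _anova_f(z, rng.permutation(labels), groups) >= f_obs - 1e-12
        p = (1 + hits) / (1 + n_perm)

    a, n = len(groups), len(labels)
    grand = z.mean()
    ssb = sum(len(z[labels == g]) * (z[labels == g].mean() - grand) ** 2 for g in groups)
    sst = ((z - grand) ** 2).sum()
    return PermanovaResult(
        factor=factor,
        F=float(f_obs),
        R2=float(ssb / sst) if sst > 0 else 0.0,
        p=float(p),
        df_between=a - 1,
        df_within=n - a,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Pairwise comparisons
# ---------------------------------------------------------------------------


def pairwise_permanova(
    d: DistanceMatrix,
    m: SampleMetadata,
    factor: str,
    n_perm: int = 999,
    correction: str = "BH",
    seed: int | None = None,
) -> list[PermanovaResult]:
    """One PERMANOVA per pair of factor levels on the subsetted distance
    matrix, with Benjamini-Hochberg (default) or Bonferroni adjustment."""
    if correction not in ("BH", "bonferroni"):
        raise ParameterError("correction must be 'BH' or 'bonferroni'")
    labels = _factor_array(m, d, factor)
    groups = _check_groups(labels)
    rng = np.random.default_rng(seed)
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pair = (str(groups[i]), str(groups[j]))
            sids = [
                s
                for s, lab in zip(d.sample_ids, labels)
                if lab in (groups[i], groups[j])
            ]
            sub = d.subset(sids)
            res = permanova(
                sub, m, factor, n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            res.comparison = pair
            results.append(res)
    raw = [r.p for r in results]
    method = "fdr_bh" if correction == "BH" else "bonferroni"
    adj = multipletests(raw, method=method)[1]
    for r, pa in zip(results, adj):
        r.p_adj = float(min(pa, 1.0))
    return results


def permanova_report(results: list[PermanovaResult]) -> pd.DataFrame:
    rows = []
    for r in results if isinstance(results, list) else [results]:
        rows.append(
            {
                "factor": r.factor,
                "comparison": "" if r.comparison is None else " vs ".join(r.comparison),
                "df_between": r.df_between,
                "df_within": r.df_within,
                "F": r.F,
                "R2": r.R2,
                "p": r.p,
                "p_adj": "" if r.p_adj is None else r.p_adj,
            }
        )
    return pd.DataFrame(rows)
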