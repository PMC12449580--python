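"""Count-table, taxonomy and metadata I/O.

The universal in-memory currency is :class:`CountTable`, a samples x features
non-negative matrix with ordered, unique sample and feature IDs.  On disk,
count tables are stored either as TSV (features as rows, samples as columns,
first header cell ``#ASV_ID``) or as sparse BIOM v1 JSON.

Sample metadata records the experimental design of a host/substrate study:
each sample carries a treatment (host species or control), a substrate
(seaweed surface, proxy-biofilm filter, control filter or ambient seawater),
a timepoint and the panel/bottle blocks it came from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

SUBSTRATES = ("seaweed", "proxy_biofilm", "control_filter", "seawater")
DOMAIN_CLASSES = ("prokaryote", "microalga")

TSV_HEADER = "#ASV_ID"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for i in ids:
            (dupes if i in seen else seen).add(i)
        raise ValidationError(f"duplicate {what} IDs: {sorted(dupes)[:5]}")


@dataclass
class CountTable:
    """Samples x features abundance matrix.

    ``counts`` may be integer (raw reads) or real-valued (after gene-copy
    normalisation); construction drops samples whose total is zero, so every
    retained sample has a positive library size.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.feature_ids),
        ):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("count matrix contains non-finite entries")
        if (self.counts < 0).any():
            raise ValidationError("count matrix contains negative entries")
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            dropped = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            if len(dropped) == len(self.sample_ids):
                raise EmptyResultError("every sample has zero total count")
            logger.warning("dropping %d zero-total sample(s): %s", len(dropped), dropped)
            keep = totals > 0
            self.counts = self.counts[keep]
            self.sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (rows sum to 1)."""
        return self.counts / self.totals()[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        wanted = list(sample_ids)
        missing = set(wanted) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)[:5]}")
        idx = [self.sample_ids.index(s) for s in wanted]
        return CountTable(wanted, list(self.feature_ids), self.counts[idx].copy())

    def select_features(self, feature_ids: Iterable[str]) -> "CountTable":
        wanted = list(feature_ids)
        missing = set(wanted) - set(self.feature_ids)
        if missing:
            raise ValidationError(f"unknown feature IDs: {sorted(missing)[:5]}")
        idx = [self.feature_ids.index(f) for f in wanted]
        return CountTable(list(self.sample_ids), wanted, self.counts[:, idx].copy())


@dataclass
class SampleMetadata:
    """Design information: treatment, substrate, timepoint and blocks per sample."""

    frame: pd.DataFrame  # index: sample_id; columns: treatment, substrate, timepoint, panel, bottle

    REQUIRED = ("treatment", "substrate", "timepoint", "panel", "bottle")

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in metadata")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        for c in self.REQUIRED:
            col = df[c].astype(str)
            if (col.str.len() == 0).any() or col.isin(["nan", "None"]).any():
                raise ValidationError(f"metadata column '{c}' has empty values")
        bad = set(df["substrate"].astype(str)) - set(SUBSTRATES)
        if bad:
            raise ValidationError(f"unknown substrate values: {sorted(bad)}")
        self.frame = df.copy()
        self.frame.index = self.frame.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_where(self, **criteria: str | Sequence[str]) -> list[str]:
        """Sample IDs matching every (column == value) criterion; values may be lists."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in criteria.items():
            if col not in self.frame.columns:
                raise ValidationError(f"unknown metadata column '{col}'")
            if isinstance(val, str):
                mask &= self.frame[col].astype(str) == val
            else:
                mask &= self.frame[col].astype(str).isin([str(v) for v in val])
        return list(self.frame.index[mask])

    def factor(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise ValidationError(f"unknown metadata column '{name}'")
        return self.frame[name].astype(str)


@dataclass
class FeatureTaxonomy:
    """Domain class, lineage and (prokaryote) 16S gene copy number per feature."""

    frame: pd.DataFrame  # index: feature_id; columns: domain_class, lineage, copy_number

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            raise ValidationError("duplicate feature IDs in taxonomy")
        for c in ("domain_class", "lineage"):
            if c not in df.columns:
                raise ValidationError(f"taxonomy missing column '{c}'")
        bad = set(df["domain_class"].astype(str)) - set(DOMAIN_CLASSES)
        if bad:
            raise ValidationError(f"unknown domain_class values: {sorted(bad)}")
        if "copy_number" not in df.columns:
            df = df.assign(copy_number=np.nan)
        cn = pd.to_numeric(df["copy_number"], errors="coerce")
        if (cn.dropna() <= 0).any():
            raise ValidationError("copy numbers must be positive where present")
        df = df.copy()
        df["copy_number"] = cn
        df.index = df.index.astype(str)
        self.frame = df

    def covers(self, table: CountTable) -> bool:
        return set(table.feature_ids) <= set(self.frame.index)

    def domain_of(self, feature_id: str) -> str:
        return str(self.frame.loc[feature_id, "domain_class"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path, format: str = "tsv", allow_real: bool = False) -> CountTable:
    """Read a count table from TSV or BIOM v1 JSON.

    TSV stores features as rows and samples as columns with first header cell
    ``#ASV_ID``; BIOM JSON follows the sparse v1 layout (rows = features).
    Zero-total samples are dropped with a warning.  Non-integer or negative
    entries raise :class:`ValidationError` unless ``allow_real`` is set (used
    to read back copy-number-normalised tables).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name != TSV_HEADER:
            logger.warning("TSV header cell is %r, expected %r", df.index.name, TSV_HEADER)
        sample_ids = [str(c) for c in df.columns]
        feature_ids = [str(i) for i in df.index]
        mat = df.to_numpy().T  # -> samples x features
    elif format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "sparse":
            raise ValidationError("only sparse BIOM v1 tables are supported")
        n_feat, n_samp = doc["shape"]
        feature_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        mat = np.zeros((n_samp, n_feat))
        for i, j, v in doc["data"]:
            mat[int(j), int(i)] = v
    else:
        raise ParameterError(f"unknown count-table format '{format}'")

    if not np.all(np.isfinite(mat)):
        raise ValidationError("count table contains non-finite entries")
    if not allow_real:
        if np.any(mat != np.round(mat)):
            raise ValidationError("count table contains non-integer entries")
        mat = np.round(mat).astype(np.int64)
    return CountTable(sample_ids, feature_ids, mat)


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    """Write a count table as TSV or sparse BIOM v1 JSON (deterministic output)."""
    if format == "tsv":
        df = table.to_dataframe().T  # features as rows
        df.index.name = TSV_HEADER
        is_int = np.issubdtype(table.counts.dtype, np.integer)
        df.to_csv(path, sep="\t", float_format=None if is_int else "%.10g")
    elif format == "biom_json":
        data = []
        for i in range(table.n_features):
            col = table.counts[:, i]
            for j in np.nonzero(col)[0]:
                v = col[j]
                data.append([i, int(j), int(v) if float(v).is_integer() else float(v)])
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "biofilmnet",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int"
            if np.issubdtype(table.counts.dtype, np.integer)
            else "float",
            "shape": [table.n_features, table.n_samples],
            "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"))
    else:
        raise ParameterError(f"unknown count-table format '{format}'")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> FeatureTaxonomy:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return FeatureTaxonomy(df)


def write_taxonomy(tax: FeatureTaxonomy, path) -> None:
    df = tax.frame.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------


def filter_min_depth(table: CountTable, min_reads: int) -> CountTable:
    """Retain samples with total reads >= ``min_reads`` (inclusive boundary).

    Mirrors the usual amplicon depth filters (e.g. 2000 reads for prokaryote
    libraries, 100 for plastid-derived microalgal libraries).
    """
    if min_reads < 1:
        raise ParameterError("min_reads must be >= 1")
    keep = table.totals() >= min_reads
    if not keep.any():
        raise EmptyResultError(f"no sample reaches the depth threshold {min_reads}")
    kept = [s for s, k in zip(table.sample_ids, keep) if k]
    return CountTable(kept, list(table.feature_ids), table.counts[keep].copy())


def copy_number_normalize(table: CountTable, taxonomy: FeatureTaxonomy) -> CountTable:
    """Divide each feature's counts by its 16S gene copy number.

    Microalgal (plastid) features and prokaryotes without a database copy
    number are divided by 1; the latter are logged, since reference copy-number
    databases never cover all taxa.
    """
    divisors = np.ones(table.n_features)
    missing: list[str] = []
    for i, fid in enumerate(table.feature_ids):
        if fid not in taxonomy.frame.index:
            raise ValidationError(f"feature '{fid}' missing from taxonomy")
        row = taxonomy.frame.loc[fid]
        if str(row["domain_class"]) != "prokaryote":
            continue
        cn = row["copy_number"]
        if pd.isna(cn):
            missing.append(fid)
        else:
            if cn <= 0:
                raise ValidationError(f"non-positive copy number for '{fid}'")
            divisors[i] = float(cn)
    if missing:
        logger.warning(
            "%d prokaryotic feature(s) lack copy numbers; using 1: %s",
            len(missing),
            missing[:5],
        )
    return CountTable(
        list(table.sample_ids), list(table.feature_ids), table.counts / divisors[None, :]
    )
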