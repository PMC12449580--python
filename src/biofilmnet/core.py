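"""Compositional core and host-specific taxon extraction.

A feature belongs to a group's compositional core when it is detected (more
than ``min_reads`` reads, strict inequality) in at least ``min_prevalence`` of
the group's samples and its group-level mean relative abundance reaches
``min_abundance_fraction``.  Host-specific taxa are stricter: present (any
read) in every sample of a host and its proxy-biofilm group at both
timepoints, and absent from every control-filter and seawater sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ValidationError
from .tables_io import CountTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class CoreSet:
    group: str
    features: set[str]
    params: dict  # min_reads, min_prevalence, min_abundance_fraction

    def table(self, t: CountTable, sample_ids: list[str]) -> pd.DataFrame:
        """Per-member prevalence and mean relative abundance report."""
        sub = t.select_samples(sample_ids)
        rel = sub.relative_abundance()
        rows = []
        for f in sorted(self.features):
            j = sub.feature_ids.index(f)
            rows.append(
                {
                    "group": self.group,
                    "feature_id": f,
                    "prevalence": float(
                        (sub.counts[:, j] > self.params["min_reads"]).mean()
                    ),
                    "mean_rel_abundance": float(rel[:, j].mean()),
                }
            )
        return pd.DataFrame(
            rows, columns=["group", "feature_id", "prevalence", "mean_rel_abundance"]
        )


@dataclass
class HostSpecificSet:
    host: str
    features: set[str]
    excluded_groups: list[str]


def prevalence(t: CountTable, feature: str, detection_min_reads: int = 3) -> float:
    """Fraction of samples in which ``feature`` exceeds the detection threshold
    (strictly more than ``detection_min_reads`` reads)."""
    if feature not in t.feature_ids:
        raise ValidationError(f"feature '{feature}' not in table")
    j = t.feature_ids.index(feature)
    return float((t.counts[:, j] > detection_min_reads).mean())


def extract_core(
    t: CountTable,
    m: SampleMetadata,
    group: dict[str, str] | str,
    min_reads: int = 3,
    min_prevalence: float = 0.9,
    min_abundance_fraction: float = 1e-5,
) -> CoreSet:
    """Compositional core of one sample group.

    ``group`` is either a treatment label or a dict of metadata criteria,
    e.g. ``{"treatment": "gracilaria", "substrate": "seaweed"}``; by default
    samples are pooled across timepoints.  Prevalence uses the strict read
    threshold (> ``min_reads``); the prevalence boundary itself is inclusive
    (>= ``min_prevalence``), as is the mean-relative-abundance floor.
    """
    criteria = {"treatment": group} if isinstance(group, str) else dict(group)
    sample_ids = [s for s in m.samples_where(**criteria) if s in set(t.sample_ids)]
    if len(sample_ids) < 2:
        raise EmptyResultError(f"group {criteria} has fewer than 2 samples")
    sub = t.select_samples(sample_ids)
    detected = sub.counts > min_reads
    prev = detected.mean(axis=0)
    mean_rel = sub.relative_abundance().mean(axis=0)
    keep = (prev >= min_prevalence) & (mean_rel >= min_abundance_fraction)
    label = "_".join(str(criteria[k]) for k in sorted(criteria))
    return CoreSet(
        group=label,
        features={f for f, k in zip(sub.feature_ids, keep) if k},
        params={
            "min_reads": min_reads,
            "min_prevalence": min_prevalence,
            "min_abundance_fraction": min_abundance_fraction,
        },
    )


def extract_host_specific(
    t: CountTable,
    m: SampleMetadata,
    host: str,
    detection_min_reads: int = 0,
) -> HostSpecificSet:
    """Features present in every sample of ``host``'s seaweed and proxy-biofilm
    groups across both timepoints, and absent from all control-filter and
    seawater samples.

    Presence means count > ``detection_min_reads`` (default: any read).
    """
    in_table = set(t.sample_ids)
    tps = sorted(set(m.factor("timepoint")))
    host_samples: list[str] = []
    for sub in ("seaweed", "proxy_biofilm"):
        for tp in tps:
            sids = [
                s
                for s in m.samples_where(treatment=host, substrate=sub, timepoint=tp)
                if s in in_table
            ]
            if not sids:
                raise EmptyResultError(
                    f"missing samples for host '{host}', substrate '{sub}', timepoint '{tp}'"
                )
            host_samples.extend(sids)
    excluded = [
        s
        for s in m.samples_where(substrate=["control_filter", "seawater"])
        if s in in_table
    ]
    if not excluded:
        raise EmptyResultError("no control-filter or seawater samples present")

    host_t = t.select_samples(host_samples)
    excl_t = t.select_samples(excluded)
    always_present = (host_t.counts > detection_min_reads).all(axis=0)
    never_in_controls = (excl_t.counts == 0).all(axis=0)
    keep = always_present & never_in_controls
    return HostSpecificSet(
        host=host,
        features={f for f, k in zip(t.feature_ids, keep) if k},
        excluded_groups=sorted({str(m.frame.loc[s, "substrate"]) for s in excluded}),
    )


def core_report(
    t: CountTable,
    m: SampleMetadata,
    groups: list[dict[str, str]],
    **params,
) -> pd.DataFrame:
    """Stacked per-group core membership table (TSV-ready)."""
    frames = []
    for g in groups:
        cs = extract_core(t, m, g, **params)
        sids = [s for s in m.samples_where(**g) if s in set(t.sample_ids)]
        frames.append(cs.table(t, sids))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "feature_id", "prevalence", "mean_rel_abundance"]
    )
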