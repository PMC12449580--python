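"""End-to-end pipeline: simulate -> filter -> core -> stats -> networks ->
metrics -> compare, driven by a TOML config with deterministic seeding.

Per-stage seeds are derived from the master seed by hashing the stage name,
so adding or reordering stages never perturbs the randomness of the others.
Stage outputs are plain TSV; the run manifest records the package version,
a hash of the config, per-stage seeds and runtimes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import core_report, extract_host_specific
from .errors import ParameterError, StageError
from .inference import infer_association_network
from .netcompare import profile_distance, profile_pca, shared_structure_report
from .netmetrics import PROFILE_FIELDS, node_role_report, profile
from .stats import (
    bray_curtis,
    pairwise_permanova,
    pcoa,
    permanova,
    permanova_report,
    shannon_table,
)
from .synthetic import make_graph, simulate_counts, study_design, write_truth_edges
from .tables_io import (
    filter_min_depth,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_metadata,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "core", "stats", "network", "metrics", "netcompare")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage seed below 2**31, stable across runs and stage additions."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    simulate: dict = field(default_factory=dict)  # or {"counts": path, ...} to load
    filter: dict = field(default_factory=dict)
    core: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    netcompare: dict = field(default_factory=dict)

    def validate(self) -> None:
        def _range(section, key, lo, hi):
            v = section.get(key)
            if v is not None and not (lo <= v <= hi):
                raise ParameterError(f"{key}={v} outside [{lo}, {hi}]")

        _range(self.core, "min_prevalence", 0.0, 1.0)
        _range(self.core, "min_abundance_fraction", 0.0, 1.0)
        _range(self.network, "min_mean_rel_abund", 0.0, 1.0)
        _range(self.network, "beta_threshold", 0.0, 0.5)
        if self.stats.get("n_perm", 999) < 1:
            raise ParameterError("n_perm must be >= 1")
        for key in ("counts", "metadata", "taxonomy"):
            p = self.simulate.get(key)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": self.simulate,
            "filter": self.filter,
            "core": self.core,
            "stats": self.stats,
            "network": self.network,
            "metrics": self.metrics,
            "netcompare": self.netcompare,
        }


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    known = {"seed", "outdir", *STAGES}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown config sections/keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(doc.get("seed", 0)),
        outdir=str(doc.get("outdir", "pipeline_out")),
        simulate=dict(doc.get("simulate", {})),
        filter=dict(doc.get("filter", {})),
        core=dict(doc.get("core", {})),
        stats=dict(doc.get("stats", {})),
        network=dict(doc.get("network", {})),
        metrics=dict(doc.get("metrics", {})),
        netcompare=dict(doc.get("netcompare", {})),
    )
    cfg.validate()
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Identical config + seed produce byte-identical stage outputs.  A stage
    failure raises :class:`StageError` naming the stage; outputs of earlier
    stages are retained.
    """
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": cfg.seed,
        "stages": {},
    }

    state: dict = {}

    def _run(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            outputs = fn(stage_seed(cfg.seed, stage))
        except Exception as exc:  # noqa: BLE001 - re-raised with stage label
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(cfg.seed, stage),
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": outputs,
        }

    # -- simulate / load ---------------------------------------------------
    def _simulate(seed: int) -> list[str]:
        sc = cfg.simulate
        if "counts" in sc:  # load real inputs instead of simulating
            state["table"] = read_count_table(sc["counts"], sc.get("format", "tsv"))
            state["meta"] = read_metadata(sc["metadata"])
            state["tax"] = read_taxonomy(sc["taxonomy"])
            state["graph"] = None
            return []
        design = study_design(
            seed=seed,
            n_features=int(sc.get("n_features", 60)),
            n_replicates=int(sc.get("n_replicates", 6)),
            effect_size=float(sc.get("effect_size", 1.0)),
        )
        graph = make_graph(
            int(sc.get("n_features", 60)),
            topology=sc.get("topology", "cluster"),
            density=float(sc.get("graph_density", 0.04)),
            seed=seed,
        )
        table, meta, tax = simulate_counts(graph, design)
        state.update(table=table, meta=meta, tax=tax, graph=graph)
        write_count_table(table, out / "counts.tsv")
        write_metadata(meta, out / "metadata.tsv")
        write_taxonomy(tax, out / "taxonomy.tsv")
        write_truth_edges(graph, out / "truth_edges.tsv")
        return ["counts.tsv", "metadata.tsv", "taxonomy.tsv", "truth_edges.tsv"]

    # -- depth filter ------------------------------------------------------
    def _filter(seed: int) -> list[str]:
        t = filter_min_depth(state["table"], int(cfg.filter.get("min_depth", 2000)))
        state["table"] = t
        keep = set(t.sample_ids)
        state["meta"].frame = state["meta"].frame.loc[[s for s in state["meta"].sample_ids if s in keep]]
        write_count_table(t, out / "filtered_counts.tsv")
        return ["filtered_counts.tsv"]

    # -- core microbiome ---------------------------------------------------
    def _core(seed: int) -> list[str]:
        t, meta = state["table"], state["meta"]
        groups = cfg.core.get("groups")
        if groups is None:
            combos = sorted(
                set(
                    zip(
                        meta.factor("treatment"),
                        meta.factor("substrate"),
                    )
                )
            )
            groups = [
                {"treatment": tr, "substrate": su}
                for tr, su in combos
                if su != "seawater"
            ]
        params = {
            "min_reads": int(cfg.core.get("min_reads", 3)),
            "min_prevalence": float(cfg.core.get("min_prevalence", 0.9)),
            "min_abundance_fraction": float(cfg.core.get("min_abundance_fraction", 1e-5)),
        }
        rep = core_report(t, meta, groups, **params)
        _write_tsv(rep, out / "core_sets.tsv")
        hosts = cfg.core.get(
            "hosts", sorted(set(meta.factor("treatment")) - {"control", "ambient"})
        )
        rows = []
        for h in hosts:
            hs = extract_host_specific(t, meta, h)
            for f in sorted(hs.features):
                rows.append({"host": h, "feature_id": f})
        _write_tsv(
            pd.DataFrame(rows, columns=["host", "feature_id"]),
            out / "host_specific.tsv",
        )
        return ["core_sets.tsv", "host_specific.tsv"]

    # -- composition statistics -------------------------------------------
    def _stats(seed: int) -> list[str]:
        t, meta = state["table"], state["meta"]
        rel = t.relative_abundance()
        d = bray_curtis(rel, t.sample_ids)
        state["distance"] = d
        _write_tsv(d.to_dataframe(), out / "bray_curtis.tsv", index=True)
        sh = shannon_table(t)
        _write_tsv(sh.to_frame(), out / "shannon.tsv", index=True)
        ord_res = pcoa(d, n_axes=min(4, len(t.sample_ids) - 1))
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=ord_res.sample_ids,
            columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])],
        )
        _write_tsv(coords, out / "pcoa_coordinates.tsv", index=True)
        n_perm = int(cfg.stats.get("n_perm", 999))
        results = []
        for factor in cfg.stats.get("factors", ["substrate", "treatment"]):
            results.append(
                permanova(d, meta, factor, n_perm=n_perm, seed=stage_seed(seed, factor))
            )
            if cfg.stats.get("pairwise", False):
                results.extend(
                    pairwise_permanova(
                        d, meta, factor, n_perm=n_perm, seed=stage_seed(seed, factor + ":pw")
                    )
                )
        _write_tsv(permanova_report(results), out / "permanova.tsv")
        return ["bray_curtis.tsv", "shannon.tsv", "pcoa_coordinates.tsv", "permanova.tsv"]

    # -- association networks ---------------------------------------------
    def _network(seed: int) -> list[str]:
        t, meta, tax = state["table"], state["meta"], state["tax"]
        groups = cfg.network.get("groups")
        if groups is None:
            combos = sorted(
                set(zip(meta.factor("treatment"), meta.factor("substrate")))
            )
            groups = [
                {"name": f"{tr}_{su}", "treatment": tr, "substrate": su}
                for tr, su in combos
                if su not in ("seawater",)
            ]
        nets = {}
        files = []
        for g in groups:
            name = g.get("name") or "_".join(
                str(v) for k, v in sorted(g.items()) if k != "name"
            )
            criteria = {k: v for k, v in g.items() if k != "name"}
            sids = [s for s in meta.samples_where(**criteria) if s in set(t.sample_ids)]
            sub = t.select_samples(sids)
            net = infer_association_network(
                sub,
                taxonomy=tax,
                min_total_reads=int(cfg.network.get("min_total_reads", 3)),
                min_mean_rel_abund=float(cfg.network.get("min_mean_rel_abund", 0.0025)),
                n_lambda=int(cfg.network.get("n_lambda", 30)),
                n_subsamples=int(cfg.network.get("n_subsamples", 20)),
                beta_threshold=float(cfg.network.get("beta_threshold", 0.05)),
                rule=cfg.network.get("rule", "or"),
                seed=stage_seed(seed, name),
            )
            nets[name] = net
            net.write_edges(out / f"network_{name}_edges.tsv")
            net.write_nodes(out / f"network_{name}_nodes.tsv")
            files += [f"network_{name}_edges.tsv", f"network_{name}_nodes.tsv"]
        state["networks"] = nets
        return files

    # -- network metrics ---------------------------------------------------
    def _metrics(seed: int) -> list[str]:
        nets = state["networks"]
        profiles = {}
        files = []
        for name, net in nets.items():
            prof = profile(net, seed=stage_seed(seed, name))
            profiles[name] = prof
            roles = node_role_report(
                net,
                seed=stage_seed(seed, name),
                z_thresh=float(cfg.metrics.get("z_thresh", 2.5)),
                p_thresh=float(cfg.metrics.get("p_thresh", 0.62)),
            )
            _write_tsv(roles, out / f"node_roles_{name}.tsv", index=True)
            files.append(f"node_roles_{name}.tsv")
        state["profiles"] = profiles
        prof_df = pd.DataFrame(
            {name: p.as_series() for name, p in profiles.items()}
        ).T[list(PROFILE_FIELDS)]
        prof_df.index.name = "network"
        _write_tsv(prof_df, out / "network_profiles.tsv", index=True)
        files.append("network_profiles.tsv")
        return files

    # -- network comparison ------------------------------------------------
    def _netcompare(seed: int) -> list[str]:
        profiles, nets = state["profiles"], state["networks"]
        pd_mat = profile_distance(profiles, cfg.netcompare.get("standardize", "zscore"))
        _write_tsv(pd_mat.to_dataframe(), out / "profile_distance.tsv", index=True)
        files = ["profile_distance.tsv"]
        if len(profiles) >= 3:
            ores = profile_pca(profiles, cfg.netcompare.get("standardize", "zscore"))
            coords = pd.DataFrame(
                ores.coordinates,
                index=ores.sample_ids,
                columns=[f"PC{i+1}" for i in range(ores.coordinates.shape[1])],
            )
            _write_tsv(coords, out / "profile_pca.tsv", index=True)
            files.append("profile_pca.tsv")
        _write_tsv(shared_structure_report(nets), out / "shared_structure.tsv")
        files.append("shared_structure.tsv")
        return files

    _run("simulate", _simulate)
    _run("filter", _filter)
    _run("core", _core)
    _run("stats", _stats)
    _run("network", _network)
    _run("metrics", _metrics)
    _run("netcompare", _netcompare)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
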