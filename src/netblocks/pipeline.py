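"""End-to-end orchestration: corpus -> samples -> censuses -> delta ->
SI transient times -> regression -> ranking and best-subgraph extraction.

Every stage derives its RNG seed deterministically from ``master_seed`` and
a stage-specific token, so a rerun with the same configuration yields a
byte-identical JSON report.  Per-cell failures (one (method, size, variant)
combination on one host) are recorded in the report instead of aborting the
run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .diffusion import SIParams, estimate_transient_time
from .errors import ConfigError, NetblocksError
from .evaluation import (
    EvalReport,
    RegressionConfig,
    build_feature_table,
    evaluate_prediction,
    feature_vector,
    motif_mse,
    rank_and_select,
)
from .graphcore import largest_component, load_edge_list, write_edge_list
from .motifs import FrequencyVariant, OverlapPolicy, build_census
from .samplers import SamplerMethod, SamplerSpec, draw_sample
from .synthetic import BUNDLED_TOPICS, TopicSpec, generate_corpus, write_corpus

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "extract_best_subgraphs", "derive_seed"]

FAILURE_EXIT_FRACTION = 0.10


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic child seed from the master seed and stage tokens."""
    digest = zlib.crc32(":".join(str(t) for t in tokens).encode())
    return (int(master_seed) + digest) % (2**31)


@dataclass
class PipelineConfig:
    """Full configuration of one framework run (echoed into all outputs)."""

    corpus_dir: str | None = None          # directory of *.edges files, or
    topics: tuple[TopicSpec, ...] = BUNDLED_TOPICS  # synthetic corpus specs
    methods: tuple[str, ...] = tuple(m.value for m in SamplerMethod)
    size_grid: tuple[int, ...] = (10, 20, 30, 40, 50)
    replicates: int = 3
    motif_k: int = 4
    overlap_policy: OverlapPolicy = OverlapPolicy.EDGE_DISJOINT
    variants: tuple[FrequencyVariant, ...] = (
        FrequencyVariant.JOINT_RATIO,
        FrequencyVariant.DISJOINT_RATIO,
    )
    si: SIParams = field(default_factory=SIParams)
    n_si_runs: int = 10
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.methods = tuple(SamplerMethod(str(m).upper()).value for m in self.methods)
        self.overlap_policy = OverlapPolicy(self.overlap_policy)
        self.variants = tuple(FrequencyVariant(v) for v in self.variants)
        if not self.size_grid:
            raise ConfigError("size grid is empty")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate per cell")

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "corpus_dir": self.corpus_dir,
            "topics": [dataclasses.asdict(t) for t in self.topics]
            if self.corpus_dir is None else None,
            "methods": list(self.methods),
            "size_grid": list(self.size_grid),
            "replicates": self.replicates,
            "motif_k": self.motif_k,
            "overlap_policy": self.overlap_policy.value,
            "variants": [v.value for v in self.variants],
            "si": dataclasses.asdict(self.si),
            "n_si_runs": self.n_si_runs,
            "regression": dataclasses.asdict(self.regression),
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "topics" in raw and raw["topics"] is not None:
            raw["topics"] = tuple(
                TopicSpec(
                    label=t["label"],
                    n_nodes=int(t["n_nodes"]),
                    target_density=float(t["density"]),
                    target_clustering=float(t["clustering"]),
                    target_assortativity=float(t["assortativity"]),
                    months=int(t.get("months", 11)),
                )
                for t in raw["topics"]
            )
        if "si" in raw and isinstance(raw["si"], dict):
            raw["si"] = SIParams(**raw["si"])
        if "regression" in raw and isinstance(raw["regression"], dict):
            raw["regression"] = RegressionConfig(**raw["regression"])
        return cls(**raw)


def _load_corpus(cfg: PipelineConfig):
    if cfg.corpus_dir is not None:
        graphs = {}
        for path in sorted(Path(cfg.corpus_dir).glob("*.edges")):
            graphs[path.stem] = load_edge_list(path)
        if not graphs:
            raise ConfigError(f"no *.edges files found in {cfg.corpus_dir}")
        return None, graphs
    manifest, graphs = generate_corpus(
        cfg.topics, base_seed=derive_seed(cfg.master_seed, "corpus")
    )
    return manifest, graphs


def run_pipeline(cfg: PipelineConfig) -> EvalReport:
    """Run the full framework; returns the report (also written to disk
    when ``cfg.out_dir`` is set)."""
    t_start = time.monotonic()
    manifest, graphs = _load_corpus(cfg)
    max_size = max(cfg.size_grid)
    report = EvalReport(config_echo=cfg.to_dict())

    hosts: dict[str, nx.Graph] = {}
    for host_id in sorted(graphs):
        lc = largest_component(graphs[host_id])
        if lc.number_of_nodes() < max_size:
            report.failures[f"host:{host_id}"] = (
                f"largest component {lc.number_of_nodes()} < max sample size {max_size}"
            )
            continue
        hosts[host_id] = lc

    logger.info("corpus: %d usable hosts", len(hosts))
    taus = {}
    host_censuses = {}
    host_freqs = {}
    for host_id, lc in hosts.items():
        taus[host_id] = estimate_transient_time(
            lc, cfg.si, n_runs=cfg.n_si_runs,
            base_seed=derive_seed(cfg.master_seed, "si", host_id),
        )
        census = build_census(
            lc, cfg.motif_k, cfg.overlap_policy,
            seed=derive_seed(cfg.master_seed, "mis", host_id),
        )
        host_censuses[host_id] = census
        host_freqs[host_id] = {
            v: feature_vector(census, v)[:-1] for v in cfg.variants
        }
    logger.info("host transient times and censuses done (%.1fs)",
                time.monotonic() - t_start)

    delta_rows = []
    samples = []
    sample_censuses = {}
    for host_id, lc in hosts.items():
        for method in cfg.methods:
            for size in cfg.size_grid:
                for rep in range(cfg.replicates):
                    cell = f"{host_id}|{method}|{size}|rep{rep}"
                    try:
                        spec = SamplerSpec(
                            method=method, target_size=size,
                            rng_seed=derive_seed(cfg.master_seed, "sample",
                                                 host_id, method, size, rep),
                        )
                        sample = draw_sample(lc, spec, host_id=host_id)
                        census = build_census(
                            sample.subgraph, cfg.motif_k, cfg.overlap_policy,
                            seed=derive_seed(cfg.master_seed, "mis-sample",
                                             host_id, method, size, rep),
                        )
                    except NetblocksError as exc:
                        report.failures[cell] = str(exc)
                        continue
                    idx = len(samples)
                    samples.append(sample)
                    sample_censuses[idx] = census
                    for variant in cfg.variants:
                        delta = motif_mse(
                            host_freqs[host_id][variant],
                            feature_vector(census, variant)[:-1],
                        )
                        delta_rows.append({
                            "host_id": host_id, "method": method, "size": size,
                            "replicate": rep, "variant": variant.value,
                            "delta_raw": delta.raw, "delta_mean": delta.mean,
                        })
    delta_df = pd.DataFrame(delta_rows)
    logger.info("samples and deltas done (%.1fs)", time.monotonic() - t_start)

    for (method, size, variant), group in delta_df.groupby(
            ["method", "size", "variant"], sort=True):
        report.mse_table[(method, int(size), variant)] = float(
            group["delta_mean"].mean()
        )

    feature_tables = {
        v: build_feature_table(samples, sample_censuses, taus, variant=v)
        for v in cfg.variants
    }
    for variant, table in feature_tables.items():
        for method in cfg.methods:
            for size in cfg.size_grid:
                cell_rows = table[(table["method"] == method)
                                  & (table["sample_size"] == size)]
                key = (method, int(size), variant.value)
                try:
                    report.r2_table[key] = evaluate_prediction(
                        cell_rows, cfg.regression
                    )
                except NetblocksError as exc:
                    report.failures[f"r2:{method}|{size}|{variant.value}"] = str(exc)

    if report.mse_table and report.r2_table:
        rank_and_select(report, list(cfg.size_grid))
    logger.info("evaluation done (%.1fs)", time.monotonic() - t_start)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if manifest is not None:
            write_corpus(manifest, graphs, out / "corpus")
        delta_df.to_csv(out / "delta.csv", index=False)
        pd.concat(feature_tables.values(), ignore_index=True).to_csv(
            out / "features.csv", index=False
        )
        (out / "report.json").write_text(report_json(report))
    return report


def report_json(report: EvalReport) -> str:
    payload = {
        "config": report.config_echo,
        "mse_table": {f"{m}|{s}|{v}": val
                      for (m, s, v), val in sorted(report.mse_table.items())},
        "r2_table": {f"{m}|{s}|{v}": val
                     for (m, s, v), val in sorted(report.r2_table.items())},
        "ranking_by_mse": report.ranking_by_mse,
        "ranking_by_r2": report.ranking_by_r2,
        "recommended_method": report.recommended_method,
        "recommended_size": report.recommended_size,
        "failures": dict(sorted(report.failures.items())),
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def failure_fraction(report: EvalReport) -> float:
    n_cells = len(report.mse_table) + len(report.r2_table)
    if n_cells == 0:
        return 1.0
    return len(report.failures) / (n_cells + len(report.failures))


def extract_best_subgraphs(
    cfg: PipelineConfig, method: str, size: int, out_dir: str | Path
) -> dict[str, "nx.Graph"]:
    """One recommended-method sample per host, written as edge lists.

    A JSON sidecar per host records the sampled node membership for
    highlighting the sample inside its host graph.  Hosts whose largest
    component is smaller than ``size`` are skipped with a warning.
    """
    _, graphs = _load_corpus(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    method = SamplerMethod(str(method).upper())
    extracted = {}
    for host_id in sorted(graphs):
        lc = largest_component(graphs[host_id])
        if lc.number_of_nodes() < size:
            logger.warning("host %s: component %d < %d, skipped",
                           host_id, lc.number_of_nodes(), size)
            continue
        spec = SamplerSpec(
            method=method, target_size=size,
            rng_seed=derive_seed(cfg.master_seed, "extract", host_id,
                                 method.value, size),
        )
        sample = draw_sample(lc, spec, host_id=host_id)
        write_edge_list(sample.subgraph, out / f"{host_id}.best.edges")
        (out / f"{host_id}.best.json").write_text(json.dumps({
            "host_id": host_id,
            "method": method.value,
            "size": size,
            "nodes": sorted(sample.subgraph.nodes),
        }, indent=2, sort_keys=True))
        extracted[host_id] = sample.subgraph
    return extracted
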