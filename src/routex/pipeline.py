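"""End-to-end orchestration: solver → pre-extraction → filter → metrics.

A :class:`PipelineConfig` (YAML-serialisable) fixes every stage
parameter; :func:`run_pipeline` executes the stages in order, optionally
writing all artefacts (mesh, solution tables, graphs, terminal report,
energy traces, metric report) plus a JSON manifest that suffices to
reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .continuous import ContinuousSolution, DmkOptions, run_continuous_dmk
from .errors import EmptyGraphWarning, RoutexError
from .extraction import ExtractedGraph, ExtractionConfig, pre_extract
from .filtering import FilterResult, filter_graph
from .fixtures import forcing_fixture, mu0_fixture
from .forcing import ForcingSpec, evaluate_forcing
from .mesh import build_structured_mesh
from .metrics import DomainPartition, MetricReport, local_weight_metric
from .terminals import build_terminals

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of one extraction run."""

    ndiv: int = 32
    nref: int = 0
    forcing: str | dict = "two-rectangles"      # fixture name or spec dict
    mu0: str = "uniform-mu0"
    beta: float = 1.1
    dt: float = 0.1
    tol: float = 1e-4
    max_iter: int = 20000
    rule: str = "I"
    weight_rule: str = "ER"
    delta: float = 0.01
    tau_bc: float = 0.1
    beta_d: float = 1.1
    delta_d: float = 1e-3
    weight_mode: str = "BPW"
    q: float = 2.0
    partition_n: int = 11
    seed: int = 0

    def forcing_spec(self) -> ForcingSpec:
        if isinstance(self.forcing, str):
            return forcing_fixture(self.forcing)
        return ForcingSpec.from_dict(self.forcing)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: PipelineConfig
    mesh: object
    forcing_field: object
    solution: ContinuousSolution
    pregraph: ExtractedGraph
    terminals: object
    filter_result: FilterResult
    filtered: ExtractedGraph
    metrics: MetricReport
    metrics_filtered: MetricReport


class StageError(RoutexError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except RoutexError as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full extraction pipeline under one configuration."""
    mesh = _stage("mesh")(build_structured_mesh)(config.ndiv, config.nref)
    spec = config.forcing_spec()
    f = _stage("forcing")(evaluate_forcing)(mesh, spec)
    mu0 = mu0_fixture(config.mu0, mesh)
    opts = DmkOptions(
        beta=config.beta, dt=config.dt, tol=config.tol, max_iter=config.max_iter
    )
    solution = _stage("continuous-dmk")(run_continuous_dmk)(mesh, f, mu0, opts)

    with warnings.catch_warnings():
        warnings.simplefilter("error", EmptyGraphWarning)
        try:
            pregraph = pre_extract(
                mesh,
                solution,
                ExtractionConfig(config.rule, config.weight_rule, config.delta),
            )
        except EmptyGraphWarning as exc:
            raise StageError("pre-extraction", RoutexError(str(exc))) from exc

    terminals = _stage("terminal-selection")(build_terminals)(
        pregraph, spec, config.tau_bc
    )
    filtered, filt_result = _stage("filter")(filter_graph)(
        pregraph,
        terminals,
        beta_d=config.beta_d,
        delta_d=config.delta_d,
        mode=config.weight_mode,
    )
    partition = DomainPartition(config.partition_n)
    metrics = local_weight_metric(
        pregraph, mesh, solution.mu, config.delta, partition, config.q
    )
    metrics_filtered = local_weight_metric(
        filtered, mesh, solution.mu, config.delta, partition, config.q
    )

    result = PipelineResult(
        config=config,
        mesh=mesh,
        forcing_field=f,
        solution=solution,
        pregraph=pregraph,
        terminals=terminals,
        filter_result=filt_result,
        filtered=filtered,
        metrics=metrics,
        metrics_filtered=metrics_filtered,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    io.write_mesh(result.mesh, outdir / "mesh.txt")
    io.write_solution(
        result.mesh, result.solution, outdir / "solution_triangles.tsv",
        outdir / "solution_vertices.tsv",
    )
    io.write_energy_trace(result.solution.energy_trace, outdir / "energy_continuous.csv")
    io.write_energy_trace(
        result.filter_result.energy_trace, outdir / "energy_discrete.csv"
    )
    io.write_graph_tsv(
        result.pregraph, outdir / "pregraph_edges.tsv", outdir / "pregraph_nodes.tsv"
    )
    io.write_graphml(result.pregraph, outdir / "pregraph.graphml")
    io.write_graph_tsv(
        result.filtered, outdir / "filtered_edges.tsv", outdir / "filtered_nodes.tsv"
    )
    if result.filtered.n_nodes:
        io.write_graphml(result.filtered, outdir / "filtered.graphml")
    io.write_terminal_report(result.pregraph, result.terminals, outdir / "terminals.tsv")
    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "continuous_converged": bool(result.solution.converged),
        "continuous_iterations": int(result.solution.iterations),
        "filter_converged": bool(result.filter_result.converged),
        "filter_iterations": int(result.filter_result.iterations),
        "energy_split_pct": list(result.filter_result.energy_split),
        "w_hat_pregraph": result.metrics.w_hat,
        "w_hat_filtered": result.metrics_filtered.w_hat,
        "L_pregraph": result.metrics.L,
        "L_filtered": result.metrics_filtered.L,
    }
    io.write_json(manifest, outdir / "manifest.json")
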