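"""End-to-end experiment orchestration.

An :class:`ExperimentConfig` fully describes a study: the simulation
parameters, how many topologies of which model to generate, replicate
counts per selection mode, and what to retain.  ``run_experiment`` then
executes, per topology: generate -> establish -> evolve under both modes x
replicates -> metrics and gene-level statistics, and writes tidy TSV tables
plus a JSON manifest recording every derived seed so any sub-result is
re-derivable bit for bit.

Seeds are derived hierarchically (root -> topology -> stage -> replicate)
with counter-based keys, so adding replicates never perturbs existing ones.

Two named presets ship with the package: ``"paper"`` (full study scale:
2,000 topologies, N=1,000, T=10,000, 10+10 replicates) and ``"desk"``
(a desk-scale study: 10 topologies, establishment at N=100 for 1,000
generations, noise evolution at N=200 for 500 generations, 3+3
replicates).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import NetworkGenotype
from .evolution import (
    AllOscillatingError,
    EvolutionRecord,
    establish_network,
    evolve_noise,
)
from .metrics import graph_metrics, node_strengths, synthetic_axes
from .params import SimulationParams
from .rng import child_seed
from .stats import build_gene_table
from .topology import generate_topology, write_adjacency

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "PRESETS", "preset"]


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end experiment."""

    params: SimulationParams = field(default_factory=SimulationParams)
    topology_model: str = "ER"
    n_topologies: int = 10
    density: float = 0.05
    weight_low: float = -3.0
    weight_high: float = 3.0
    replicates_selection: int = 10
    replicates_neutral: int = 10
    seed: int = 0
    output_dir: str | None = None
    keep_eta_trajectories: bool = True
    establishment_params: SimulationParams | None = None

    def __post_init__(self) -> None:
        if self.replicates_selection < 1 or self.replicates_neutral < 0:
            raise ValueError("replicate counts must be >= 1 (selection) / >= 0 (neutral)")
        if self.n_topologies < 1:
            raise ValueError("n_topologies must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["establishment_params"] = (
            None if self.establishment_params is None
            else self.establishment_params.to_dict()
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("params"), dict):
            d["params"] = SimulationParams.from_dict(d["params"])
        if isinstance(d.get("establishment_params"), dict):
            d["establishment_params"] = SimulationParams.from_dict(d["establishment_params"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load a YAML or JSON config document."""
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def preset(name: str, **overrides) -> ExperimentConfig:
    """A named configuration preset ("paper" or "desk")."""
    if name == "paper":
        cfg = ExperimentConfig(
            params=SimulationParams(),
            n_topologies=2000,
            replicates_selection=10,
            replicates_neutral=10,
        )
    elif name == "desk":
        cfg = ExperimentConfig(
            params=SimulationParams(n_pop=200, t_gen=500),
            establishment_params=SimulationParams(n_pop=100, t_gen=1000),
            n_topologies=10,
            replicates_selection=3,
            replicates_neutral=3,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


PRESETS = ("paper", "desk")


@dataclass
class ExperimentResult:
    """In-memory bundle of one experiment."""

    config: ExperimentConfig
    founders: dict  # network id -> NetworkGenotype
    establishment_logs: dict  # network id -> EstablishmentLog
    records: dict  # (network id, mode) -> list[EvolutionRecord]
    gene_tables: dict  # mode -> DataFrame
    graph_metrics_table: pd.DataFrame
    manifest: dict
    skipped: list  # network ids discarded (e.g. all-oscillating)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the configured experiment; optionally write an output bundle.

    Topologies whose establishment fails because the entire population
    oscillates are logged under ``skipped`` (the discard policy) and do not
    abort the experiment.
    """
    est_params = config.establishment_params or config.params
    founders, logs, skipped = {}, {}, []
    records: dict = {}
    metrics_rows = {}
    manifest = {
        "config": config.to_dict(),
        "topologies": {},
    }
    for t in range(config.n_topologies):
        net_id = f"net{t:04d}"
        topo_seed = int(child_seed(config.seed, 1, t).generate_state(1)[0] % (2**31))
        graph = generate_topology(
            config.topology_model,
            est_params.n_genes,
            config.density,
            config.weight_low,
            config.weight_high,
            seed=topo_seed,
        )
        est_seed = child_seed(config.seed, 2, t)
        try:
            founder, log = establish_network(graph, est_params, seed=est_seed)
        except AllOscillatingError as err:
            warnings.warn(f"{net_id}: discarded ({err})")
            skipped.append(net_id)
            manifest["topologies"][net_id] = {"topology_seed": topo_seed, "skipped": True}
            continue
        founders[net_id] = founder
        logs[net_id] = log
        metrics_rows[net_id] = graph_metrics(founder.graph)
        rep_seeds = {}
        for mode, n_reps in (
            ("selection", config.replicates_selection),
            ("neutral", config.replicates_neutral),
        ):
            recs = []
            for rep in range(n_reps):
                stage = 3 if mode == "selection" else 4
                rep_seed = child_seed(config.seed, stage, t, rep)
                recs.append(
                    evolve_noise(
                        founder,
                        config.params,
                        mode=mode,
                        seed=rep_seed,
                        s_opt=log.steady_state,
                        intermediate_mask=log.intermediate_mask,
                    )
                )
                rep_seeds[f"{mode}:{rep}"] = list(map(int, rep_seed.spawn_key))
            records[(net_id, mode)] = recs
        manifest["topologies"][net_id] = {
            "topology_seed": topo_seed,
            "establishment_seed": list(map(int, est_seed.spawn_key)),
            "replicate_seeds": rep_seeds,
            "best_fitness": logs[net_id].best_fitness,
            "n_intermediate": int(log.intermediate_mask.sum()),
        }
    gene_tables = {}
    for mode in ("selection", "neutral"):
        per_net = {nid: records[(nid, mode)] for nid in founders
                   if records.get((nid, mode))}
        if per_net:
            gene_tables[mode] = build_gene_table(
                per_net,
                {nid: node_strengths(founders[nid].graph) for nid in per_net},
                {nid: logs[nid].intermediate_mask for nid in per_net},
                pressure_threshold=config.params.pressure_threshold,
            )
    gm_table = pd.DataFrame(metrics_rows).T
    gm_table.index.name = "network"
    result = ExperimentResult(
        config=config,
        founders=founders,
        establishment_logs=logs,
        records=records,
        gene_tables=gene_tables,
        graph_metrics_table=gm_table,
        manifest=manifest,
        skipped=skipped,
    )
    if config.output_dir is not None:
        _write_bundle(result, Path(config.output_dir))
    return result


def _write_bundle(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    for mode, table in result.gene_tables.items():
        table.to_csv(outdir / f"gene_table_{mode}.tsv", sep="\t", index=False)
    result.graph_metrics_table.to_csv(outdir / "graph_metrics.tsv", sep="\t")
    if len(result.graph_metrics_table) >= 3:
        axes = synthetic_axes(result.graph_metrics_table)
        axes.scores.to_csv(outdir / "synthetic_axes.tsv", sep="\t")
        axes.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    nets = outdir / "networks"
    nets.mkdir(exist_ok=True)
    for nid, founder in result.founders.items():
        write_adjacency(founder.graph, nets / f"{nid}_weights.tsv")
        np.savetxt(nets / f"{nid}_steady_state.tsv",
                   result.establishment_logs[nid].steady_state[None], delimiter="\t")
    rec_dir = outdir / "records"
    rec_dir.mkdir(exist_ok=True)
    for (nid, mode), recs in result.records.items():
        for rep, rec in enumerate(recs):
            rec.to_frame().to_csv(rec_dir / f"{nid}_{mode}_{rep}.tsv",
                                  sep="\t", index=False)
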