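"""End-to-end orchestration: config validation and the full group-wise run.

A run takes a cohort table (real CSV or the synthetic study fixture),
performs the standard mean-comparison stage, then per group: penalized
network estimation, the full-pipeline bootstrap, edge/centrality
confidence intervals, community detection with restarts, co-assignment
stability, and all figures — into a run directory with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .boot import (
    bootstrap_pipeline,
    centrality_ci_table,
    centrality_nonoverlap_table,
    edge_ci_table,
    save_ensemble,
)
from .ggm import estimate_network, network_to_csv, network_to_graphml, path_to_csv
from .graph import best_partition, coassignment
from .groupstats import compare_groups
from .preprocess import DEFAULT_NODE_COLUMNS, load_cohort_csv, split_complete_cases
from .report import layout_circular, layout_spring, render_ci_lines, render_coassignment_panel, render_network
from .synth import make_study_fixture

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage name and group."""

    def __init__(self, stage: str, group: str | None, cause: Exception):
        self.stage, self.group = stage, group
        where = f"stage {stage!r}" + (f", group {group!r}" if group else "")
        super().__init__(f"{where}: {cause}")


@dataclass
class RunConfig:
    seed: int
    input: str = "synthetic"  # path to a cohort CSV, or "synthetic"
    output_dir: str = "runs/latest"
    group_column: str = "group"
    group_levels: list[str] | None = None
    node_columns: list[str] = field(default_factory=lambda: list(DEFAULT_NODE_COLUMNS))
    nonnormal: list[str] = field(default_factory=lambda: ["TMT"])
    B: int = 1000
    restarts: int = 100
    modularity: str = "signed"
    n_lambda: int = 100
    lambda_ratio: float = 0.01
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if self.modularity not in ("signed", "absolute"):
            raise ConfigError("modularity must be 'signed' or 'absolute'")
        if not isinstance(self.seed, int):
            raise ConfigError("seed is required and must be an integer")


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML/JSON config, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must set 'seed'")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cognet")
    root.addHandler(handler)
    artifacts: list[str] = []
    timings: dict[str, float] = {}

    def _stage(name, group, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with context
            raise StageError(name, group, exc) from exc
        timings[f"{name}:{group}" if group else name] = time.perf_counter() - t0
        log.info("stage %s%s done in %.1fs", name, f" [{group}]" if group else "",
                 timings[f"{name}:{group}" if group else name])
        return result

    def _save(relpath: str, writer) -> None:
        writer(out / relpath)
        artifacts.append(relpath)

    try:
        # --- input -------------------------------------------------------
        if config.input == "synthetic":
            table = _stage("simulate", None, make_study_fixture, config.seed)
            _save("cohort.csv", lambda p: table.to_csv(p, index=False))
        else:
            table = _stage(
                "load", None, load_cohort_csv, config.input,
                config.group_column, config.group_levels, config.node_columns,
            )
        groups_present = list(pd.unique(table[config.group_column]))
        levels = config.group_levels or groups_present

        # --- standard stage ----------------------------------------------
        comparisons = _stage(
            "groupstats", None, compare_groups, table, config.node_columns,
            config.group_column, set(config.nonnormal),
        )
        _save("group_comparisons.csv", lambda p: comparisons.to_csv(p, index=False))

        scores = _stage(
            "preprocess", None, split_complete_cases, table,
            config.group_column, config.node_columns, levels,
        )

        # --- per-group network stage ---------------------------------------
        networks, cams, cent_tables, edge_tables = {}, {}, {}, {}
        for g, sm in scores.items():
            net, ppath = _stage(
                "estimate", g, estimate_network, sm,
                config.n_lambda, config.lambda_ratio, config.gamma,
            )
            networks[g] = net
            _save(f"{g}_network.csv", lambda p, net=net: network_to_csv(net, p))
            _save(f"{g}_network.graphml", lambda p, net=net: network_to_graphml(net, p))
            _save(f"{g}_penalty_path.csv", lambda p, pp=ppath: path_to_csv(pp, p))

            part = _stage(
                "communities", g, best_partition, net,
                config.restarts, config.seed, config.modularity,
            )
            _save(
                f"{g}_partition.csv",
                lambda p, part=part, g=g: pd.DataFrame(
                    {"node": part.labels,
                     "community": [part.assignment[x] for x in part.labels],
                     "Q": part.Q}
                ).to_csv(p, index=False),
            )

            ens = _stage(
                "bootstrap", g, bootstrap_pipeline, sm, config.B,
                config.restarts, config.seed, config.modularity,
                config.n_lambda, config.lambda_ratio, config.gamma,
            )
            save_ensemble(ens, out / f"{g}_ensemble")
            artifacts.append(f"{g}_ensemble/manifest.json")

            cent_tables[g] = centrality_ci_table(ens, net)
            edge_tables[g] = edge_ci_table(ens, net)
            _save(f"{g}_centrality_ci.csv",
                  lambda p, t=cent_tables[g]: t.to_csv(p, index=False))
            _save(f"{g}_edge_ci.csv",
                  lambda p, t=edge_tables[g]: t.to_csv(p, index=False))

            cam = _stage("coassignment", g, coassignment, ens.partitions)
            cams[g] = cam
            _save(f"{g}_coassignment.csv", lambda p, c=cam: c.to_frame().to_csv(p))

            # figures
            _stage("figures", g, render_network, net, layout_circular(net.labels),
                   part, out / f"{g}_network_circular.svg")
            artifacts += [f"{g}_network_circular.svg", f"{g}_network_circular.svg.manifest.json"]
            _stage("figures", g, render_network, net,
                   layout_spring(net, seed=config.seed), part,
                   out / f"{g}_network_spring.svg")
            artifacts += [f"{g}_network_spring.svg", f"{g}_network_spring.svg.manifest.json"]

        # --- cross-group outputs -------------------------------------------
        nonoverlap = centrality_nonoverlap_table(cent_tables)
        _save("centrality_nonoverlap.csv", lambda p: nonoverlap.to_csv(p, index=False))
        render_ci_lines(cent_tables, out / "centrality_ci.svg", title="Node strength")
        artifacts += ["centrality_ci.svg", "centrality_ci.svg.manifest.json"]
        render_ci_lines(edge_tables, out / "edge_ci.svg", title="Edge weights")
        artifacts += ["edge_ci.svg", "edge_ci.svg.manifest.json"]
        for node in config.node_columns:
            render_coassignment_panel(cams, node, out / f"coassignment_{node}.svg")
            artifacts += [f"coassignment_{node}.svg",
                          f"coassignment_{node}.svg.manifest.json"]

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "groups": list(scores),
            "artifacts": sorted(set(artifacts)),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
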