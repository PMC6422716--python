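"""Nonparametric bootstrap of the full network-estimation pipeline.

Each bootstrap replicate resamples subjects with replacement (n out of
n), re-runs the entire estimation — including re-selecting the penalty
by BIC — and re-detects communities, following the convention that the
bootstrap must repeat every data-dependent choice. Edge-weight and
centrality 95% confidence intervals are the 2.5th and 97.5th empirical
percentiles of the bootstrap distributions; nonoverlap of intervals
between groups is taken as evidence of a group difference.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork, estimate_network
from .graph import CommunityPartition, best_partition, node_strength
from .preprocess import ScoreMatrix

__all__ = [
    "BootstrapEnsemble",
    "IntervalEstimate",
    "bootstrap_pipeline",
    "percentile_interval",
    "ci_nonoverlap",
    "edge_ci_table",
    "centrality_ci_table",
    "centrality_nonoverlap_table",
    "save_ensemble",
    "load_ensemble",
]

log = logging.getLogger(__name__)


@dataclass
class IntervalEstimate:
    """Full-sample point estimate with a bootstrap percentile interval."""

    point: float | None
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("interval must satisfy lo <= hi")


@dataclass
class BootstrapEnsemble:
    """B resampled networks and their community partitions for one group."""

    group_name: str
    B: int
    networks: list[PartialCorrelationNetwork]
    partitions: list[CommunityPartition]
    seed: int
    n_redraws: int = 0

    @property
    def labels(self) -> list[str]:
        return self.networks[0].labels

    def edge_weights(self) -> np.ndarray:
        """B x p x p array of bootstrap partial-correlation matrices."""
        return np.stack([net.W for net in self.networks])

    def strengths(self) -> np.ndarray:
        """B x p array of bootstrap node strengths."""
        return np.stack([node_strength(net).strength for net in self.networks])


def _bootstrap_seed(seed: int, b: int, stream: int) -> int:
    """Deterministic, stream-separated sub-seed (kept below 2**31)."""
    return int(np.random.SeedSequence([seed, b, stream]).generate_state(1)[0] % (2**31))


def bootstrap_pipeline(
    scores: ScoreMatrix,
    B: int = 1000,
    restarts: int = 100,
    seed: int = 0,
    mode: str = "signed",
    n_lambda: int = 100,
    ratio: float = 0.01,
    gamma: float = 0.0,
) -> BootstrapEnsemble:
    """Run estimation + community detection on B with-replacement resamples.

    Per-bootstrap RNG streams are derived deterministically from ``seed``
    and the bootstrap index, so runs are reproducible regardless of
    execution order. A degenerate resample (some column constant, so no
    correlation matrix exists) is redrawn and counted; more than 5% of B
    redraws aborts, because then n is too small for the bootstrap to be
    meaningful.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = scores.n
    max_redraws = max(1, int(0.05 * B))
    redraws = 0
    networks, partitions = [], []
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b, 0]))
        while True:
            idx = rng.integers(0, n, size=n)
            Xb = scores.X[idx]
            if np.ptp(Xb, axis=0).min() > 0:
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} degenerate bootstrap resamples "
                    f"(constant column); n={n} is too small"
                )
        boot_scores = ScoreMatrix(
            group_name=scores.group_name, labels=scores.labels, X=Xb
        )
        net, _ = estimate_network(
            boot_scores, n_lambda=n_lambda, ratio=ratio, gamma=gamma
        )
        part = best_partition(
            net, restarts=restarts, seed=_bootstrap_seed(seed, b, 1), mode=mode
        )
        networks.append(net)
        partitions.append(part)
    if redraws:
        log.info("group %s: %d degenerate resamples redrawn", scores.group_name, redraws)
    return BootstrapEnsemble(
        group_name=scores.group_name,
        B=B,
        networks=networks,
        partitions=partitions,
        seed=seed,
        n_redraws=redraws,
    )


def percentile_interval(values, point: float | None = None) -> IntervalEstimate:
    """95% percentile interval (2.5th / 97.5th, linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot form an interval from an empty sample")
    if values.size < 40:
        warnings.warn(
            f"only {values.size} bootstrap values; the 95% percentile "
            "interval will be unreliable"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return IntervalEstimate(point=point, lo=float(lo), hi=float(hi))


def ci_nonoverlap(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """True iff the two closed intervals are disjoint (touching = overlap)."""
    return a.hi < b.lo or b.hi < a.lo


def edge_ci_table(
    ensemble: BootstrapEnsemble, full_net: PartialCorrelationNetwork
) -> pd.DataFrame:
    """Tidy per-edge table: point estimate plus bootstrap 95% CI."""
    weights = ensemble.edge_weights()
    labels = full_net.labels
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ci = percentile_interval(weights[:, i, j], point=float(full_net.W[i, j]))
            rows.append(
                {
                    "group": ensemble.group_name,
                    "node_a": labels[i],
                    "node_b": labels[j],
                    "point": ci.point,
                    "lo": ci.lo,
                    "hi": ci.hi,
                }
            )
    return pd.DataFrame(rows)


def centrality_ci_table(
    ensemble: BootstrapEnsemble, full_net: PartialCorrelationNetwork
) -> pd.DataFrame:
    """Tidy per-node strength table: point estimate plus bootstrap 95% CI."""
    strengths = ensemble.strengths()
    point = node_strength(full_net).strength
    rows = []
    for i, lbl in enumerate(full_net.labels):
        ci = percentile_interval(strengths[:, i], point=float(point[i]))
        rows.append(
            {
                "group": ensemble.group_name,
                "node": lbl,
                "point": ci.point,
                "lo": ci.lo,
                "hi": ci.hi,
            }
        )
    return pd.DataFrame(rows)


def centrality_nonoverlap_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise group comparison of node centralities by CI nonoverlap."""
    groups = list(tables)
    rows = []
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            a = tables[groups[gi]].set_index("node")
            b = tables[groups[gj]].set_index("node")
            for node in a.index:
                ia = IntervalEstimate(a.loc[node, "point"], a.loc[node, "lo"], a.loc[node, "hi"])
                ib = IntervalEstimate(b.loc[node, "point"], b.loc[node, "lo"], b.loc[node, "hi"])
                rows.append(
                    {
                        "node": node,
                        "group_a": groups[gi],
                        "group_b": groups[gj],
                        "nonoverlap": ci_nonoverlap(ia, ib),
                    }
                )
    return pd.DataFrame(rows)


def save_ensemble(ensemble: BootstrapEnsemble, directory: str | Path) -> None:
    """Persist as a directory of matrix CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = ensemble.labels
    for b, (net, part) in enumerate(zip(ensemble.networks, ensemble.partitions)):
        pd.DataFrame(net.W, index=labels, columns=labels).to_csv(
            directory / f"network_{b:04d}.csv"
        )
    parts = pd.DataFrame(
        {
            "bootstrap": np.repeat(range(ensemble.B), len(labels)),
            "node": labels * ensemble.B,
            "community": [
                p.assignment[lbl] for p in ensemble.partitions for lbl in labels
            ],
            "Q": np.repeat([p.Q for p in ensemble.partitions], len(labels)),
        }
    )
    parts.to_csv(directory / "partitions.csv", index=False)
    manifest = {
        "group_name": ensemble.group_name,
        "B": ensemble.B,
        "seed": ensemble.seed,
        "n_redraws": ensemble.n_redraws,
        "labels": labels,
        "lambdas": [net.lambda_selected for net in ensemble.networks],
        "n": ensemble.networks[0].n,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory: str | Path) -> BootstrapEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    labels = manifest["labels"]
    networks = []
    for b in range(manifest["B"]):
        W = pd.read_csv(directory / f"network_{b:04d}.csv", index_col=0).to_numpy()
        networks.append(
            PartialCorrelationNetwork(
                labels=labels,
                W=W,
                lambda_selected=manifest["lambdas"][b],
                n=manifest["n"],
                group_name=manifest["group_name"],
            )
        )
    parts_df = pd.read_csv(directory / "partitions.csv")
    partitions = []
    for b, grp in parts_df.groupby("bootstrap"):
        assignment = dict(zip(grp["node"], grp["community"].astype(int)))
        partitions.append(
            CommunityPartition(
                labels=labels, assignment=assignment, Q=float(grp["Q"].iloc[0])
            )
        )
    return BootstrapEnsemble(
        group_name=manifest["group_name"],
        B=manifest["B"],
        networks=networks,
        partitions=partitions,
        seed=manifest["seed"],
        n_redraws=manifest["n_redraws"],
    )
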