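"""Self-contained validation studies for the whole pipeline.

Each function here sets up a known ground truth (a planted Gaussian
graphical model, an independence null, or an exhaustive search), runs
the package's own estimation path on data generated under that truth,
and returns a scalar quality measure: oracle agreement, structure
recovery, confidence-interval coverage, community-stability separation,
null calibration, and determinism. The oracles (regression-residual
partial correlations, exhaustive partition enumeration) are deliberately
independent of the implementation paths they check.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path
from typing import Iterator

import numpy as np

from .boot import bootstrap_pipeline, edge_ci_table, percentile_interval
from .ggm import estimate_network, glasso_solve, precision_to_partial
from .graph import best_partition, coassignment, modularity_Q
from .groupstats import oneway_anova
from .pipeline import RunConfig, run_pipeline
from .preprocess import ScoreMatrix, split_complete_cases
from .synth import (
    NODE_ORDER,
    CohortSpec,
    PlantedModel,
    make_planted_precision,
    make_study_fixture,
    sample_cohort,
)

__all__ = [
    "make_twoblock_model",
    "residual_partial_correlations",
    "iter_partitions",
    "brute_force_best_partition",
    "partial_corr_oracle_error",
    "modularity_bruteforce_match",
    "structure_recovery",
    "edge_ci_coverage",
    "coassignment_separation",
    "null_calibration",
    "anova_type1_rate",
    "determinism_check",
]

TWOBLOCK_BLOCKS = {lbl: (0 if i < 4 else 1) for i, lbl in enumerate(NODE_ORDER)}


def make_twoblock_model(
    within: float = 0.3, memory_edge: float | None = None
) -> PlantedModel:
    """Planted 9-node, 2-block benchmark model (blocks of 4 and 5 nodes).

    All within-block pairs get partial correlation ``within``; optionally
    the 15T-15R pair is strengthened to ``memory_edge`` (the verbal-memory
    analog). Cross-block pairs are conditionally independent.
    """
    overrides = {("15T", "15R"): memory_edge} if memory_edge is not None else None
    return make_planted_precision(
        NODE_ORDER, TWOBLOCK_BLOCKS, within_strength=within, edge_overrides=overrides
    )


def _sample_scores(model: PlantedModel, n: int, seed: int, name: str = "sim") -> ScoreMatrix:
    spec = CohortSpec(groups=[(name, n, model)], seed=seed)
    table = sample_cohort(spec)
    return split_complete_cases(table, node_columns=model.labels)[name]


def residual_partial_correlations(X: np.ndarray) -> np.ndarray:
    """Partial correlations by the regression-residual definition.

    For each pair (i, j), regress both variables on all remaining ones
    (with intercept) by least squares and correlate the residuals. This
    route never touches a precision matrix, so it is an independent
    oracle for the standardized-negated-inverse formula.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            A = Xc[:, rest]
            ri = Xc[:, i] - A @ np.linalg.lstsq(A, Xc[:, i], rcond=None)[0]
            rj = Xc[:, j] - A @ np.linalg.lstsq(A, Xc[:, j], rcond=None)[0]
            W[i, j] = W[j, i] = float(np.corrcoef(ri, rj)[0, 1])
    return W


def iter_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of n items as restricted-growth strings."""
    a = [0] * n

    def rec(i: int, width: int):
        if i == n:
            yield tuple(a)
            return
        for c in range(width + 1):
            a[i] = c
            yield from rec(i + 1, width + 1 if c == width else width)

    yield from rec(0, 0)


def brute_force_best_partition(W: np.ndarray, mode: str = "signed") -> tuple[tuple[int, ...], float]:
    """Exhaustive modularity maximization over all partitions (small p)."""
    best_q, best_part = -np.inf, None
    for part in iter_partitions(W.shape[0]):
        q = modularity_Q(W, np.array(part), mode=mode)
        if q > best_q:
            best_q, best_part = q, part
    return best_part, best_q


# --------------------------------------------------------------------------
# validation studies


def partial_corr_oracle_error(seed: int, n: int = 10_000) -> float:
    """Max |difference| between unpenalized (lambda=0) network weights and
    regression-residual partial correlations on the same sample."""
    scores = _sample_scores(make_twoblock_model(), n=n, seed=seed)
    Theta = glasso_solve(scores.correlation, 0.0)
    W = precision_to_partial(Theta)
    W_oracle = residual_partial_correlations(scores.X)
    return float(np.abs(W - W_oracle).max())


def modularity_bruteforce_match(
    seed: int, n_graphs: int = 100, restarts: int = 100, max_nodes: int = 6
) -> tuple[int, int]:
    """Count random small graphs on which best-of-restarts Louvain attains
    the exhaustive-search modularity optimum (within 1e-9)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for g in range(n_graphs):
        p = int(rng.integers(4, max_nodes + 1))
        W = np.zeros((p, p))
        iu = np.triu_indices(p, k=1)
        mask = rng.random(len(iu[0])) < 0.6
        w = rng.uniform(-1, 1, size=len(iu[0])) * mask
        W[iu] = w
        W += W.T
        _, q_star = brute_force_best_partition(W)
        part = best_partition(W, restarts=restarts, seed=int(rng.integers(2**31)))
        if part.Q >= q_star - 1e-9:
            hits += 1
    return hits, n_graphs


def structure_recovery(
    seed: int, reps: int = 50, n: int = 5000, within: float = 0.3
) -> tuple[float, float]:
    """Edge sensitivity and false-edge rate of BIC-selected networks on
    samples from the planted 2-block model."""
    model = make_twoblock_model(within=within)
    true_edges = model.edge_set()
    p = model.p
    all_pairs = {(model.labels[i], model.labels[j])
                 for i in range(p) for j in range(i + 1, p)}
    non_edges = all_pairs - true_edges
    sens, fpr = [], []
    for r in range(reps):
        scores = _sample_scores(model, n=n, seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31))
        net, _ = estimate_network(scores)
        found = net.edge_set()
        sens.append(len(found & true_edges) / len(true_edges))
        fpr.append(len(found & non_edges) / len(non_edges))
    return float(np.mean(sens)), float(np.mean(fpr))


def edge_ci_coverage(
    seed: int, reps: int = 25, n: int = 500, B: int = 200
) -> tuple[float, int]:
    """Empirical coverage of bootstrap 95% percentile CIs for the planted
    nonzero edges, pooled over edges and outer replicates."""
    model = make_twoblock_model()
    truth = model.partial_correlations()
    labels = model.labels
    idx = {lbl: i for i, lbl in enumerate(labels)}
    true_edges = sorted(model.edge_set())
    covered = total = 0
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)
        scores = _sample_scores(model, n=n, seed=rep_seed)
        net, _ = estimate_network(scores)
        ens = bootstrap_pipeline(scores, B=B, restarts=1, seed=rep_seed)
        table = edge_ci_table(ens, net)
        table = table.set_index(["node_a", "node_b"])
        for a, b in true_edges:
            row = table.loc[(a, b)] if (a, b) in table.index else table.loc[(b, a)]
            rho = truth[idx[a], idx[b]]
            covered += int(row["lo"] <= rho <= row["hi"])
            total += 1
    return covered / total, total


def coassignment_separation(
    seed: int, n: int = 2000, B: int = 200, restarts: int = 10
) -> dict[str, float]:
    """Within/between-block co-assignment proportions under the full
    pipeline on the planted 2-block model with a 0.6 memory edge.

    Within-block strength 0.2 keeps the model positive definite without
    loading once the 0.6 edge is added (a 0.3 block plus a 0.6 pair has
    a negative eigenvalue), so the planted values are exact."""
    model = make_twoblock_model(within=0.2, memory_edge=0.6)
    scores = _sample_scores(model, n=n, seed=seed)
    ens = bootstrap_pipeline(scores, B=B, restarts=restarts, seed=seed)
    cam = coassignment(ens.partitions)
    blocks = np.array([model.communities[lbl] for lbl in cam.labels])
    same = blocks[:, None] == blocks[None, :]
    off = ~np.eye(len(blocks), dtype=bool)
    return {
        "within_min": float(cam.P[same & off].min()),
        "between_max": float(cam.P[~same].max()),
        "memory_pair": float(cam.P[cam.labels.index("15T"), cam.labels.index("15R")]),
    }


def null_calibration(seed: int, reps: int = 100, n: int = 65, p: int = 9) -> tuple[float, float]:
    """Fraction of empty selected networks and mean false-edge count on
    independent Gaussian data at study-scale n."""
    rng = np.random.default_rng(seed)
    empty = 0
    false_edges = []
    for _ in range(reps):
        X = rng.standard_normal((n, p))
        scores = ScoreMatrix(group_name="null", labels=[f"v{i}" for i in range(p)], X=X)
        net, _ = estimate_network(scores)
        e = len(net.edge_set())
        empty += int(e == 0)
        false_edges.append(e)
    return empty / reps, float(np.mean(false_edges))


def anova_type1_rate(seed: int, reps: int = 500, alpha: float = 0.05) -> tuple[float, int]:
    """Per-variable ANOVA rejection rate on the equal-means study fixture,
    pooled over variables and replicates (type-I calibration)."""
    rejections = total = 0
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)
        table = make_study_fixture(rep_seed)
        for var in NODE_ORDER:
            res = oneway_anova(table[var], table["group"], variable=var, alpha=alpha)
            rejections += int(res.p_value < alpha)
            total += 1
    return rejections / total, total


def determinism_check(seed: int) -> bool:
    """Run the reduced pipeline twice with one seed; True iff key numeric
    artifacts (networks, partitions, CIs, co-assignment, figure manifests)
    are byte-identical."""
    compare = [
        "control_network.csv",
        "control_partition.csv",
        "control_centrality_ci.csv",
        "control_edge_ci.csv",
        "control_coassignment.csv",
        "control_network_circular.svg.manifest.json",
        "centrality_ci.svg.manifest.json",
    ]
    with tempfile.TemporaryDirectory() as tmp:
        dirs = []
        for tag in ("a", "b"):
            cfg = RunConfig(
                seed=seed, output_dir=str(Path(tmp) / tag), B=5, restarts=3, n_lambda=25
            )
            dirs.append(run_pipeline(cfg))
        return all(filecmp.cmp(dirs[0] / f, dirs[1] / f, shallow=False) for f in compare)
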