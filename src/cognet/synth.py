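"""Synthetic cohorts with planted conditional-dependence structure.

Every downstream stage (penalized network estimation, bootstrap stability,
community detection) is exercised against cohorts sampled from multivariate
Gaussian models whose sparse precision matrices encode known communities.
Group means are identical across groups by construction, so differences
between groups live entirely in the conditional-dependence structure —
the situation the network analysis is designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlantedModel",
    "CohortSpec",
    "make_planted_precision",
    "sample_cohort",
    "make_study_fixture",
    "study_models",
    "write_cohort_csv",
    "write_ground_truth",
    "NODE_ORDER",
]

#: canonical node order for the nine-score battery
NODE_ORDER = ["15T", "15R", "DSB", "FLU", "STR", "TMT", "FAP", "FID", "FEF"]

#: plausible raw-score scales (means / SDs) per node; irrelevant to network
#: estimation (which standardizes) but exercises the preprocessing path.
DEFAULT_MEANS = {
    "15T": 45.0, "15R": 9.0, "DSB": 8.0, "FLU": 34.0, "STR": 1.9,
    "TMT": 2.4, "FAP": 32.0, "FID": 28.0, "FEF": 42.0,
}
DEFAULT_SDS = {
    "15T": 10.0, "15R": 3.0, "DSB": 2.0, "FLU": 11.0, "STR": 0.45,
    "TMT": 0.8, "FAP": 8.0, "FID": 7.0, "FEF": 10.0,
}


@dataclass
class PlantedModel:
    """Ground-truth Gaussian graphical model for one group.

    ``precision`` is symmetric positive definite with unit diagonal; its
    negated, standardized off-diagonal entries are the planted partial
    correlations, and its zero pattern is the planted edge set.
    """

    labels: list[str]
    precision: np.ndarray
    communities: dict[str, int]
    group_name: str = ""

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if P.shape != (len(self.labels), len(self.labels)):
            raise ValueError("precision shape does not match labels")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("precision must be positive definite")
        if set(self.communities) != set(self.labels):
            raise ValueError("communities must cover exactly the labels")
        self.precision = P

    @property
    def p(self) -> int:
        return len(self.labels)

    def partial_correlations(self) -> np.ndarray:
        """Planted partial correlations: rho_ij = -P_ij / sqrt(P_ii P_jj)."""
        d = np.sqrt(np.diag(self.precision))
        R = -self.precision / np.outer(d, d)
        np.fill_diagonal(R, 0.0)
        return R

    def covariance(self) -> np.ndarray:
        """Model covariance (inverse precision), as a correlation matrix."""
        C = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(C))
        return C / np.outer(d, d)

    def edge_set(self, tol: float = 1e-12) -> set[tuple[str, str]]:
        """Planted edges as sorted label pairs."""
        edges = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.precision[i, j]) > tol:
                    edges.add((self.labels[i], self.labels[j]))
        return edges


@dataclass
class CohortSpec:
    """Sampling recipe: per-group sizes and models, score scales, seed."""

    groups: list[tuple[str, int, PlantedModel]]
    seed: int
    mean_vector: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sd_vector: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))

    def __post_init__(self) -> None:
        for name, n, model in self.groups:
            if n < model.p + 1:
                raise ValueError(f"group {name!r}: n={n} < p+1={model.p + 1}")
        for lbl, sd in self.sd_vector.items():
            if sd <= 0:
                raise ValueError(f"sd for {lbl!r} must be > 0")


def make_planted_precision(
    labels: list[str],
    blocks: dict[str, int],
    within_strength: float,
    between_strength: float = 0.0,
    seed: int = 0,
    edge_overrides: dict[tuple[str, str], float] | None = None,
    max_loading_iter: int = 60,
) -> PlantedModel:
    """Build a standardized precision matrix with block-structured support.

    Every pair of nodes in the same block gets partial correlation
    ``within_strength``; pairs in different blocks get ``between_strength``
    (default 0, i.e. conditionally independent). ``edge_overrides`` pins
    individual pairs to a different partial correlation. If the implied
    matrix is not positive definite, diagonal loading (add eps*I, doubling
    eps until the smallest eigenvalue exceeds 1e-8) is applied and the
    matrix re-standardized to unit diagonal, which shrinks the planted
    magnitudes; a loaded model records the achieved values in ``precision``.
    """
    if abs(within_strength) >= 1:
        raise ValueError("|within_strength| must be < 1")
    if set(blocks) != set(labels):
        raise ValueError("blocks must cover all labels")
    p = len(labels)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    P = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            same = blocks[labels[i]] == blocks[labels[j]]
            rho = within_strength if same else between_strength
            P[i, j] = P[j, i] = -rho
    if edge_overrides:
        for (a, b), rho in edge_overrides.items():
            P[idx[a], idx[b]] = P[idx[b], idx[a]] = -rho

    eps, it = 1e-10, 0
    while np.linalg.eigvalsh(P).min() <= 1e-8:
        if it >= max_loading_iter:
            raise RuntimeError(
                "planted precision not positive definite after maximum "
                "diagonal-loading iterations"
            )
        P = P + eps * np.eye(p)
        d = np.sqrt(np.diag(P))
        P = P / np.outer(d, d)
        eps *= 2
        it += 1

    return PlantedModel(labels=list(labels), precision=P, communities=dict(blocks))


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort table: one row per subject, one column per score.

    For each group, n i.i.d. draws from N(mean, D R D) where R is the
    model's implied correlation matrix and D = diag(sd). Group draws use
    independent, deterministic RNG streams spawned from ``spec.seed``.
    """
    frames = []
    for g, (name, n, model) in enumerate(spec.groups):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g]))
        R = model.covariance()
        sd = np.array([spec.sd_vector[lbl] for lbl in model.labels])
        mu = np.array([spec.mean_vector[lbl] for lbl in model.labels])
        cov = R * np.outer(sd, sd)
        X = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        df = pd.DataFrame(X, columns=model.labels)
        df.insert(0, "group", name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(out))])
    return out


def study_models() -> dict[str, PlantedModel]:
    """The three planted models emulating the study's qualitative structure.

    All groups share a strong verbal-memory edge (15T-15R, partial
    correlation 0.6) and a DSB-FLU edge (0.4). In the frontal model,
    {15T, 15R, DSB, FLU} form a single block (memory + working memory +
    fluency merge into one community); in the control and non-frontal
    models the memory pair stays separate from {DSB, FLU}. All models
    keep an executive-speed block {STR, TMT} and a behavioral block
    {FAP, FID, FEF}.
    """
    merged = {
        "15T": 0, "15R": 0, "DSB": 0, "FLU": 0,
        "STR": 1, "TMT": 1, "FAP": 2, "FID": 2, "FEF": 2,
    }
    split = {
        "15T": 0, "15R": 0, "DSB": 1, "FLU": 1,
        "STR": 2, "TMT": 2, "FAP": 3, "FID": 3, "FEF": 3,
    }
    overrides = {("15T", "15R"): 0.6, ("DSB", "FLU"): 0.4}
    frontal = make_planted_precision(
        NODE_ORDER, merged, within_strength=0.15, edge_overrides=overrides
    )
    frontal.group_name = "frontal"
    models = {"frontal": frontal}
    for name in ("control", "nonfrontal"):
        m = make_planted_precision(
            NODE_ORDER, split, within_strength=0.3, edge_overrides=overrides
        )
        m.group_name = name
        models[name] = m
    return models


def make_study_fixture(seed: int, n_override: dict[str, int] | None = None) -> pd.DataFrame:
    """Three-group cohort table emulating the study: n = 67 / 66 / 61.

    Group means are identical across groups (the study found no mean
    differences on the cognitive measures); only the conditional-dependence
    structure differs. ``n_override`` inflates group sizes for oracle checks.
    """
    models = study_models()
    sizes = {"control": 67, "nonfrontal": 66, "frontal": 61}
    if n_override:
        sizes.update(n_override)
    spec = CohortSpec(
        groups=[(g, sizes[g], models[g]) for g in ("control", "nonfrontal", "frontal")],
        seed=seed,
    )
    return sample_cohort(spec)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_ground_truth(models: dict[str, PlantedModel], seed: int, path: str | Path) -> None:
    """Persist precision matrices, block maps and the sampling seed as JSON."""
    payload = {
        "seed": seed,
        "groups": {
            name: {
                "labels": m.labels,
                "precision": m.precision.tolist(),
                "communities": m.communities,
            }
            for name, m in models.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
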