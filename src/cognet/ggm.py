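"""Sparse partial-correlation networks via the graphical lasso with BIC.

Per group, the Gaussian precision matrix is estimated by L1-penalized
maximum likelihood,

    maximize  log det(Theta) - tr(S Theta) - lambda * sum_{i!=j} |Theta_ij|,

with the penalty on off-diagonal entries only (the qgraph/EBICglasso
convention; diagonal penalization would distort partial-correlation
magnitudes). The penalty strength is chosen by minimizing the (E)BIC over
a descending log-spaced grid, and the selected precision matrix is
rescaled to partial correlations rho_ij = -Theta_ij / sqrt(Theta_ii
Theta_jj). Zero entries of the solution are exact zeros, so the nonzero
pattern is the estimated edge set.

The solver is Friedman-style block coordinate descent on the covariance
(each column update is a lasso), jitted with numba because the bootstrap
re-fits the whole penalty path thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .preprocess import ScoreMatrix

__all__ = [
    "PenaltyPath",
    "PartialCorrelationNetwork",
    "glasso_solve",
    "precision_to_partial",
    "bic_score",
    "lambda_grid",
    "estimate_network",
    "network_to_csv",
    "network_to_graphml",
    "path_to_csv",
]


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_outer, inner_tol, max_inner):
    """Block coordinate descent; W and B are updated in place.

    W is the working covariance estimate (diagonal fixed at S's diagonal,
    i.e. unpenalized); B[:, j] holds the lasso coefficients of column j.
    Returns the number of outer sweeps used, or -1 if not converged.
    """
    p = S.shape[0]
    for outer in range(max_outer):
        max_d = 0.0
        for j in range(p):
            for _ in range(max_inner):
                d_in = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    old = B[k, j]
                    if r > lam:
                        b = (r - lam) / W[k, k]
                    elif r < -lam:
                        b = (r + lam) / W[k, k]
                    else:
                        b = 0.0
                    B[k, j] = b
                    d = abs(b - old)
                    if d > d_in:
                        d_in = d
                if d_in < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > max_d:
                    max_d = d
                W[k, j] = w
                W[j, k] = w
        if max_d < tol:
            return outer + 1
    return -1


def _theta_from_wb(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Recover the precision matrix from the converged (W, B) pair.

    theta_jj = 1 / (W_jj - w12' beta_j), theta_ij = -beta_ij * theta_jj.
    Off-diagonals are exactly zero only where both column problems agree
    the coefficient is zero, which holds at convergence by the KKT
    conditions; elsewhere the two estimates are averaged.
    """
    p = W.shape[0]
    diag = np.empty(p)
    for j in range(p):
        beta = B[:, j]
        denom = W[j, j] - float(W[:, j] @ beta)
        if denom <= 0:
            raise np.linalg.LinAlgError("graphical lasso produced a nonpositive pivot")
        diag[j] = 1.0 / denom
    Theta = np.zeros_like(W)
    for i in range(p):
        for j in range(p):
            if i == j:
                Theta[i, j] = diag[j]
            elif B[i, j] == 0.0 and B[j, i] == 0.0:
                Theta[i, j] = 0.0
            else:
                Theta[i, j] = -0.5 * (B[i, j] * diag[j] + B[j, i] * diag[i])
    return Theta


def glasso_solve(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Solve one graphical-lasso problem, returning the precision estimate.

    Parameters
    ----------
    S : correlation (or covariance) matrix, symmetric PSD.
    lam : penalty on off-diagonal precision entries, >= 0.
    warm : optional (W, B) pair from a nearby lambda, updated in place.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0.0:
        # unpenalized problem: the exact maximizer is S^-1, and coordinate
        # descent converges too slowly on ill-conditioned S to beat it
        Theta = np.linalg.inv(S)
        return 0.5 * (Theta + Theta.T)
    if warm is None:
        W = S.copy()
        B = np.zeros_like(S)
    else:
        W, B = warm
    sweeps = _glasso_cd(S, float(lam), W, B, tol, max_iter, tol * 1e-2, 200)
    if sweeps < 0:
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={lam:.6g} "
            f"within {max_iter} sweeps (tolerance {tol:g})"
        )
    return _theta_from_wb(W, B)


def precision_to_partial(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix (zero diagonal)."""
    Theta = np.asarray(Theta, dtype=float)
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have a strictly positive diagonal")
    W = -Theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(W, 0.0)
    return W


def bic_score(Theta: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.0) -> float:
    """Extended BIC of a precision estimate; gamma=0 is the plain BIC.

    BIC = -2*l + E*ln(n) + 4*gamma*E*ln(p), with Gaussian profile
    log-likelihood l = (n/2)(log det Theta - tr(S Theta)) (additive
    constant dropped) and E the number of nonzero upper-triangle
    off-diagonal entries.
    """
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = Theta.shape[0]
    ll = 0.5 * n * (logdet - float(np.trace(S @ Theta)))
    E = int(np.count_nonzero(np.triu(Theta, k=1)))
    return -2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def lambda_grid(S: np.ndarray, n_lambda: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max = max |S_ij|, i!=j.

    At lambda_max the estimated network is empty, so the grid spans the
    full range from no edges down to (nearly) unpenalized.
    """
    S = np.asarray(S, dtype=float)
    off = S[~np.eye(S.shape[0], dtype=bool)]
    lam_max = float(np.max(np.abs(off))) if off.size else 0.0
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; single-point grid at 0")
        return np.array([0.0])
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


@dataclass
class PenaltyPath:
    """BIC path over the penalty grid, including the selected model."""

    lambdas: np.ndarray
    bics: np.ndarray
    loglik: np.ndarray
    edge_counts: np.ndarray
    selected_index: int

    def __post_init__(self) -> None:
        if len(self.lambdas) > 1 and not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")
        if np.any(np.diff(self.edge_counts) < 0):
            warnings.warn("edge count is not monotone along the penalty path")


@dataclass
class PartialCorrelationNetwork:
    """Penalized partial-correlation network for one group."""

    labels: list[str]
    W: np.ndarray
    lambda_selected: float
    n: int
    group_name: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("network matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("network matrix must have a zero diagonal")
        if np.any(np.abs(W) >= 1):
            raise ValueError("partial correlations must satisfy |w| < 1")
        self.W = W

    @property
    def p(self) -> int:
        return len(self.labels)

    def edge_set(self) -> set[tuple[str, str]]:
        edges = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.W[i, j] != 0.0:
                    edges.add((self.labels[i], self.labels[j]))
        return edges


def estimate_network(
    scores: ScoreMatrix,
    n_lambda: int = 100,
    ratio: float = 0.01,
    gamma: float = 0.0,
    tol: float = 1e-6,
) -> tuple[PartialCorrelationNetwork, PenaltyPath]:
    """Fit the penalty path on a group's correlation matrix, select by BIC.

    Ties in BIC (within 1e-9) are broken toward the larger penalty, i.e.
    the sparser model. Estimation uses the correlation matrix, so the
    result is invariant to affine rescaling of the score columns.
    """
    S = scores.correlation
    n = scores.n
    lambdas = lambda_grid(S, n_lambda=n_lambda, ratio=ratio)
    W = S.copy()
    B = np.zeros_like(S)
    bics, lls, edges, thetas = [], [], [], []
    for lam in lambdas:
        Theta = glasso_solve(S, lam, tol=tol, warm=(W, B))
        sign, logdet = np.linalg.slogdet(Theta)
        ll = 0.5 * n * (logdet - float(np.trace(S @ Theta)))
        E = int(np.count_nonzero(np.triu(Theta, k=1)))
        bics.append(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(len(scores.labels)))
        lls.append(ll)
        edges.append(E)
        thetas.append(Theta)
    bics = np.asarray(bics)
    best = int(np.flatnonzero(bics <= bics.min() + 1e-9)[0])
    path = PenaltyPath(
        lambdas=np.asarray(lambdas),
        bics=bics,
        loglik=np.asarray(lls),
        edge_counts=np.asarray(edges),
        selected_index=best,
    )
    net = PartialCorrelationNetwork(
        labels=list(scores.labels),
        W=precision_to_partial(thetas[best]),
        lambda_selected=float(lambdas[best]),
        n=n,
        group_name=scores.group_name,
    )
    return net, path


def network_to_csv(net: PartialCorrelationNetwork, path: str | Path) -> None:
    pd.DataFrame(net.W, index=net.labels, columns=net.labels).to_csv(path)


def network_to_graphml(net: PartialCorrelationNetwork, path: str | Path) -> None:
    G = nx.Graph(group=net.group_name, lambda_selected=net.lambda_selected, n=net.n)
    G.add_nodes_from(net.labels)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if net.W[i, j] != 0.0:
                G.add_edge(net.labels[i], net.labels[j], weight=float(net.W[i, j]))
    nx.write_graphml(G, path)


def path_to_csv(path_obj: PenaltyPath, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lambda": path_obj.lambdas,
            "loglik": path_obj.loglik,
            "edges": path_obj.edge_counts,
            "bic": path_obj.bics,
            "selected": [i == path_obj.selected_index for i in range(len(path_obj.lambdas))],
        }
    ).to_csv(path, index=False)
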