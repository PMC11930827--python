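"""eLasso estimation of an Ising comorbidity network.

Each disease (node) is regressed on all others with l1-penalized logistic
regression over a decreasing penalty path; the Extended Bayesian Information
Criterion,

    EBIC(lambda) = -2 ll + df log n + 2 gamma df log(p - 1),

with df the number of non-zero slopes, selects one model per node.  Node-wise
coefficient pairs are then symmetrized (AND rule by default: an edge survives
only if both regressions select it, with the averaged coefficient as weight).
A positive weight w_ij means the two diseases co-occur more often than their
baselines predict; a negative weight, less often.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import logistic_lasso_path
from .etl import ComorbidityMatrix

__all__ = [
    "IsingNetwork",
    "NodewiseFit",
    "conditional_probability",
    "lambda_path",
    "fit_node",
    "symmetrize",
    "fit_ising",
]


@dataclass
class IsingNetwork:
    """Symmetric edge-weight matrix plus per-node thresholds."""

    weights: np.ndarray          # (p, p), symmetric, zero diagonal
    thresholds: np.ndarray       # (p,)
    labels: list[str]
    n_rows: int = 0
    ebic_gamma: float = 0.25
    rule: str = "AND"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        self.weights = w
        self.thresholds = np.asarray(self.thresholds, dtype=float)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def index(self, node: str | int) -> int:
        if isinstance(node, (int, np.integer)):
            if not 0 <= node < self.p:
                raise KeyError(f"node index {node} out of range")
            return int(node)
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame({
            "code_i": [self.labels[a] for a in i],
            "code_j": [self.labels[b] for b in j],
            "weight": self.weights[i, j],
        })

    def to_edgelist_tsv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def to_thresholds_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"node": self.labels, "threshold": self.thresholds}).to_csv(
            path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx
        g = nx.Graph()
        for lbl, thr in zip(self.labels, self.thresholds):
            g.add_node(lbl, threshold=float(thr))
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["code_i"], row["code_j"], weight=float(row["weight"]))
        nx.write_graphml(g, path)


@dataclass
class NodewiseFit:
    """The full regularization path of one node's logistic regression."""

    node: int
    label: str
    neighbor_labels: list[str]
    lambdas: np.ndarray          # (L,) decreasing
    coefs: np.ndarray            # (L, p-1) slopes on the other nodes
    intercepts: np.ndarray       # (L,)
    loglik: np.ndarray           # (L,) unpenalized log-likelihood
    ebic: np.ndarray             # (L,)
    selected: int                # index minimizing EBIC
    degenerate: bool = False

    @property
    def selected_coefs(self) -> np.ndarray:
        return self.coefs[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])

    def path_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "lambda": self.lambdas,
            "loglik": self.loglik,
            "df": (self.coefs != 0).sum(axis=1),
            "ebic": self.ebic,
        })
        df["selected"] = df.index == self.selected
        return df


def _as_array(X: ComorbidityMatrix | np.ndarray | pd.DataFrame
              ) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ComorbidityMatrix):
        return X.values.astype(np.float64), X.codes
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=np.float64)
    return arr, [f"V{i}" for i in range(arr.shape[1])]


def conditional_probability(net: IsingNetwork, x: Sequence[int], i: str | int
                            ) -> float:
    """P(x_i = 1 | x_-i) = sigmoid(b_i + Σ_{j != i} w_ij x_j)."""
    idx = net.index(i)
    x = np.asarray(x, dtype=float)
    if x.shape != (net.p,):
        raise ValueError(f"x must have {net.p} entries")
    eta = net.thresholds[idx] + net.weights[idx] @ x - net.weights[idx, idx] * x[idx]
    return float(1.0 / (1.0 + np.exp(-eta)))


def lambda_path(Z: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                lambda_min_ratio: float = 0.01) -> np.ndarray:
    """glmnet-style log-spaced path from lambda_max down to its ratio.

    ``lambda_max`` is the smallest penalty that zeroes every slope of the
    intercept-only model: max_j |Z_j'(y - ybar)| / n.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Z.T @ resid).max() / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)


def fit_node(
    X: ComorbidityMatrix | np.ndarray,
    i: int,
    *,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    ebic_gamma: float = 0.25,
    penalty_weights: np.ndarray | None = None,
) -> NodewiseFit:
    """Fit one node's l1 logistic path and select the EBIC-optimal model.

    A constant column cannot be regressed; such a node is returned with zero
    slopes, a smoothed empirical log-odds intercept and ``degenerate=True``.
    """
    arr, labels = _as_array(X)
    n, p = arr.shape
    if p < 2:
        raise ValueError("need at least two columns")
    y = arr[:, i]
    Z = np.delete(arr, i, axis=1)
    neigh = [lbl for k, lbl in enumerate(labels) if k != i]

    n_ones = y.sum()
    if n_ones == 0 or n_ones == n:
        # empirical log-odds with a half-count continuity correction
        b0 = float(np.log((n_ones + 0.5) / (n - n_ones + 0.5)))
        L = 1
        lam = np.array([0.0])
        ll = float(n_ones * b0 - n * np.log1p(np.exp(b0))) if b0 < 30 else 0.0
        return NodewiseFit(i, labels[i], neigh, lam, np.zeros((L, p - 1)),
                           np.array([b0]), np.array([ll]), np.array([np.nan]),
                           selected=0, degenerate=True)

    if lambdas is None:
        lambdas = lambda_path(Z, y, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    pen = (np.ones(p - 1) if penalty_weights is None
           else np.asarray(penalty_weights, dtype=float))
    coefs, intercepts, loglik = logistic_lasso_path(
        np.ascontiguousarray(Z), y, lambdas, pen)
    df = (coefs != 0).sum(axis=1)
    ebic = -2.0 * loglik + df * np.log(n) + 2.0 * ebic_gamma * df * np.log(p - 1)
    selected = int(np.argmin(ebic))
    return NodewiseFit(i, labels[i], neigh, lambdas, coefs, intercepts,
                       loglik, ebic, selected)


def symmetrize(fits: Sequence[NodewiseFit], rule: str = "AND",
               *, n_rows: int = 0, ebic_gamma: float = 0.25) -> IsingNetwork:
    """Combine node-wise coefficient pairs into a symmetric network.

    AND: w_ij = mean(coef_{i->j}, coef_{j->i}) if both are non-zero, else 0.
    OR:  mean of the non-zero members if either is non-zero.
    Thresholds are the selected intercepts.
    """
    if rule not in ("AND", "OR"):
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    p = len(fits)
    labels = [f.label for f in fits]
    raw = np.zeros((p, p))
    for f in fits:
        coefs = f.selected_coefs
        others = [k for k in range(p) if k != f.node]
        raw[f.node, others] = coefs
    w = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            x, z = raw[a, b], raw[b, a]
            if rule == "AND":
                val = 0.5 * (x + z) if (x != 0 and z != 0) else 0.0
            else:
                nz = [v for v in (x, z) if v != 0]
                val = float(np.mean(nz)) if nz else 0.0
            w[a, b] = w[b, a] = val
    thresholds = np.array([f.selected_intercept for f in fits])
    return IsingNetwork(w, thresholds, labels, n_rows=n_rows,
                        ebic_gamma=ebic_gamma, rule=rule)


def fit_ising(
    X: ComorbidityMatrix | np.ndarray,
    *,
    ebic_gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> IsingNetwork:
    """Estimate the full network: per-node eLasso fits + symmetrization.

    Deterministic given the matrix and hyperparameters (no randomness in the
    path fitting), and invariant to row order.
    """
    arr, _ = _as_array(X)
    fits = [fit_node(X, i, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                     ebic_gamma=ebic_gamma) for i in range(arr.shape[1])]
    return symmetrize(fits, rule, n_rows=arr.shape[0], ebic_gamma=ebic_gamma)


def fit_ising_with_fits(
    X: ComorbidityMatrix | np.ndarray,
    **kwargs,
) -> tuple[IsingNetwork, list[NodewiseFit]]:
    """Like :func:`fit_ising` but also return the per-node paths for audit."""
    arr, _ = _as_array(X)
    ebic_gamma = kwargs.get("ebic_gamma", 0.25)
    rule = kwargs.pop("rule", "AND")
    fits = [fit_node(X, i, **kwargs) for i in range(arr.shape[1])]
    return symmetrize(fits, rule, n_rows=arr.shape[0],
                      ebic_gamma=ebic_gamma), fits
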