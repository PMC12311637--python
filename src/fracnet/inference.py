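"""Compositionally-aware sparse co-occurrence network inference.

Counts are mapped to the real line with a modified centered log-ratio
(mclr) transform (zeros preserved), then a conditional-dependence graph
is estimated by Meinshausen-Buhlmann neighborhood selection: each
node's mclr profile is lasso-regressed on all the others, and the
symmetrized support is the edge set.  The penalty is chosen by StARS
(Stability Approach to Regularization Selection): along a geometric
lambda path, edge-selection frequencies are measured across random
subsamples and the densest graph whose edge instability stays below a
target (0.05) is retained.

Defaults mirror common amplicon-network practice: nlambda = 20,
lambda.min.ratio = 0.005, instability threshold 0.05, 20 subsamples of
size min(floor(10 sqrt(n)), floor(0.8 n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "clr_transform",
    "neighborhood_lasso",
    "symmetrize",
    "StarsNetworkInference",
    "stars_select",
    "LambdaPath",
]


def clr_transform(counts) -> np.ndarray:
    """Modified centered log-ratio transform, robust to zeros.

    Non-zero entries of each row are log-transformed and centered by the
    geometric mean of that row's non-zero entries; zeros stay exactly 0.
    Scale-invariant per row; all-zero rows map to zero rows.
    """
    x = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(
        counts, dtype=float
    )
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.zeros_like(x)
    for i, row in enumerate(x):
        nz = row > 0
        if not nz.any():
            continue
        logs = np.log(row[nz])
        out[i, nz] = logs - logs.mean()
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def _standardize(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def lambda_max(X: np.ndarray) -> float:
    """Smallest penalty at which every neighborhood regression is empty.

    Equals the largest absolute off-diagonal entry of the cross-
    covariance of the column-standardized data (sklearn's 1/(2n)
    least-squares scaling).
    """
    Z = _standardize(np.asarray(X, dtype=float))
    n = Z.shape[0]
    C = np.abs(Z.T @ Z) / n
    np.fill_diagonal(C, 0.0)
    return float(C.max())


def neighborhood_lasso(X, lam: float, tol: float = 1e-6, max_iter: int = 10_000) -> np.ndarray:
    """Per-node lasso neighborhood regressions at a single penalty.

    Column j of the result holds the coefficients of regressing
    (standardized) column j on all other columns; the diagonal is zero.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 columns")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    Z = _standardize(X)
    p = Z.shape[1]
    beta = np.zeros((p, p))
    model = Lasso(alpha=max(lam, 1e-12), fit_intercept=False, tol=tol, max_iter=max_iter)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        model.fit(Z[:, others], Z[:, j])
        beta[others, j] = model.coef_
    return beta


def symmetrize(beta: np.ndarray, rule: str = "or") -> np.ndarray:
    """Symmetric signed weights from a directed coefficient matrix.

    OR rule (default): edge (i, j) exists when either beta_ij or beta_ji
    is non-zero, weighted by the larger-magnitude coefficient.  AND rule
    requires both.
    """
    b = np.asarray(beta, dtype=float)
    bt = b.T
    larger = np.where(np.abs(b) >= np.abs(bt), b, bt)
    if rule == "or":
        mask = (b != 0) | (bt != 0)
    elif rule == "and":
        mask = (b != 0) & (bt != 0)
    else:
        raise ValueError("rule must be 'or' or 'and'")
    W = np.where(mask, larger, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


@dataclass
class LambdaPath:
    """StARS diagnostics along the penalty path (lambda decreasing)."""

    lambdas: np.ndarray
    instability: np.ndarray
    monotonized_instability: np.ndarray
    edge_frequencies: list  # per-lambda p x p selection frequency matrices
    lambda_opt: float
    opt_index: int
    threshold_met: bool

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "instability": self.instability.tolist(),
            "monotonized_instability": self.monotonized_instability.tolist(),
            "lambda_opt": self.lambda_opt,
            "opt_index": self.opt_index,
            "threshold_met": self.threshold_met,
        }


class StarsNetworkInference(BaseEstimator):
    """Neighborhood-selection network with StARS penalty selection.

    Parameters follow the standard stability-selection setup; ``fit``
    expects a samples x features real matrix (e.g. the mclr transform of
    a count table).

    Attributes
    ----------
    graph_ : networkx.Graph
        Selected network; edges carry ``weight`` (signed) and
        ``abs_weight``.
    adjacency_ : ndarray
        Signed weighted adjacency at the selected penalty.
    lambda_path_ : LambdaPath
    lambda_opt_ : float
    """

    def __init__(
        self,
        nlambda: int = 20,
        lambda_min_ratio: float = 0.005,
        stars_threshold: float = 0.05,
        n_subsamples: int = 20,
        subsample_ratio: float | None = None,
        symmetrize_rule: str = "or",
        min_rows: int = 20,
        random_state: int | None = 0,
    ):
        self.nlambda = nlambda
        self.lambda_min_ratio = lambda_min_ratio
        self.stars_threshold = stars_threshold
        self.n_subsamples = n_subsamples
        self.subsample_ratio = subsample_ratio
        self.symmetrize_rule = symmetrize_rule
        self.min_rows = min_rows
        self.random_state = random_state

    # -- internals ---------------------------------------------------
    def _lambda_grid(self, X: np.ndarray) -> np.ndarray:
        lmax = lambda_max(X)
        if lmax == 0:
            lmax = 1e-3
        return np.geomspace(lmax, lmax * self.lambda_min_ratio, self.nlambda)

    def _subsample_size(self, n: int) -> int:
        if self.subsample_ratio is not None:
            return max(3, int(np.floor(self.subsample_ratio * n)))
        return max(3, min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n))))

    @staticmethod
    def _path_supports(Z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
        """Boolean (nlambda, p, p) symmetrized-OR supports along the path."""
        p = Z.shape[1]
        supports = np.zeros((len(lambdas), p, p), dtype=bool)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            with warnings.catch_warnings():
                # the smallest path penalties need not converge tightly on
                # tiny subsamples; supports are still well defined
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = lasso_path(Z[:, others], Z[:, j], alphas=lambdas)
            # coefs: (p-1, nlambda), lasso_path orders alphas descending
            nz = coefs != 0
            for li in range(len(lambdas)):
                supports[li, others, j] = nz[:, li]
        return supports | supports.transpose(0, 2, 1)

    def fit(self, X, feature_names=None) -> "StarsNetworkInference":
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < self.min_rows:
            raise ValueError(f"need at least {self.min_rows} rows, got {n}")
        if p < 3:
            raise ValueError("need at least 3 features")
        names = list(feature_names) if feature_names is not None else list(range(p))

        rng = np.random.default_rng(self.random_state)
        lambdas = self._lambda_grid(X)
        b = self._subsample_size(n)

        freq = np.zeros((self.nlambda, p, p))
        for _ in range(self.n_subsamples):
            idx = rng.choice(n, size=b, replace=False)
            Z = _standardize(X[idx])
            freq += self._path_supports(Z, lambdas)
        freq /= self.n_subsamples

        iu = np.triu_indices(p, 1)
        xi = freq[:, iu[0], iu[1]]
        instability = (2 * xi * (1 - xi)).mean(axis=1)
        mono = np.maximum.accumulate(instability)  # lambda decreasing

        ok = np.flatnonzero(mono <= self.stars_threshold)
        if len(ok):
            opt_index = int(ok[-1])  # smallest lambda still under threshold
            threshold_met = True
        else:
            opt_index = 0  # sparsest available
            threshold_met = False
        lam_opt = float(lambdas[opt_index])

        beta = neighborhood_lasso(X, lam_opt)
        W = symmetrize(beta, rule=self.symmetrize_rule)

        self.lambda_path_ = LambdaPath(
            lambdas=lambdas,
            instability=instability,
            monotonized_instability=mono,
            edge_frequencies=[freq[i] for i in range(self.nlambda)],
            lambda_opt=lam_opt,
            opt_index=opt_index,
            threshold_met=threshold_met,
        )
        self.lambda_opt_ = lam_opt
        self.adjacency_ = W
        self.feature_names_ = names
        self.graph_ = adjacency_to_graph(W, names)
        self.graph_.graph.update(
            method="mb-stars",
            lambda_opt=lam_opt,
            threshold_met=threshold_met,
            seed=self.random_state,
        )
        return self


def adjacency_to_graph(W: np.ndarray, names, node_attrs: dict | None = None) -> nx.Graph:
    """networkx graph from a signed weighted adjacency matrix."""
    G = nx.Graph()
    for i, name in enumerate(names):
        attrs = dict(node_attrs.get(name, {})) if node_attrs else {}
        G.add_node(name, **attrs)
    p = len(names)
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(
                    names[i], names[j], weight=float(W[i, j]), abs_weight=abs(float(W[i, j]))
                )
    return G


def stars_select(
    X,
    nlambda: int = 20,
    lambda_min_ratio: float = 0.005,
    stars_threshold: float = 0.05,
    n_subsamples: int = 20,
    subsample_ratio: float | None = None,
    seed: int | None = 0,
    **kwargs,
) -> tuple[nx.Graph, LambdaPath]:
    """Functional wrapper around :class:`StarsNetworkInference`."""
    model = StarsNetworkInference(
        nlambda=nlambda,
        lambda_min_ratio=lambda_min_ratio,
        stars_threshold=stars_threshold,
        n_subsamples=n_subsamples,
        subsample_ratio=subsample_ratio,
        random_state=seed,
        **kwargs,
    ).fit(X)
    return model.graph_, model.lambda_path_
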