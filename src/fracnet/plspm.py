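"""Partial least squares path modeling (PLS-PM) with bootstrap and gof.

The inner (structural) model is a recursive (acyclic, lower-triangular)
system of latent variables; each latent is measured reflectively
(mode A) by one or more standardized indicators.  Estimation follows
the classic Lohmoller alternating scheme: latent scores are updated by
outer weights, inner proxies by the chosen scheme (path, factor or
centroid weighting), and mode-A outer weights by the covariance of
indicators with the inner proxy, iterated to convergence.  Path
coefficients are then OLS regressions of each endogenous latent score
on its predecessors; model quality is summarized by the goodness of
fit, gof = sqrt(mean communality x mean R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PlsPmSpec",
    "PlsPathModel",
    "fit_plspm",
    "prune_loadings",
    "bootstrap_plspm",
    "effects_decomposition",
    "gof",
    "BlockEmptyError",
]


class BlockEmptyError(ValueError):
    """Raised when loading-based pruning would empty a latent block."""


@dataclass
class PlsPmSpec:
    """Blocks, inner adjacency and estimation options for a PLS-PM model.

    ``blocks`` maps latent name -> list of indicator columns.
    ``path_matrix`` is a 0/1 DataFrame over latents (rows = targets,
    columns = sources) that must be lower-triangular in the given latent
    order (recursive inner model).
    """

    blocks: dict
    path_matrix: pd.DataFrame
    scheme: str = "path"
    max_iter: int = 300
    tol: float = 1e-8

    def __post_init__(self) -> None:
        latents = list(self.blocks)
        if not isinstance(self.path_matrix, pd.DataFrame):
            self.path_matrix = pd.DataFrame(
                np.asarray(self.path_matrix), index=latents, columns=latents
            )
        pm = self.path_matrix.loc[latents, latents].to_numpy()
        if np.any(np.triu(pm) != 0):
            raise ValueError("inner path matrix must be lower-triangular (acyclic)")
        for name, cols in self.blocks.items():
            if len(cols) == 0:
                raise ValueError(f"latent {name!r} has no indicators")
        if self.scheme not in ("path", "factor", "centroid"):
            raise ValueError("scheme must be path, factor or centroid")

    @property
    def latents(self) -> list:
        return list(self.blocks)

    def drop_indicators(self, to_drop: set) -> "PlsPmSpec":
        blocks = {}
        for name, cols in self.blocks.items():
            kept = [c for c in cols if c not in to_drop]
            if not kept:
                raise BlockEmptyError(
                    f"pruning would remove every indicator of block {name!r}"
                )
            blocks[name] = kept
        return PlsPmSpec(
            blocks=blocks,
            path_matrix=self.path_matrix.copy(),
            scheme=self.scheme,
            max_iter=self.max_iter,
            tol=self.tol,
        )


@dataclass
class PlsPmFit:
    spec: PlsPmSpec
    outer_weights: pd.Series
    loadings: pd.Series
    scores: pd.DataFrame
    paths: pd.DataFrame  # rows = target, cols = source
    r2: pd.Series
    communalities: pd.Series
    gof: float
    n_samples: int
    n_iter: int
    dropped_rows: int = 0
    bootstrap: dict | None = None
    metadata: dict = field(default_factory=dict)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    return (X - mu) / sd


class PlsPathModel(BaseEstimator):
    """Sklearn-style estimator wrapping the PLS-PM algorithm.

    ``fit(data)`` expects a DataFrame containing every indicator column
    named in the spec; rows with missing values are dropped (count kept
    in ``fit_.dropped_rows``).  Fitted results live in ``fit_`` (a
    :class:`PlsPmFit`); ``transform`` returns latent scores for the
    training data.
    """

    def __init__(
        self,
        blocks: dict | None = None,
        path_matrix=None,
        scheme: str = "path",
        max_iter: int = 300,
        tol: float = 1e-8,
    ):
        self.blocks = blocks
        self.path_matrix = path_matrix
        self.scheme = scheme
        self.max_iter = max_iter
        self.tol = tol

    def _spec(self) -> PlsPmSpec:
        return PlsPmSpec(
            blocks=self.blocks,
            path_matrix=self.path_matrix,
            scheme=self.scheme,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, data: pd.DataFrame, y=None) -> "PlsPathModel":
        self.fit_ = _fit_plspm_core(data, self._spec())
        return self

    def transform(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "fit_"):
            raise ValueError("model is not fitted")
        if data is None:
            return self.fit_.scores
        raise NotImplementedError("out-of-sample scoring is not supported")


def _fit_plspm_core(data: pd.DataFrame, spec: PlsPmSpec) -> PlsPmFit:
    latents = spec.latents
    cols = [c for block in spec.blocks.values() for c in block]
    if len(set(cols)) != len(cols):
        raise ValueError("an indicator may belong to only one block")
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    frame = data[cols].dropna()
    dropped = len(data) - len(frame)
    n = len(frame)
    if n < 10:
        raise ValueError("need at least 10 complete rows")

    X = _zscore(frame.to_numpy(dtype=float))
    col_index = {c: i for i, c in enumerate(cols)}
    block_cols = {b: [col_index[c] for c in spec.blocks[b]] for b in latents}
    L = len(latents)
    pm = spec.path_matrix.loc[latents, latents].to_numpy() != 0
    adjacent = pm | pm.T

    def standardize_scores(Y: np.ndarray) -> np.ndarray:
        return (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)

    # init: equal outer weights
    W = {b: np.ones(len(block_cols[b])) for b in latents}
    Y = np.column_stack([X[:, block_cols[b]] @ W[b] for b in latents])
    Y = standardize_scores(Y)

    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        # inner estimation
        C = np.corrcoef(Y, rowvar=False).reshape(L, L)
        E = np.zeros((L, L))
        for j in range(L):
            if spec.scheme == "centroid":
                E[j, adjacent[j]] = np.sign(C[j, adjacent[j]])
            elif spec.scheme == "factor":
                E[j, adjacent[j]] = C[j, adjacent[j]]
            else:  # path
                preds = np.flatnonzero(pm[j])
                succs = np.flatnonzero(pm[:, j])
                if len(preds):
                    Cpp = C[np.ix_(preds, preds)]
                    E[j, preds] = np.linalg.solve(Cpp, C[preds, j])
                E[j, succs] = C[succs, j]
        Z = Y @ E.T
        # mode-A outer weights
        W_new = {}
        delta = 0.0
        for li, b in enumerate(latents):
            z = Z[:, li]
            if np.allclose(z.std(), 0):
                z = Y[:, li]
            w = X[:, block_cols[b]].T @ z / n
            # fix sign/scale so the proxy is standardized
            y = X[:, block_cols[b]] @ w
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate block {b!r}")
            w = w / sd
            W_new[b] = w
            prev = W[b]
            scale = np.linalg.norm(prev)
            if scale > 0:
                delta = max(delta, np.max(np.abs(w - prev)))
        W = W_new
        Y = standardize_scores(
            np.column_stack([X[:, block_cols[b]] @ W[b] for b in latents])
        )
        if delta < spec.tol:
            break
    else:
        raise RuntimeError(
            f"PLS-PM did not converge in {spec.max_iter} iterations (last delta {delta:.3g})"
        )

    # loadings = correlation of indicator with its latent score
    loadings = {}
    for li, b in enumerate(latents):
        for c in spec.blocks[b]:
            x = X[:, col_index[c]]
            loadings[c] = float(np.corrcoef(x, Y[:, li])[0, 1])
    loadings = pd.Series(loadings)

    # orient each latent with the bulk of its block (positive mean loading)
    for li, b in enumerate(latents):
        if loadings[spec.blocks[b]].mean() < 0:
            Y[:, li] *= -1
            W[b] = -W[b]
            for c in spec.blocks[b]:
                loadings[c] *= -1

    # inner paths by OLS of each endogenous latent on its predecessors
    paths = pd.DataFrame(0.0, index=latents, columns=latents)
    r2 = {}
    for j, b in enumerate(latents):
        preds = np.flatnonzero(pm[j])
        if len(preds) == 0:
            continue
        Xp = Y[:, preds]
        beta, *_ = np.linalg.lstsq(Xp, Y[:, j], rcond=None)
        paths.iloc[j, preds] = beta
        resid = Y[:, j] - Xp @ beta
        r2[b] = float(1 - resid.var() / Y[:, j].var())
    r2 = pd.Series(r2)

    communalities = loadings**2
    mean_r2 = float(r2.mean()) if len(r2) else 0.0
    gof_value = float(np.sqrt(communalities.mean() * mean_r2))

    outer_weights = pd.Series(
        {c: W[b][k] for b in latents for k, c in enumerate(spec.blocks[b])}
    )
    scores = pd.DataFrame(Y, index=frame.index, columns=latents)
    return PlsPmFit(
        spec=spec,
        outer_weights=outer_weights,
        loadings=loadings,
        scores=scores,
        paths=paths,
        r2=r2,
        communalities=communalities,
        gof=gof_value,
        n_samples=n,
        n_iter=n_iter,
        dropped_rows=dropped,
    )


def fit_plspm(data: pd.DataFrame, spec: PlsPmSpec) -> PlsPmFit:
    """Fit a PLS path model; see :class:`PlsPathModel`."""
    return _fit_plspm_core(data, spec)


def prune_loadings(
    fit: PlsPmFit, data: pd.DataFrame, threshold: float = 0.7
) -> PlsPmFit:
    """Iteratively drop indicators with |loading| below ``threshold`` and refit.

    Raises :class:`BlockEmptyError` when a block would lose all of its
    indicators.  With threshold 0 the fit is returned unchanged.
    """
    spec = fit.spec
    current = fit
    while True:
        weak = current.loadings[current.loadings.abs() < threshold]
        if weak.empty:
            return current
        spec = spec.drop_indicators(set(weak.index))
        current = _fit_plspm_core(data, spec)


def bootstrap_plspm(
    data: pd.DataFrame,
    spec: PlsPmSpec,
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> dict:
    """Percentile bootstrap CIs for path coefficients and loadings.

    Rows are resampled with replacement; replicates whose resample has
    a constant indicator (or any other degenerate fit) are skipped and
    counted.  A path is flagged significant when its CI excludes 0.
    """
    rng = np.random.default_rng(seed)
    base = _fit_plspm_core(data, spec)
    cols = [c for block in spec.blocks.values() for c in block]
    frame = data[cols].dropna()
    n = len(frame)
    path_idx = [
        (t, s)
        for t in spec.latents
        for s in spec.latents
        if spec.path_matrix.loc[t, s] != 0
    ]
    path_samples = {k: [] for k in path_idx}
    loading_samples = {c: [] for c in base.loadings.index}
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            f = _fit_plspm_core(frame.iloc[idx], spec)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            skipped += 1
            continue
        for k in path_idx:
            path_samples[k].append(float(f.paths.loc[k[0], k[1]]))
        for c in loading_samples:
            loading_samples[c].append(float(f.loadings[c]))

    alpha = (1 - ci_level) / 2
    qs = (100 * alpha, 100 * (1 - alpha))

    def summarize(samples: dict, point: dict) -> dict:
        out = {}
        for k, vals in samples.items():
            arr = np.asarray(vals)
            lo, hi = (np.percentile(arr, qs) if len(arr) else (np.nan, np.nan))
            out[k] = {
                "estimate": point[k],
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0) if len(arr) else False,
            }
        return out

    return {
        "paths": summarize(
            path_samples, {k: float(base.paths.loc[k[0], k[1]]) for k in path_idx}
        ),
        "loadings": summarize(loading_samples, base.loadings.to_dict()),
        "n_boot": n_boot,
        "n_skipped": skipped,
        "seed": seed,
        "ci_level": ci_level,
    }


def effects_decomposition(fit: PlsPmFit) -> pd.DataFrame:
    """Direct, indirect and total effects between all latent pairs.

    With B the path-coefficient matrix (rows = targets), total effects
    are sum_k B^k; indirect = total - direct.  Finite because the inner
    model is acyclic.
    """
    latents = fit.spec.latents
    B = fit.paths.loc[latents, latents].to_numpy()
    L = len(latents)
    total = np.zeros_like(B)
    power = np.eye(L)
    for _ in range(L):
        power = power @ B
        total += power
    rows = []
    for ti, t in enumerate(latents):
        for si, s in enumerate(latents):
            if ti == si:
                continue
            direct = B[ti, si]
            tot = total[ti, si]
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "direct": float(direct),
                    "indirect": float(tot - direct),
                    "total": float(tot),
                }
            )
    return pd.DataFrame(rows)


def gof(fit: PlsPmFit) -> float:
    """Goodness of fit: sqrt(mean communality x mean R^2 over endogenous)."""
    return fit.gof
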