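"""Alpha/beta diversity, ordination and permutation tests.

Alpha diversity covers Shannon entropy (natural log), Chao1 richness
(bias-corrected by default) and Pielou's evenness.  Beta diversity uses
Bray-Curtis dissimilarity; community differences are tested with
PERMANOVA (Anderson's pseudo-F) and environmental association with
(partial) Mantel tests.  All permutation p-values follow the add-one
rule p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control, rankdata, spearmanr
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .tables import AsvTable

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "DistanceMatrix",
    "NMDS",
    "nmds",
    "permanova",
    "mantel",
    "partial_mantel",
    "spearman_env_correlations",
    "PermutationTestResult",
]


# ----------------------------------------------------------------- alpha
def alpha_diversity(table: AsvTable, chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample Shannon H, Chao1 and Pielou's J from a count table.

    Shannon H = -sum p ln p.  Chao1 (bias-corrected) =
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) where F1/F2 are singleton and
    doubleton counts; the classic estimator S_obs + F1^2 / (2 F2) is
    available with ``chao1_bias_corrected=False`` (undefined when
    F2 = 0, reported as NaN).  Pielou J = H / ln S_obs; undefined (NaN)
    for samples with fewer than two observed ASVs.
    """
    counts = table.data.to_numpy(dtype=float)
    if table.is_relative:
        raise ValueError("alpha diversity (Chao1) requires integer counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("Chao1 requires integer counts")

    rows = []
    for row in counts:
        total = row.sum()
        s_obs = int((row > 0).sum())
        if total == 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        p = row[row > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        f1 = int((row == 1).sum())
        f2 = int((row == 2).sum())
        if chao1_bias_corrected:
            chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        else:
            chao1 = s_obs + f1 * f1 / (2.0 * f2) if f2 > 0 else np.nan
        pielou = shannon / np.log(s_obs) if s_obs > 1 else np.nan
        rows.append((shannon, chao1, pielou))
    return pd.DataFrame(
        rows, index=table.samples, columns=["shannon", "chao1", "pielou"]
    )


# ------------------------------------------------------------------ beta
@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix with sample labels."""

    values: np.ndarray
    labels: list
    flagged_pairs: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = 1 - 2 sum(min) / sum(x + y).

    Accepts an :class:`AsvTable` or a samples x features DataFrame/array.
    Pairs of all-zero rows get d = 0 by convention and are listed in
    ``flagged_pairs``.
    """
    if isinstance(matrix, AsvTable):
        frame = matrix.data
    elif isinstance(matrix, pd.DataFrame):
        frame = matrix
    else:
        frame = pd.DataFrame(np.asarray(matrix, dtype=float))
    x = frame.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    d = squareform(pdist(x, metric="braycurtis"))
    empty = np.flatnonzero(x.sum(axis=1) == 0)
    flagged = []
    for i in empty:
        for j in empty:
            if i < j:
                d[i, j] = d[j, i] = 0.0
                flagged.append((frame.index[i], frame.index[j]))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(np.nan_to_num(d), list(frame.index), flagged or None)


# ------------------------------------------------------------------ NMDS
class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling by iterative majorization.

    Minimizes Kruskal stress-1 with monotone (isotonic) regression of
    embedding distances on observed dissimilarities, using the SMACOF
    Guttman transform.  The best of ``n_starts`` initializations is
    kept; the first start is classical (Torgerson) MDS, the rest are
    random.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, k)
    stress_ : float
        Kruskal stress-1 of the best configuration.
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 2,
        n_starts: int = 8,
        max_iter: int = 300,
        tol: float = 1e-7,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, dist: DistanceMatrix) -> "NMDS":
        self.fit_transform(dist)
        return self

    def fit_transform(self, dist: DistanceMatrix) -> np.ndarray:
        if isinstance(dist, DistanceMatrix):
            d = dist.values
        else:
            d = np.asarray(dist, dtype=float)
        n = d.shape[0]
        k = self.n_components
        if n < k + 1:
            raise ValueError("need at least n_components + 1 points")
        rng = np.random.default_rng(self.random_state)
        iu = np.triu_indices(n, 1)
        dvec = d[iu]
        order = np.argsort(dvec, kind="stable")

        best = (np.inf, None, False)
        for start in range(self.n_starts):
            if start == 0:
                X = _classical_mds(d, k)
            else:
                X = rng.normal(size=(n, k))
            stress_prev = np.inf
            converged = False
            for _ in range(self.max_iter):
                ed = _pairwise(X)
                evec = ed[iu]
                # monotone regression of embedding distances on rank order
                iso = IsotonicRegression(increasing=True)
                dhat_sorted = iso.fit_transform(
                    np.arange(len(order)), evec[order]
                )
                dhat = np.empty_like(evec)
                dhat[order] = dhat_sorted
                denom = (evec**2).sum()
                stress = np.sqrt(((evec - dhat) ** 2).sum() / denom) if denom else 0.0
                if stress_prev - stress < self.tol:
                    converged = True
                    break
                stress_prev = stress
                # Guttman transform with disparities dhat
                B = np.zeros((n, n))
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(evec > 0, dhat / evec, 0.0)
                B[iu] = -ratio
                B += B.T
                np.fill_diagonal(B, -B.sum(axis=1))
                X = B @ X / n
            if stress < best[0]:
                best = (stress, X, converged)

        self.stress_ = float(best[0])
        self.embedding_ = best[1]
        self.converged_ = best[2]
        return self.embedding_


def _pairwise(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(w)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
):
    """Functional wrapper around :class:`NMDS`; returns (coords, stress)."""
    model = NMDS(
        n_components=k, n_starts=n_starts, max_iter=max_iter, tol=tol, random_state=seed
    )
    coords = model.fit_transform(dist)
    return coords, model.stress_


# ------------------------------------------------------- permutation tests
@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    name: str = ""
    extra: dict | None = None


def _permanova_ss(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    """SS_within from squared distances for stacked group indicators."""
    # onehot: (n_groups, P, n) boolean
    within = np.zeros(onehot.shape[1])
    for g in range(onehot.shape[0]):
        M = onehot[g].astype(float)
        within += np.einsum("pi,ij,pj->p", M, d2, M) / (2.0 * sizes[g])
    return within


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """One-factor PERMANOVA on a distance matrix (Anderson's pseudo-F).

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous terms
    inside each group; pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)).
    The null distribution permutes group labels freely.
    """
    groups = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    n = dist.n
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")

    d2 = dist.values**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=int)
    perms[0] = groups
    for p in range(1, n_perm + 1):
        perms[p] = rng.permutation(groups)

    onehot = np.stack([(perms == u) for u in uniq])  # (g, P, n)
    ss_within = _permanova_ss(d2, onehot, counts)
    ss_between = ss_total - ss_within
    f = (ss_between / (g - 1)) / (ss_within / (n - g))

    p_value = (1 + np.sum(f[1:] >= f[0])) / (1 + n_perm)
    return PermutationTestResult(
        statistic=float(f[0]),
        p_value=float(p_value),
        n_permutations=n_perm,
        seed=seed,
        name="permanova",
        extra={
            "R2": float(ss_between[0] / ss_total),
            "SS_total": float(ss_total),
            "SS_between": float(ss_between[0]),
            "SS_within": float(ss_within[0]),
            "df_between": g - 1,
            "df_within": n - g,
        },
    )


def _upper(d: np.ndarray) -> np.ndarray:
    return d[np.triu_indices(d.shape[0], 1)]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    return float((x * y).sum() / denom) if denom else 0.0


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Mantel correlation of two distance matrices with a permutation null.

    The statistic is the (rank) correlation of upper-triangle entries;
    the null permutes the rows/columns of ``d1`` simultaneously.
    """
    if d1.n != d2.n:
        raise ValueError("matrices must match in size")
    rng = np.random.default_rng(seed)
    v2 = _upper(d2.values)
    obs = _corr(_upper(d1.values), v2, method)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(d1.n)
        perm = d1.values[np.ix_(p, p)]
        if _corr(_upper(perm), v2, method) >= obs:
            count += 1
    return PermutationTestResult(
        statistic=obs,
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        name=f"mantel-{method}",
    )


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_control: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """First-order partial Mantel test controlling for a third matrix.

    r(12.3) = (r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2)); the null
    permutes the labels of ``d1`` only.
    """
    if not (d1.n == d2.n == d_control.n):
        raise ValueError("matrices must match in size")
    v2 = _upper(d2.values)
    v3 = _upper(d_control.values)
    r23 = _corr(v2, v3, method)

    def partial_r(m1: np.ndarray) -> float:
        v1 = _upper(m1)
        r12 = _corr(v1, v2, method)
        r13 = _corr(v1, v3, method)
        denom = np.sqrt((1 - r13**2) * (1 - r23**2))
        return (r12 - r13 * r23) / denom if denom else 0.0

    rng = np.random.default_rng(seed)
    obs = partial_r(d1.values)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(d1.n)
        if partial_r(d1.values[np.ix_(p, p)]) >= obs:
            count += 1
    return PermutationTestResult(
        statistic=float(obs),
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        name=f"partial-mantel-{method}",
    )


def spearman_env_correlations(
    abundance: pd.DataFrame, env: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho between columns of two sample-aligned tables.

    Returns (rho, p_adjusted) DataFrames; p-values are Benjamini-
    Hochberg adjusted across the whole matrix.
    """
    if not abundance.index.equals(env.index):
        env = env.loc[abundance.index]
    rho = np.zeros((abundance.shape[1], env.shape[1]))
    pval = np.zeros_like(rho)
    for i, a in enumerate(abundance.columns):
        for j, e in enumerate(env.columns):
            r, p = spearmanr(abundance[a], env[e])
            rho[i, j] = r
            pval[i, j] = p
    padj = false_discovery_control(pval.ravel(), method="bh").reshape(pval.shape)
    rho_df = pd.DataFrame(rho, index=abundance.columns, columns=env.columns)
    padj_df = pd.DataFrame(padj, index=abundance.columns, columns=env.columns)
    return rho_df, padj_df
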