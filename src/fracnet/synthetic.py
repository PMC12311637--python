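"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates what a seasonal survey of size-fractionated
microbial communities delivers after sequence processing: three ASV
count tables (bacteria, pico-protists, nano-protists) whose log-scale
dependence among a "core" of network-eligible ASVs follows a known
sparse precision matrix (so network recovery can be scored against
ground truth), a seasonal environmental table, cytometry counts, and
optional cross-fraction contamination at prescribed abundance ratios
(the artifact the ratio filter must remove).

Counts use a logistic-normal-multinomial model: latent log-abundances
are multivariate normal with covariance equal to the inverse of the
true precision matrix, passed through a per-fraction softmax and a
multinomial at the sequencing depth, with optional Bernoulli
zero-inflation applied afterwards.  Seasons are categorical labels on
blocks of samples; no temporal autocorrelation is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import SEASONS, AsvTable

__all__ = [
    "SyntheticScenario",
    "generate_env_table",
    "generate_counts",
    "inject_cross_fraction_contamination",
    "generate_cytometry",
    "generate_latent_path_data",
    "chain_precision",
    "random_sparse_precision",
]

# season-specific means chosen to resemble a subtropical bay:
# temperature (deg C), salinity (PSU), dissolved oxygen (mg/L),
# total nitrogen / total phosphorus (umol/L)
_ENV_MEANS = {
    "winter": {"temperature": 13.0, "salinity": 31.0, "DO": 8.5, "TN": 60.0, "TP": 2.4},
    "spring": {"temperature": 19.0, "salinity": 30.0, "DO": 7.5, "TN": 45.0, "TP": 1.8},
    "summer": {"temperature": 28.0, "salinity": 29.0, "DO": 6.0, "TN": 40.0, "TP": 1.5},
    "autumn": {"temperature": 22.0, "salinity": 30.5, "DO": 7.0, "TN": 55.0, "TP": 2.2},
}
_ENV_SD = {"temperature": 1.0, "salinity": 0.5, "DO": 0.4, "TN": 5.0, "TP": 0.3}

# cytometry group mean log10 abundance (cells/mL) per season, loosely
# tracking the seasonal biomass patterns of a eutrophic bay
_CYTO_MEANS = {
    "HB": {"winter": 6.3, "spring": 6.0, "summer": 6.4, "autumn": 6.0},
    "Syn": {"winter": 3.8, "spring": 4.4, "summer": 4.9, "autumn": 4.6},
    "PPE": {"winter": 3.4, "spring": 4.0, "summer": 4.2, "autumn": 3.9},
    "HNF": {"winter": 3.2, "spring": 2.9, "summer": 3.3, "autumn": 2.9},
    "PNF": {"winter": 3.5, "spring": 3.1, "summer": 3.0, "autumn": 3.0},
}
_CYTO_SD = 0.15  # log10 scale


def chain_precision(p: int, partial: float = 0.4) -> np.ndarray:
    """Tridiagonal (chain-graph) precision matrix with p-1 true edges."""
    omega = np.eye(p)
    for i in range(p - 1):
        omega[i, i + 1] = omega[i + 1, i] = -partial
    # diagonal dominance keeps it positive definite
    omega += np.eye(p) * (2 * partial)
    return omega


def random_sparse_precision(
    p: int, edge_prob: float = 0.05, partial: float = 0.35, seed: int | None = 0
) -> np.ndarray:
    """Random sparse positive-definite precision matrix.

    The default edge probability gives an expected degree near 3,
    matching the sparse topology typical of amplicon co-occurrence
    networks.
    """
    rng = np.random.default_rng(seed)
    omega = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                omega[i, j] = omega[j, i] = -partial * rng.choice([-1.0, 1.0])
    row = np.abs(omega).sum(axis=1)
    np.fill_diagonal(omega, row + 1.0)
    return omega


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic seasonal survey.

    The true precision matrix spans the network-eligible core ASVs of
    all three fractions concatenated (bacteria, pico, nano); its
    off-diagonal support is the ground-truth edge set.  Each fraction
    additionally carries ``n_noise_asvs`` independent rare ASVs that the
    prevalence/abundance filter should discard.
    """

    n_seasons: int = 4
    samples_per_season: int = 10
    n_core_asvs: dict = field(
        default_factory=lambda: {"bacteria": 20, "pico": 20, "nano": 20}
    )
    n_noise_asvs: dict = field(
        default_factory=lambda: {"bacteria": 40, "pico": 40, "nano": 40}
    )
    true_precision_matrix: np.ndarray | None = None
    sequencing_depth: int = 20_000
    zero_inflation: float = 0.02
    contamination_pairs: list = field(default_factory=list)
    season_effect: float = 1.0
    core_mean_advantage: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seasons < 1 or self.samples_per_season < 1:
            raise ValueError("sample counts must be positive")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        p = self.n_core_total
        if self.true_precision_matrix is None:
            self.true_precision_matrix = random_sparse_precision(p, seed=self.seed)
        self.true_precision_matrix = np.asarray(self.true_precision_matrix, float)
        if self.true_precision_matrix.shape != (p, p):
            raise ValueError("precision matrix must cover all core ASVs")
        if not np.allclose(self.true_precision_matrix, self.true_precision_matrix.T):
            raise ValueError("precision matrix must be symmetric")
        eig = np.linalg.eigvalsh(self.true_precision_matrix)
        if eig.min() <= 1e-10:
            raise ValueError("precision matrix must be positive definite")

    @property
    def n_core_total(self) -> int:
        return sum(self.n_core_asvs.values())

    @property
    def seasons(self) -> list:
        return list(SEASONS[: self.n_seasons])

    @property
    def n_samples(self) -> int:
        return self.n_seasons * self.samples_per_season

    def sample_ids(self) -> list:
        return [
            f"{season[:2].upper()}{i + 1:02d}"
            for season in self.seasons
            for i in range(self.samples_per_season)
        ]

    def season_labels(self) -> list:
        return [s for s in self.seasons for _ in range(self.samples_per_season)]

    def metadata(self) -> pd.DataFrame:
        n = self.samples_per_season
        layers = (["surface", "bottom"] * ((n + 1) // 2))[:n]
        return pd.DataFrame(
            {
                "season": self.season_labels(),
                "layer": layers * self.n_seasons,
                "station": [f"S{i % 5 + 1}" for i in range(self.n_samples)],
            },
            index=self.sample_ids(),
        )

    def true_edges(self) -> set:
        """Ground truth: support of the off-diagonal precision matrix."""
        omega = self.true_precision_matrix
        ids = self.core_asv_ids()
        edges = set()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if omega[i, j] != 0:
                    edges.add(frozenset((ids[i], ids[j])))
        return edges

    def core_asv_ids(self) -> list:
        ids = []
        for frac in ("bacteria", "pico", "nano"):
            ids += [f"{frac[:1].upper()}core{k + 1:03d}" for k in range(self.n_core_asvs[frac])]
        return ids


def generate_env_table(scenario: SyntheticScenario) -> pd.DataFrame:
    """Seasonal environmental table: Gaussian noise around season means.

    ``scenario.season_effect`` scales each season mean's deviation from
    the across-season average, so 0 gives a season-free null.
    Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    variables = list(_ENV_SD)
    grand = {v: np.mean([_ENV_MEANS[s][v] for s in SEASONS]) for v in variables}
    rows = []
    for season in scenario.season_labels():
        row = {}
        for v in variables:
            mu = grand[v] + scenario.season_effect * (_ENV_MEANS[season][v] - grand[v])
            row[v] = mu + rng.normal(0, _ENV_SD[v])
        rows.append(row)
    env = pd.DataFrame(rows, index=scenario.sample_ids())
    env["season"] = scenario.season_labels()
    return env


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def generate_counts(
    scenario: SyntheticScenario,
) -> tuple[dict[str, AsvTable], set]:
    """Three fraction count tables plus the ground-truth edge set.

    Core ASVs get latent log-abundances from a multivariate normal with
    covariance equal to the inverse true precision matrix and a mean
    advantage (``core_mean_advantage``) so they pass the prevalence and
    abundance screens; noise ASVs get independent low-mean normals.
    Per fraction the latent vector is softmaxed and counts drawn from a
    multinomial at the sequencing depth, then thinned by Bernoulli
    zero-inflation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    sigma = np.linalg.inv(scenario.true_precision_matrix)
    n = scenario.n_samples
    core = rng.multivariate_normal(
        np.zeros(scenario.n_core_total), sigma, size=n, method="cholesky"
    )
    core += scenario.core_mean_advantage

    metadata = scenario.metadata()
    tables: dict[str, AsvTable] = {}
    offset = 0
    core_ids = scenario.core_asv_ids()
    for frac in ("bacteria", "pico", "nano"):
        k_core = scenario.n_core_asvs[frac]
        k_noise = scenario.n_noise_asvs[frac]
        ids = core_ids[offset : offset + k_core] + [
            f"{frac[:1].upper()}noise{k + 1:03d}" for k in range(k_noise)
        ]
        latent = np.empty((n, k_core + k_noise))
        latent[:, :k_core] = core[:, offset : offset + k_core]
        # rare background taxa: low mean, high variance, so most fail the
        # prevalence/abundance screens
        latent[:, k_core:] = rng.normal(-4.5, 2.0, size=(n, k_noise))
        probs = _softmax(latent)
        counts = np.empty_like(probs, dtype=np.int64)
        for i in range(n):
            counts[i] = rng.multinomial(scenario.sequencing_depth, probs[i])
        if scenario.zero_inflation > 0:
            mask = rng.random(counts.shape) < scenario.zero_inflation
            counts[mask] = 0
        taxonomy = pd.DataFrame(
            {
                "lineage": [f"{frac};clade{k % 7 + 1}" for k in range(len(ids))],
                "trophic_mode": "unknown"
                if frac == "bacteria"
                else [
                    ["photoautotroph", "heterotroph", "mixotroph", "parasite", "symbiont"][
                        k % 5
                    ]
                    for k in range(len(ids))
                ],
            },
            index=ids,
        )
        tables[frac] = AsvTable(
            data=pd.DataFrame(counts, index=scenario.sample_ids(), columns=ids),
            fraction=frac,
            sample_metadata=metadata.copy(),
            taxonomy=taxonomy,
        )
        offset += k_core
    return tables, scenario.true_edges()


def inject_cross_fraction_contamination(
    pico: AsvTable, nano: AsvTable, pairs: list
) -> tuple[AsvTable, AsvTable]:
    """Make ASVs shared between fractions at a target mean-abundance ratio.

    ``pairs`` is a list of ``(pico_asv, nano_asv, target_ratio)``; for
    each pair the pico ASV's counts are copied (scaled) into the nano
    table under the pico ASV's id so that the ratio of mean relative
    abundance (nano/pico) matches ``target_ratio``.  Copy-based so the
    realized ratio is controllable.
    """
    if not pico.samples.equals(nano.samples):
        raise ValueError("tables must share a sample set")
    pico_out, nano_out = pico.copy(), nano.copy()
    for pico_asv, nano_asv, target in pairs:
        if pico_asv not in pico.asv_ids:
            raise KeyError(f"unknown pico ASV {pico_asv!r}")
        if nano_asv is not None and nano_asv not in nano.asv_ids:
            raise KeyError(f"unknown nano ASV {nano_asv!r}")
        pico_rel = pico_out.data[pico_asv] / pico_out.data.sum(axis=1)
        target_rel = target * pico_rel.mean()
        if target_rel >= 1:
            raise ValueError("target relative abundance would exceed 1")
        nano_totals = nano_out.data.sum(axis=1)
        # counts that put the shared id at the target mean relative
        # abundance after the new column inflates the row totals
        shared_counts = np.round(
            target_rel / (1 - target_rel) * nano_totals
        ).astype(np.int64)
        nano_out.data[pico_asv] = shared_counts
        if nano_out.taxonomy is not None and pico.taxonomy is not None:
            nano_out.taxonomy.loc[pico_asv] = pico.taxonomy.loc[pico_asv]
    return pico_out, nano_out


def generate_cytometry(
    env: pd.DataFrame,
    scenario: SyntheticScenario,
    sd_log10: float = _CYTO_SD,
    season_effect: float | None = None,
) -> pd.DataFrame:
    """Log-normal cytometry/microscopy abundances (cells/mL) per sample.

    Means are season-dependent (log10 scale) and loosely coupled to the
    sample's temperature anomaly; ``season_effect=0`` flattens the
    seasonal signal; ``sd_log10=0`` gives constant columns per season.
    """
    if len(env) < 1:
        raise ValueError("environmental table is empty")
    if season_effect is None:
        season_effect = scenario.season_effect
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    out = pd.DataFrame(index=env.index)
    seasons = env["season"]
    for group, means in _CYTO_MEANS.items():
        grand = np.mean(list(means.values()))
        mu = np.array(
            [grand + season_effect * (means[s] - grand) for s in seasons]
        )
        out[group] = 10 ** (mu + rng.normal(0, sd_log10, size=len(env)))
    out["season"] = seasons.to_numpy()
    return out


def generate_latent_path_data(
    path_matrix,
    loadings: dict,
    n: int,
    seed: int | None = 0,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indicators from a known recursive latent path model.

    ``path_matrix`` (rows = targets, columns = sources) must be lower
    triangular; latents follow the structural equations with residual
    variance topping each latent up to 1.  ``loadings`` maps latent name
    -> list of loadings in (0, 1]; each indicator is
    loading x latent + sqrt(1 - loading^2) x noise, so indicators are
    standardized in expectation.  ``noise_sd`` overrides the indicator
    noise scale (0 gives noise-free indicators).  Returns
    (indicator table, true latent scores).
    """
    names = list(loadings)
    pm = np.asarray(
        path_matrix.loc[names, names] if isinstance(path_matrix, pd.DataFrame) else path_matrix,
        dtype=float,
    )
    if np.any(np.triu(pm) != 0):
        raise ValueError("path matrix must be lower-triangular (acyclic)")
    L = len(names)
    if pm.shape != (L, L):
        raise ValueError("path matrix shape must match number of latent blocks")
    rng = np.random.default_rng(seed)
    latents = np.zeros((n, L))
    for j in range(L):
        structural = latents[:, :j] @ pm[j, :j]
        if j:
            cov = np.atleast_2d(np.cov(latents[:, :j].T, ddof=0))
            resid_var = 1.0 - float(pm[j, :j] @ cov @ pm[j, :j])
        else:
            resid_var = 1.0
        resid_var = max(resid_var, 1e-12)
        latents[:, j] = structural + rng.normal(0, np.sqrt(resid_var), size=n)

    cols, data = [], []
    for j, name in enumerate(names):
        for k, lam in enumerate(loadings[name]):
            if not 0 < lam <= 1:
                raise ValueError("loadings must lie in (0, 1]")
            sd = np.sqrt(max(1 - lam**2, 0.0)) if noise_sd is None else noise_sd
            cols.append(f"{name}_x{k + 1}")
            data.append(lam * latents[:, j] + rng.normal(0, sd, size=n))
    indicators = pd.DataFrame(np.column_stack(data), columns=cols)
    return indicators, pd.DataFrame(latents, columns=names)
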