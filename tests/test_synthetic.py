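"""Synthetic survey generators: determinism, structure, null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fracnet.filtering import relative_abundance, resolve_shared_asvs
from fracnet.synthetic import (
    SyntheticScenario,
    chain_precision,
    generate_counts,
    generate_cytometry,
    generate_env_table,
    generate_latent_path_data,
    inject_cross_fraction_contamination,
)


def small_scenario(**kw):
    defaults = dict(
        n_seasons=4,
        samples_per_season=5,
        n_core_asvs={"bacteria": 5, "pico": 5, "nano": 5},
        n_noise_asvs={"bacteria": 3, "pico": 3, "nano": 3},
        sequencing_depth=5000,
        seed=0,
    )
    defaults.update(kw)
    return SyntheticScenario(**defaults)


class TestScenarioValidation:
    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            small_scenario(samples_per_season=0)

    def test_rejects_singular_precision(self):
        with pytest.raises(ValueError):
            small_scenario(true_precision_matrix=np.zeros((15, 15)))

    def test_rejects_bad_zero_inflation(self):
        with pytest.raises(ValueError):
            small_scenario(zero_inflation=1.5)


class TestEnvTable:
    def test_seeded_determinism(self):
        sc = small_scenario(seed=5)
        pd.testing.assert_frame_equal(generate_env_table(sc), generate_env_table(sc))

    def test_row_count(self):
        env = generate_env_table(small_scenario(n_seasons=4, samples_per_season=10))
        assert len(env) == 40

    def test_null_season_effect_gives_uniform_anova_p(self):
        pvals = []
        for seed in range(60):
            env = generate_env_table(small_scenario(seed=seed, season_effect=0.0))
            groups = [g["temperature"].to_numpy() for _, g in env.groupby("season")]
            pvals.append(stats.f_oneway(*groups).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCounts:
    def test_seeded_determinism(self):
        sc = small_scenario(seed=2)
        t1, e1 = generate_counts(sc)
        t2, e2 = generate_counts(sc)
        for f in t1:
            pd.testing.assert_frame_equal(t1[f].data, t2[f].data)
        assert e1 == e2

    def test_full_zero_inflation(self):
        tables, _ = generate_counts(small_scenario(zero_inflation=1.0))
        for t in tables.values():
            assert t.data.to_numpy().sum() == 0

    def test_chain_ground_truth_edge_count(self):
        sc = small_scenario(true_precision_matrix=chain_precision(15))
        _, edges = generate_counts(sc)
        assert len(edges) == 14

    def test_counts_nonnegative_integers_near_depth(self):
        sc = small_scenario(zero_inflation=0.0)
        tables, _ = generate_counts(sc)
        for t in tables.values():
            arr = t.data.to_numpy()
            assert (arr >= 0).all()
            assert np.issubdtype(arr.dtype, np.integer)
            np.testing.assert_array_equal(arr.sum(axis=1), sc.sequencing_depth)

    def test_identity_precision_gives_small_partial_correlations(self):
        # latent log-abundances from an identity precision matrix are
        # independent: empirical partial correlations vanish at large n
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal(np.zeros(8), np.eye(8), size=2000)
        prec = np.linalg.inv(np.cov(z.T))
        d = np.sqrt(np.diag(prec))
        pcor = -prec / np.outer(d, d)
        np.fill_diagonal(pcor, 0)
        assert np.abs(pcor).max() < 0.1


class TestContamination:
    def _tables(self):
        tables, _ = generate_counts(small_scenario(seed=4))
        return tables["pico"], tables["nano"]

    def test_target_ratio_realized(self):
        pico, nano = self._tables()
        asv = pico.asv_ids[0]
        pico2, nano2 = inject_cross_fraction_contamination(
            pico, nano, [(asv, None, 3.0)]
        )
        p_rel = relative_abundance(pico2).data[asv].mean()
        n_rel = relative_abundance(nano2).data[asv].mean()
        assert n_rel / p_rel == pytest.approx(3.0, rel=0.1)

    def test_empty_pairs_identity(self):
        pico, nano = self._tables()
        pico2, nano2 = inject_cross_fraction_contamination(pico, nano, [])
        pd.testing.assert_frame_equal(pico.data, pico2.data)
        pd.testing.assert_frame_equal(nano.data, nano2.data)

    def test_ratio_one_survives_filter(self):
        pico, nano = self._tables()
        asv = pico.asv_ids[0]
        pico2, nano2 = inject_cross_fraction_contamination(
            pico, nano, [(asv, None, 1.0)]
        )
        pico_f, nano_f, _ = resolve_shared_asvs(pico2, nano2)
        assert asv in pico_f.asv_ids and asv in nano_f.asv_ids

    def test_unknown_asv_rejected(self):
        pico, nano = self._tables()
        with pytest.raises(KeyError):
            inject_cross_fraction_contamination(pico, nano, [("nope", None, 2.0)])


class TestCytometry:
    def test_seeded_determinism(self):
        sc = small_scenario(seed=6)
        env = generate_env_table(sc)
        pd.testing.assert_frame_equal(
            generate_cytometry(env, sc), generate_cytometry(env, sc)
        )

    def test_strictly_positive(self):
        sc = small_scenario(seed=7)
        cyto = generate_cytometry(generate_env_table(sc), sc)
        assert (cyto.drop(columns="season").to_numpy() > 0).all()

    def test_zero_variance_constant_within_season(self):
        sc = small_scenario(seed=8)
        cyto = generate_cytometry(generate_env_table(sc), sc, sd_log10=0.0)
        for _, g in cyto.groupby("season"):
            assert g["HB"].nunique() == 1

    def test_null_season_effect_mostly_nonsignificant(self):
        nonsig = 0
        n_rep = 40
        for seed in range(n_rep):
            sc = small_scenario(seed=seed)
            env = generate_env_table(sc)
            cyto = generate_cytometry(env, sc, season_effect=0.0)
            groups = [np.log10(g["HNF"].to_numpy()) for _, g in cyto.groupby("season")]
            if stats.f_oneway(*groups).pvalue > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_rep - 2


class TestLatentPathData:
    def test_single_path_indicator_correlation(self):
        pm = pd.DataFrame([[0, 0], [0.5, 0]], index=["A", "B"], columns=["A", "B"])
        ind, _ = generate_latent_path_data(
            pm, {"A": [1.0], "B": [1.0]}, n=5000, seed=0, noise_sd=0.0
        )
        r = np.corrcoef(ind["A_x1"], ind["B_x1"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)

    def test_zero_paths_uncorrelated_latents(self):
        pm = np.zeros((3, 3))
        _, lat = generate_latent_path_data(
            pm, {"A": [0.9], "B": [0.9], "C": [0.9]}, n=5000, seed=1
        )
        corr = lat.corr().to_numpy()
        assert np.abs(corr[np.triu_indices(3, 1)]).max() < 0.05

    def test_seeded_determinism(self):
        pm = np.zeros((2, 2))
        a = generate_latent_path_data(pm, {"A": [0.8], "B": [0.8]}, n=50, seed=2)
        b = generate_latent_path_data(pm, {"A": [0.8], "B": [0.8]}, n=50, seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_cyclic_rejected(self):
        pm = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError):
            generate_latent_path_data(pm, {"A": [1.0], "B": [1.0]}, n=10, seed=0)
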