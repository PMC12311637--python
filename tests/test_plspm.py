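"""PLS path modeling: oracles, recovery, pruning, bootstrap, effects."""

import numpy as np
import pandas as pd
import pytest

from fracnet.plspm import (
    BlockEmptyError,
    PlsPathModel,
    PlsPmSpec,
    bootstrap_plspm,
    effects_decomposition,
    fit_plspm,
    prune_loadings,
)
from fracnet.synthetic import generate_latent_path_data

LATENTS = list("ABC")
CHAIN = pd.DataFrame(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0]], index=LATENTS, columns=LATENTS
)


def chain_spec(n_indicators=1):
    blocks = {b: [f"{b}_x{k + 1}" for k in range(n_indicators)] for b in LATENTS}
    return PlsPmSpec(blocks=blocks, path_matrix=CHAIN)


def chain_data(n_indicators=1, n=300, seed=0, paths=(0.6, 0.3), loading=0.9):
    pm = CHAIN.astype(float).copy()
    pm.loc["B", "A"], pm.loc["C", "B"] = paths
    ind, lat = generate_latent_path_data(
        pm, {b: [loading] * n_indicators for b in LATENTS}, n=n, seed=seed
    )
    return ind, lat


class TestFit:
    def test_single_indicator_equals_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        b = 0.5 * a + rng.normal(size=100)
        df = pd.DataFrame({"A_x1": a, "B_x1": b})
        spec = PlsPmSpec(
            blocks={"A": ["A_x1"], "B": ["B_x1"]},
            path_matrix=pd.DataFrame([[0, 0], [1, 0]], index=["A", "B"], columns=["A", "B"]),
        )
        fit = fit_plspm(df, spec)
        assert fit.paths.loc["B", "A"] == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-10)

    def test_single_indicator_matches_ols_path_oracle(self):
        ind, _ = chain_data(n_indicators=1, n=400, seed=1)
        fit = fit_plspm(ind, chain_spec(1))
        z = (ind - ind.mean()) / ind.std(ddof=1)
        for target, source in (("B", "A"), ("C", "B")):
            ols = np.linalg.lstsq(
                z[[f"{source}_x1"]].to_numpy(), z[f"{target}_x1"].to_numpy(), rcond=None
            )[0][0]
            assert fit.paths.loc[target, source] == pytest.approx(ols, abs=1e-8)

    def test_parameter_recovery(self):
        ba, cb, loads = [], [], []
        for seed in range(20):
            ind, _ = chain_data(n_indicators=4, n=500, seed=seed)
            fit = fit_plspm(ind, chain_spec(4))
            ba.append(fit.paths.loc["B", "A"])
            cb.append(fit.paths.loc["C", "B"])
            loads.append(fit.loadings.mean())
        assert np.mean(ba) == pytest.approx(0.6, abs=0.05)
        assert np.mean(cb) == pytest.approx(0.3, abs=0.05)
        assert np.mean(loads) == pytest.approx(0.9, abs=0.05)

    def test_scores_standardized(self):
        ind, _ = chain_data(n_indicators=3, n=120, seed=2)
        fit = fit_plspm(ind, chain_spec(3))
        np.testing.assert_allclose(fit.scores.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(fit.scores.std(ddof=1), 1, atol=1e-10)

    def test_sample_order_invariance(self):
        ind, _ = chain_data(n_indicators=2, n=150, seed=3)
        fit1 = fit_plspm(ind, chain_spec(2))
        shuffled = ind.sample(frac=1, random_state=0)
        fit2 = fit_plspm(shuffled, chain_spec(2))
        np.testing.assert_allclose(fit1.paths, fit2.paths, atol=1e-9)

    def test_gof_identity(self):
        ind, _ = chain_data(n_indicators=3, n=200, seed=4)
        fit = fit_plspm(ind, chain_spec(3))
        assert fit.gof**2 == pytest.approx(
            fit.communalities.mean() * fit.r2.mean(), abs=1e-12
        )

    def test_cyclic_inner_model_rejected(self):
        bad = CHAIN.copy()
        bad.loc["A", "C"] = 1
        with pytest.raises(ValueError):
            PlsPmSpec(blocks={b: [f"{b}_x1"] for b in LATENTS}, path_matrix=bad)

    def test_estimator_wrapper(self):
        ind, _ = chain_data(n_indicators=2, n=100, seed=5)
        model = PlsPathModel(
            blocks={b: [f"{b}_x{k+1}" for k in range(2)] for b in LATENTS},
            path_matrix=CHAIN,
        ).fit(ind)
        scores = model.transform()
        assert scores.shape == (100, 3)
        assert model.get_params()["scheme"] == "path"


class TestPruning:
    def test_noise_indicator_removed(self):
        ind, _ = chain_data(n_indicators=3, n=400, seed=6)
        rng = np.random.default_rng(987)  # unrelated stream
        ind["B_noise"] = rng.normal(size=len(ind))
        blocks = {b: [f"{b}_x{k+1}" for k in range(3)] for b in LATENTS}
        blocks["B"] = blocks["B"] + ["B_noise"]
        spec = PlsPmSpec(blocks=blocks, path_matrix=CHAIN)
        fit = fit_plspm(ind, spec)
        pruned = prune_loadings(fit, ind, threshold=0.7)
        assert "B_noise" not in pruned.loadings.index
        assert (pruned.loadings.abs() >= 0.7).all()

    def test_fixed_point_when_all_strong(self):
        ind, _ = chain_data(n_indicators=3, n=300, seed=7)
        fit = fit_plspm(ind, chain_spec(3))
        pruned = prune_loadings(fit, ind, threshold=0.7)
        pd.testing.assert_series_equal(pruned.loadings, fit.loadings)

    def test_threshold_zero_noop(self):
        ind, _ = chain_data(n_indicators=2, n=100, seed=8)
        fit = fit_plspm(ind, chain_spec(2))
        assert prune_loadings(fit, ind, threshold=0.0) is fit

    def test_emptying_block_raises(self):
        # when every indicator of a block falls below the threshold the
        # refit cannot proceed and the offending block is named
        ind, _ = chain_data(n_indicators=2, n=200, seed=9)
        fit = fit_plspm(ind, chain_spec(2))
        weak = fit.loadings.copy()
        weak[["B_x1", "B_x2"]] = 0.1
        import dataclasses

        fake = dataclasses.replace(fit, loadings=weak)
        with pytest.raises(BlockEmptyError, match="B"):
            prune_loadings(fake, ind, threshold=0.7)


class TestBootstrap:
    def test_seeded_determinism(self):
        ind, _ = chain_data(n_indicators=1, n=120, seed=10)
        b1 = bootstrap_plspm(ind, chain_spec(1), n_boot=25, seed=3)
        b2 = bootstrap_plspm(ind, chain_spec(1), n_boot=25, seed=3)
        assert b1["paths"] == b2["paths"]

    def test_single_replicate_degenerate_ci(self):
        ind, _ = chain_data(n_indicators=1, n=100, seed=11)
        b = bootstrap_plspm(ind, chain_spec(1), n_boot=1, seed=0)
        for entry in b["paths"].values():
            assert entry["ci_low"] == pytest.approx(entry["ci_high"])

    def test_strong_path_significant(self):
        ind, _ = chain_data(n_indicators=1, n=400, seed=12, paths=(0.8, 0.6))
        b = bootstrap_plspm(ind, chain_spec(1), n_boot=99, seed=0)
        assert b["paths"][("B", "A")]["significant"]


class TestEffects:
    def _fit_with_paths(self, entries):
        latents = sorted({x for pair in entries for x in pair[:2]})
        pm = pd.DataFrame(0, index=latents, columns=latents)
        fit_paths = pd.DataFrame(0.0, index=latents, columns=latents)
        for source, target, coef in entries:
            pm.loc[target, source] = 1
            fit_paths.loc[target, source] = coef
        spec = PlsPmSpec(blocks={b: [f"{b}_x1"] for b in latents}, path_matrix=pm)
        # build a minimal fit object directly; only spec and paths are used
        from fracnet.plspm import PlsPmFit

        return PlsPmFit(
            spec=spec,
            outer_weights=pd.Series(dtype=float),
            loadings=pd.Series(dtype=float),
            scores=pd.DataFrame(),
            paths=fit_paths,
            r2=pd.Series(dtype=float),
            communalities=pd.Series(dtype=float),
            gof=0.0,
            n_samples=0,
            n_iter=0,
        )

    def test_chain_product_rule(self):
        fit = self._fit_with_paths([("A", "B", 0.5), ("B", "C", 0.4)])
        eff = effects_decomposition(fit).set_index(["source", "target"])
        assert eff.loc[("A", "C"), "total"] == pytest.approx(0.2)
        assert eff.loc[("A", "C"), "direct"] == 0.0

    def test_parallel_routes_add(self):
        fit = self._fit_with_paths(
            [("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.1)]
        )
        eff = effects_decomposition(fit).set_index(["source", "target"])
        assert eff.loc[("A", "C"), "total"] == pytest.approx(0.3)
        assert eff.loc[("A", "C"), "indirect"] == pytest.approx(0.2)

    def test_unconnected_pair_zero(self):
        fit = self._fit_with_paths([("A", "B", 0.5)])
        eff = effects_decomposition(fit).set_index(["source", "target"])
        assert eff.loc[("B", "A"), "total"] == 0.0
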