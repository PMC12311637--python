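"""End-to-end orchestration: filter -> diversity -> niche -> networks ->
stability -> PPBR -> PLS-PM, driven by a config mapping with seeded
determinism and a run manifest recording every parameter actually used.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomass as biomass_mod
from . import filtering, inference, netstats, niche, plspm, synthetic
from .diversity import alpha_diversity, bray_curtis, nmds, permanova
from .io import write_asv_table, write_json, write_network
from .tables import AsvTable

logger = logging.getLogger("fracnet")

PAPER_DEFAULTS = dict(
    ratio_high=2.0,
    ratio_low=0.5,
    min_prevalence_fraction=1 / 3,
    min_mean_relabund=0.001,
    nlambda=20,
    lambda_min_ratio=0.005,
    stars_threshold=0.05,
    n_subsamples=20,
    robustness_iterations=10_000,
    keystone_percentile=80.0,
    n_boot=1000,
    loading_threshold=0.7,
)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults follow standard practice."""

    outdir: str = "fracnet_out"
    seed: int = 0
    # synthetic scenario (used when no input paths are given)
    n_seasons: int = 4
    samples_per_season: int = 10
    n_core_asvs: dict = field(default_factory=lambda: {"bacteria": 20, "pico": 20, "nano": 20})
    n_noise_asvs: dict = field(default_factory=lambda: {"bacteria": 40, "pico": 40, "nano": 40})
    sequencing_depth: int = 20_000
    zero_inflation: float = 0.02
    season_effect: float = 1.0
    # module parameters
    min_prevalence_fraction: float = PAPER_DEFAULTS["min_prevalence_fraction"]
    min_mean_relabund: float = PAPER_DEFAULTS["min_mean_relabund"]
    nlambda: int = PAPER_DEFAULTS["nlambda"]
    lambda_min_ratio: float = PAPER_DEFAULTS["lambda_min_ratio"]
    stars_threshold: float = PAPER_DEFAULTS["stars_threshold"]
    n_subsamples: int = PAPER_DEFAULTS["n_subsamples"]
    seasonal_min_rows: int = 8
    robustness_iterations: int = PAPER_DEFAULTS["robustness_iterations"]
    keystone_percentile: float = PAPER_DEFAULTS["keystone_percentile"]
    n_boot: int = PAPER_DEFAULTS["n_boot"]
    loading_threshold: float = PAPER_DEFAULTS["loading_threshold"]
    n_perm: int = 999
    nmds_starts: int = 4
    # optional real-data inputs (TSV paths); synthetic scenario otherwise
    inputs: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def scenario(self) -> synthetic.SyntheticScenario:
        return synthetic.SyntheticScenario(
            n_seasons=self.n_seasons,
            samples_per_season=self.samples_per_season,
            n_core_asvs=dict(self.n_core_asvs),
            n_noise_asvs=dict(self.n_noise_asvs),
            sequencing_depth=self.sequencing_depth,
            zero_inflation=self.zero_inflation,
            season_effect=self.season_effect,
            seed=self.seed,
        )


def default_plspm_spec() -> "plspm.PlsPmSpec":
    """Inner model wiring: water property and nutrition exogenous;
    diversity, niche breadth and PPBR intermediate; network robustness
    and efficiency terminal."""
    blocks = {
        "water_property": ["temperature", "salinity", "DO"],
        "water_nutrition": ["TN", "TP"],
        "diversity": ["shannon_pico", "shannon_nano"],
        "niche_breadth": ["niche_bacteria", "niche_pico", "niche_nano"],
        "ppbr": ["log10_ppbr_hnf_hb", "log10_ppbr_hnf_ppe"],
        "robustness": ["robustness"],
        "efficiency": ["efficiency"],
    }
    latents = list(blocks)
    pm = pd.DataFrame(0, index=latents, columns=latents)
    for target in ("diversity", "niche_breadth", "ppbr", "robustness", "efficiency"):
        pm.loc[target, "water_property"] = 1
        pm.loc[target, "water_nutrition"] = 1
    for target in ("robustness", "efficiency"):
        for source in ("diversity", "niche_breadth", "ppbr"):
            pm.loc[target, source] = 1
    return plspm.PlsPmSpec(blocks=blocks, path_matrix=pm)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _combined_relative(tables: dict[str, AsvTable]) -> dict[str, pd.DataFrame]:
    """Season-shared relative tables of network-eligible ASVs per fraction."""
    return {frac: t.data for frac, t in tables.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": [],
        "warnings": [],
        "divergences": ["network inference: MB neighborhood selection + StARS"],
        "outputs": {},
    }

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {str(p.relative_to(out)): _checksum(p) for p in paths}

    try:
        # ---- stage 1: simulate / load ------------------------------
        stage = "simulate"
        scenario = config.scenario()
        counts, true_edges = synthetic.generate_counts(scenario)
        if scenario.contamination_pairs:
            counts["pico"], counts["nano"] = synthetic.inject_cross_fraction_contamination(
                counts["pico"], counts["nano"], scenario.contamination_pairs
            )
        env = synthetic.generate_env_table(scenario)
        cyto = synthetic.generate_cytometry(env, scenario)
        paths = []
        for frac, table in counts.items():
            paths += write_asv_table(table, out / f"sim_{frac}")
        env.to_csv(out / "sim_env.tsv", sep="\t", index_label="sample_id")
        cyto.to_csv(out / "sim_cytometry.tsv", sep="\t", index_label="sample_id")
        paths += [out / "sim_env.tsv", out / "sim_cytometry.tsv"]
        paths.append(
            write_json(
                {"true_edges": [sorted(e) for e in true_edges],
                 "n_core": scenario.n_core_asvs},
                out / "sim_ground_truth.json",
            )
        )
        record(stage, paths)

        # ---- stage 2: fraction filter ------------------------------
        stage = "filter"
        pico_f, nano_f, report = filtering.resolve_shared_asvs(
            counts["pico"], counts["nano"]
        )
        filtered = {"bacteria": counts["bacteria"], "pico": pico_f, "nano": nano_f}
        selected = {
            frac: filtering.select_network_asvs(
                table,
                min_prevalence_fraction=config.min_prevalence_fraction,
                min_mean_relabund=config.min_mean_relabund,
            )
            for frac, table in filtered.items()
        }
        paths = [
            write_json(
                {"ratio_basis": report.ratio_basis, "entries": report.to_records()},
                out / "shared_asv_report.json",
            )
        ]
        for frac, table in selected.items():
            paths += write_asv_table(table, out / f"selected_{frac}")
        record(stage, paths)

        # ---- stage 3: diversity ------------------------------------
        stage = "diversity"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
        alpha = {}
        beta_results = {}
        paths = []
        for frac, table in filtered.items():
            alpha[frac] = alpha_diversity(table)
            alpha[frac].to_csv(out / f"alpha_{frac}.tsv", sep="\t", index_label="sample_id")
            paths.append(out / f"alpha_{frac}.tsv")
            hel = filtering.hellinger_transform(table)
            dist = bray_curtis(hel)
            coords, stress = nmds(
                dist, n_starts=config.nmds_starts, seed=int(rng.integers(2**31 - 1))
            )
            seasons = table.seasons()
            res = permanova(
                dist, seasons, n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1))
            )
            beta_results[frac] = {
                "nmds_stress": stress,
                "permanova_season_pseudo_F": res.statistic,
                "permanova_season_p": res.p_value,
                "permanova_season_R2": res.extra["R2"],
            }
            pd.DataFrame(
                coords, index=table.samples, columns=["NMDS1", "NMDS2"]
            ).to_csv(out / f"nmds_{frac}.tsv", sep="\t", index_label="sample_id")
            paths.append(out / f"nmds_{frac}.tsv")
        paths.append(write_json(beta_results, out / "beta_diversity.json"))
        record(stage, paths)

        # ---- stage 4: niche breadth --------------------------------
        stage = "niche"
        breadth_tables = []
        community_breadth = {}
        for frac, table in filtered.items():
            rel = filtering.relative_abundance(table)
            results = niche.levins_breadth(rel, "season")
            community_breadth[frac] = niche.community_level_breadth(results)
            for season, res in results.items():
                breadth_tables.append(
                    pd.DataFrame(
                        {
                            "asv_id": res.breadth.index,
                            "season": season,
                            "fraction": frac,
                            "B": res.breadth.to_numpy(),
                        }
                    )
                )
        breadth_df = pd.concat(breadth_tables, ignore_index=True)
        breadth_df.to_csv(out / "niche_breadth_asv.tsv", sep="\t", index=False)
        cb = pd.DataFrame(community_breadth)
        cb.to_csv(out / "niche_breadth_community.tsv", sep="\t", index_label="sample_id")
        record(stage, [out / "niche_breadth_asv.tsv", out / "niche_breadth_community.tsv"])

        # ---- stage 5: network inference ----------------------------
        stage = "network"
        rel_selected = _combined_relative(selected)
        domains = {}
        for frac, frame in rel_selected.items():
            for asv in frame.columns:
                domains[asv] = frac
        variants = {
            "BPN": ("bacteria", "pico", "nano"),
            "BP": ("bacteria", "pico"),
            "BN": ("bacteria", "nano"),
        }
        networks = {}
        paths = []
        net_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20]))
        meta = next(iter(selected.values())).sample_metadata
        seasons_series = meta["season"]

        def infer(frames: list[pd.DataFrame], rows, min_rows: int, seed: int):
            data = pd.concat([f.loc[rows] for f in frames], axis=1)
            mclr = inference.clr_transform(data)
            model = inference.StarsNetworkInference(
                nlambda=config.nlambda,
                lambda_min_ratio=config.lambda_min_ratio,
                stars_threshold=config.stars_threshold,
                n_subsamples=config.n_subsamples,
                min_rows=min_rows,
                random_state=seed,
            ).fit(mclr)
            for node in model.graph_.nodes:
                model.graph_.nodes[node]["domain"] = domains[node]
            return model

        all_rows = meta.index
        for name, fracs in variants.items():
            model = infer(
                [rel_selected[f] for f in fracs],
                all_rows,
                min_rows=20,
                seed=int(net_rng.integers(2**31 - 1)),
            )
            networks[name] = model.graph_
            paths += write_network(model.graph_, out / f"network_{name}")
            paths.append(write_json(model.lambda_path_.to_dict(), out / f"lambda_path_{name}.json"))
        for season in dict.fromkeys(seasons_series):
            rows = seasons_series.index[seasons_series == season]
            if len(rows) < config.seasonal_min_rows:
                manifest["warnings"].append(
                    f"season {season}: {len(rows)} samples below seasonal_min_rows; skipped"
                )
                continue
            if len(rows) < 20:
                manifest["warnings"].append(
                    f"season {season}: StARS run on only {len(rows)} samples"
                )
            model = infer(
                [rel_selected[f] for f in variants["BPN"]],
                rows,
                min_rows=config.seasonal_min_rows,
                seed=int(net_rng.integers(2**31 - 1)),
            )
            networks[f"season:{season}"] = model.graph_
            paths += write_network(model.graph_, out / f"network_season_{season}")
        record(stage, paths)

        # ---- stage 6: stability (topology/robustness/efficiency) ---
        stage = "stability"
        stab_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 30]))
        stability = {}
        paths = []
        for name, G in networks.items():
            entry: dict = {"n_nodes": G.number_of_nodes(), "n_edges": G.number_of_edges()}
            if G.number_of_nodes() >= 2:
                entry.update(
                    netstats.topology_metrics(G, seed=int(stab_rng.integers(2**31 - 1)))
                )
                curve = netstats.random_attack_robustness(
                    G,
                    n_iterations=config.robustness_iterations,
                    seed=int(stab_rng.integers(2**31 - 1)),
                )
                eff = netstats.efficiency_distribution(G)
                entry.update(
                    robustness=curve.robustness,
                    vulnerability=curve.vulnerability,
                    efficiency_mean=eff.mean,
                    efficiency_std=eff.std,
                    global_efficiency=eff.global_efficiency,
                )
                pd.DataFrame(
                    {"step": np.arange(1, curve.n_nodes + 1), "mean_sigma": curve.sigma}
                ).to_csv(out / f"robustness_{name.replace(':', '_')}.tsv", sep="\t", index=False)
                paths.append(out / f"robustness_{name.replace(':', '_')}.tsv")
                if G.number_of_nodes() >= 5:
                    entry["keystones"] = sorted(
                        netstats.keystone_nodes(G, percentile=config.keystone_percentile)
                    )
            stability[name] = entry
        paths.append(write_json(stability, out / "network_stability.json"))
        record(stage, paths)

        # ---- stage 7: PPBR -----------------------------------------
        stage = "ppbr"
        cyto_biomass = biomass_mod.abundance_to_biomass(cyto.drop(columns=["season"]))
        ratios = biomass_mod.ppbr(cyto_biomass)
        ratios["season"] = cyto["season"]
        ratios.to_csv(out / "ppbr.tsv", sep="\t", index_label="sample_id")
        record(stage, [out / "ppbr.tsv"])

        # ---- stage 8: PLS-PM ---------------------------------------
        stage = "plspm"
        indicators = pd.DataFrame(index=env.index)
        indicators[["temperature", "salinity", "DO", "TN", "TP"]] = env[
            ["temperature", "salinity", "DO", "TN", "TP"]
        ]
        indicators["shannon_pico"] = alpha["pico"]["shannon"]
        indicators["shannon_nano"] = alpha["nano"]["shannon"]
        for frac in ("bacteria", "pico", "nano"):
            indicators[f"niche_{frac}"] = cb[frac]
        indicators["log10_ppbr_hnf_hb"] = ratios["log10_ppbr_hnf_hb"]
        indicators["log10_ppbr_hnf_ppe"] = ratios["log10_ppbr_hnf_ppe"]
        indicators.to_csv(out / "plspm_indicators.tsv", sep="\t", index_label="sample_id")
        # season-level network properties broadcast to member samples
        rob_by_season, eff_by_season = {}, {}
        for season in dict.fromkeys(seasons_series):
            key = f"season:{season}"
            if key in stability and "robustness" in stability[key]:
                rob_by_season[season] = stability[key]["robustness"]
                eff_by_season[season] = stability[key]["efficiency_mean"]
        if len(rob_by_season) == len(dict.fromkeys(seasons_series)):
            indicators["robustness"] = seasons_series.map(rob_by_season)
            indicators["efficiency"] = seasons_series.map(eff_by_season)
            indicators.to_csv(
                out / "plspm_indicators.tsv", sep="\t", index_label="sample_id"
            )
            spec = default_plspm_spec()
            fit = plspm.fit_plspm(indicators, spec)
            try:
                fit = plspm.prune_loadings(fit, indicators, threshold=config.loading_threshold)
            except plspm.BlockEmptyError as exc:
                manifest["warnings"].append(f"plspm pruning skipped: {exc}")
            boot = plspm.bootstrap_plspm(
                indicators,
                fit.spec,
                n_boot=config.n_boot,
                seed=int(np.random.default_rng(np.random.SeedSequence([config.seed, 40])).integers(2**31 - 1)),
            )
            effects = plspm.effects_decomposition(fit)
            payload = {
                "gof": fit.gof,
                "r2": fit.r2.to_dict(),
                "loadings": fit.loadings.to_dict(),
                "paths": {
                    f"{s}->{t}": float(fit.paths.loc[t, s])
                    for t in fit.spec.latents
                    for s in fit.spec.latents
                    if fit.spec.path_matrix.loc[t, s] != 0
                },
                "bootstrap": {
                    "paths": {f"{s}->{t}": v for (t, s), v in boot["paths"].items()},
                    "n_skipped": boot["n_skipped"],
                },
            }
            paths = [write_json(payload, out / "plspm_fit.json")]
            effects.to_csv(out / "plspm_effects.tsv", sep="\t", index=False)
            paths.append(out / "plspm_effects.tsv")
            record(stage, paths)
        else:
            manifest["warnings"].append(
                "plspm skipped: seasonal network properties unavailable"
            )
            manifest["stages"].append("plspm (skipped)")
    except Exception as exc:  # halt with the stage name, per contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    write_json(manifest, manifest_path)
    return manifest
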