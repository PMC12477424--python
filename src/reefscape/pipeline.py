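"""End-to-end orchestration: metrics -> site comparison -> escape models.

A single :class:`RunConfig` drives three stages:

1. *structure*: per-transect field of view, rugosity, and per-quadrat
   refuge densities over the study layout (12 transects per site; 4
   quadrats x 3 depth thresholds each for refuges);
2. *comparison*: Levene + Welch ANOVA per metric with Games-Howell post
   hocs; when no refuge-density threshold differs across sites, refuge
   density is flagged as excluded from behavioral modeling;
3. *behavior*: Bayesian escape models per taxon and response, posterior
   site contrasts per species, and the regressions of field of view and
   10-cm refuge density on rugosity.

All randomness flows from one master seed through named substreams, and
every run writes a manifest (config, seeds, package version) next to its
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import ModelSpec, fit_escape_model, site_contrasts, structure_regression
from .fov import FovConfig, transect_fov
from .grid import DEMGrid
from .refuge import RefugeConfig, quadrat_refuge_densities
from .rugosity import planar_rugosity
from .simulate import SITES, make_study_layout
from .site_stats import games_howell, levene_test, welch_anova

__all__ = [
    "RunConfig",
    "run_structure_stage",
    "run_comparison_stage",
    "run_behavior_stage",
    "run_all",
]

logger = logging.getLogger(__name__)

_STAGE_STREAMS = ("simulate", "structure", "behavior")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    preset: str = "desk"
    seed: int = 0
    output_dir: str | None = None
    n_transects: int = 12
    fov: FovConfig = field(default_factory=lambda: FovConfig(section_length=4.0))
    refuge: RefugeConfig = field(default_factory=RefugeConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    n_quadrats: int = 4
    quadrat_size: float = 1.0
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML or JSON file.

        Top-level keys mirror the dataclass fields; the ``fov``, ``refuge``
        and ``model`` sections are mappings passed to the respective
        config constructors.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "fov" in kwargs:
            kwargs["fov"] = FovConfig(**kwargs["fov"])
        if "refuge" in kwargs:
            refuge = dict(kwargs["refuge"])
            if "depth_thresholds" in refuge:
                refuge["depth_thresholds"] = tuple(refuge["depth_thresholds"])
            kwargs["refuge"] = RefugeConfig(**refuge)
        if "model" in kwargs:
            kwargs["model"] = ModelSpec(**kwargs["model"])
        return cls(**kwargs)

    def substream(self, stage: str) -> np.random.SeedSequence:
        if stage not in _STAGE_STREAMS:
            raise ValueError(f"unknown stage {stage!r}")
        return np.random.SeedSequence(
            self.seed, spawn_key=(_STAGE_STREAMS.index(stage),)
        )


def run_structure_stage(
    grids_by_site: dict[str, list[DEMGrid]],
    config: RunConfig,
) -> pd.DataFrame:
    """Per-transect structural metrics in tidy form.

    Columns: site, transect_id, metric, value.  Field of view and rugosity
    yield one row per transect; refuge densities one row per quadrat and
    threshold (transect_id suffixed ``.q<k>``).
    """
    rng = np.random.default_rng(config.substream("structure"))
    rows = []
    for site, grids in grids_by_site.items():
        for t, grid in enumerate(grids):
            tid = f"t{t:02d}"
            try:
                fov_val, _profile = transect_fov(grid, config.fov, rng)
                rows.append(
                    {"site": site, "transect_id": tid, "metric": "fov", "value": fov_val}
                )
                rug = planar_rugosity(grid)
                rows.append(
                    {"site": site, "transect_id": tid, "metric": "rugosity",
                     "value": rug.rugosity}
                )
                dens = quadrat_refuge_densities(
                    grid, config.refuge, config.n_quadrats, rng, config.quadrat_size
                )
                for _, r in dens.iterrows():
                    rows.append(
                        {
                            "site": site,
                            "transect_id": f"{tid}.q{int(r['quadrat'])}",
                            "metric": f"refuge_density_{int(round(r['threshold_m'] * 100))}",
                            "value": r["density_per_m2"],
                        }
                    )
            except ValueError as exc:
                logger.error("transect %s/%s failed: %s", site, tid, exc)
    return pd.DataFrame(rows)


def _metric_groups(table: pd.DataFrame, metric: str) -> tuple[list[str], list[np.ndarray]]:
    sub = table[table["metric"] == metric]
    sites = sorted(sub["site"].unique())
    return sites, [sub.loc[sub["site"] == s, "value"].to_numpy() for s in sites]


def run_comparison_stage(metric_table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Site comparisons per metric; decides whether refuge density is modeled.

    Returns a dict with per-metric Levene/Welch results, Games-Howell
    pairwise tables, and ``model_refuge_density`` — False when no refuge
    threshold shows a site difference at ``alpha`` (in which case refuge
    density is dropped from the behavioral stage).
    """
    report: dict = {"metrics": {}, "alpha": alpha}
    refuge_significant = False
    for metric in sorted(metric_table["metric"].unique()):
        sites, groups = _metric_groups(metric_table, metric)
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            logger.warning("metric %s lacks replication; skipped", metric)
            continue
        entry: dict = {"sites": sites}
        try:
            lev = levene_test(groups)
            entry["levene"] = dataclasses.asdict(lev)
        except ValueError as exc:
            entry["levene"] = {"error": str(exc)}
        try:
            welch = welch_anova(groups)
        except ValueError as exc:
            # e.g. a refuge threshold with no holes anywhere: no variance,
            # trivially no site difference
            logger.warning("metric %s: %s", metric, exc)
            entry["welch"] = {"error": str(exc)}
            entry["significant"] = False
            report["metrics"][metric] = entry
            continue
        entry["welch"] = dataclasses.asdict(welch)
        entry["games_howell"] = [
            {**dataclasses.asdict(p), "pair": (sites[p.pair[0]], sites[p.pair[1]])}
            for p in games_howell(groups)
        ]
        entry["significant"] = welch.p_value < alpha
        if metric.startswith("refuge_density") and entry["significant"]:
            refuge_significant = True
        report["metrics"][metric] = entry
    report["model_refuge_density"] = refuge_significant
    if not refuge_significant:
        logger.info(
            "no site differences in refuge density at alpha=%.2f; "
            "refuge density excluded from behavioral modeling", alpha,
        )
    return report


def _transect_means(metric_table: pd.DataFrame, metric: str) -> pd.Series:
    sub = metric_table[metric_table["metric"] == metric].copy()
    sub["transect"] = sub["site"] + "/" + sub["transect_id"].str.split(".").str[0]
    return sub.groupby("transect")["value"].mean()


def run_behavior_stage(
    behavior_table: pd.DataFrame,
    metric_table: pd.DataFrame,
    config: RunConfig,
    comparison: dict | None = None,
) -> dict:
    """Escape models per taxon x response plus structure regressions."""
    seed_seq = config.substream("behavior")
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in seed_seq.spawn(64))
    results: dict = {"fits": {}, "contrasts": [], "regressions": {}}
    taxa = sorted(behavior_table["taxon"].unique())
    for taxon in taxa:
        for response in ("fid", "distance_open", "distance_refuge"):
            spec = dataclasses.replace(config.model, taxon=taxon, response=response)
            try:
                fit = fit_escape_model(behavior_table, spec, seed=int(next(seeds)))
            except ValueError as exc:
                logger.warning("%s/%s not fit: %s", taxon, response, exc)
                continue
            key = f"{taxon}:{response}"
            results["fits"][key] = fit
            if not fit.converged:
                logger.warning("%s failed convergence; contrasts skipped", key)
                continue
            for sp in fit.species:
                for con in site_contrasts(fit, sp):
                    results["contrasts"].append(
                        {
                            "taxon": taxon, "response": response,
                            "species": con.species,
                            "site_a": con.site_pair[0], "site_b": con.site_pair[1],
                            "estimate_cm": con.estimate_cm,
                            "hpdi_lo": con.hpdi_89[0], "hpdi_hi": con.hpdi_89[1],
                            "significant": con.significant,
                        }
                    )
    rug = _transect_means(metric_table, "rugosity")
    model_refuge = comparison.get("model_refuge_density", True) if comparison else True
    targets = {"fov": "fov"}
    if model_refuge:
        targets["refuge_density_10"] = "refuge_density_10"
    for name, metric in targets.items():
        yvals = _transect_means(metric_table, metric)
        joined = pd.concat([rug.rename("x"), yvals.rename("y")], axis=1).dropna()
        if len(joined) >= 3:
            results["regressions"][f"{name}_on_rugosity"] = structure_regression(
                joined["x"].to_numpy(), joined["y"].to_numpy(),
                seed=int(next(seeds)), spec=config.model,
            )
    return results


def run_all(config: RunConfig, behavior_table: pd.DataFrame | None = None) -> dict:
    """Simulate (or accept) inputs and run all three stages.

    When ``behavior_table`` is None a synthetic table with the default
    effect structure is generated from the config's behavior substream.
    Writes CSVs and a JSON manifest when ``config.output_dir`` is set.
    """
    from .simulate import example_effect_spec, make_behavior_table

    sim_seed = int(config.substream("simulate").generate_state(1)[0] % (2**31))
    grids, layout_manifest = make_study_layout(
        preset=config.preset, seed=sim_seed, n_transects=config.n_transects
    )
    metric_table = run_structure_stage(grids, config)
    comparison = run_comparison_stage(metric_table, config.alpha)
    if behavior_table is None:
        behavior_table = make_behavior_table(example_effect_spec(seed=sim_seed + 1))
    behavior = run_behavior_stage(behavior_table, metric_table, config, comparison)
    out = {
        "metric_table": metric_table,
        "comparison": comparison,
        "behavior": behavior,
        "layout_manifest": layout_manifest,
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        metric_table.to_csv(outdir / "metrics.csv", index=False)
        pd.DataFrame(behavior["contrasts"]).to_csv(outdir / "contrasts.csv", index=False)
        for key, fit in behavior["fits"].items():
            fit.summary.to_csv(outdir / f"fit_{key.replace(':', '_')}.csv", index=False)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "preset": config.preset,
            "fov": dataclasses.asdict(config.fov),
            "refuge": dataclasses.asdict(config.refuge),
            "model": dataclasses.asdict(config.model),
            "layout": layout_manifest,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
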