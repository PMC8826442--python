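"""Configuration-driven orchestration of the full analysis chain.

One YAML-serializable config drives synthetic generation → survey summaries →
allometric carbon budget → isotope mixing → radiocarbon inference, and a
single JSON report collects every stage output together with the config echo,
seed, and package version, so a run can be repeated bit-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import budget as budget_mod
from . import defaults as dflt
from . import isotope as iso_mod
from . import radiocarbon as c14_mod
from . import survey as survey_mod
from . import synth

log = logging.getLogger("spongeground")

__all__ = ["ConfigError", "default_config", "load_config", "run_pipeline", "make_fixtures"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def default_config() -> dict:
    """The default all-synthetic demo configuration."""
    return {
        "seed": 0,
        "survey": {
            "n_images": dict(dflt.DEFAULT_IMAGE_COUNTS),
            "image_area_m2": 4.0,
            "juvenile_density": dflt.DEFAULT_JUVENILE_DENSITY,
            "size": dataclasses.asdict(dflt.DEFAULT_SIZE_SPEC),
            "categories": [
                {
                    "label": c.label,
                    "density_mean": c.density_mean,
                    "density_sd": c.density_sd,
                    "area_km2": c.area_km2,
                    "depth_range_m": list(c.depth_range_m),
                }
                for c in dflt.DEFAULT_CATEGORIES
            ],
        },
        "allometry": {
            **{
                k: v
                for k, v in dataclasses.asdict(budget_mod.AllometryParams()).items()
            },
            "calibration": {
                "enabled": True,
                "resp_target_mmol_m2_d": 25.0,
                "resp_categories": ["c", "d"],
                "pump_target_L_m2_d": 1640.0,
                "pump_categories": ["d"],
            },
        },
        "isotopes": {
            # reconstitute samples with group means/SDs matched exactly, the
            # standard reconstruction from published summary statistics
            "exact_moments": True,
        },
        "mixing": {
            "consumer_groups": list(dflt.ADULT_GPARVA_GROUPS),
            "sources": list(dflt.DEFAULT_SOURCE_NAMES),
            "tef_scenarios": {
                name: {
                    iso: [tef.means[iso], tef.sds[iso]] for iso in ("d13C", "d15N")
                }
                for name, tef in dflt.TEF_SCENARIOS.items()
            },
            "mcmc": {
                "n_iter": 40_000,
                "burn_in": 10_000,
                "thin": 10,
                "prior_alpha": 1.0,
                "sigma_prior_scale": 5.0,
            },
        },
        "radiocarbon": {
            "true_growth_mm_yr": 0.55,
            "radius_mm": 90.0,
            "n_sections": 6,
            "noise_sd": 3.0,
            "juvenile_age_yr": 133.0,
        },
        "mat": dataclasses.asdict(c14_mod.MatStockParams()),
        "export_flux_gC_m2_yr": 1.0,
    }


def _check_keys(given: Mapping, allowed: Mapping, path: str = "") -> None:
    for key, value in given.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in allowed:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(allowed[key], dict) and key not in (
            "n_images",
            "tef_scenarios",
        ):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {here} must be a mapping")
            _check_keys(value, allowed[key], here)


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Load a YAML config, layering file values over defaults.

    Unknown keys are rejected with the offending key named; scalar
    ``overrides`` (e.g. CLI flags) take highest precedence.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, cfg)
        cfg = _deep_merge(cfg, user)
    if overrides:
        for key, value in overrides.items():
            if value is not None:
                cfg[key] = value
    _validate_config(cfg)
    return cfg


def _deep_merge(base: dict, update: Mapping) -> dict:
    out = dict(base)
    for k, v in update.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict) and k not in (
            "n_images",
            "tef_scenarios",
        ):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate_config(cfg: Mapping) -> None:
    cats = cfg["survey"]["categories"]
    for entry in cats:
        if "area_km2" not in entry:
            raise ConfigError(
                f"config key survey.categories[{entry.get('label', '?')}].area_km2 "
                "is missing: the category areas map is required for upscaling"
            )
    if int(cfg["seed"]) < 0:
        raise ConfigError("seed must be a non-negative integer")


def _category_specs(cfg: Mapping) -> list[synth.CategorySpec]:
    return [
        synth.CategorySpec(
            label=e["label"],
            density_mean=e["density_mean"],
            density_sd=e["density_sd"],
            area_km2=e["area_km2"],
            depth_range_m=tuple(e["depth_range_m"]),
        )
        for e in cfg["survey"]["categories"]
    ]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_csv(df: pd.DataFrame, path: Path, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spongeground v{__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: Mapping | None = None, outdir=None) -> dict:
    """Execute every stage and assemble the study report.

    Returns the report as a plain dict; when ``outdir`` is given, also writes
    the stage tables (CSV) and ``report.json`` there, removing partial
    outputs if any stage fails.
    """
    cfg = dict(config) if config is not None else default_config()
    _validate_config(cfg)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    seed_survey, seed_iso, seed_c14, seed_mix = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    written: list[Path] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[str] = []
    try:
        # --- stage: synth -------------------------------------------------
        log.info("[synth] generating survey, isotope, and radiocarbon tables")
        scfg = cfg["survey"]
        categories = _category_specs(cfg)
        size_spec = synth.SizeDistributionSpec(**scfg["size"])
        survey_df = synth.generate_survey(
            categories,
            sizes=size_spec,
            n_images=scfg["n_images"],
            image_area_m2=scfg["image_area_m2"],
            juvenile_density=scfg["juvenile_density"],
            seed=seed_survey,
        )
        groups = dflt.REFERENCE_ISOTOPE_GROUPS
        isotope_df = synth.generate_isotopes(
            groups,
            seed=seed_iso,
            exact_moments=cfg["isotopes"]["exact_moments"],
        )
        rcfg = cfg["radiocarbon"]
        sections = synth.generate_radial_profile(
            true_growth=rcfg["true_growth_mm_yr"],
            radius_mm=rcfg["radius_mm"],
            n_sections=rcfg["n_sections"],
            juvenile_age_yr=rcfg["juvenile_age_yr"],
            noise_sd=rcfg["noise_sd"],
            seed=seed_c14,
        )

        # --- stage: survey ------------------------------------------------
        log.info("[survey] summarizing %d observation rows", len(survey_df))
        images = survey_mod.images_from_table(survey_df)
        by_cat: dict[str, list] = {}
        for im in images:
            by_cat.setdefault(im.category, []).append(im)
        summaries = {
            c: survey_mod.summarize_category(ims) for c, ims in sorted(by_cat.items())
        }
        sizes_all = survey_mod.size_frequency(images)
        areas = {c.label: c.area_km2 for c in categories}

        # --- stage: budget ------------------------------------------------
        log.info("[budget] allometric community budget")
        acfg = {k: v for k, v in cfg["allometry"].items() if k != "calibration"}
        params = budget_mod.AllometryParams(**acfg)
        cal = cfg["allometry"]["calibration"]
        if cal.get("enabled", True):
            params = budget_mod.calibrate_unit_scales(
                images,
                params,
                areas,
                resp_target_mmol_m2_d=cal["resp_target_mmol_m2_d"],
                resp_categories=tuple(cal["resp_categories"]),
                pump_target_L_m2_d=cal["pump_target_L_m2_d"],
                pump_categories=tuple(cal["pump_categories"]),
            )
        report_budget = budget_mod.community_budget(
            images, params, areas=areas, export_flux_gC_m2_yr=cfg["export_flux_gC_m2_yr"]
        )
        # headline budget over the dense sponge-ground domain (the summit
        # categories the community-rate calibration refers to)
        ground_cats = tuple(cal["resp_categories"])
        ground_images = [im for im in images if im.category in ground_cats]
        ground_budget = budget_mod.community_budget(
            ground_images,
            params,
            areas={c: areas[c] for c in ground_cats},
            export_flux_gC_m2_yr=cfg["export_flux_gC_m2_yr"],
        )
        for c, s in summaries.items():
            if c in report_budget.per_category:
                s.biomass_C_mean = report_budget.per_category[c].c_g_m2
                s.biomass_C_sd = report_budget.per_category[c].c_sd

        # --- stage: isotope -----------------------------------------------
        log.info("[isotope] group statistics, SEAc, mixing model")
        collected_warnings += iso_mod.validate_isotope_table(isotope_df)
        gstats = iso_mod.group_stats(isotope_df)
        ellipses = {}
        for group, grp in isotope_df.groupby("group"):
            pts = grp[["d13C", "d15N"]].dropna().to_numpy()
            if len(pts) >= 3:
                ellipses[group] = dataclasses.asdict(iso_mod.seac(pts))
        mcfg = cfg["mixing"]
        consumers = isotope_df[isotope_df["group"].isin(mcfg["consumer_groups"])]
        sources = [
            dflt.source_from_groups(dflt.SOURCE_POOLS[name], name, groups)
            for name in mcfg["sources"]
        ]
        scenarios = {
            name: iso_mod.TrophicEnrichment(
                means={iso: mv[0] for iso, mv in spec.items()},
                sds={iso: mv[1] for iso, mv in spec.items()},
            )
            for name, spec in mcfg["tef_scenarios"].items()
        }
        comparison = iso_mod.tef_alternatives(
            consumers[["d13C", "d15N"]],
            sources,
            scenarios,
            seed=seed_mix,
            **mcfg["mcmc"],
        )
        for name, post in comparison.posteriors.items():
            collected_warnings += [f"mixing[{name}]: {w}" for w in post.warnings]

        # --- stage: radiocarbon --------------------------------------------
        log.info("[c14] growth rate and ages")
        aged = c14_mod.sections_with_ages(sections)
        growth = c14_mod.growth_rate(aged)
        span = rcfg["radius_mm"] / growth.rate_mm_yr if growth.rate_mm_yr > 0 else float("nan")
        age = c14_mod.adult_age(rcfg["juvenile_age_yr"], max(span, 0.0))
        mat = c14_mod.MatStockParams(**cfg["mat"])
        mat_stock = c14_mod.mat_carbon_stock(mat)
        if growth.negative_rate:
            collected_warnings.append("radiocarbon: negative growth-rate estimate")

        report = {
            "version": __version__,
            "seed": seed,
            "config": cfg,
            "survey": {
                "categories": {c: vars(s).copy() for c, s in summaries.items()},
                "size_frequency": vars(sizes_all).copy(),
                "n_images": {c: len(ims) for c, ims in by_cat.items()},
            },
            "budget": {
                "sponge_ground": ground_budget.to_dict(),
                "entire_survey": report_budget.to_dict(),
                "carbon_demand_gC_m2_yr": ground_budget.overall.carbon_demand_gC_m2_yr,
            },
            "isotopes": {
                "group_stats": gstats.reset_index().to_dict(orient="records"),
                "seac": ellipses,
            },
            "mixing": {
                name: {
                    "mean_proportions": post.mean_proportions.to_dict(),
                    "summary": post.summary.reset_index()
                    .rename(columns={"index": "parameter"})
                    .to_dict(orient="records"),
                    "acceptance_rate": post.acceptance_rate,
                    "warnings": post.warnings,
                }
                for name, post in comparison.posteriors.items()
            },
            "mixing_shifts": (
                comparison.shifts.to_dict(orient="index")
                if comparison.shifts is not None
                else None
            ),
            "radiocarbon": {
                "growth_rate_mm_yr": growth.rate_mm_yr,
                "growth_rate_se": growth.se_mm_yr,
                "age_span_yr": growth.age_span_yr,
                "adult_age_yr": age.age_yr,
                "adult_age_rounded_yr": age.age_rounded_yr,
                "mat_carbon_stock_gC_m2": mat_stock,
                "mat_assumptions": dataclasses.asdict(mat),
                "post_bomb_sections": int(aged["post_bomb"].sum()),
            },
            "warnings": collected_warnings,
        }

        if out is not None:
            for name, df in (
                ("survey.csv", survey_df),
                ("isotopes.csv", isotope_df),
                ("radiocarbon_sections.csv", aged),
            ):
                p = out / name
                _write_csv(df, p, seed)
                written.append(p)
            p = out / "category_summary.csv"
            _write_csv(
                survey_mod.summaries_to_frame(summaries.values()).reset_index(), p, seed
            )
            written.append(p)
            for name, post in comparison.posteriors.items():
                p = out / f"mixing_draws_{name.replace(' ', '_')}.csv"
                _write_csv(pd.concat([post.p_draws, post.sigma_draws], axis=1), p, seed)
                written.append(p)
            p = out / "report.json"
            with open(p, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            written.append(p)
        return report
    except Exception:
        for p in written:  # remove partial outputs
            try:
                p.unlink()
            except OSError:
                pass
        raise


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the small CSV fixtures (survey, isotopes, radiocarbon).

    Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_survey, s_iso = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    paths = []
    survey_df = synth.generate_survey(
        dflt.DEFAULT_CATEGORIES, n_images=20, seed=s_survey
    )
    p = out / "survey_fixture.csv"
    _write_csv(survey_df, p, seed)
    paths.append(p)
    iso_df = synth.generate_isotopes(dflt.REFERENCE_ISOTOPE_GROUPS, seed=s_iso)
    p = out / "isotope_fixture.csv"
    _write_csv(iso_df, p, seed)
    paths.append(p)
    sections = synth.generate_radial_profile(
        true_growth=90.0 / 163.0, radius_mm=90.0, n_sections=2, noise_sd=0.0, seed=0
    )
    p = out / "radiocarbon_fixture.csv"
    _write_csv(sections, p, seed)
    paths.append(p)
    return paths
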