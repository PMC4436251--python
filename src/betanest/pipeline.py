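"""End-to-end study reproduction: read community matrices and island
attributes, drop empty sites, and compute the full set of summary tables —
multiple-site partition components and beta_ratio, the NODF null-model
table, richness regressions with stepwise selection, and the
distance-matrix association table (MRM slopes/intercepts plus simple and
space-partialled Mantel statistics).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .community import (
    CommunityMatrix, drop_empty_sites, matrix_fill, read_attributes_csv,
    read_community_csv, richness_cv, site_richness, ValidationError,
)
from .partition import multisite_partition, pairwise_matrices, resampled_multisite
from .nodf import nodf_null_test
from .association import attribute_distance, geo_distance, mantel, partial_mantel, mrm
from .island_models import backward_stepwise_aic, attribute_correlations, \
    species_area_regression
from .synthetic import table1_fixture


@dataclass
class AnalysisConfig:
    """Configuration of a full reproduction run.

    ``communities`` maps a taxon label to its community CSV;
    ``attributes`` is an island attribute CSV path (None uses the built-in
    37-island table). ``resample_size`` triggers subset-resampled
    multiple-site components for taxa with more retained sites than the
    target size, so taxa surveyed on different numbers of islands stay
    comparable.
    """
    communities: dict[str, str] = field(default_factory=dict)
    attributes: str | None = None
    orientation: str = "auto"
    resample_size: int | None = None
    resample_n: int = 100
    nodf_sims: int = 1000
    nodf_axis: str = "sites"
    n_perm: int = 9999
    mrm_perm: int = 999
    distance_transforms: dict[str, str] = field(default_factory=lambda: {
        "area_ha": "log10", "isolation": "none", "habitat_richness": "none"})
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _round(x, nd=4):
    if isinstance(x, float):
        return round(x, nd)
    return x


def _analyse_taxon(
    name: str, matrix: CommunityMatrix, attrs, cfg: AnalysisConfig,
    seeds: dict[str, int],
) -> dict:
    out: dict = {"taxon": name, "n_sites_total": matrix.n_sites,
                 "n_species": matrix.n_species}
    kept, removed = drop_empty_sites(matrix)
    out["empty_sites_removed"] = removed
    out["n_sites_used"] = kept.n_sites
    out["fill_pct"] = matrix_fill(kept)
    rich_all = site_richness(matrix)
    out["richness_cv"] = richness_cv(rich_all, exclude_empty=True)

    msb = multisite_partition(kept)
    out["multisite"] = {
        "beta_SOR": msb.beta_SOR, "beta_SIM": msb.beta_SIM,
        "beta_SNE": msb.beta_SNE, "beta_ratio": msb.beta_ratio,
        "dominance": msb.dominance, "n_sites": msb.n_sites,
        "tag": "sorensen/full",
    }
    if cfg.resample_size and kept.n_sites > cfg.resample_size:
        rs = resampled_multisite(kept, cfg.resample_size, cfg.resample_n,
                                 seed=seeds["resample"])
        out["multisite_resampled"] = {
            "beta_SOR": rs.mean.beta_SOR, "beta_SIM": rs.mean.beta_SIM,
            "beta_SNE": rs.mean.beta_SNE, "beta_ratio": rs.beta_ratio,
            "sd_SOR": rs.sd_SOR, "sd_SIM": rs.sd_SIM, "sd_SNE": rs.sd_SNE,
            "subset_size": rs.subset_size, "n_samples": rs.n_samples,
            "seed": seeds["resample"],
            "tag": f"sorensen/resampled {rs.subset_size}x{rs.n_samples}",
        }

    nt = nodf_null_test(kept, n_sim=cfg.nodf_sims, seed=seeds["nodf"],
                        axis=cfg.nodf_axis)
    out["nodf"] = {
        "n_obs": nt.n_obs, "n_exp_mean": nt.n_exp_mean, "n_exp_sd": nt.n_exp_sd,
        "z": nt.z, "p": nt.p, "direction": nt.direction, "n_sim": nt.n_sim,
        "axis": nt.axis, "seed": seeds["nodf"], "tag": "NODF/PP-null",
    }

    # richness model on the attribute table, aligned by island label
    sub = attrs.loc[[s for s in matrix.site_ids if s in attrs.index]]
    rich = site_richness(matrix.select_sites(sub.index))
    drop_zeros = bool((rich == 0).any())
    candidates = ("area_ha", "isolation", "habitat_richness")
    step = backward_stepwise_aic(rich, sub, candidates,
                                 drop_zeros=drop_zeros, response_name=name)
    area_only = species_area_regression(rich, sub, ("area_ha",),
                                        drop_zeros=drop_zeros, response_name=name)
    out["richness_model"] = {
        "stepwise_terms": step.terms.round(6).to_dict(orient="index"),
        "stepwise_r_squared": step.r_squared, "stepwise_aic": step.aic,
        "area_only": {
            "intercept": area_only.estimate("Intercept"),
            "slope": area_only.estimate("area_ha"),
            "r_squared": area_only.r_squared,
        },
        "n": step.n, "drop_zeros": drop_zeros,
        "tag": "OLS log10-log10, backward stepwise by AIC",
    }

    # association of pairwise dissimilarity with attribute differences
    sub_kept = attrs.loc[[s for s in kept.site_ids if s in attrs.index]]
    aligned = kept.select_sites(sub_kept.index)
    bsor, bsim, bsne = pairwise_matrices(aligned)
    dgeo = geo_distance(sub_kept["lat"], sub_kept["lon"])
    assoc: dict = {}
    for var in ("area_ha", "isolation", "habitat_richness"):
        dvar = attribute_distance(sub_kept[var],
                                  transform=cfg.distance_transforms.get(var, "none"))
        assoc[var] = {}
        for rname, resp in (("beta_sor", bsor), ("beta_sim", bsim),
                            ("beta_sne", bsne)):
            fit = mrm(resp, [dvar], n_perm=cfg.mrm_perm,
                      seed=seeds[f"mrm:{var}:{rname}"], predictor_names=[var])
            try:
                simple = mantel(dvar, resp, n_perm=cfg.n_perm,
                                seed=seeds[f"mantel:{var}:{rname}"])
                partial = partial_mantel(dvar, resp, dgeo, n_perm=cfg.n_perm,
                                         seed=seeds[f"pmantel:{var}:{rname}"],
                                         covariate_name="geographic")
                mantel_stats = {"mantel_r": simple.r, "mantel_p": simple.p,
                                "partial_mantel_r": partial.r,
                                "partial_mantel_p": partial.p}
            except ValidationError as exc:
                # e.g. a constant dissimilarity triangle (perfectly nested
                # system has beta_sim identically 0): r is undefined
                mantel_stats = {"mantel_r": None, "mantel_p": None,
                                "partial_mantel_r": None,
                                "partial_mantel_p": None, "note": str(exc)}
            assoc[var][rname] = {
                "mrm_slope": fit.slopes[0], "mrm_intercept": fit.intercept,
                "mrm_r_squared": fit.r_squared, "mrm_p": fit.p_slopes[0],
                **mantel_stats,
                "tag": (f"transform={cfg.distance_transforms.get(var, 'none')}, "
                        f"n_perm={cfg.n_perm}, mrm_perm={cfg.mrm_perm}"),
            }
    out["associations"] = assoc
    return out


def reproduce(cfg: AnalysisConfig) -> dict:
    """Run the full analysis described by ``cfg`` and return a report
    bundle; if ``cfg.out_dir`` is set, also writes results.json and
    report.txt there."""
    root = np.random.SeedSequence(cfg.seed)
    attrs = (read_attributes_csv(cfg.attributes) if cfg.attributes
             else table1_fixture())

    results: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "attribute_correlations_log10": attribute_correlations(
            attrs).round(6).to_dict(orient="index"),
        "taxa": {},
    }
    for idx, (name, path) in enumerate(sorted(cfg.communities.items())):
        try:
            matrix = read_community_csv(path, orientation=cfg.orientation)
            # a derived, stable per-purpose seed stream for this taxon
            base = int(np.random.SeedSequence([cfg.seed, idx]).generate_state(1)[0]
                       % (2 ** 31))
            seeds: dict[str, int] = {}
            counter = 0
            class _Seeds(dict):
                def __missing__(self, key):
                    nonlocal counter
                    counter += 1
                    self[key] = (base + counter) % (2 ** 31)
                    return self[key]
            seeds = _Seeds()
            results["taxa"][name] = _analyse_taxon(name, matrix, attrs, cfg, seeds)
        except ValidationError as exc:
            raise ValidationError(f"stage taxon={name!r}: {exc}") from exc
    if cfg.out_dir:
        outdir = Path(cfg.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default)
        (outdir / "report.txt").write_text(format_report(results))
    return results


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def format_report(results: dict) -> str:
    """Human-readable text report, rounded to two decimals as in the
    printed tables; the JSON bundle keeps full precision."""
    lines = [f"betanest {results['version']} reproduction report "
             f"(seed {results['seed']})", ""]
    for name, t in results["taxa"].items():
        lines.append(f"== {name} ==")
        lines.append(
            f"sites: {t['n_sites_used']}/{t['n_sites_total']} used "
            f"(removed empty: {', '.join(t['empty_sites_removed']) or 'none'}); "
            f"species: {t['n_species']}; fill {t['fill_pct']:.1f}%; "
            f"richness CV {t['richness_cv']:.2f}"
        )
        ms = t["multisite"]
        lines.append(
            f"multiple-site: beta_SOR={ms['beta_SOR']:.2f} "
            f"beta_SIM={ms['beta_SIM']:.2f} beta_SNE={ms['beta_SNE']:.2f} "
            f"beta_ratio={ms['beta_ratio']:.2f} ({ms['dominance']})"
        )
        if "multisite_resampled" in t:
            rs = t["multisite_resampled"]
            lines.append(
                f"resampled ({rs['subset_size']} sites x {rs['n_samples']}): "
                f"beta_SOR={rs['beta_SOR']:.2f} beta_SIM={rs['beta_SIM']:.2f} "
                f"beta_SNE={rs['beta_SNE']:.2f} beta_ratio={rs['beta_ratio']:.2f}"
            )
        nd = t["nodf"]
        z = "n/a" if nd["z"] is None else f"{nd['z']:.2f}"
        lines.append(
            f"NODF ({nd['axis']}): N_obs={nd['n_obs']:.2f} "
            f"N_exp={nd['n_exp_mean']:.2f} (SD {nd['n_exp_sd']:.2f}) "
            f"Z={z} p={nd['p']:.3f} [{nd['direction']}]"
        )
        rm = t["richness_model"]["area_only"]
        kept_terms = [k for k in t["richness_model"]["stepwise_terms"]
                      if k != "Intercept"]
        lines.append(
            f"species-area: slope={rm['slope']:.2f} intercept={rm['intercept']:.2f} "
            f"R2={rm['r_squared']:.2f}; stepwise retains: "
            f"{', '.join(kept_terms) or 'intercept only'}"
        )
        for var, block in t["associations"].items():
            for rname, st in block.items():
                if st["mantel_r"] is None:
                    corr = f"r undefined ({st.get('note', '')})"
                else:
                    corr = (f"r={st['mantel_r']:.2f} "
                            f"(partial r={st['partial_mantel_r']:.2f}, "
                            f"p={st['partial_mantel_p']:.4f})")
                lines.append(
                    f"  {rname} ~ d({var}): a={st['mrm_slope']:.3f} "
                    f"b={st['mrm_intercept']:.3f} {corr}"
                )
        lines.append("")
    return "\n".join(lines)
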