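"""Config-driven orchestration of the full analysis, from VCF + annotation
+ MK tables to table/figure data files."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import dfe as dfe_mod
from . import io as io_mod
from . import mk as mk_mod
from .demography import DemographicModel, SelectionGrid, build_cache
from .sfs import build_spectrum, fold, project, rescale_to_segregating, residual_spectrum
from .summaries import ibs_matrix

logger = logging.getLogger("popsel.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    vcf: str
    pop_map: str
    annotation: str
    mk_tables: str
    out_dir: str
    seed: int
    demography: dict = field(default_factory=dict)
    families: list[str] = field(default_factory=lambda: ["point_lethal"])
    grid: dict = field(default_factory=lambda: {"n_neg": 47, "n_pos": 12})
    min_quality: float = 0.95
    project_to: list[int] = field(default_factory=lambda: [8, 8])
    gene_filter_rule: str = "max"
    theta_ratio: float = 2.5
    cache_pts: int = 80
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "pop_map", "annotation", "mk_tables"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name}: {p}")
        if self.seed is None:
            raise ValueError("seed is required")

    def model(self) -> DemographicModel:
        if self.demography:
            return DemographicModel(**self.demography)
        return DemographicModel.illustrative_default()


def run_pipeline(config: RunConfig) -> dict:
    """Execute build -> project -> fold -> cache -> DFE fits -> MK stats ->
    random-effects classification -> IBS; returns {output name: path}."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    log_lines = []

    def _log(stage, **info):
        line = {"stage": stage, **info}
        log_lines.append(line)
        logger.info("%s", line)

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001
                _flush_log()
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    def _flush_log():
        path = os.path.join(config.out_dir, "run_log.json")
        with open(path, "w") as fh:
            json.dump(log_lines, fh, indent=1)
        outputs["run_log"] = path

    for name in ("vcf", "pop_map", "annotation", "mk_tables"):
        _log("inputs", file=name, path=getattr(config, name),
             sha256=io_mod.provenance_hash(getattr(config, name)))
    _log("config", seed=config.seed, min_quality=config.min_quality,
         project_to=config.project_to, families=config.families,
         theta_ratio=config.theta_ratio, gene_filter=config.gene_filter_rule)

    # --- spectra ---
    def _spectra():
        pop_map = io_mod.read_pop_map(config.pop_map)
        geno = io_mod.read_vcf(config.vcf, pop_map)
        ann = io_mod.read_annotation(config.annotation)
        parts = io_mod.annotate_sites(geno, ann)
        _log("sfs", n_sites=len(geno.site_ids),
             partition={k: len(v.site_ids) for k, v in parts.items()})
        specs = {}
        for cat, sub in parts.items():
            if not len(sub.site_ids):
                continue
            spec = build_spectrum(sub, min_quality=config.min_quality,
                                  target_sizes=tuple(config.project_to))
            spec = project(spec, config.project_to)
            specs[cat] = fold(spec)
            path = os.path.join(config.out_dir, f"sfs_{cat}.txt")
            specs[cat].save(path)
            outputs[f"sfs_{cat}"] = path
        return specs

    specs = _stage("spectra")(_spectra)

    # Fig-2-style residual comparisons on rescaled spectra
    def _residuals():
        if "synonymous" in specs and "non_synonymous" in specs:
            ns = specs["non_synonymous"]
            syn = rescale_to_segregating(specs["synonymous"], ns.segregating_total())
            res = residual_spectrum(ns, syn)
            path = os.path.join(config.out_dir, "residuals_nonsyn_vs_syn.txt")
            np.savetxt(path, res.filled(0.0), fmt="%.6f", delimiter="\t")
            outputs["residuals_nonsyn_vs_syn"] = path

    _stage("residuals")(_residuals)

    # --- DFE fits ---
    def _dfe():
        if "non_synonymous" not in specs:
            return
        model = config.model()
        grid = SelectionGrid.reduced(**config.grid)
        sizes = tuple(config.project_to)
        cache = build_cache(model, grid, sizes, pts=config.cache_pts)
        _log("cache", n_gamma=len(grid), sizes=sizes)
        data = specs["non_synonymous"]
        theta_syn = None
        if "synonymous" in specs:
            # crude theta_syn from the synonymous segregating total under the
            # neutral cached spectrum
            neutral = cache.spectra[int(np.flatnonzero(grid.gamma_values == 0)[0])]
            theta_syn = specs["synonymous"].segregating_total() / neutral.fold().segregating_total()
        results = {}
        curves = {}
        for family in config.families:
            theta_non = config.theta_ratio * theta_syn if theta_syn else "free"
            fit = dfe_mod.fit_dfe(data, cache, family, theta_non=theta_non,
                                  seed=config.seed)
            results[family] = fit.to_dict()
            masses = dfe_mod.class_masses(fit.dfe(), model.N_anc)
            results[family]["class_masses_percent"] = [round(float(v)) for v in masses]
            # Fig-4-style cumulative distribution over s
            s_grid = -np.geomspace(1e-1, 1e-7, 200)
            cdf = [
                float(
                    fit.dfe().lethal_mass()
                    + fit.dfe().continuous_mass() * fit.dfe().cdf_gamma(2 * model.N_anc * s)
                )
                if fit.family != "point_lethal"
                else float(
                    (1 - fit.params["p_point"])
                    + (fit.params["p_point"] if fit.params["gamma_point"] <= 2 * model.N_anc * s else 0.0)
                )
                for s in s_grid
            ]
            curves[family] = {"s": s_grid.tolist(), "cdf": cdf}
            _log("fit_dfe", family=family, loglik=fit.loglik, params=fit.params)
        path = os.path.join(config.out_dir, "dfe_fits.json")
        with open(path, "w") as fh:
            json.dump(results, fh, indent=1)
        outputs["dfe_fits"] = path
        # Table-2-format class-mass table
        path = os.path.join(config.out_dir, "dfe_class_masses.tsv")
        with open(path, "w") as fh:
            fh.write("selection_model\ts<-1e-2\t-1e-2<s<-1e-3\t-1e-3<s<-1e-4\t-1e-4<s\n")
            for family, r in results.items():
                fh.write(family + "\t" + "\t".join(str(v) for v in r["class_masses_percent"]) + "\n")
        outputs["dfe_class_masses"] = path
        path = os.path.join(config.out_dir, "dfe_cumulative.json")
        with open(path, "w") as fh:
            json.dump(curves, fh)
        outputs["dfe_cumulative"] = path

    _stage("dfe")(_dfe)

    # --- MK statistics and gene classification ---
    def _mk():
        tables = mk_mod.read_mk_tables(config.mk_tables)
        totals = mk_mod.MKTable(
            "genome",
            D_n=sum(t.D_n for t in tables), D_s=sum(t.D_s for t in tables),
            P_n=sum(t.P_n for t in tables), P_s=sum(t.P_s for t in tables),
            L_n=sum(t.L_n for t in tables), L_s=sum(t.L_s for t in tables),
        )
        stat, p = mk_mod.mk_chi2(totals)
        summary = {
            "counts": {"D_n": totals.D_n, "D_s": totals.D_s,
                       "P_n": totals.P_n, "P_s": totals.P_s},
            "rates_percent": {
                "syn_divergence": mk_mod.per_site_rate(totals.D_s, totals.L_s),
                "nonsyn_divergence": mk_mod.per_site_rate(totals.D_n, totals.L_n),
                "syn_polymorphism": mk_mod.per_site_rate(totals.P_s, totals.L_s),
                "nonsyn_polymorphism": mk_mod.per_site_rate(totals.P_n, totals.L_n),
            },
            "ratios_percent": {
                "divergence": mk_mod.ns_s_rate_ratio(totals, "fixed"),
                "polymorphism": mk_mod.ns_s_rate_ratio(totals, "polymorphic"),
            },
            "chi2": {"statistic": stat, "p_value": p},
        }
        path = os.path.join(config.out_dir, "mk_summary.json")
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=1)
        outputs["mk_summary"] = path
        kept = mk_mod.filter_genes(tables, rule=config.gene_filter_rule)
        _log("mk", n_genes=len(tables), n_kept=len(kept),
             chi2=stat, p=p)
        if len(kept) >= 20:
            settings = mk_mod.MCMCSettings(**config.mcmc) if config.mcmc else mk_mod.MCMCSettings()
            est = mk_mod.fit_random_effects_mk(kept, settings, seed=config.seed)
            path = os.path.join(config.out_dir, "gene_selection.tsv")
            with open(path, "w") as fh:
                fh.write("gene_id\tselection_effect\tci_low\tci_high\tclassification\n")
                for e in est:
                    fh.write(f"{e.gene_id}\t{e.selection_effect:.6f}\t"
                             f"{e.ci_low:.6f}\t{e.ci_high:.6f}\t{e.classification}\n")
            outputs["gene_selection"] = path
            _log("classify", **mk_mod.classify_genes(est))

    _stage("mk")(_mk)

    # --- IBS ---
    def _ibs():
        pop_map = io_mod.read_pop_map(config.pop_map)
        geno = io_mod.read_vcf(config.vcf, pop_map)
        mat = ibs_matrix(geno)
        path = os.path.join(config.out_dir, "ibs_matrix.tsv")
        mat.save(path)
        outputs["ibs_matrix"] = path

    _stage("ibs")(_ibs)

    _flush_log()
    return outputs
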