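"""End-to-end study orchestration: simulate -> process -> kernels -> fit ->
cross-validate -> select OTUs, with a reproducibility manifest.

Every stage communicates through the declared tabular formats (TSV, Newick,
YAML); :func:`run_study` wires them together for a configuration-driven run
and emits variance-component, predictive-ability and OTU-selection tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .kernels import KernelMatrix, build_kernel
from .mixed_model import ChainConfig, ModelSpec, RandomTerm, em_reml, gibbs_sample
from .otu_processing import OTUTable, css_normalize, filter_prevalence_abundance, \
    remove_doubletons
from .pedigree import Pedigree, numerator_relationship
from .spls import stability_selection
from .synthetic_data import SimulationConfig, simulate_study
from .traits import build_design_matrices, derive_phenotypes
from .validation import run_cv_experiment

log = logging.getLogger(__name__)

__all__ = ["make_model_spec", "process_counts", "run_study", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "simulation": {},            # SimulationConfig overrides
    "trait": "adg_al",
    "dataset": "m",              # 'm' (assessed animals) or 'full'
    "kernels": ["M_O", "M_B", "M_U"],
    "expansion": "none",         # for dataset='full': identity_block | cage_average
    "estimator": "gibbs",        # gibbs | reml
    "chain": {"n_iter": 5000, "burn_in": 1000, "thin": 5},
    "include_microbial": True,
    "cv": {"enabled": True, "n_replicates": 20},
    "spls": {"enabled": True, "n_repeats": 4,
             "eta_grid": [0.1, 0.3, 0.5, 0.7, 0.9], "K_grid": [1, 2, 3, 4, 5]},
}


def process_counts(counts: OTUTable) -> OTUTable:
    """Standard count processing: doubleton removal, prevalence/abundance
    filter, CSS normalization."""
    table = remove_doubletons(counts)
    table = filter_prevalence_abundance(table)
    return css_normalize(table)


def make_model_spec(
    trait: str,
    y: pd.Series,
    design: pd.DataFrame,
    pedigree: Pedigree,
    kernel: KernelMatrix | None = None,
    trait_kind: str = "individual",
) -> ModelSpec:
    """Assemble a ModelSpec for one trait.

    ``y`` is indexed by animal (individual traits) or cage (cage traits).
    Individual traits carry additive, litter, cage and (optionally)
    microbial terms; cage-average traits drop the cage term and use
    fractional incidence matrices.  The microbial kernel, when given, must
    cover every animal the records reference (use an expansion strategy
    otherwise).
    """
    y = y.dropna()
    record_ids = list(y.index)
    dm = build_design_matrices(design, trait_kind, record_ids,
                               microbial_levels=list(kernel.ids) if kernel else None)
    A_sub, _ = numerator_relationship(pedigree, ids=dm.levels["additive"])
    terms = [RandomTerm("additive", dm.Z["additive"], A_sub, dm.levels["additive"]),
             RandomTerm("litter", dm.Z["litter"], None, dm.levels["litter"])]
    if trait_kind == "individual":
        terms.append(RandomTerm("cage", dm.Z["cage"], None, dm.levels["cage"]))
    if kernel is not None:
        terms.append(RandomTerm("microbial", dm.Z["microbial"], kernel.matrix,
                                dm.levels["microbial"]))
    return ModelSpec(trait, y.to_numpy(dtype=float), dm.X, terms, trait_kind, record_ids)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def run_study(config: dict | None = None, outdir: str | Path = "results",
              seed: int = 0) -> dict:
    """Run the full study analogue and write result tables + manifest.

    Returns a dict of in-memory results keyed by stage.  All randomness
    derives from ``seed``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("chain", "cv", "spls"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    sim_cfg = SimulationConfig(**{**cfg["simulation"], "seed": seed})
    study = simulate_study(sim_cfg)
    log.info("simulated %d animals in %d cages", len(study.design),
             study.design["cage"].nunique())

    css = process_counts(study.otu_counts)
    phen = derive_phenotypes(study.design, study.bw_records, study.cage_fi)

    trait = cfg["trait"]
    trait_kind = "individual" if trait.startswith("adg") else "cage"
    if cfg["dataset"] == "m" and trait_kind == "individual":
        assessed = study.design.loc[study.design["assessed"], "animal"]
        y = phen.trait(trait).reindex(assessed).dropna()
        css_sub = OTUTable(css.data.loc[[a for a in y.index if a in css.data.index]],
                           stage="css")
        expansion = "none"
    else:
        y = phen.trait(trait)
        css_sub = OTUTable(css.data.loc[study.design.loc[study.design["assessed"],
                                                         "animal"]], stage="css")
        expansion = cfg["expansion"] if cfg["expansion"] != "none" else "identity_block"

    results: dict = {"config": cfg, "seed": seed}
    var_rows = []
    fits = {}
    for method in (cfg["kernels"] if cfg["include_microbial"] else []):
        kern = build_kernel(css_sub, study.design, method, expansion,
                            tree=study.tree)
        spec = make_model_spec(trait, y, study.design, study.pedigree, kern, trait_kind)
        if cfg["estimator"] == "gibbs":
            fit = gibbs_sample(spec, ChainConfig(seed=seed, **cfg["chain"]))
        else:
            fit = em_reml(spec)
        fits[method] = fit
        for _, r in fit.estimates.to_frame().iterrows():
            var_rows.append({"model": "M2", "microbial_matrix": method, **r})
    spec_m1 = make_model_spec(trait, y, study.design, study.pedigree, None, trait_kind)
    if cfg["estimator"] == "gibbs":
        fit_m1 = gibbs_sample(spec_m1, ChainConfig(seed=seed, **cfg["chain"]))
    else:
        fit_m1 = em_reml(spec_m1)
    fits["M1"] = fit_m1
    for _, r in fit_m1.estimates.to_frame().iterrows():
        var_rows.append({"model": "M1", "microbial_matrix": "-", **r})
    var_df = pd.DataFrame(var_rows)
    var_df.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    results["variance_components"] = var_df
    results["fits"] = fits

    if cfg["cv"]["enabled"] and cfg["include_microbial"]:
        cv_rows = []
        for method in cfg["kernels"]:
            kern = build_kernel(css_sub, study.design, method, expansion,
                                tree=study.tree)
            spec = make_model_spec(trait, y, study.design, study.pedigree, kern,
                                   trait_kind)
            cv = run_cv_experiment(spec, study.design,
                                   n_replicates=cfg["cv"]["n_replicates"],
                                   seed=seed, n_comparisons=len(cfg["kernels"]))
            cv_rows.append({"trait": trait, "microbial_matrix": method, **cv.summary()})
        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out / "cv_results.tsv", sep="\t", index=False)
        results["cv"] = cv_df

    if cfg["spls"]["enabled"]:
        X = css.data.loc[[a for a in y.index if a in css.data.index]]
        y_spls = y.reindex(X.index)
        sel = stability_selection(
            X.to_numpy(), y_spls.to_numpy(), var_names=list(X.columns),
            n_repeats=cfg["spls"]["n_repeats"], seed=seed,
            eta_grid=tuple(cfg["spls"]["eta_grid"]),
            K_grid=tuple(cfg["spls"]["K_grid"]))
        counts_df = sel.counts.rename("times_selected").rename_axis("otu").reset_index()
        counts_df["stable"] = counts_df["otu"].isin(sel.stable)
        counts_df.to_csv(out / "spls_selection.tsv", sep="\t", index=False)
        results["spls"] = sel

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "runtime_s": round(time.time() - t0, 2),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
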