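"""Per-parasite-group orchestration of the full analysis.

For each parasite group the pipeline (1) converts reported statistics to
Fisher's Zr, (2) computes species weighted-mean effects with Pagel's
lambda fits and boundary LRTs, (3) fits the intercept-only multilevel REM
with phylogenetic heritability, (4) runs the phylogenetic PCA and attaches
the pace-of-life PC1, (5) enumerates the candidate MEMs, ranks them by
AICc with importances and REML pseudo-R2, and (6) reports top-model
coefficients with back-transformed r and effect classes.  Everything is
written as CSV/JSON with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    PARASITE_GROUPS,
    read_effect_table,
    read_trait_table,
    traits_to_frame,
    effects_to_frame,
    validate_dataset,
)
from .effect_conversion import classify_effect, derive_effect_sizes, zr_to_r
from .meta_mixed import DesignSpec, build_design, fit_meta_mixed, heritability, qm_test
from .model_selection import (
    CandidateSet,
    generate_candidates,
    importance_table,
    selection_table,
)
from .phylo_signal import (
    lambda_lrt,
    means_to_series,
    pagel_lambda_ml,
    species_weighted_means,
)
from .phylo_tools import (
    grafen_lengths,
    is_binary,
    phylo_corr,
    prune,
    read_tree,
    resolve_polytomies,
)
from .trait_pca import attach_pc1, pace_transforms, phylo_pca

log = logging.getLogger("provmeta")

#: Default candidate term sets per parasite group.  Interactions mirror the
#: biologically motivated pairs considered per group (home range x pace of
#: life is never considered because home range scales with body size).  The
#: collinearity exclusion list is a best-effort transcription and can be
#: overridden in the config.
DEFAULT_MAINS = (
    "dietary_breadth",
    "migratory",
    "pace_of_life",
    "provisioning_type",
    "home_range",
    "trophic_level",
)
DEFAULT_INTERACTIONS = {
    "microparasite": (
        ("dietary_breadth", "pace_of_life"),
        ("dietary_breadth", "home_range"),
        ("pace_of_life", "migratory"),
        ("provisioning_type", "dietary_breadth"),
        ("provisioning_type", "migratory"),
        ("provisioning_type", "pace_of_life"),
        ("home_range", "provisioning_type"),
        ("provisioning_type", "trophic_level"),
        ("home_range", "migratory"),
        ("trophic_level", "migratory"),
        ("trophic_level", "pace_of_life"),
    ),
    "helminth": (
        ("dietary_breadth", "pace_of_life"),
        ("dietary_breadth", "home_range"),
        ("pace_of_life", "migratory"),
        ("provisioning_type", "dietary_breadth"),
        ("provisioning_type", "pace_of_life"),
        ("home_range", "provisioning_type"),
        ("home_range", "migratory"),
        ("trophic_level", "pace_of_life"),
    ),
    "ectoparasite": (
        ("dietary_breadth", "home_range"),
        ("provisioning_type", "dietary_breadth"),
        ("provisioning_type", "pace_of_life"),
    ),
}
DEFAULT_EXCLUSIONS = (frozenset({"dietary_breadth", "trophic_level"}),)


def _candidate_set(group: str, config: dict) -> CandidateSet:
    cand = (config.get("candidates") or {}).get(group, {})
    return CandidateSet(
        main_effects=tuple(cand.get("main_effects", DEFAULT_MAINS)),
        interactions=tuple(
            tuple(x) for x in cand.get(
                "interactions", DEFAULT_INTERACTIONS.get(group, ())
            )
        ),
        exclusions=tuple(
            frozenset(x) for x in cand.get("exclusions", DEFAULT_EXCLUSIONS)
        ),
        max_covariates=int(cand.get("max_covariates", 3)),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def prepare_inputs(config: dict):
    """Load (or simulate) records, traits and tree per the config."""
    seed = int(config.get("seed", 0))
    if "simulate" in config:
        from .synthetic_data import SimConfig, generate_dataset

        sim = dict(config["simulate"] or {})
        sim.setdefault("seed", seed)
        for key in ("studies_per_species", "records_per_study", "n_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        tree, traits, records, _sidecar = generate_dataset(SimConfig(**sim))
    else:
        inputs = config["inputs"]
        aliases = config.get("species_aliases") or {}
        records = read_effect_table(
            inputs["effects"], species_aliases=aliases,
            column_map=config.get("column_map"),
        )
        traits = read_trait_table(inputs["traits"], species_aliases=aliases)
        tree = read_tree(inputs["tree"])
    return records, traits, tree


def prepare_tree(tree, species, seed: int):
    """Prune to study species, resolve, Grafen lengths, correlation matrix."""
    tree = prune(tree, species)
    if not is_binary(tree):
        tree = resolve_polytomies(tree, seed=seed)
    tree = grafen_lengths(tree)
    return tree, phylo_corr(tree)


def run_full_analysis(config, outdir) -> dict:
    """Run the complete stratified workflow; returns the result bundle."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    weighting = config.get("weighting", "n")
    k_mode = config.get("k_mode", "full")

    records, traits, tree = prepare_inputs(config)

    # stage 1: effect conversion + annotation
    records = derive_effect_sizes(records)
    usable = [r for r in records if r.zr is not None]
    dropped = len(records) - len(usable)
    if dropped:
        log.warning("%d records dropped (n_total < 4)", dropped)
    effects_to_frame(records).to_csv(outdir / "effects_annotated.csv", index=False)

    report = validate_dataset(usable, traits, tree)
    (outdir / "validation.json").write_text(report.to_json())
    if not report.ok:
        raise ValueError(
            "dataset inconsistent with traits/tree:\n" + report.to_text()
        )

    species = sorted({r.host_species for r in usable})
    work_tree, C = prepare_tree(tree, species, seed)

    # stage 4 (needed before modelling): phylo-PCA and pace PC1
    tframe = traits_to_frame(traits).loc[
        [t.species for t in traits if t.species in set(species)]
    ]
    tframe = tframe.loc[sorted(tframe.index)]
    X_pace = pace_transforms(tframe)
    pca = phylo_pca(X_pace, C.loc[X_pace.index, X_pace.index])
    tframe = attach_pc1(tframe, pca)
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    pca.scores.to_csv(outdir / "pca_scores.csv")
    (outdir / "pca_summary.json").write_text(
        json.dumps(
            {
                "eigenvalues": pca.eigenvalues.tolist(),
                "variance_explained": pca.variance_explained.tolist(),
                "ancestral_means": pca.ancestral_means.to_dict(),
            },
            indent=2,
        )
    )

    results: dict = {"groups": {}, "pca_variance_explained":
                     pca.variance_explained.tolist()}
    only = config.get("_only_group")
    for group in PARASITE_GROUPS:
        if only and group != only:
            continue
        grp_records = [r for r in usable if r.parasite_group == group]
        if not grp_records:
            log.warning("group %s: no records; skipped", group)
            continue
        results["groups"][group] = _analyze_group(
            group, grp_records, tframe, C, outdir,
            config, seed, weighting, k_mode,
        )

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "weighting": weighting,
        "k_mode": k_mode,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_records": len(records),
        "n_records_usable": len(usable),
        "n_species": len(species),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def _analyze_group(
    group, grp_records, tframe, C, outdir, config, seed, weighting, k_mode
):
    out: dict = {"n_records": len(grp_records)}
    grp_species = sorted({r.host_species for r in grp_records})
    out["n_species"] = len(grp_species)
    C_grp = C.loc[grp_species, grp_species]

    # stage 2: species means + Pagel's lambda
    means = species_weighted_means(grp_records, weighting=weighting)
    mean_series = means_to_series(means)
    pd.DataFrame([m.__dict__ for m in means]).to_csv(
        outdir / f"species_means_{group}.csv", index=False
    )
    if len(grp_species) < 4 or np.ptp(mean_series.to_numpy()) == 0:
        log.warning(
            "group %s: %d species; lambda stage skipped (needs >= 4 species "
            "and non-constant means)", group, len(grp_species)
        )
        out["lambda"] = None
    else:
        lam = pagel_lambda_ml(mean_series, C_grp)
        lrt0 = lambda_lrt(lam, 0.0, mean_series, C_grp)
        lrt1 = lambda_lrt(lam, 1.0, mean_series, C_grp)
        out["lambda"] = {
            "lambda_hat": lam.lambda_hat,
            "loglik": lam.loglik,
            "n_species": lam.n_species,
            "lrt_vs_lambda0": {"statistic": lrt0[0], "p": lrt0[1]},
            "lrt_vs_lambda1": {"statistic": lrt1[0], "p": lrt1[1]},
        }
        (outdir / f"lambda_{group}.json").write_text(
            json.dumps(out["lambda"], indent=2)
        )

    # stage 3: intercept-only REM with H2
    rem_spec = DesignSpec(())
    y, v, X, study_idx, sp_idx = build_design(grp_records, tframe, rem_spec)
    rem = fit_meta_mixed(
        y, v, X, study_idx, sp_idx, C_grp, method="REML", spec=rem_spec
    )
    out["rem"] = {
        "mu": float(rem.beta.iloc[0]),
        "sigma2_obs": rem.sigma2_obs,
        "sigma2_study": rem.sigma2_study,
        "sigma2_species": rem.sigma2_species,
        "h2": heritability(rem),
        "loglik": rem.loglik,
    }
    (outdir / f"rem_{group}.json").write_text(json.dumps(out["rem"], indent=2))

    # stage 5: candidate generation, AICc table, importances, pseudo-R2
    cs = _candidate_set(group, config)
    specs = generate_candidates(cs)
    ml_fits, reml_fits = [], []
    for spec in specs:
        ys, vs, Xs, st, sp = build_design(grp_records, tframe, spec)
        if len(ys) <= (Xs.shape[1] + 3) + 1:
            log.warning(
                "group %s: skipping %s (n too small for AICc)", group, spec.label
            )
            continue
        if np.linalg.matrix_rank(Xs.to_numpy()) < Xs.shape[1]:
            log.warning(
                "group %s: skipping %s (design not of full rank in this "
                "stratum, e.g. an unobserved factor level)", group, spec.label
            )
            continue
        ml_fits.append(
            fit_meta_mixed(ys, vs, Xs, st, sp, C_grp, method="ML", spec=spec)
        )
        reml_fits.append(
            fit_meta_mixed(ys, vs, Xs, st, sp, C_grp, method="REML", spec=spec)
        )
    if not ml_fits:
        log.warning(
            "group %s: too few records for any candidate model; model "
            "selection skipped", group
        )
        out["n_candidates"] = 0
        out["importance"] = {}
        out["selection_head"] = []
        out["top_model"] = None
        return out
    table = selection_table(ml_fits, reml_fits, rem, k_mode=k_mode)
    table.drop(columns=["terms"]).to_csv(
        outdir / f"selection_{group}.csv", index=False
    )
    imp = importance_table(table)
    imp.to_csv(outdir / f"importance_{group}.csv")
    out["n_candidates"] = len(ml_fits)
    out["importance"] = imp.to_dict()
    out["selection_head"] = table.drop(columns=["terms"]).head(10).to_dict("records")

    # stage 6: top-model coefficients with back-transformed r + classes
    top_terms = table.iloc[0]["terms"]
    top_reml = next(
        f for f in reml_fits if frozenset(f.spec.terms) == frozenset(top_terms)
    )
    coef = top_reml.summary_frame()
    coef["effect_class"] = [classify_effect(zr_to_r(b)) for b in top_reml.beta]
    coef.to_csv(outdir / f"top_model_{group}.csv")
    top = {
        "model": top_reml.spec.label,
        "h2": heritability(top_reml),
        "coefficients": coef.to_dict("index"),
    }
    if top_reml.k_fixed > 1:
        qm, df, p = qm_test(top_reml)
        top["qm"] = {"statistic": qm, "df": df, "p": p}
    (outdir / f"top_model_{group}.json").write_text(
        json.dumps(top, indent=2, default=float)
    )
    out["top_model"] = top
    return out
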