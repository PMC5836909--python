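"""Parameter-recovery experiments on generator output.

These functions define the simulation study used to validate the
estimators: a 60-species design (3 studies per species, 3 records per
study) with a known home-range slope of 0.3 and variance components
(0.02, 0.02, 0.04) — a species share of 0.5 — for the multilevel model,
and 100-tip trees for Pagel's lambda under Brownian-motion truth versus
phylogenetic independence.  Results are medians over seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import traits_to_frame
from .effect_conversion import derive_effect_sizes
from .meta_mixed import DesignSpec, build_design, fit_meta_mixed, heritability
from .phylo_signal import pagel_lambda_ml
from .phylo_tools import phylo_corr
from .synthetic_data import SimConfig, generate_dataset, simulate_tree

#: the recovery design: true slope and variance components
TRUE_BETA1 = 0.3
TRUE_COMPONENTS = (0.02, 0.02, 0.04)
TRUE_H2 = TRUE_COMPONENTS[2] / sum(TRUE_COMPONENTS)


def _recovery_config(seed: int) -> SimConfig:
    return SimConfig(
        n_species=60,
        studies_per_species=(3, 3),
        records_per_study=(3, 3),
        beta={"intercept": 0.0, "home_range_qrt": TRUE_BETA1},
        sigma2_obs=TRUE_COMPONENTS[0],
        sigma2_study=TRUE_COMPONENTS[1],
        sigma2_species=TRUE_COMPONENTS[2],
        lambda_true=1.0,
        seed=seed,
    )


def beta_h2_recovery(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Median slope and H2 estimates across seeded replicates."""
    beta1, h2 = [], []
    for i in range(n_seeds):
        cfg = _recovery_config(base_seed + i)
        tree, traits, records, _ = generate_dataset(cfg)
        records = derive_effect_sizes(records)
        tf = traits_to_frame(traits)
        tf["pace_pc1"] = 0.0
        y, v, X, st, sp = build_design(
            records, tf, DesignSpec(("home_range",))
        )
        fit = fit_meta_mixed(y, v, X, st, sp, phylo_corr(tree), method="REML")
        beta1.append(float(fit.beta["home_range"]))
        h2.append(heritability(fit))
    return {
        "beta1_median": float(np.median(beta1)),
        "h2_median": float(np.median(h2)),
        "beta1_true": TRUE_BETA1,
        "h2_true": TRUE_H2,
        "n_seeds": n_seeds,
        "n_obs": 540,
    }


def lambda_recovery(
    n_seeds: int = 50, n_tips: int = 100, base_seed: int = 0
) -> dict:
    """Median lambda-hat under Brownian truth and under independence."""
    bm, iid = [], []
    for i in range(n_seeds):
        tree = simulate_tree(n_tips, seed=base_seed + i)
        C = phylo_corr(tree)
        rng = np.random.default_rng((base_seed + i, 17))
        L = np.linalg.cholesky(C.to_numpy() + 1e-10 * np.eye(n_tips))
        y_bm = pd.Series(L @ rng.standard_normal(n_tips), index=C.index)
        y_iid = pd.Series(rng.standard_normal(n_tips), index=C.index)
        bm.append(pagel_lambda_ml(y_bm, C).lambda_hat)
        iid.append(pagel_lambda_ml(y_iid, C).lambda_hat)
    return {
        "lambda_bm_median": float(np.median(bm)),
        "lambda_iid_median": float(np.median(iid)),
        "n_seeds": n_seeds,
        "n_tips": n_tips,
    }
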