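#!/usr/bin/env python
"""Phylogenetic signal in species mean effect sizes, per parasite group.

Collapses records to sample-size-weighted species means, estimates
Pagel's lambda by ML on the Grafen-scaled host tree, and tests the
estimate against the independence (lambda = 0) and Brownian (lambda = 1)
boundaries with likelihood-ratio tests.  Writes results/signal/*.json.
"""

import json
from pathlib import Path

from provmeta.data_io import PARASITE_GROUPS, read_effect_table
from provmeta.effect_conversion import derive_effect_sizes
from provmeta.phylo_signal import (
    lambda_lrt, means_to_series, pagel_lambda_ml, species_weighted_means,
)
from provmeta.phylo_tools import read_tree
from provmeta.pipeline import prepare_tree

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260929


def main():
    records = derive_effect_sizes(read_effect_table(ROOT / "data/effects.csv"))
    records = [r for r in records if r.zr is not None]
    tree = read_tree(ROOT / "data/tree.nwk")
    outdir = ROOT / "signal"
    outdir.mkdir(parents=True, exist_ok=True)
    for group in PARASITE_GROUPS:
        grp = [r for r in records if r.parasite_group == group]
        means = means_to_series(species_weighted_means(grp))
        if len(means) < 4:
            print(f"{group}: only {len(means)} species; lambda skipped")
            continue
        _, C = prepare_tree(tree, list(means.index), seed=SEED)
        fit = pagel_lambda_ml(means, C)
        res = {"lambda_hat": fit.lambda_hat, "n_species": fit.n_species}
        for null in (0.0, 1.0):
            stat, p = lambda_lrt(fit, null, means, C)
            res[f"lrt_vs_lambda{int(null)}"] = {"statistic": stat, "p": p}
        (outdir / f"lambda_{group}.json").write_text(json.dumps(res, indent=2))
        print(
            f"{group}: lambda_hat = {fit.lambda_hat:.3f} "
            f"({fit.n_species} species); "
            f"p(vs 0) = {res['lrt_vs_lambda0']['p']:.3f}, "
            f"p(vs 1) = {res['lrt_vs_lambda1']['p']:.3g}"
        )


if __name__ == "__main__":
    main()
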