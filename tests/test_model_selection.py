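"""Candidate enumeration, AICc algebra, importance and pseudo-R2."""

import math
from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from provmeta.meta_mixed import DesignSpec, build_design, fit_meta_mixed
from provmeta.model_selection import (
    CandidateSet,
    aicc,
    generate_candidates,
    importance,
    importance_table,
    pseudo_r2,
    rank_and_weight,
    selection_table,
)


# ----------------------------------------------------------- enumeration


def test_two_mains_no_interactions():
    cs = CandidateSet(main_effects=("home_range", "migratory"))
    specs = generate_candidates(cs)
    labels = {s.label for s in specs}
    assert labels == {
        "Zr ~ 1",
        "Zr ~ home_range",
        "Zr ~ migratory",
        "Zr ~ home_range + migratory",
    }


def test_exclusion_pair_removes_joint_model():
    cs = CandidateSet(
        main_effects=("home_range", "migratory"),
        exclusions=(frozenset({"home_range", "migratory"}),),
    )
    labels = {s.label for s in generate_candidates(cs)}
    assert "Zr ~ home_range + migratory" not in labels
    assert len(labels) == 3


def _brute_force_count(mains, interactions, exclusions, cap):
    """Powerset filter oracle for the candidate count."""
    count = 0
    for k in range(len(mains) + 1):
        for subset in combinations(mains, k):
            s = set(subset)
            if len(s) > cap:
                continue
            if any(e <= s for e in exclusions):
                continue
            inters = [i for i in interactions if set(i) <= s]
            count += 2 ** len(inters)
    return count


def test_enumeration_matches_powerset_oracle():
    mains = ("dietary_breadth", "home_range", "pace_of_life",
             "provisioning_type", "migratory")
    interactions = (
        ("dietary_breadth", "home_range"),
        ("provisioning_type", "pace_of_life"),
        ("provisioning_type", "migratory"),
    )
    exclusions = (frozenset({"dietary_breadth", "pace_of_life"}),)
    cs = CandidateSet(mains, interactions, exclusions, max_covariates=3)
    specs = generate_candidates(cs)
    assert len(specs) == _brute_force_count(mains, interactions, exclusions, 3)
    assert specs[0].terms == ()  # intercept-only included, first
    # marginality: every interaction's mains present
    for s in specs:
        mains_present = set(s.main_effects)
        for t in s.interactions:
            assert set(t.split(":")) <= mains_present
    # no duplicates
    assert len({frozenset(s.terms) for s in specs}) == len(specs)


def test_unknown_interaction_rejected():
    with pytest.raises(ValueError, match="unknown main effect"):
        CandidateSet(("home_range",), (("home_range", "migratory"),))


# ------------------------------------------------------------------ AICc


def test_aicc_value_and_limits():
    assert aicc(-10, 2, 10) == pytest.approx(24 + 12 / 7)
    # approaches AIC as n grows
    assert aicc(-10, 2, 10**9) == pytest.approx(24, abs=1e-6)
    # monotone in k at fixed loglik and n
    assert aicc(-10, 3, 20) > aicc(-10, 2, 20)
    with pytest.raises(ValueError):
        aicc(-10, 9, 10)


# ------------------------------------------------------- weights/importance


def _fake_fit(terms, loglik, n=50, k_fixed=None):
    spec = DesignSpec(terms)
    p = k_fixed or (1 + len(terms))
    beta = pd.Series(np.zeros(p))
    return type(
        "F", (),
        {"spec": spec, "loglik": loglik, "n_obs": n, "method": "ML",
         "k_fixed": p},
    )()


def test_single_model_weight_one():
    rows = rank_and_weight([_fake_fit((), -10.0)])
    assert rows.loc[0, "weight"] == pytest.approx(1.0)
    assert rows.loc[0, "delta_aicc"] == 0.0


def test_equal_aicc_splits_weights():
    fits = [_fake_fit((), -10.0), _fake_fit(("home_range",), -10.0, k_fixed=1)]
    rows = rank_and_weight(fits)
    assert rows["weight"].to_numpy() == pytest.approx([0.5, 0.5])


def test_delta_two_weight_ratio_is_exp_minus_one():
    # delta AICc of exactly 2 <=> loglik difference of 1 at equal k
    fits = [_fake_fit((), -10.0), _fake_fit(("home_range",), -11.0, k_fixed=1)]
    rows = rank_and_weight(fits)
    ratio = rows.loc[1, "weight"] / rows.loc[0, "weight"]
    assert rows.loc[1, "delta_aicc"] == pytest.approx(2.0)
    assert ratio == pytest.approx(math.exp(-1.0))
    assert rows["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    assert bool(rows.loc[1, "competitive"])


def test_mixed_n_rejected():
    with pytest.raises(ValueError, match="different data"):
        rank_and_weight([_fake_fit((), -10, n=50), _fake_fit((), -10, n=49)])


def test_rank_invariant_to_candidate_order():
    fits = [
        _fake_fit((), -12.0),
        _fake_fit(("home_range",), -10.0),
        _fake_fit(("migratory",), -11.0),
    ]
    a = rank_and_weight(fits)
    b = rank_and_weight(fits[::-1])
    pd.testing.assert_frame_equal(a, b)


def test_importance_rules():
    fits = [
        _fake_fit((), -12.0),
        _fake_fit(("home_range",), -10.0),
        _fake_fit(
            ("home_range", "migratory", "home_range:migratory"), -11.0
        ),
    ]
    rows = rank_and_weight(fits)
    w = dict(zip([tuple(t) for t in rows["terms"]], rows["weight"]))
    imp_hr = importance(rows, "home_range")
    # home_range occurs in both non-null models
    assert imp_hr == pytest.approx(
        w[("home_range",)]
        + w[("home_range", "migratory", "home_range:migratory")]
    )
    # the interaction counts for itself only
    assert importance(rows, "home_range:migratory") == pytest.approx(
        w[("home_range", "migratory", "home_range:migratory")]
    )
    # a term in no model has importance 0 is impossible here; unknown errors
    with pytest.raises(ValueError, match="unknown term"):
        importance(rows, "pace_of_life")
    tab = importance_table(rows)
    assert set(tab.index) == {
        "home_range", "migratory", "home_range:migratory"
    }
    assert (tab <= 1.0 + 1e-12).all()


def test_term_in_every_model_has_importance_one():
    fits = [
        _fake_fit(("home_range",), -10.0),
        _fake_fit(("home_range", "migratory"), -11.0),
    ]
    rows = rank_and_weight(fits)
    assert importance(rows, "home_range") == pytest.approx(1.0)


# -------------------------------------------------------------- pseudo-R2


def _reml_pair(ds, terms):
    rem_spec = DesignSpec(())
    y, v, X, st, sp = build_design(ds["records"], ds["tframe"], rem_spec)
    rem = fit_meta_mixed(y, v, X, st, sp, ds["C"], method="REML",
                         spec=rem_spec)
    spec = DesignSpec(terms)
    y, v, X, st, sp = build_design(ds["records"], ds["tframe"], spec)
    mem = fit_meta_mixed(y, v, X, st, sp, ds["C"], method="REML", spec=spec)
    return mem, rem


def test_pseudo_r2_self_comparison_is_zero(small_dataset):
    _, rem = _reml_pair(small_dataset, ("home_range",))
    assert pseudo_r2(rem, rem) == (0.0, 0.0, 0.0)


def test_pseudo_r2_truncated_at_zero_and_bounded(small_dataset):
    mem, rem = _reml_pair(small_dataset, ("home_range",))
    rv2, rr2, rp2 = pseudo_r2(mem, rem)
    for val in (rv2, rr2, rp2):
        assert 0.0 <= val <= 1.0


def test_pseudo_r2_strong_fixed_effect_near_one():
    """A huge simulated fixed effect with null components gives Rv2 near 1."""
    from provmeta.synthetic_data import SimConfig, generate_dataset
    from provmeta.data_io import traits_to_frame
    from provmeta.effect_conversion import derive_effect_sizes

    cfg = SimConfig(
        n_species=20, seed=3,
        beta={"intercept": 0.0, "home_range_qrt": 0.8},
        sigma2_obs=1e-4, sigma2_study=1e-4, sigma2_species=1e-4,
        n_range=(150, 200),
    )
    tree, traits, records, _ = generate_dataset(cfg)
    records = derive_effect_sizes(records)
    tf = traits_to_frame(traits)
    tf["pace_pc1"] = 0.0
    from provmeta.phylo_tools import phylo_corr

    ds = {"records": records, "tframe": tf, "C": phylo_corr(tree)}
    mem, rem = _reml_pair(ds, ("home_range",))
    rv2, _, rp2 = pseudo_r2(mem, rem)
    assert rv2 > 0.8
    assert rp2 > 0.5


def test_pseudo_r2_requires_intercept_only_rem(small_dataset):
    mem, rem = _reml_pair(small_dataset, ("home_range",))
    with pytest.raises(ValueError, match="intercept-only"):
        pseudo_r2(mem, mem)


def test_selection_table_schema(small_dataset):
    ds = small_dataset
    specs = generate_candidates(
        CandidateSet(("home_range", "migratory"), max_covariates=2)
    )
    ml, reml = [], []
    rem = None
    for spec in specs:
        y, v, X, st, sp = build_design(ds["records"], ds["tframe"], spec)
        ml.append(fit_meta_mixed(y, v, X, st, sp, ds["C"], method="ML",
                                 spec=spec))
        f = fit_meta_mixed(y, v, X, st, sp, ds["C"], method="REML", spec=spec)
        reml.append(f)
        if spec.terms == ():
            rem = f
    table = selection_table(ml, reml, rem)
    assert table.loc[0, "delta_aicc"] == 0.0
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    for col in ("h2", "rv2", "rr2", "rp2"):
        assert ((table[col] >= 0) & (table[col] <= 1)).all()
    # full-parameter k counts fixed effects plus 3 variance components
    null_row = table[table["model"] == "Zr ~ 1"].iloc[0]
    assert null_row["k"] == 4 and null_row["k_fixed"] == 1
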