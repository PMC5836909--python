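"""Multilevel meta-analytic mixed model: design, estimation, inference."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from provmeta.meta_mixed import (
    DesignSpec,
    build_design,
    fit_meta_mixed,
    heritability,
    predict,
    qm_test,
    _gls_loglik,
    _structure_matrices,
)
from provmeta.phylo_tools import grafen_lengths, phylo_corr
from provmeta.synthetic_data import SimConfig, generate_dataset, simulate_tree
from provmeta.data_io import traits_to_frame
from provmeta.effect_conversion import derive_effect_sizes


# ---------------------------------------------------------------- design


def test_design_spec_marginality_and_unknown_terms():
    with pytest.raises(ValueError, match="main effect"):
        DesignSpec(("dietary_breadth:home_range",))
    with pytest.raises(ValueError, match="unknown term"):
        DesignSpec(("body_odour",))
    DesignSpec(("dietary_breadth", "home_range", "dietary_breadth:home_range"))


def test_intercept_only_design(small_dataset):
    y, v, X, st, sp = build_design(
        small_dataset["records"], small_dataset["tframe"], DesignSpec(())
    )
    assert list(X.columns) == ["intercept"]
    assert np.all(X.to_numpy() == 1.0)
    assert y.size == v.size == len(st) == len(sp)


def test_interaction_design_has_six_columns(small_dataset):
    """Dietary breadth (3 classes) x home range: 1 + 2 + 1 + 2 columns."""
    spec = DesignSpec(
        ("dietary_breadth", "home_range", "dietary_breadth:home_range")
    )
    _, _, X, _, _ = build_design(
        small_dataset["records"], small_dataset["tframe"], spec
    )
    assert X.shape[1] == 6
    assert list(X.columns)[0] == "intercept"


def test_design_shares_study_index(small_dataset):
    recs = small_dataset["records"]
    _, _, _, st, _ = build_design(recs, small_dataset["tframe"], DesignSpec(()))
    by_study = {}
    for rec, s in zip(recs, st):
        by_study.setdefault(rec.study_id, set()).add(s)
    assert all(len(v) == 1 for v in by_study.values())


def test_design_missing_trait_value_errors(small_dataset):
    tf = small_dataset["tframe"].copy()
    tf.loc[tf.index[0], "pace_pc1"] = np.nan
    recs = [
        r for r in small_dataset["records"] if r.host_species == tf.index[0]
    ]
    with pytest.raises(ValueError, match="pace_of_life"):
        build_design(recs, tf, DesignSpec(("pace_of_life",)))


# ------------------------------------------------------------ estimation


def _fit_inputs(ds, terms=("home_range",)):
    spec = DesignSpec(terms)
    y, v, X, st, sp = build_design(ds["records"], ds["tframe"], spec)
    return y, v, X, st, sp, ds["C"], spec


def test_zero_components_reduce_to_wls(small_dataset):
    """With all variance components pinned at 0, beta is 1/v-weighted WLS."""
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    fit = fit_meta_mixed(
        y, v, X, st, sp, C, method="REML", fixed_components=(0, 0, 0)
    )
    import statsmodels.api as sm

    wls = sm.WLS(y, X, weights=1 / v).fit()
    assert fit.beta.to_numpy() == pytest.approx(wls.params, abs=1e-8)
    fit_ml = fit_meta_mixed(
        y, v, X, st, sp, C, method="ML", fixed_components=(0, 0, 0)
    )
    assert fit_ml.beta.to_numpy() == pytest.approx(wls.params, abs=1e-8)


def test_reml_matches_variance_grid_oracle(small_dataset):
    """REML optimum beats a dense 3-component grid on a small instance."""
    recs = small_dataset["records"][:14]
    spec = DesignSpec(("home_range",))
    y, v, X, st, sp = build_design(recs, small_dataset["tframe"], spec)
    fit = fit_meta_mixed(y, v, X, st, sp, small_dataset["C"], method="REML")
    S, P, Isp = _structure_matrices(v, st, sp, small_dataset["C"])
    Xm = X.to_numpy(dtype=float)
    grid = np.concatenate([[0.0], np.geomspace(1e-6, 1.0, 12)])
    best = -np.inf
    for a in grid:
        for b in grid:
            for c in grid:
                ll, _, _ = _gls_loglik(
                    (a, b, c), y, v, Xm, S, P, Isp, "REML", False
                )
                best = max(best, ll)
    assert fit.loglik >= best - 1e-3


def test_loglik_invariant_to_record_order(small_dataset):
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    perm = np.random.default_rng(1).permutation(y.size)
    f1 = fit_meta_mixed(y, v, X, st, sp, C, method="REML")
    f2 = fit_meta_mixed(
        y[perm], v[perm], X.iloc[perm].reset_index(drop=True),
        st[perm], sp[perm], C, method="REML",
    )
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
    assert f1.beta.to_numpy() == pytest.approx(f2.beta.to_numpy(), abs=1e-4)


def test_unidentifiable_single_level_warns_and_matches_tau2():
    """One record per species/study, C = I: report warning; total
    heterogeneity equals the one-level REML tau2 oracle."""
    rng = np.random.default_rng(5)
    n = 20
    y = rng.normal(0.2, 0.25, size=n)
    v = np.full(n, 0.04)
    X = pd.DataFrame({"intercept": np.ones(n)})
    st = np.array([f"s{i}" for i in range(n)], dtype=object)
    sp = np.array([f"sp{i}" for i in range(n)], dtype=object)
    with pytest.warns(UserWarning, match="unidentifiable"):
        fit = fit_meta_mixed(y, v, X, st, sp, C=None, method="REML")
    total = fit.sigma2_obs + fit.sigma2_study + fit.sigma2_species

    # one-level REML oracle: grid + refine over a single tau2
    from scipy.optimize import minimize_scalar

    def nll(tau2):
        w = 1 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return -0.5 * (
            np.sum(np.log(1 / w)) + np.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    res = minimize_scalar(
        lambda t: -nll(t), bounds=(0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    assert total == pytest.approx(res.x, abs=1e-4)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_reml_matches_metafor_oracle(tmp_path, small_dataset):
    """Independent cross-check against metafor::rma.mv on a small fixture."""
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    fit = fit_meta_mixed(y, v, X, st, sp, C, method="REML")
    df = pd.DataFrame(
        {"yi": y, "vi": v, "hr": X["home_range"], "study": st,
         "species": sp, "obs": range(len(y))}
    )
    df.to_csv(tmp_path / "mm.csv", index=False)
    C.to_csv(tmp_path / "C.csv")
    r_code = f"""
    suppressMessages(library(metafor))
    d <- read.csv("{tmp_path}/mm.csv")
    C <- as.matrix(read.csv("{tmp_path}/C.csv", row.names=1))
    colnames(C) <- rownames(C)
    fit <- rma.mv(yi, vi, mods=~hr,
                  random=list(~1|obs, ~1|study, ~1|species),
                  R=list(species=C), Rscale=FALSE, data=d, method="REML",
                  control=list(optimizer="BFGS"))
    cat(c(as.numeric(fit$beta), fit$sigma2, as.numeric(logLik(fit))), sep=",")
    """
    out = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr[-500:]
    vals = [float(x) for x in out.stdout.strip().split(",")]
    b0, b1, s2o, s2s, s2p, ll_r = vals
    assert fit.beta.to_numpy() == pytest.approx([b0, b1], abs=2e-4)
    assert fit.sigma2_obs == pytest.approx(s2o, abs=2e-4)
    assert fit.sigma2_study == pytest.approx(s2s, abs=2e-4)
    assert fit.sigma2_species == pytest.approx(s2p, abs=2e-4)
    # metafor's REML loglik includes the +0.5 log|X'X| constant
    const = 0.5 * np.linalg.slogdet(X.to_numpy().T @ X.to_numpy())[1]
    assert fit.loglik + const == pytest.approx(ll_r, abs=1e-3)


# -------------------------------------------------------------- inference


def test_heritability_limits(small_dataset):
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    f0 = fit_meta_mixed(y, v, X, st, sp, C, fixed_components=(0.1, 0.1, 0.0))
    assert heritability(f0) == 0.0
    f1 = fit_meta_mixed(y, v, X, st, sp, C, fixed_components=(0.0, 0.0, 0.3))
    assert heritability(f1) == 1.0
    fz = fit_meta_mixed(y, v, X, st, sp, C, fixed_components=(0, 0, 0))
    assert heritability(fz) == 0.0  # 0/0 defined as 0


def test_qm_single_coefficient_is_z_squared(small_dataset):
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    fit = fit_meta_mixed(y, v, X, st, sp, C, method="REML")
    qm, df, p = qm_test(fit)
    assert df == 1
    z = fit.beta["home_range"] / fit.se()["home_range"]
    assert qm == pytest.approx(z**2, rel=1e-10)


def test_qm_df_five_for_breadth_by_home_range(small_dataset):
    spec = DesignSpec(
        ("dietary_breadth", "home_range", "dietary_breadth:home_range")
    )
    y, v, X, st, sp = build_design(
        small_dataset["records"], small_dataset["tframe"], spec
    )
    fit = fit_meta_mixed(y, v, X, st, sp, small_dataset["C"], method="REML")
    _, df, _ = qm_test(fit)
    assert df == 5


def test_qm_intercept_only_errors(small_dataset):
    y, v, X, st, sp = build_design(
        small_dataset["records"], small_dataset["tframe"], DesignSpec(())
    )
    fit = fit_meta_mixed(y, v, X, st, sp, small_dataset["C"], method="REML")
    with pytest.raises(ValueError, match="intercept-only"):
        qm_test(fit)


def test_predict_linearity_and_mismatch(small_dataset):
    y, v, X, st, sp, C, spec = _fit_inputs(small_dataset)
    fit = fit_meta_mixed(y, v, X, st, sp, C, method="REML")
    yhat = predict(fit, X)
    assert yhat.shape == y.shape
    # prediction at reference levels (hr = 0) equals the intercept
    X0 = pd.DataFrame({"intercept": [1.0], "home_range": [0.0]})
    assert predict(fit, X0)[0] == pytest.approx(fit.beta["intercept"])
    # linearity in the design
    Xa = X.copy()
    Xa["home_range"] *= 2
    lhs = predict(fit, Xa) - predict(fit, X)
    assert lhs == pytest.approx(X["home_range"] * fit.beta["home_range"])
    with pytest.raises(ValueError, match="match"):
        predict(fit, X[["home_range", "intercept"]])


def test_beta_recovery_on_generator_truth(medium_dataset):
    """The fitted home-range slope lands near the generator's truth."""
    ds = medium_dataset
    tf = traits_to_frame(ds["traits"])
    tf["pace_pc1"] = 0.0
    spec = DesignSpec(("home_range",))
    y, v, X, st, sp = build_design(ds["records"], tf, spec)
    fit = fit_meta_mixed(y, v, X, st, sp, ds["C"], method="REML")
    true_beta = ds["config"].beta["home_range_qrt"]
    se = fit.se()["home_range"]
    assert abs(fit.beta["home_range"] - true_beta) < 4 * se
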