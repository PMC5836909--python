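"""Multilevel meta-analytic mixed models with a phylogenetic species effect.

The model for record-level effect sizes is

    y ~ N(X beta, V),
    V = s2_obs I + s2_study Zs Zs' + s2_species Zp C Zp' + diag(v)

with known sampling variances v_i = 1/(n_i - 3), an observation-level
(residual-heterogeneity) component, a study component, and a species
component whose covariance follows the phylogenetic correlation matrix C.
Variance components are estimated by ML or REML with quasi-Newton
optimization on the log scale (multi-start); beta is the GLS solution at
the optimum.  Phylogenetic heritability H2 is the species share of the
summed variance components (the known sampling variances are excluded from
the denominator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "DesignSpec",
    "MetaModelFit",
    "build_design",
    "fit_meta_mixed",
    "heritability",
    "qm_test",
    "predict",
]

# Model terms over the trait table and record metadata.  Categorical terms
# use treatment contrasts; reference levels: dietary breadth low, trophic
# herbivore, provisioning unintentional, non-migratory.
_CATEGORICAL = {
    "dietary_breadth": ("dietary_breadth_class", ["medium", "high"], "low"),
    "trophic_level": ("trophic_level", ["omnivore", "carnivore"], "herbivore"),
}
_CONTINUOUS = {
    "home_range": "home_range_qrt",
    "pace_of_life": "pace_pc1",
}
KNOWN_TERMS = tuple(sorted(
    list(_CATEGORICAL) + list(_CONTINUOUS) + ["provisioning_type", "migratory"]
))


@dataclass(frozen=True)
class DesignSpec:
    """Ordered fixed-effect terms; interactions written 'a:b'.

    Every interaction's constituent main effects must be present.
    """

    terms: tuple[str, ...] = ()

    def __post_init__(self):
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                for part in t.split(":"):
                    if part not in mains:
                        raise ValueError(
                            f"interaction {t!r} lacks main effect {part!r}"
                        )
            elif t not in KNOWN_TERMS:
                raise ValueError(f"unknown term {t!r}; known: {KNOWN_TERMS}")

    @property
    def label(self) -> str:
        if not self.terms:
            return "Zr ~ 1"
        return "Zr ~ " + " + ".join(
            t.replace(":", " x ") for t in self.terms
        )

    @property
    def main_effects(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if ":" not in t)

    @property
    def interactions(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if ":" in t)


def _term_columns(term: str, rec, trait_row) -> dict[str, float]:
    """Design columns contributed by one main-effect term for one record."""
    if term in _CATEGORICAL:
        col, levels, _ref = _CATEGORICAL[term]
        val = getattr(trait_row, col)
        return {f"{term}[{lv}]": float(val == lv) for lv in levels}
    if term in _CONTINUOUS:
        val = getattr(trait_row, _CONTINUOUS[term])
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise ValueError(
                f"species {rec.host_species}: missing value for term {term!r}"
            )
        return {term: float(val)}
    if term == "provisioning_type":
        return {"provisioning_type[intentional]": float(
            rec.provisioning_type == "intentional"
        )}
    if term == "migratory":
        return {"migratory[True]": float(trait_row.migratory)}
    raise ValueError(f"unknown term {term!r}")


def build_design(records, traits, spec: DesignSpec):
    """Assemble (y, v, X, study_index, species_index) for a model fit.

    ``traits`` is a collection of SpeciesTraits (or a species-indexed frame
    of the same fields).  X carries an intercept column first; categorical
    terms enter as treatment-coded dummies, home range quarter-root
    transformed, pace of life as the phylogenetic PC1 score.
    """
    if hasattr(traits, "loc"):
        trait_map = {sp: traits.loc[sp] for sp in traits.index}
    else:
        trait_map = {t.species: t for t in traits}
    rows, y, v, study_idx, species_idx = [], [], [], [], []
    for rec in records:
        if rec.zr is None:
            raise ValueError(f"record {rec.record_id} has no derived zr")
        if rec.host_species not in trait_map:
            raise ValueError(
                f"record {rec.record_id}: no trait row for {rec.host_species}"
            )
        tr = trait_map[rec.host_species]
        cols = {"intercept": 1.0}
        main_cols: dict[str, dict[str, float]] = {}
        for term in spec.main_effects:
            main_cols[term] = _term_columns(term, rec, tr)
            cols.update(main_cols[term])
        for term in spec.interactions:
            a, b = term.split(":")
            for na, va in main_cols[a].items():
                for nb, vb in main_cols[b].items():
                    cols[f"{na}:{nb}"] = va * vb
        rows.append(cols)
        y.append(rec.zr)
        v.append(rec.sampling_variance)
        study_idx.append(rec.study_id)
        species_idx.append(rec.host_species)
    X = pd.DataFrame(rows)
    return (
        np.asarray(y, dtype=float),
        np.asarray(v, dtype=float),
        X,
        np.asarray(study_idx, dtype=object),
        np.asarray(species_idx, dtype=object),
    )


@dataclass
class MetaModelFit:
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_obs: float
    sigma2_study: float
    sigma2_species: float
    loglik: float
    method: str
    k_fixed: int
    n_obs: int
    sigma2_species_iid: float = 0.0
    converged: bool = True
    messages: list = field(default_factory=list)
    spec: DesignSpec | None = None
    # retained data for downstream prediction / pseudo-R2
    y: np.ndarray | None = None
    v: np.ndarray | None = None
    X: pd.DataFrame | None = None

    @property
    def variance_components(self) -> tuple[float, float, float]:
        return (self.sigma2_obs, self.sigma2_study, self.sigma2_species)

    @property
    def h2(self) -> float:
        return heritability(self)

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_beta.to_numpy())), index=self.beta.index
        )

    def summary_frame(self) -> pd.DataFrame:
        from .effect_conversion import zr_to_r

        se = self.se()
        z = self.beta / se
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "r": [zr_to_r(b) for b in self.beta],
            }
        )


def _structure_matrices(v, study_index, species_index, C):
    n = v.size
    codes, _ = pd.factorize(study_index)
    S = (codes[:, None] == codes[None, :]).astype(float)
    if C is None:
        P = (
            np.asarray(species_index)[:, None]
            == np.asarray(species_index)[None, :]
        ).astype(float)
        Isp = P
    else:
        pos = {sp: i for i, sp in enumerate(C.index)}
        missing = sorted({s for s in species_index if s not in pos})
        if missing:
            raise ValueError(f"species missing from C: {missing}")
        idx = np.array([pos[s] for s in species_index])
        P = C.to_numpy()[np.ix_(idx, idx)]
        Isp = (idx[:, None] == idx[None, :]).astype(float)
    return S, P, Isp


def _gls_loglik(s2, y, v, X, S, P, Isp, method, n_extra):
    """(loglik, beta, cov_beta) at fixed variance components."""
    n, p = X.shape
    V = np.diag(v + s2[0])
    V += s2[1] * S + s2[2] * P
    if n_extra:
        V += s2[3] * Isp
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, None, None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    try:
        cfx = linalg.cho_factor(XtViX, lower=True)
    except linalg.LinAlgError:
        return -np.inf, None, None
    beta = linalg.cho_solve(cfx, X.T @ Viy)
    cov = linalg.cho_solve(cfx, np.eye(p))
    r = y - X @ beta
    quad = r @ linalg.cho_solve(cf, r)
    if method == "ML":
        ll = -0.5 * (n * math.log(2 * math.pi) + logdetV + quad)
    else:
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi) + logdetV + logdetXtViX + quad
        )
    return ll, beta, cov


START_FACTORS = (1e-4, 1e-2, 1e-1)


def fit_meta_mixed(
    y,
    v,
    X,
    study_index,
    species_index,
    C: pd.DataFrame | None = None,
    method: str = "REML",
    fixed_components=None,
    extra_species_iid: bool = False,
    spec: DesignSpec | None = None,
) -> MetaModelFit:
    """Fit the multilevel meta-analytic mixed model.

    Parameters
    ----------
    y, v : record-level effect sizes and their known sampling variances.
    X : design frame, intercept column first.
    study_index, species_index : grouping labels per record.
    C : phylogenetic correlation matrix over species (None -> identity,
        i.e. a non-phylogenetic species effect).
    method : 'REML' (unbiased variance components) or 'ML' (for AICc).
    fixed_components : optionally pin (s2_obs, s2_study, s2_species) instead
        of optimizing — e.g. all zeros reduces beta to weighted least squares.
    extra_species_iid : add a fourth, non-phylogenetic species component.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    if isinstance(X, pd.DataFrame):
        colnames = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        colnames = [f"x{i}" for i in range(Xm.shape[1])]
    n, p = Xm.shape
    if not (y.size == v.size == n == len(study_index) == len(species_index)):
        raise ValueError("inconsistent dimensions")
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")

    S, P, Isp = _structure_matrices(v, study_index, species_index, C)
    n_comp = 4 if extra_species_iid else 3
    messages: list[str] = []

    n_studies = len(set(study_index))
    n_species = len(set(species_index))
    if (
        fixed_components is None
        and n_studies == n
        and n_species == n
        and np.allclose(P, np.eye(n))
    ):
        messages.append(
            "one record per species and study with an identity species "
            "correlation: the three variance components are jointly "
            "unidentifiable; only their sum (total heterogeneity tau2) is "
            "estimated"
        )
        warnings.warn(messages[-1], stacklevel=2)

    if fixed_components is not None:
        s2 = np.asarray(fixed_components, dtype=float)
        if s2.size == 3 and extra_species_iid:
            s2 = np.append(s2, 0.0)
        ll, beta, cov = _gls_loglik(s2, y, v, Xm, S, P, Isp, method, n_comp == 4)
        converged = True
    else:
        vt = max(float(np.var(y)), float(np.mean(v)), 1e-8)
        lb, ub = math.log(vt) - 30.0, math.log(vt) + 8.0

        def neg_ll(theta):
            ll, _, _ = _gls_loglik(
                np.exp(theta), y, v, Xm, S, P, Isp, method, n_comp == 4
            )
            return -ll if np.isfinite(ll) else 1e12

        best = None
        for f in START_FACTORS:
            x0 = np.full(n_comp, math.log(f * vt))
            res = optimize.minimize(
                neg_ll,
                x0,
                method="L-BFGS-B",
                bounds=[(lb, ub)] * n_comp,
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(
                "non-finite likelihood at all starts; check v and C for "
                "degeneracies"
            )
        converged = bool(best.success)
        if not converged:
            messages.append(f"optimizer message: {best.message}")
        s2 = np.exp(best.x)
        # snap numerically-zero components (at the lower bound) to 0
        s2[s2 < 1e-12] = 0.0
        ll, beta, cov = _gls_loglik(s2, y, v, Xm, S, P, Isp, method, n_comp == 4)

    if beta is None:
        raise RuntimeError("GLS solve failed at the reported optimum")

    return MetaModelFit(
        beta=pd.Series(beta, index=colnames),
        cov_beta=pd.DataFrame(cov, index=colnames, columns=colnames),
        sigma2_obs=float(s2[0]),
        sigma2_study=float(s2[1]),
        sigma2_species=float(s2[2]),
        sigma2_species_iid=float(s2[3]) if n_comp == 4 else 0.0,
        loglik=float(ll),
        method=method,
        k_fixed=p,
        n_obs=n,
        converged=converged,
        messages=messages,
        spec=spec,
        y=y,
        v=v,
        X=pd.DataFrame(Xm, columns=colnames),
    )


def heritability(fit: MetaModelFit) -> float:
    """Phylogenetic heritability H2 = s2_species / sum of components.

    The known sampling variances are excluded from the denominator.  When
    every component is zero the ratio 0/0 is defined as 0.
    """
    total = (
        fit.sigma2_obs
        + fit.sigma2_study
        + fit.sigma2_species
        + fit.sigma2_species_iid
    )
    if total <= 0:
        return 0.0
    return fit.sigma2_species / total


def qm_test(fit: MetaModelFit) -> tuple[float, int, float]:
    """Omnibus Wald chi-square (QM) on all non-intercept coefficients."""
    mask = [c != "intercept" for c in fit.beta.index]
    df = int(sum(mask))
    if df == 0:
        raise ValueError("intercept-only model: nothing to test")
    b = fit.beta.to_numpy()[mask]
    cov = fit.cov_beta.to_numpy()[np.ix_(mask, mask)]
    qm = float(b @ linalg.solve(cov, b, assume_a="pos"))
    return qm, df, float(stats.chi2.sf(qm, df=df))


def predict(fit: MetaModelFit, X_new) -> np.ndarray:
    """Fixed-effects prediction X_new beta (no random-effect BLUPs)."""
    if isinstance(X_new, pd.DataFrame):
        if list(X_new.columns) != list(fit.beta.index):
            raise ValueError(
                f"design columns {list(X_new.columns)} do not match fitted "
                f"coefficients {list(fit.beta.index)}"
            )
        Xm = X_new.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.shape[1] != fit.k_fixed:
            raise ValueError("column-count mismatch with fitted model")
    return Xm @ fit.beta.to_numpy()
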