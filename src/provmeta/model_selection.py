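"""Candidate-model generation, AICc ranking, importance and pseudo-R2.

Candidate mixed-effects meta-regressions (MEMs) are all additive
combinations of allowed main effects (at most ``max_covariates`` distinct
predictors per model, collinear pairs excluded) plus any allowed two-way
interactions whose main effects are present; the intercept-only model is
always included.  ML fits feed AICc, Akaike weights and per-predictor
importance; REML refits of the same formulas feed residual H2 and the
three pseudo-R2 statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meta_mixed import DesignSpec, MetaModelFit, heritability, predict

__all__ = [
    "CandidateSet",
    "generate_candidates",
    "aicc",
    "rank_and_weight",
    "importance",
    "pseudo_r2",
    "selection_table",
]

#: variance components counted in the default AICc parameter count
N_VARIANCE_PARAMS = 3


@dataclass(frozen=True)
class CandidateSet:
    """Constraints defining the candidate-model space."""

    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    exclusions: tuple[frozenset, ...] = ()
    max_covariates: int = 3

    def __post_init__(self):
        mains = set(self.main_effects)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction ({a}, {b}) references an unknown main effect"
                )
        object.__setattr__(
            self, "exclusions", tuple(frozenset(e) for e in self.exclusions)
        )


def generate_candidates(cs: CandidateSet) -> list[DesignSpec]:
    """Enumerate the candidate set (deterministic order, intercept-only first).

    An interaction consumes no extra covariate slot beyond its two main
    effects, matching a cap counted in distinct predictors.
    """
    specs = []
    mains = list(cs.main_effects)
    for k in range(0, cs.max_covariates + 1):
        for subset in combinations(mains, k):
            sset = set(subset)
            if any(excl <= sset for excl in cs.exclusions):
                continue
            inters = [
                (a, b) for (a, b) in cs.interactions if a in sset and b in sset
            ]
            for j in range(0, len(inters) + 1):
                for isub in combinations(inters, j):
                    terms = tuple(subset) + tuple(f"{a}:{b}" for a, b in isub)
                    specs.append(DesignSpec(terms=terms))
    # dedupe preserving order
    seen, out = set(), []
    for s in specs:
        key = frozenset(s.terms)
        if key not in seen:
            seen.add(key)
            out.append(s)
    out.sort(key=lambda s: (len(s.terms), s.label))
    return out


def aicc(loglik_ml: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1 and an ML
    (not REML) log-likelihood.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik_ml + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _model_k(fit: MetaModelFit, k_mode: str) -> int:
    if k_mode == "fixed":
        return fit.k_fixed
    if k_mode == "full":
        return fit.k_fixed + N_VARIANCE_PARAMS
    raise ValueError("k_mode must be 'full' or 'fixed'")


def rank_and_weight(fits: list[MetaModelFit], k_mode: str = "full") -> pd.DataFrame:
    """Delta-AICc ranking and Akaike weights for ML fits of all candidates.

    Returns one row per model sorted by delta, with the competitive flag at
    delta <= 2.  All fits must share the same data (n)."""
    if not fits:
        raise ValueError("no fits supplied")
    ns = {f.n_obs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different data (n = {sorted(ns)})")
    for f in fits:
        if f.method != "ML":
            raise ValueError("AICc ranking requires ML fits")
    n = ns.pop()
    rows = []
    for f in fits:
        k = _model_k(f, k_mode)
        rows.append(
            {
                "model": f.spec.label if f.spec else "?",
                "terms": f.spec.terms if f.spec else (),
                "k": k,
                "k_fixed": f.k_fixed,
                "loglik": f.loglik,
                "aicc": aicc(f.loglik, k, n),
            }
        )
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-0.5 * df["delta_aicc"])
    df["weight"] = rel / rel.sum()
    df["competitive"] = df["delta_aicc"] <= 2.0
    return df.sort_values(
        ["delta_aicc", "model"], kind="mergesort"
    ).reset_index(drop=True)


def importance(rows: pd.DataFrame, predictor: str) -> float:
    """Summed Akaike weights of models containing ``predictor``.

    A main effect counts wherever it appears, including inside an
    interaction; an interaction term counts for itself only.
    """
    known = set()
    for terms in rows["terms"]:
        for t in terms:
            known.add(t)
            known.update(t.split(":"))
    if predictor not in known:
        raise ValueError(f"unknown term {predictor!r}")

    def contains(terms):
        for t in terms:
            if t == predictor:
                return True
            if ":" not in predictor and predictor in t.split(":"):
                return True
        return False

    return float(rows.loc[[contains(t) for t in rows["terms"]], "weight"].sum())


def importance_table(rows: pd.DataFrame) -> pd.Series:
    """Importance for every term appearing anywhere in the candidate set."""
    terms = set()
    for t in rows["terms"]:
        terms.update(t)
        terms.update(p for x in t for p in x.split(":"))
    return pd.Series(
        {t: importance(rows, t) for t in sorted(terms)}, name="importance"
    )


def pseudo_r2(
    mem: MetaModelFit, rem: MetaModelFit
) -> tuple[float, float, float]:
    """The three pseudo-R2 statistics of a REML MEM against the REM.

    Rv2: proportional reduction in the summed variance components; Rr2:
    proportional reduction in the residual (observation-level) component;
    Rp2: adjusted R2 of a weighted (1/v) linear regression of observed on
    predicted effect sizes.  All truncated below at 0.
    """
    if rem.k_fixed != 1:
        raise ValueError("rem must be the intercept-only model")
    if mem.n_obs != rem.n_obs:
        raise ValueError("mem and rem must share the same data")
    tot_mem = sum(mem.variance_components) + mem.sigma2_species_iid
    tot_rem = sum(rem.variance_components) + rem.sigma2_species_iid
    rv2 = max(0.0, 1.0 - tot_mem / tot_rem) if tot_rem > 0 else 0.0
    rr2 = (
        max(0.0, 1.0 - mem.sigma2_obs / rem.sigma2_obs)
        if rem.sigma2_obs > 0
        else 0.0
    )
    if mem.k_fixed == 1:
        rp2 = 0.0
    else:
        yhat = predict(mem, mem.X)
        if np.ptp(yhat) == 0:
            rp2 = 0.0
        else:
            wls = sm.WLS(
                mem.y, sm.add_constant(yhat), weights=1.0 / mem.v
            ).fit()
            rp2 = max(0.0, float(wls.rsquared_adj))
    return rv2, rr2, rp2


def selection_table(
    ml_fits: list[MetaModelFit],
    reml_fits: list[MetaModelFit],
    rem_reml: MetaModelFit,
    k_mode: str = "full",
) -> pd.DataFrame:
    """Full ranking table: delta-AICc, weights, residual H2, k, pseudo-R2.

    ``ml_fits`` and ``reml_fits`` are same-ordered fits of the same
    candidate formulas; ``rem_reml`` is the intercept-only REML fit.
    """
    if len(ml_fits) != len(reml_fits):
        raise ValueError("ml_fits and reml_fits must pair up")
    rows = rank_and_weight(ml_fits, k_mode=k_mode)
    by_terms = {frozenset(f.spec.terms): f for f in reml_fits}
    h2s, rv, rr, rp = [], [], [], []
    for terms in rows["terms"]:
        f = by_terms[frozenset(terms)]
        h2s.append(heritability(f))
        a, b, c = pseudo_r2(f, rem_reml)
        rv.append(a)
        rr.append(b)
        rp.append(c)
    rows["h2"] = h2s
    rows["rv2"] = rv
    rows["rr2"] = rr
    rows["rp2"] = rp
    return rows
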