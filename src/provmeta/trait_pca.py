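"""Phylogenetic PCA of the five pace-of-life variables.

Closely related species share similar life histories, so an ordinary PCA
of trait values would conflate phylogeny with the slow-fast continuum.
The phylogenetic PCA centres traits at their GLS ancestral means and
eigendecomposes the evolutionary covariance matrix

    R = (X - 1 a')' C^-1 (X - 1 a') / (n - 1),
    a = (1' C^-1 1)^-1 1' C^-1 X,

with C the species correlation matrix under Brownian motion (lambda fixed
at 1).  Loadings are reported as trait-score correlations.  PC1 is
oriented so that fast-lived species (small, fecund, short-lived) score
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

PACE_TRAITS = (
    "body_mass",
    "body_size",
    "offspring_per_year",
    "max_lifespan",
    "age_sexual_maturity",
)

#: column -> (transform, transformed name); mass, maturity, life span and
#: fecundity are log-transformed, body size square-rooted.
_TRANSFORMS = {
    "body_mass": (np.log, "log_body_mass"),
    "body_size": (np.sqrt, "sqrt_body_size"),
    "offspring_per_year": (np.log, "log_offspring_per_year"),
    "max_lifespan": (np.log, "log_max_lifespan"),
    "age_sexual_maturity": (np.log, "log_age_sexual_maturity"),
}

#: PC1 sign rule: flip so log body mass loads negatively (heavy = slow =
#: negative score), making positive PC1 the fast end of the continuum.
ORIENT_COLUMN = "log_body_mass"


@dataclass
class PhyloPCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame      # trait x component, trait-score correlations
    scores: pd.DataFrame        # species x component
    variance_explained: np.ndarray
    ancestral_means: pd.Series


def pace_transforms(traits) -> pd.DataFrame:
    """Normalizing transforms of the raw pace-of-life columns.

    ``traits`` may be a species-indexed DataFrame or a collection of
    SpeciesTraits.  All values must be strictly positive.
    """
    if not hasattr(traits, "loc"):
        from .data_io import traits_to_frame

        traits = traits_to_frame(traits)
    out = {}
    for col, (fn, name) in _TRANSFORMS.items():
        vals = traits[col].astype(float)
        bad = vals.index[~(vals > 0)].tolist()
        if bad:
            raise ValueError(f"non-positive {col} for species: {bad}")
        out[name] = fn(vals)
    return pd.DataFrame(out, index=traits.index)


def phylo_pca(
    X: pd.DataFrame, C: pd.DataFrame, mode: str = "covariance"
) -> PhyloPCAResult:
    """Phylogenetic PCA of a species x trait matrix.

    ``mode='covariance'`` (default) decomposes R as-is; ``'correlation'``
    standardizes traits by their evolutionary standard deviations first.
    With C = I (a star phylogeny) the result reduces to ordinary PCA of
    the centred data.
    """
    if X.isna().any().any():
        raise ValueError("X contains missing cells")
    missing = [s for s in X.index if s not in C.index]
    if missing:
        raise ValueError(f"species missing from C: {missing}")
    C = C.loc[X.index, X.index]
    n, m = X.shape
    if n < m:
        import warnings

        warnings.warn(
            f"fewer species ({n}) than traits ({m}): R is rank deficient",
            stacklevel=2,
        )
    Xm = X.to_numpy(dtype=float)
    try:
        cf = linalg.cho_factor(C.to_numpy(), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic correlation matrix") from exc
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    a = (Xm.T @ Ci1) / (ones @ Ci1)
    Xc = Xm - a
    R = Xc.T @ linalg.cho_solve(cf, Xc) / (n - 1)
    if mode == "correlation":
        sd = np.sqrt(np.diag(R))
        if np.any(sd == 0):
            raise ValueError("zero-variance trait column in correlation mode")
        Xc = Xc / sd
        R = R / np.outer(sd, sd)
    elif mode != "covariance":
        raise ValueError("mode must be 'covariance' or 'correlation'")

    evals, evecs = linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = Xc @ evecs

    pcs = [f"PC{i + 1}" for i in range(m)]
    # loadings as ordinary trait-score correlations
    load = np.zeros((m, m))
    for j in range(m):
        sj = scores[:, j]
        if np.std(sj) == 0:
            continue
        for i in range(m):
            if np.std(Xc[:, i]) == 0:
                continue
            load[i, j] = np.corrcoef(Xc[:, i], sj)[0, 1]

    # orient PC1: the heaviest-loading slow trait must load negatively
    if ORIENT_COLUMN in X.columns:
        i0 = list(X.columns).index(ORIENT_COLUMN)
        if load[i0, 0] > 0:
            evecs[:, 0] *= -1
            scores[:, 0] *= -1
            load[:, 0] *= -1

    total = evals.sum()
    return PhyloPCAResult(
        eigenvalues=evals,
        loadings=pd.DataFrame(load, index=X.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=X.index, columns=pcs),
        variance_explained=evals / total if total > 0 else np.zeros(m),
        ancestral_means=pd.Series(a, index=X.columns),
    )


def attach_pc1(traits, result: PhyloPCAResult):
    """Populate pace_pc1 on the trait collection from the PCA scores."""
    if hasattr(traits, "loc"):
        missing = [s for s in traits.index if s not in result.scores.index]
        if missing:
            raise ValueError(f"species missing from PCA scores: {missing}")
        out = traits.copy()
        out["pace_pc1"] = result.scores.loc[out.index, "PC1"]
        return out
    scores = result.scores["PC1"]
    for t in traits:
        if t.species not in scores.index:
            raise ValueError(f"species missing from PCA scores: {t.species}")
        t.pace_pc1 = float(scores.loc[t.species])
    return traits
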