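"""Synthetic stand-ins for the compiled host-parasite effect-size dataset.

The generator emulates the structure of the study inputs: a pure-birth
host phylogeny; Brownian-motion life-history traits (so the slow-fast pace
axis is phylogenetically structured); and record-level Fisher's Zr effect
sizes built from known fixed effects plus observation-, study- and
(phylogenetically correlated) species-level random effects, with sampling
noise at the Fisher-Z approximation sd = sqrt(1/(n-3)).  A sidecar records
every latent draw so recovery tests can compare estimates against truth.
Defaults give ~40 species and ~200 records across the three parasite
groups, with variance components (0.02, 0.02, 0.04) and lambda = 1
(phylogenetic heritability 0.5, in the moderate range the multilevel
models are designed to detect).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import effect_conversion as ec
from .data_io import (
    EffectRecord,
    SpeciesTraits,
    PARASITE_GROUPS,
    write_effect_table,
    write_trait_table,
)
from .phylo_tools import phylo_corr, lambda_transform, write_tree

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_effects",
    "backfill_statistics",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class SimConfig:
    n_species: int = 40
    studies_per_species: tuple[int, int] = (1, 3)   # inclusive range
    records_per_study: tuple[int, int] = (1, 4)
    n_range: tuple[int, int] = (10, 200)
    beta: dict = field(
        default_factory=lambda: {"intercept": 0.0, "home_range_qrt": 0.15}
    )
    sigma2_obs: float = 0.02
    sigma2_study: float = 0.02
    sigma2_species: float = 0.04
    lambda_true: float = 1.0
    group_probs: dict = field(
        default_factory=lambda: {
            "microparasite": 0.42,
            "helminth": 0.40,
            "ectoparasite": 0.18,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_range[0] < 4:
            raise ValueError("minimum per-record n must be >= 4")
        for name in ("sigma2_obs", "sigma2_study", "sigma2_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lambda_true <= 1:
            raise ValueError("lambda_true must lie in [0, 1]")


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth ultrametric tree scaled to unit depth, tips sp_001..."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.is_rooted = True
    # the process stops at the n-th speciation, leaving zero-length sister
    # tips; run the clock one extra waiting time so tips are distinct
    extra = rng.expovariate(1.0 * n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # scale to unit depth and zero any numerical drift in tip depths
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (
            0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
        )
    max_d = max(depths[leaf] for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.edge.length or 0.0) / max_d
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        leaf.edge.length += 1.0 - d
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ):
        leaf.taxon.label = f"sp_{i + 1:03d}"
    return tree


def _brownian(rng, L: np.ndarray, rate: float) -> np.ndarray:
    return np.sqrt(rate) * (L @ rng.standard_normal(L.shape[0]))


def simulate_traits(tree: dendropy.Tree, config: SimConfig) -> list[SpeciesTraits]:
    """Phylogenetically structured trait table.

    Continuous pace-of-life traits are driven by a shared Brownian "pace"
    axis plus independent Brownian noise, then back-transformed to positive
    raw values; dietary breadth, trophic level and migratory status are
    seeded categorical draws; home range is log-normal (phylogenetic on the
    log scale).
    """
    rng = np.random.default_rng((config.seed, 1))
    C = phylo_corr(tree)
    species = list(C.index)
    L = np.linalg.cholesky(C.to_numpy() + 1e-10 * np.eye(len(species)))

    pace = _brownian(rng, L, 1.0)
    noise = {k: _brownian(rng, L, 0.15) for k in "abcde"}
    log_mass = 8.0 - 1.5 * pace + noise["a"]
    sqrt_size = np.clip(20.0 - 3.0 * pace + 2.0 * noise["b"], 0.5, None)
    log_life = 2.0 - 0.5 * pace + 0.3 * noise["c"]
    log_mat = 5.0 - 1.2 * pace + noise["d"]
    log_off = 0.5 + 0.4 * pace + 0.3 * noise["e"]
    log_hr = 1.5 * _brownian(rng, L, 1.0)

    breadth = rng.choice(
        np.arange(1, 7), size=len(species), p=[0.05, 0.1, 0.25, 0.3, 0.2, 0.1]
    )
    trophic = rng.choice(
        ["herbivore", "omnivore", "carnivore"], size=len(species),
        p=[0.15, 0.65, 0.20],
    )
    migratory = rng.random(len(species)) < 0.25

    traits = []
    for i, sp in enumerate(species):
        traits.append(
            SpeciesTraits(
                species=sp,
                dietary_breadth_count=int(breadth[i]),
                trophic_level=str(trophic[i]),
                body_mass=float(np.exp(log_mass[i])),
                body_size=float(sqrt_size[i] ** 2),
                offspring_per_year=float(np.exp(log_off[i])),
                max_lifespan=float(np.exp(log_life[i])),
                age_sexual_maturity=float(np.exp(log_mat[i])),
                home_range=float(np.exp(log_hr[i])),
                migratory=bool(migratory[i]),
            )
        )
    return traits


def _predictor_value(key: str, trait: SpeciesTraits) -> float:
    if key == "intercept":
        return 1.0
    if hasattr(trait, key):
        return float(getattr(trait, key))
    raise ValueError(f"beta key {key!r} is not a trait column")


def simulate_effects(
    tree: dendropy.Tree, traits, config: SimConfig
) -> tuple[list[EffectRecord], dict]:
    """Record-level effect sizes with known truth sidecar.

    true zr = x' beta + u_species + u_study + u_obs; observed zr adds
    N(0, 1/(n-3)) sampling noise.  Species effects are multivariate normal
    with covariance sigma2_species * C(lambda_true).
    """
    rng = np.random.default_rng((config.seed, 2))
    C = phylo_corr(tree)
    species = list(C.index)
    trait_map = {t.species: t for t in traits}

    Cl = lambda_transform(C, config.lambda_true).to_numpy()
    L = np.linalg.cholesky(Cl + 1e-10 * np.eye(len(species)))
    u_species = np.sqrt(config.sigma2_species) * (
        L @ rng.standard_normal(len(species))
    )

    groups = list(PARASITE_GROUPS)
    gp = np.array([config.group_probs[g] for g in groups], dtype=float)
    gp = gp / gp.sum()

    records, sidecar_records = [], []
    u_study_all = {}
    rec_i = 0
    for si, sp in enumerate(species):
        n_studies = int(
            rng.integers(
                config.studies_per_species[0], config.studies_per_species[1] + 1
            )
        )
        for j in range(n_studies):
            study_id = f"study_{si:03d}_{j}"
            u_study = float(
                rng.normal(0.0, np.sqrt(config.sigma2_study))
            )
            u_study_all[study_id] = u_study
            n_records = int(
                rng.integers(
                    config.records_per_study[0], config.records_per_study[1] + 1
                )
            )
            for _ in range(n_records):
                rec_i += 1
                trait = trait_map[sp]
                xb = sum(
                    coef * _predictor_value(key, trait)
                    for key, coef in config.beta.items()
                )
                u_obs = float(rng.normal(0.0, np.sqrt(config.sigma2_obs)))
                n_total = int(
                    rng.integers(config.n_range[0], config.n_range[1] + 1)
                )
                true_zr = xb + u_species[si] + u_study + u_obs
                obs_zr = true_zr + float(
                    rng.normal(0.0, np.sqrt(1.0 / (n_total - 3)))
                )
                group = str(rng.choice(groups, p=gp))
                rec = EffectRecord(
                    record_id=f"rec_{rec_i:04d}",
                    study_id=study_id,
                    host_species=sp,
                    parasite_group=group,
                    provisioning_type=str(
                        rng.choice(["intentional", "unintentional"])
                    ),
                    outcome_measure=str(
                        rng.choice(
                            ["binary_status", "prevalence", "intensity",
                             "seroprevalence"],
                            p=[0.4, 0.34, 0.16, 0.1],
                        )
                    ),
                    stat_kind="r",
                    stat_payload={"value": abs(np.tanh(obs_zr))},
                    n_total=n_total,
                    direction="increase" if obs_zr >= 0 else "decrease",
                    zr=float(obs_zr),
                    sampling_variance=1.0 / (n_total - 3),
                )
                records.append(rec)
                sidecar_records.append(
                    {
                        "record_id": rec.record_id,
                        "true_zr": float(true_zr),
                        "u_obs": u_obs,
                        "xb": float(xb),
                    }
                )
    sidecar = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "u_species": {sp: float(u_species[i]) for i, sp in enumerate(species)},
        "u_study": u_study_all,
        "records": sidecar_records,
    }
    return records, sidecar


_BACKFILL_KINDS = ("r", "chi2", "F", "odds_ratio", "cohens_d", "contingency")


def backfill_statistics(records, seed: int):
    """Replace each record's payload by an equivalent published statistic.

    The assigned format round-trips to the same zr through the conversion
    routines (contingency tables use real-valued balanced-margin counts so
    the phi coefficient equals |r| exactly).  Records with |r| extremely
    close to 1 keep the 'r' format to avoid numerical blow-up in F/OR.
    """
    rng = np.random.default_rng((seed, 3))
    for rec in records:
        if rec.zr is None:
            raise ValueError(f"record {rec.record_id} has no zr to backfill")
        r = abs(np.tanh(rec.zr))
        kind = str(rng.choice(_BACKFILL_KINDS))
        n = rec.n_total
        if r > 0.995 and kind in ("F", "odds_ratio", "cohens_d"):
            kind = "r"
        if kind == "r":
            payload = {"value": r}
        elif kind == "chi2":
            payload = {"value": r * r * n}
        elif kind == "F":
            df_error = n - 2
            payload = {
                "value": r * r * df_error / (1.0 - r * r),
                "df_error": float(df_error),
            }
        elif kind == "odds_ratio":
            ratio = ((1.0 + r) / (1.0 - r)) ** (4.0 / 3.0)
            payload = {
                "value": ratio if rec.direction == "increase" else 1.0 / ratio
            }
        elif kind == "cohens_d":
            n1 = n // 2
            n2 = n - n1
            a = (n1 + n2) ** 2 / (n1 * n2)
            payload = {
                "value": r * np.sqrt(a) / np.sqrt(1.0 - r * r),
                "n1": n1,
                "n2": n2,
            }
        else:  # contingency with balanced margins: phi == r
            payload = {
                "a": n * (1.0 + r) / 4.0,
                "b": n * (1.0 - r) / 4.0,
                "c": n * (1.0 - r) / 4.0,
                "d": n * (1.0 + r) / 4.0,
            }
            if min(payload.values()) <= 0:
                kind, payload = "r", {"value": r}
        rec.stat_kind = kind
        rec.stat_payload = payload
    return records


def generate_dataset(config: SimConfig):
    """Tree, traits, records (+ sidecar) for one seeded configuration."""
    tree = simulate_tree(config.n_species, config.seed)
    traits = simulate_traits(tree, config)
    records, sidecar = simulate_effects(tree, traits, config)
    backfill_statistics(records, config.seed)
    return tree, traits, records, sidecar


def write_dataset(outdir, tree, traits, records, sidecar) -> dict:
    """Write the CSV + Newick + JSON files data_io reads back."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "effects": outdir / "effects.csv",
        "traits": outdir / "traits.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    # strip derived fields: the written table carries only reported stats
    frame_records = []
    for rec in records:
        import copy

        r2 = copy.copy(rec)
        r2.zr = None
        r2.sampling_variance = None
        r2.conversion_note = None
        frame_records.append(r2)
    write_effect_table(frame_records, paths["effects"])
    write_trait_table(traits, paths["traits"])
    write_tree(tree, paths["tree"])
    paths["truth"].write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
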