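"""Domain types, delimited-text readers/writers and dataset validation.

The effect table holds one row per host-parasite interaction (nested in
studies); the trait table one row per host species.  Species names are
canonicalized (spaces -> underscores) before any matching against tree tip
labels, and an optional user-supplied alias map collapses synonyms (e.g.
standardizing a species complex to one representative) at read time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PARASITE_GROUPS = ("microparasite", "helminth", "ectoparasite")
PROVISIONING_TYPES = ("intentional", "unintentional")
OUTCOME_MEASURES = ("binary_status", "prevalence", "intensity", "seroprevalence")
STAT_KINDS = ("r", "chi2", "F", "odds_ratio", "cohens_d", "contingency")
DIRECTIONS = ("increase", "decrease")
TROPHIC_LEVELS = ("herbivore", "omnivore", "carnivore")

EFFECT_COLUMNS = (
    "record_id",
    "study_id",
    "host_species",
    "parasite_group",
    "provisioning_type",
    "outcome_measure",
    "stat_kind",
    "stat_value",
    "n_total",
    "direction",
)

TRAIT_COLUMNS = (
    "species",
    "dietary_breadth_count",
    "trophic_level",
    "body_mass",
    "body_size",
    "offspring_per_year",
    "max_lifespan",
    "age_sexual_maturity",
    "home_range",
    "migratory",
)


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


def normalize_species(name: str) -> str:
    """Canonical species label: strip, collapse spaces to underscores."""
    return "_".join(str(name).strip().split())


@dataclass
class EffectRecord:
    """One host-parasite-study observation."""

    record_id: str
    study_id: str
    host_species: str
    parasite_group: str
    provisioning_type: str
    outcome_measure: str
    stat_kind: str
    stat_payload: dict
    n_total: int
    direction: str
    zr: float | None = None
    sampling_variance: float | None = None
    transmission_route: str | None = None
    conversion_note: str | None = None


@dataclass
class SpeciesTraits:
    """Per-species covariates, with derived fields populated at read time.

    ``dietary_breadth_class`` follows the low (1-2) / medium (3-4) /
    high (5-6) rule; counts of 7-8 (the upper end of the PanTHERIA food
    categories) are also mapped to high.  ``home_range_qrt`` is the
    quarter-root transformed home range.
    """

    species: str
    dietary_breadth_count: int
    trophic_level: str
    body_mass: float
    body_size: float
    offspring_per_year: float
    max_lifespan: float
    age_sexual_maturity: float
    home_range: float
    migratory: bool
    dietary_breadth_class: str = field(default="", init=False)
    home_range_qrt: float = field(default=np.nan, init=False)
    pace_pc1: float | None = None

    def __post_init__(self):
        self.dietary_breadth_class = dietary_breadth_class(
            self.dietary_breadth_count
        )
        self.home_range_qrt = float(self.home_range) ** 0.25


def dietary_breadth_class(count: int) -> str:
    count = int(count)
    if not 1 <= count <= 8:
        raise SchemaError(f"dietary_breadth_count {count} outside 1-8")
    if count <= 2:
        return "low"
    if count <= 4:
        return "medium"
    return "high"


def _check_enum(value, allowed, column, record_id):
    if value not in allowed:
        raise SchemaError(
            f"record {record_id}: {column}={value!r} not one of {sorted(allowed)}"
        )
    return value


def _payload_from_row(row, record_id) -> dict:
    kind = row["stat_kind"]
    try:
        if kind == "contingency":
            return {k: float(row[f"count_{k}"]) for k in "abcd"}
        payload = {"value": float(row["stat_value"])}
        if kind == "F":
            payload["df_error"] = float(row["df_error"])
        if kind == "cohens_d":
            n1, n2 = row.get("n1"), row.get("n2")
            if pd.notna(n1) and pd.notna(n2):
                payload["n1"] = int(n1)
                payload["n2"] = int(n2)
        return payload
    except (TypeError, ValueError, KeyError) as exc:
        raise SchemaError(
            f"record {record_id}: non-numeric or missing statistic ({exc})"
        ) from exc


def read_effect_table(
    path,
    column_map: dict[str, str] | None = None,
    species_aliases: dict[str, str] | None = None,
    sep: str = ",",
) -> list[EffectRecord]:
    """Read an effect-size table into EffectRecords (derived fields unset).

    ``column_map`` maps the file's column names onto the canonical schema
    (the deposited data's exact headers vary); ``species_aliases`` maps
    synonyms onto a canonical binomial before normalization.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    # contingency rows carry counts instead of stat_value
    if "stat_value" in missing and all(
        f"count_{k}" in df.columns for k in "abcd"
    ):
        missing.remove("stat_value")
    if missing:
        raise SchemaError(f"effect table missing required columns: {missing}")
    aliases = {
        normalize_species(k): normalize_species(v)
        for k, v in (species_aliases or {}).items()
    }
    records = []
    for _, row in df.iterrows():
        rid = str(row["record_id"])
        sp = normalize_species(row["host_species"])
        sp = aliases.get(sp, sp)
        n_total = int(row["n_total"])
        if n_total < 4:
            warnings.warn(
                f"record {rid}: n_total={n_total} < 4; sampling variance "
                "1/(n-3) will be undefined",
                stacklevel=2,
            )
        records.append(
            EffectRecord(
                record_id=rid,
                study_id=str(row["study_id"]),
                host_species=sp,
                parasite_group=_check_enum(
                    row["parasite_group"], PARASITE_GROUPS, "parasite_group", rid
                ),
                provisioning_type=_check_enum(
                    row["provisioning_type"],
                    PROVISIONING_TYPES,
                    "provisioning_type",
                    rid,
                ),
                outcome_measure=_check_enum(
                    row["outcome_measure"], OUTCOME_MEASURES, "outcome_measure", rid
                ),
                stat_kind=_check_enum(
                    row["stat_kind"], STAT_KINDS, "stat_kind", rid
                ),
                stat_payload=_payload_from_row(row, rid),
                n_total=n_total,
                direction=_check_enum(
                    row["direction"], DIRECTIONS, "direction", rid
                ),
                transmission_route=(
                    str(row["transmission_route"])
                    if "transmission_route" in df.columns
                    and pd.notna(row["transmission_route"])
                    else None
                ),
            )
        )
    return records


def effects_to_frame(records) -> pd.DataFrame:
    """Flatten EffectRecords (including derived zr/variance) to a DataFrame."""
    rows = []
    for rec in records:
        row = {
            "record_id": rec.record_id,
            "study_id": rec.study_id,
            "host_species": rec.host_species,
            "parasite_group": rec.parasite_group,
            "provisioning_type": rec.provisioning_type,
            "outcome_measure": rec.outcome_measure,
            "stat_kind": rec.stat_kind,
            "n_total": rec.n_total,
            "direction": rec.direction,
            "zr": rec.zr,
            "sampling_variance": rec.sampling_variance,
            "transmission_route": rec.transmission_route,
            "conversion_note": rec.conversion_note,
        }
        if rec.stat_kind == "contingency":
            for k in "abcd":
                row[f"count_{k}"] = rec.stat_payload[k]
        else:
            row["stat_value"] = rec.stat_payload["value"]
            row["df_error"] = rec.stat_payload.get("df_error")
            row["n1"] = rec.stat_payload.get("n1")
            row["n2"] = rec.stat_payload.get("n2")
        rows.append(row)
    return pd.DataFrame(rows)


def write_effect_table(records, path, sep: str = ",") -> None:
    effects_to_frame(records).to_csv(path, sep=sep, index=False)


def read_trait_table(
    path,
    species_aliases: dict[str, str] | None = None,
    sep: str = ",",
) -> list[SpeciesTraits]:
    """Read the species trait table; derived classes/transforms populated."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table missing required columns: {missing}")
    aliases = {
        normalize_species(k): normalize_species(v)
        for k, v in (species_aliases or {}).items()
    }
    seen = set()
    traits = []
    for _, row in df.iterrows():
        sp = normalize_species(row["species"])
        sp = aliases.get(sp, sp)
        if sp in seen:
            raise SchemaError(f"duplicate species row: {sp}")
        seen.add(sp)
        pace = {
            c: float(row[c])
            for c in (
                "body_mass",
                "body_size",
                "offspring_per_year",
                "max_lifespan",
                "age_sexual_maturity",
            )
        }
        bad = [c for c, x in pace.items() if not x > 0]
        if bad:
            raise SchemaError(f"species {sp}: non-positive pace-of-life fields {bad}")
        traits.append(
            SpeciesTraits(
                species=sp,
                dietary_breadth_count=int(row["dietary_breadth_count"]),
                trophic_level=_check_enum(
                    row["trophic_level"], TROPHIC_LEVELS, "trophic_level", sp
                ),
                home_range=float(row["home_range"]),
                migratory=_parse_bool(row["migratory"]),
                **pace,
            )
        )
    return traits


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean value {x!r}")


def traits_to_frame(traits) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in traits])
    return df.set_index("species", drop=False)


def write_trait_table(traits, path, sep: str = ",") -> None:
    cols = list(TRAIT_COLUMNS)
    traits_to_frame(traits)[cols].to_csv(path, sep=sep, index=False)


@dataclass
class ValidationReport:
    """Cross-consistency report for records, traits and tree."""

    species_missing_from_traits: list[str]
    species_missing_from_tree: list[str]
    trait_species_not_in_tree: list[str]
    records_per_group: dict[str, int]
    records_per_species: dict[str, int]
    records_per_study: dict[str, int]
    small_n_records: list[str]

    @property
    def ok(self) -> bool:
        return not (
            self.species_missing_from_traits
            or self.species_missing_from_tree
            or self.trait_species_not_in_tree
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["dataset validation report", "-" * 25]
        lines.append(f"records per parasite group: {self.records_per_group}")
        for label, items in [
            ("record species missing from traits", self.species_missing_from_traits),
            ("record species missing from tree", self.species_missing_from_tree),
            ("trait species missing from tree", self.trait_species_not_in_tree),
            ("records with n_total < 4", self.small_n_records),
        ]:
            lines.append(f"{label}: {items if items else 'none'}")
        return "\n".join(lines)


def validate_dataset(records, traits, tree, strict: bool = False) -> ValidationReport:
    """Cross-check the three inputs; report-only unless ``strict``."""
    from .phylo_tools import tip_labels

    tips = set(tip_labels(tree))
    trait_sp = {t.species for t in traits}
    rec_sp = {r.host_species for r in records}

    per_group = {g: 0 for g in PARASITE_GROUPS}
    per_species: dict[str, int] = {}
    per_study: dict[str, int] = {}
    small_n = []
    for r in records:
        per_group[r.parasite_group] += 1
        per_species[r.host_species] = per_species.get(r.host_species, 0) + 1
        per_study[r.study_id] = per_study.get(r.study_id, 0) + 1
        if r.n_total < 4:
            small_n.append(r.record_id)

    report = ValidationReport(
        species_missing_from_traits=sorted(rec_sp - trait_sp),
        species_missing_from_tree=sorted(rec_sp - tips),
        trait_species_not_in_tree=sorted(trait_sp - tips),
        records_per_group=per_group,
        records_per_species=per_species,
        records_per_study=per_study,
        small_n_records=small_n,
    )
    if strict and not report.ok:
        raise SchemaError("dataset validation failed:\n" + report.to_text())
    return report
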