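"""Data model, file I/O, validation and aggregation for the nested survey design.

Sampling units are identified by hierarchical keys ``forest/treatment/quadrat/
subquadrat`` (e.g. ``"secondary_mixed/grazed/q1/s3"``).  Observations are long
(tidy): one row per (unit, species) with the estimated individual number;
absent species are implicit zeros.  Trait catalogs map each species to the
seven classification axes used in dominance analysis, and the environment
table carries the three litterfall-layer thicknesses plus the ordinal
abundance level of large plant remains.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates the survey data model."""


# ---------------------------------------------------------------------------
# Category enumerations (canonical labels)
# ---------------------------------------------------------------------------

TROPHIC_TYPES = (
    "soil saprotroph",
    "wood saprotroph",
    "alga symbiont",
    "plant symbiont",
    "insect symbiont",
    "fungus symbiont",
)
ATTACHMENT_TYPES = ("soil-inhabiting", "wood-inhabiting")
SPOROCARP_TYPES = (
    "agaricoid",
    "boletoid",
    "polyporoid",
    "cantharelloid",
    "clavarioid",
    "gastroid",
    "jelly",
    "ascomycete",
    "slime mold",
)
GEOGRAPHIC_COMPONENTS = ("cosmopolitan", "north temperate", "pantropical", "East Asian")
EDIBILITY_TYPES = ("edible", "medicinal", "poisonous", "unknown")

TRAIT_AXES = ("order", "trophic", "attachment", "sporocarp", "geographic", "edibility")

_ENUMS = {
    "trophic": TROPHIC_TYPES,
    "attachment": ATTACHMENT_TYPES,
    "sporocarp": SPOROCARP_TYPES,
    "geographic": GEOGRAPHIC_COMPONENTS,
    "edibility": EDIBILITY_TYPES,
}


def _normal_form(label: str) -> str:
    """Case- and plural-insensitive normal form used to match category labels."""
    words = str(label).strip().lower().replace("-", " ").split()
    out = []
    for w in words:
        if w in ("fungi", "fungus"):
            continue  # "agaricoid fungi" == "agaricoid"
        if len(w) > 3 and w.endswith("s") and not w.endswith("ss"):
            w = w[:-1]
        out.append(w)
    return " ".join(out)


_NORMAL_LOOKUP = {
    axis: {_normal_form(v): v for v in values} for axis, values in _ENUMS.items()
}
# canonical hyphenation of attachment types survives the hyphen fold
_NORMAL_LOOKUP["attachment"] = {
    _normal_form(v): v for v in ATTACHMENT_TYPES
}


def normalize_category(axis: str, value: str) -> str:
    """Map a free-form label onto the canonical enumeration for *axis*.

    Matching is case-insensitive and singular/plural-insensitive
    ("Wood saprotrophs" -> "wood saprotroph", "Agaricoid fungi" -> "agaricoid").
    """
    if axis == "order":
        return str(value).strip()
    lookup = _NORMAL_LOOKUP[axis]
    key = _normal_form(value)
    if key not in lookup:
        raise ValidationError(
            f"unknown {axis} category {value!r}; expected one of {sorted(_ENUMS[axis])}"
        )
    return lookup[key]


# ---------------------------------------------------------------------------
# Survey design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDesign:
    """Nested plot layout: plots (forest x treatment) hold quadrats hold subquadrats.

    Defaults mirror a design of three 400 m2 quadrats per plot, each split into
    four 100 m2 subquadrats, so each plot type contributes 12 subquadrat-level
    sampling units.
    """

    forest_types: tuple[str, ...] = ("secondary_mixed", "dense_plantation", "sparse_plantation")
    treatments: tuple[str, str] = ("ungrazed", "grazed")
    quadrats_per_plot: int = 3
    subquadrats_per_quadrat: int = 4
    quadrat_area_m2: float = 400.0
    subquadrat_area_m2: float = 100.0

    def __post_init__(self):
        if self.subquadrats_per_quadrat * self.subquadrat_area_m2 != self.quadrat_area_m2:
            raise ValidationError(
                "subquadrat count x subquadrat area must equal quadrat area "
                f"({self.subquadrats_per_quadrat} x {self.subquadrat_area_m2} "
                f"!= {self.quadrat_area_m2})"
            )

    def unit_keys(self, forest=None, treatment=None, level="subquadrat"):
        """All sampling-unit keys, optionally restricted to one stratum."""
        forests = [forest] if forest is not None else list(self.forest_types)
        treats = [treatment] if treatment is not None else list(self.treatments)
        keys = []
        for f in forests:
            for t in treats:
                for q in range(1, self.quadrats_per_plot + 1):
                    if level == "quadrat":
                        keys.append(f"{f}/{t}/q{q}")
                    else:
                        for s in range(1, self.subquadrats_per_quadrat + 1):
                            keys.append(f"{f}/{t}/q{q}/s{s}")
        return keys

    def units_per_plot(self, level="subquadrat") -> int:
        if level == "quadrat":
            return self.quadrats_per_plot
        return self.quadrats_per_plot * self.subquadrats_per_quadrat


def parse_unit_key(key: str) -> tuple[str, str, str, str | None]:
    """Split ``forest/treatment/quadrat[/subquadrat]`` into its components."""
    parts = str(key).split("/")
    if len(parts) == 4:
        return parts[0], parts[1], parts[2], parts[3]
    if len(parts) == 3:
        return parts[0], parts[1], parts[2], None
    raise ValidationError(f"malformed unit key {key!r}: expected 3 or 4 '/'-separated parts")


def quadrat_key(unit_key: str) -> str:
    """Truncate a subquadrat key to its quadrat."""
    f, t, q, _ = parse_unit_key(unit_key)
    return f"{f}/{t}/{q}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, delimiter=None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_observations(path, delimiter=None) -> pd.DataFrame:
    """Read a long observation table (columns: unit, species, individual_number).

    Unknown columns are preserved.  Raises :class:`ValidationError` on
    duplicated (unit, species) pairs or non-positive individual numbers.
    """
    df = _read_table(path, delimiter)
    _require_columns(df, ["unit", "species", "individual_number"], path)
    return validate_observations(df)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    try:
        df["individual_number"] = df["individual_number"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer individual_number: {exc}") from exc
    bad = df[df["individual_number"] < 1]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"individual_number must be >= 1; got {row['individual_number']} "
            f"for ({row['unit']}, {row['species']})"
        )
    dup = df.duplicated(subset=["unit", "species"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["unit", "species"]].values)))
        raise ValidationError(f"duplicate (unit, species) pair(s): {pairs}")
    for key in df["unit"]:
        parse_unit_key(key)
    return df.reset_index(drop=True)


def read_traits(path, delimiter=None) -> pd.DataFrame:
    """Read the species trait catalog and normalize categories onto Table-style enums."""
    df = _read_table(path, delimiter)
    _require_columns(df, ["species", *TRAIT_AXES], path)
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["species"].duplicated().any():
        dups = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValidationError(f"duplicate species in trait catalog: {dups}")
    for axis in TRAIT_AXES:
        df[axis] = [normalize_category(axis, v) for v in df[axis]]
    return df.reset_index(drop=True)


def read_environment(path, delimiter=None) -> pd.DataFrame:
    """Read per-unit environment records (litterfall layers in cm, remains level 1-4)."""
    df = _read_table(path, delimiter)
    _require_columns(df, ["unit", "lay1_cm", "lay2_cm", "lay3_cm", "remains_level"], path)
    return validate_environment(df)


def validate_environment(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("lay1_cm", "lay2_cm", "lay3_cm"):
        df[col] = df[col].astype(float)
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0].iloc[0]
            raise ValidationError(f"{col} must be >= 0; got {bad[col]} for unit {bad['unit']}")
    df["remains_level"] = df["remains_level"].astype(float)
    if not df["remains_level"].isin([1, 2, 3, 4]).all():
        bad = df.loc[~df["remains_level"].isin([1, 2, 3, 4])].iloc[0]
        raise ValidationError(
            f"remains_level must be in {{1,2,3,4}}; got {bad['remains_level']} "
            f"for unit {bad['unit']}"
        )
    df["remains_level"] = df["remains_level"].astype(int)
    if df["unit"].duplicated().any():
        dups = sorted(df.loc[df["unit"].duplicated(), "unit"])
        raise ValidationError(f"duplicate unit in environment table: {dups}")
    df["lays_cm"] = df["lay1_cm"] + df["lay2_cm"] + df["lay3_cm"]
    return df.reset_index(drop=True)


def _write(df: pd.DataFrame, path, delimiter=None):
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=delimiter, index=False, quoting=csv.QUOTE_MINIMAL)


def write_observations(df: pd.DataFrame, path, delimiter=None):
    _write(df, path, delimiter)


def write_traits(df: pd.DataFrame, path, delimiter=None):
    _write(df, path, delimiter)


def write_environment(df: pd.DataFrame, path, delimiter=None):
    cols = [c for c in df.columns if c != "lays_cm"]
    _write(df[cols], path, delimiter)


def wide_to_long(wide: pd.DataFrame, unit_column: str = "unit") -> pd.DataFrame:
    """Convert a wide species x unit matrix (units as rows) to the long format.

    Zero cells are dropped (absent species are implicit).
    """
    long = wide.melt(id_vars=[unit_column], var_name="species", value_name="individual_number")
    long["individual_number"] = long["individual_number"].astype(int)
    long = long[long["individual_number"] > 0].reset_index(drop=True)
    return validate_observations(long.rename(columns={unit_column: "unit"}))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class StratumCounts:
    """Abundance and occupancy summary for one stratum.

    ``pooled`` maps species -> n_i (summed individual numbers); ``occupancy``
    maps species -> q_i (number of sampling units where present); ``per_unit``
    keeps the per-unit species -> count maps; ``presence_units`` the set of
    units occupied by each species (needed by the literal occupancy variant of
    the dominance index).
    """

    per_unit: dict
    pooled: dict
    occupancy: dict
    presence_units: dict
    N: int
    S: int
    Q: int
    level: str = "subquadrat"


def aggregate_counts(
    obs: pd.DataFrame,
    design: SurveyDesign,
    forest=None,
    treatment=None,
    level: str = "subquadrat",
) -> StratumCounts:
    """Pool a stratum (forest type x treatment, or either marginal) of observations.

    At quadrat level the four subquadrats are pooled by summing individual
    numbers (presence is the OR of subquadrat presences).  Returns per-unit and
    pooled abundance maps together with N, S, q_i and Q.
    """
    if level not in ("subquadrat", "quadrat"):
        raise ValidationError(f"level must be 'subquadrat' or 'quadrat', got {level!r}")
    units = design.unit_keys(forest=forest, treatment=treatment, level=level)
    if not units:
        raise ValidationError(f"empty stratum: forest={forest!r}, treatment={treatment!r}")
    unit_set = set(units)

    per_unit = {u: {} for u in units}
    for row in obs.itertuples(index=False):
        key = row.unit if level == "subquadrat" else quadrat_key(row.unit)
        f, t, _, _ = parse_unit_key(row.unit)
        if forest is not None and f != forest:
            continue
        if treatment is not None and t != treatment:
            continue
        if key not in unit_set:
            raise ValidationError(f"unit {row.unit!r} does not belong to the survey design")
        counts = per_unit[key]
        counts[row.species] = counts.get(row.species, 0) + int(row.individual_number)

    pooled: dict = {}
    occupancy: dict = {}
    presence_units: dict = {}
    for u, counts in per_unit.items():
        for sp, n in counts.items():
            pooled[sp] = pooled.get(sp, 0) + n
            occupancy[sp] = occupancy.get(sp, 0) + 1
            presence_units.setdefault(sp, set()).add(u)
    return StratumCounts(
        per_unit=per_unit,
        pooled=pooled,
        occupancy=occupancy,
        presence_units=presence_units,
        N=sum(pooled.values()),
        S=len(pooled),
        Q=len(units),
        level=level,
    )


def venn_partition(species_grazed, species_ungrazed) -> dict:
    """Two-set partition of species pools: shared / unique counts and totals."""
    a, b = set(species_grazed), set(species_ungrazed)
    shared = len(a & b)
    return {
        "shared": shared,
        "unique_grazed": len(a - b),
        "unique_ungrazed": len(b - a),
        "total": len(a | b),
        "n_grazed": len(a),
        "n_ungrazed": len(b),
    }
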