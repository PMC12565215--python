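"""Seeded synthetic-survey generator.

Emulates the study conditions of a two-treatment (grazed/ungrazed), three
forest-type silvopasture survey with 12 subquadrat sampling units per plot
type: species pools with a configurable shared/unique Venn structure,
geometric-series abundance whose concentration parameter theta sweeps between
monopolistic (theta near 1) and balanced (theta near 0) dominance,
occupancy linked to abundance, treatment-dependent trait and geographic
frequencies, litterfall reduction and plant-remains increase under grazing,
and planted sporocarp point patterns with known individual codes.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mycograze.individuals import SporocarpPoint
from mycograze.survey import (
    SurveyDesign,
    validate_environment,
    validate_observations,
    validate_traits,
)

# treatment-dependent sampling tables for the trait axes.  "ungrazed" governs
# the pre-grazing pool (shared + unique-ungrazed species): lichenized alga
# symbionts dominate and geographic components are restricted to cosmopolitan/
# pantropical.  "grazed" governs the species introduced by grazing: wood and
# soil saprotrophs dominate and temperate/East Asian components appear.
TRAIT_TABLES = {
    "trophic": {
        "ungrazed": (
            ("alga symbiont", "wood saprotroph", "soil saprotroph", "plant symbiont", "insect symbiont", "fungus symbiont"),
            (0.45, 0.30, 0.10, 0.09, 0.03, 0.03),
        ),
        "grazed": (
            ("wood saprotroph", "soil saprotroph", "alga symbiont", "plant symbiont", "insect symbiont", "fungus symbiont"),
            (0.45, 0.22, 0.13, 0.10, 0.05, 0.05),
        ),
    },
    "attachment": {
        "ungrazed": (("wood-inhabiting", "soil-inhabiting"), (0.82, 0.18)),
        "grazed": (("wood-inhabiting", "soil-inhabiting"), (0.72, 0.28)),
    },
    "sporocarp": {
        "ungrazed": (
            ("ascomycete", "polyporoid", "agaricoid", "clavarioid", "jelly", "gastroid", "boletoid", "cantharelloid", "slime mold"),
            (0.45, 0.20, 0.17, 0.06, 0.04, 0.03, 0.02, 0.02, 0.01),
        ),
        "grazed": (
            ("agaricoid", "polyporoid", "ascomycete", "jelly", "clavarioid", "gastroid", "boletoid", "slime mold", "cantharelloid"),
            (0.32, 0.26, 0.20, 0.07, 0.05, 0.04, 0.03, 0.02, 0.01),
        ),
    },
    "geographic": {
        "ungrazed": (("cosmopolitan", "pantropical"), (0.70, 0.30)),
        "grazed": (("cosmopolitan", "pantropical", "north temperate", "East Asian"), (0.55, 0.25, 0.13, 0.07)),
    },
    "edibility": {
        "ungrazed": (("unknown", "edible", "medicinal", "poisonous"), (0.82, 0.07, 0.06, 0.05)),
        "grazed": (("unknown", "edible", "medicinal", "poisonous"), (0.62, 0.18, 0.12, 0.08)),
    },
}

# the taxonomic order follows deterministically from the sporocarp morphology
ORDER_BY_SPOROCARP = {
    "ascomycete": "Ostropales",
    "agaricoid": "Agaricales",
    "polyporoid": "Polyporales",
    "clavarioid": "Lepidostromatales",
    "jelly": "Auriculariales",
    "boletoid": "Boletales",
    "gastroid": "Geastrales",
    "cantharelloid": "Cantharellales",
    "slime mold": "Physarales",
}


def _default_litter_means():
    # undecomposed / semi-decomposed / decomposed layer means (cm), ungrazed;
    # the decomposed layer is absent in the two plantation types
    return {
        "secondary_mixed": (2.5, 1.25, 0.5),
        "dense_plantation": (1.0, 0.5, 0.0),
        "sparse_plantation": (1.0, 0.5, 0.0),
    }


@dataclass
class SimulationConfig:
    """Generator parameters; defaults reproduce the study's survey conditions."""

    seed: int = 0
    forest_types: tuple = ("secondary_mixed", "dense_plantation", "sparse_plantation")
    quadrats_per_plot: int = 3
    subquadrats_per_quadrat: int = 4
    # species-pool Venn structure across treatments
    shared_species: int = 17
    unique_grazed: int = 53
    unique_ungrazed: int = 16
    # geometric-series concentration per treatment (near 1 = monopolistic)
    theta_ungrazed: float = 0.8
    theta_grazed: float = 0.3
    # occupancy base rate pi: per-unit presence prob = 1 - (1 - pi)^abundance
    base_occupancy: float = 0.35
    # expected individuals per (forest, treatment) stratum
    stratum_abundance: float = 60.0
    # abundance weighting of the 1-4 individual-number codes
    code_weight: float = 2.0
    forest_affinity: float = 0.6  # prob a species can occur in a given forest type
    litter_means: dict = field(default_factory=_default_litter_means)
    litter_shape: float = 2.0  # gamma shape for layer thickness
    litter_grid_cm: float = 0.25
    litter_reduction: float = 0.5  # multiplicative effect of grazing
    remains_base: float = 2.0
    remains_sd: float = 0.7
    remains_shift: int = 1  # ordinal shift of remains level under grazing

    def __post_init__(self):
        if min(self.shared_species, self.unique_grazed, self.unique_ungrazed) < 0:
            raise ValueError("species counts must be non-negative")
        if self.shared_species + self.unique_grazed + self.unique_ungrazed < 1:
            raise ValueError("species pool must be nonempty")
        for theta in (self.theta_ungrazed, self.theta_grazed):
            if not 0 < theta < 1:
                raise ValueError(f"theta must lie in (0, 1), got {theta}")
        if not 0 < self.base_occupancy <= 1:
            raise ValueError("base_occupancy must lie in (0, 1]")
        if not 0 < self.forest_affinity <= 1:
            raise ValueError("forest_affinity must lie in (0, 1]")
        if self.litter_reduction <= 0:
            raise ValueError("litter_reduction must be positive")
        if set(self.litter_means) != set(self.forest_types):
            raise ValueError("litter_means must cover every forest type")

    @property
    def design(self) -> SurveyDesign:
        return SurveyDesign(
            forest_types=tuple(self.forest_types),
            quadrats_per_plot=self.quadrats_per_plot,
            subquadrats_per_quadrat=self.subquadrats_per_quadrat,
        )

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A no-effect configuration for false-positive calibration: symmetric
        pools, equal concentration, no litter or remains shift."""
        params = dict(
            seed=seed,
            shared_species=17,
            unique_grazed=16,
            unique_ungrazed=16,
            theta_ungrazed=0.55,
            theta_grazed=0.55,
            litter_reduction=1.0,
            remains_shift=0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class TruthRecord:
    """Ground truth of one realized dataset, for recovery tests."""

    pools: dict  # treatment -> sorted species list
    forest_assignment: dict  # species -> list of forest types
    stratum_weights: dict  # "forest/treatment" -> {species: geometric weight}
    expected_directions: dict  # variable -> configured direction symbol or "|"
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "pools": self.pools,
                "forest_assignment": self.forest_assignment,
                "stratum_weights": self.stratum_weights,
                "expected_directions": self.expected_directions,
                "config": self.config,
            },
            indent=2,
            default=str,
        )


def _geometric_weights(n: int, theta: float) -> np.ndarray:
    w = theta * (1 - theta) ** np.arange(n)
    return w / w.sum()


def generate_dataset(config: SimulationConfig):
    """Generate (observations, traits, environment, truth) for one seed.

    The realized species pools match the configured Venn structure exactly:
    any pool species not drawn by the occupancy model is planted once in a
    random unit of its treatment.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design

    n_total = config.shared_species + config.unique_grazed + config.unique_ungrazed
    species = [f"sp{i + 1:03d}" for i in range(n_total)]
    shared = species[: config.shared_species]
    uniq_g = species[config.shared_species : config.shared_species + config.unique_grazed]
    uniq_u = species[config.shared_species + config.unique_grazed :]
    pools = {"grazed": shared + uniq_g, "ungrazed": shared + uniq_u}

    forests = list(config.forest_types)
    forest_assignment = {}
    for sp in species:
        mask = rng.random(len(forests)) < config.forest_affinity
        if not mask.any():
            mask[rng.integers(len(forests))] = True
        forest_assignment[sp] = [f for f, m in zip(forests, mask) if m]

    theta = {"ungrazed": config.theta_ungrazed, "grazed": config.theta_grazed}
    records = []
    seen = {"grazed": set(), "ungrazed": set()}
    stratum_weights = {}
    for f in forests:
        for t in design.treatments:
            eligible = [sp for sp in pools[t] if f in forest_assignment[sp]]
            if not eligible:
                continue
            order = rng.permutation(len(eligible))
            ranked = [eligible[i] for i in order]
            w = _geometric_weights(len(ranked), theta[t])
            stratum_weights[f"{f}/{t}"] = {sp: float(wi) for sp, wi in zip(ranked, w)}
            abundance = config.stratum_abundance * w
            p_present = 1.0 - (1.0 - config.base_occupancy) ** abundance
            p_code = np.minimum(0.85, config.code_weight * w)
            units = design.unit_keys(forest=f, treatment=t)
            present = rng.random((len(units), len(ranked))) < p_present
            extra = rng.binomial(3, np.broadcast_to(p_code, present.shape))
            for ui, unit in enumerate(units):
                for si in np.flatnonzero(present[ui]):
                    sp = ranked[si]
                    records.append(
                        {"unit": unit, "species": sp, "individual_number": int(1 + extra[ui, si])}
                    )
                    seen[t].add(sp)

    # realize the configured Venn structure exactly
    for t in design.treatments:
        for sp in pools[t]:
            if sp in seen[t]:
                continue
            f = forest_assignment[sp][rng.integers(len(forest_assignment[sp]))]
            units = design.unit_keys(forest=f, treatment=t)
            unit = units[rng.integers(len(units))]
            records.append({"unit": unit, "species": sp, "individual_number": 1})
            seen[t].add(sp)

    obs = validate_observations(pd.DataFrame(records))

    # trait catalog: pre-grazing pool species follow the ungrazed tables
    trait_rows = []
    for sp in species:
        table_key = "grazed" if sp in set(uniq_g) else "ungrazed"
        row = {"species": sp}
        for axis in ("trophic", "attachment", "sporocarp", "geographic", "edibility"):
            labels, probs = TRAIT_TABLES[axis][table_key]
            row[axis] = str(rng.choice(labels, p=probs))
        row["order"] = ORDER_BY_SPOROCARP[row["sporocarp"]]
        trait_rows.append(row)
    traits = validate_traits(
        pd.DataFrame(trait_rows)[["species", "order", "trophic", "attachment", "sporocarp", "geographic", "edibility"]]
    )

    env_rows = []
    for f in forests:
        for t in design.treatments:
            reduction = config.litter_reduction if t == "grazed" else 1.0
            shift = config.remains_shift if t == "grazed" else 0
            for unit in design.unit_keys(forest=f, treatment=t):
                lays = []
                for mean in config.litter_means[f]:
                    m = mean * reduction
                    if m <= 0:
                        lays.append(0.0)
                        continue
                    raw = rng.gamma(config.litter_shape, m / config.litter_shape)
                    lays.append(round(raw / config.litter_grid_cm) * config.litter_grid_cm)
                level = int(np.clip(round(rng.normal(config.remains_base + shift, config.remains_sd)), 1, 4))
                env_rows.append(
                    {
                        "unit": unit,
                        "lay1_cm": lays[0],
                        "lay2_cm": lays[1],
                        "lay3_cm": lays[2],
                        "remains_level": level,
                    }
                )
    env = validate_environment(pd.DataFrame(env_rows))

    truth = TruthRecord(
        pools={t: sorted(p) for t, p in pools.items()},
        forest_assignment=forest_assignment,
        stratum_weights=stratum_weights,
        expected_directions={
            "richness": "↑" if config.unique_grazed > config.unique_ungrazed else "|",
            "litterfall": "↓" if config.litter_reduction < 1 else "|",
            "remains": "↑" if config.remains_shift > 0 else "|",
        },
        config=asdict(config),
    )
    return obs, traits, env, truth


# ---------------------------------------------------------------------------
# Planted point patterns
# ---------------------------------------------------------------------------

# inclusive within-group gap bands for codes 2-4
_CODE_BANDS = {2: (0.05, 0.5), 3: (0.5, 1.0), 4: (1.0, 2.0)}
# 2x2 anchor grid in a 10x10 m subquadrat: anchors 5 m apart, clusters stay
# within 1 m of their anchor, so inter-cluster point distance is >= 3 m (> 2)
_ANCHORS = [(2.5, 2.5), (2.5, 7.5), (7.5, 2.5), (7.5, 7.5)]


@dataclass
class PlantedPointSet:
    """One unit's planted sporocarp pattern with its true group codes."""

    points: list
    codes: list
    unit_key: str
    species_id: str

    @property
    def individual_number(self) -> int:
        return sum(self.codes)


def _planted_cluster(rng, anchor, code):
    ax, ay = anchor
    if code == 1:
        jx, jy = rng.uniform(-0.3, 0.3, 2)
        return [(ax + jx, ay + jy)]
    lo, hi = _CODE_BANDS[code]
    m = int(rng.integers(2, 4)) if code in (2, 3) else 2
    gmax = rng.uniform(lo + 1e-3, hi)
    gaps = np.array([gmax] + [float(rng.uniform(0.02, gmax)) for _ in range(m - 2)])
    rng.shuffle(gaps)
    theta = rng.uniform(0, 2 * math.pi)
    dx, dy = math.cos(theta), math.sin(theta)
    length = sum(gaps)
    offsets = np.concatenate([[0.0], np.cumsum(gaps)]) - length / 2
    return [(ax + o * dx, ay + o * dy) for o in offsets]


def generate_points(n_sets: int = 200, seed: int = 0, species_id: str = "spX", unit_prefix: str = "f/t/q1"):
    """Plant ``n_sets`` point patterns with known cluster codes.

    Each set lives in its own subquadrat, holds 1-4 clusters with planted
    codes, within-cluster gaps inside the code's band and between-cluster
    separations above 2 m.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        unit = f"{unit_prefix}/s{i + 1}"
        n_clusters = int(rng.integers(1, 5))
        anchors = [_ANCHORS[k] for k in rng.permutation(4)[:n_clusters]]
        codes = [int(rng.integers(1, 5)) for _ in range(n_clusters)]
        pts = []
        for anchor, code in zip(anchors, codes):
            for x, y in _planted_cluster(rng, anchor, code):
                pts.append(SporocarpPoint(species_id=species_id, unit_key=unit, x=x, y=y))
        sets.append(PlantedPointSet(points=pts, codes=sorted(codes), unit_key=unit, species_id=species_id))
    return sets


def generate_measurements(n: int, mean: float, sd: float, grid: float = 0.5, seed: int = 0):
    """Normal spore-measurement draws snapped to the recording grid."""
    if n < 2:
        raise ValueError("need n >= 2 measurements")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.normal(mean, sd, n) if sd > 0 else np.full(n, float(mean))
    snapped = np.round(raw / grid) * grid
    return np.maximum(snapped, grid).tolist()


def emit_dataset(config: SimulationConfig, outdir):
    """Write the three survey CSVs plus the truth JSON to ``outdir``."""
    from mycograze.survey import write_environment, write_observations, write_traits

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs, traits, env, truth = generate_dataset(config)
    write_observations(obs, outdir / "observations.csv")
    write_traits(traits, outdir / "traits.csv")
    write_environment(env, outdir / "environment.csv")
    (outdir / "truth.json").write_text(truth.to_json())
    return obs, traits, env, truth
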