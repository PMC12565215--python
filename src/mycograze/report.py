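"""Full-pipeline orchestration: the before/after comparison tables, dominance
tables for every classification axis, Venn summary and PCA outputs.

Strata follow the survey layout: one block per forest type plus a pooled
"General" block combining the three forest types within treatment (n = 36
units per side at subquadrat level).  All rounding happens at render time;
the pipeline carries full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mycograze import comparison, dominance, diversity, ordination, survey

GENERAL = "General"

DIVERSITY_VARIABLES = (
    ("Diversity index", "Div"),
    ("Evenness index", "Eve"),
    ("Richness index", "Ric"),
)
ENVIRONMENT_VARIABLES = (
    ("Undecomposed layer", "lay1_cm"),
    ("Semi-decomposed layer", "lay2_cm"),
    ("Decomposed layer", "lay3_cm"),
    ("All litterfall layers", "lays_cm"),
    ("Large plant remains", "remains_level"),
)


def unit_diversity(obs, design, level="subquadrat") -> pd.DataFrame:
    """Per-unit diversity profile (unit, Div, Eve, Ric, forest, treatment, N, S).

    Units with no recorded sporocarps get Div = Ric = 0 and undefined Eve.
    """
    rows = []
    for forest in design.forest_types:
        for treatment in design.treatments:
            counts = survey.aggregate_counts(obs, design, forest=forest, treatment=treatment, level=level)
            for unit, vec in counts.per_unit.items():
                if vec:
                    prof = diversity.diversity_profile(vec)
                    div, eve, ric, n, s = prof.div, prof.eve, prof.ric, prof.N, prof.S
                else:
                    div, eve, ric, n, s = 0.0, math.nan, 0.0, 0, 0
                rows.append(
                    {
                        "unit": unit,
                        "forest": forest,
                        "treatment": treatment,
                        "Div": div,
                        "Eve": eve,
                        "Ric": ric,
                        "N": n,
                        "S": s,
                    }
                )
    return pd.DataFrame(rows)


def _strata(design):
    return [*design.forest_types, GENERAL]


def _split(df, design, forest, column, eve_fill=None):
    out = {}
    for treatment in design.treatments:
        mask = df["treatment"] == treatment
        if forest != GENERAL:
            mask &= df["forest"] == forest
        vals = df.loc[mask, column].astype(float)
        if eve_fill is not None:
            vals = vals.fillna(eve_fill)
        out[treatment] = vals.to_numpy()
    return out


def comparison_table(per_unit: pd.DataFrame, variables, design, alpha=0.05) -> pd.DataFrame:
    """Tabulate classify_change for each variable in each stratum.

    ``variables`` is a sequence of (display name, column) pairs.  Undefined
    evenness values are excluded from that variable's samples.
    """
    rows = []
    for stratum in _strata(design):
        for name, col in variables:
            samples = _split(per_unit, design, stratum, col)
            x = samples["ungrazed"]
            y = samples["grazed"]
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            res = comparison.classify_change(x, y, alpha=alpha)
            rows.append(
                {
                    "stratum": stratum,
                    "variable": name,
                    "median_ungrazed": res.median_ungrazed,
                    "median_grazed": res.median_grazed,
                    "U": res.u_report,
                    "p": res.p_two_sided,
                    "delta": res.delta,
                    "conclusion": res.conclusion,
                }
            )
    return pd.DataFrame(rows)


def dominance_tables(obs, traits, design, level="subquadrat", k=3, axes=dominance.DOMINANCE_AXES):
    """Top-k dominance tables per axis for every stratum x treatment."""
    out = {}
    for axis in axes:
        frames = []
        for stratum in _strata(design):
            forest = None if stratum == GENERAL else stratum
            for treatment in design.treatments:
                counts = survey.aggregate_counts(obs, design, forest=forest, treatment=treatment, level=level)
                if not counts.pooled:
                    continue
                inp = dominance.DominanceInput.from_counts(counts, traits=traits, axis=axis)
                table = dominance.dominance_table(inp, k=None if axis == "attachment" else k).table
                table = table.assign(stratum=stratum, treatment=treatment)
                frames.append(table)
        out[axis] = pd.concat(frames, ignore_index=True)[
            ["stratum", "treatment", "rank", "group", "dominance_pct", "tied"]
        ]
    return out


def pca_by_stratum(per_unit_div, env, design, level="subquadrat"):
    """Correlation PCA per forest type and pooled, with zero-variance exclusion."""
    results = {}
    env = env.copy()
    if level == "quadrat":
        env["unit"] = env["unit"].map(survey.quadrat_key)
        env = env.groupby("unit", as_index=False).mean(numeric_only=True)
        env["remains_level"] = env["remains_level"].round().astype(int)
    for stratum in _strata(design):
        if stratum == GENERAL:
            div_s = per_unit_div
        else:
            div_s = per_unit_div[per_unit_div["forest"] == stratum]
        env_s = env[env["unit"].isin(div_s["unit"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ordination.assemble_matrix(div_s[["unit", "Div", "Eve", "Ric"]], env_s)
        m, excluded = ordination.drop_zero_variance(m)
        results[stratum] = ordination.pca(m, excluded=excluded)
    return results


@dataclass
class ReportBundle:
    """Everything the survey analysis produces for one dataset."""

    diversity_comparison: pd.DataFrame
    environment_comparison: pd.DataFrame
    dominance: dict
    venn: dict
    pca: dict
    per_unit_diversity: pd.DataFrame
    log: list = field(default_factory=list)

    def digest(self) -> str:
        """Stable digest of the rendered numbers (for determinism checks)."""
        payload = {
            "diversity": self.diversity_comparison.round(6).to_csv(index=False),
            "environment": self.environment_comparison.round(6).to_csv(index=False),
            "venn": self.venn,
            "dominance": {ax: df.round(6).to_csv(index=False) for ax, df in self.dominance.items()},
            "explained": {s: np.round(r.explained, 9).tolist() for s, r in self.pca.items()},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_full_analysis(obs, traits, env, design=None, level="subquadrat", alpha=0.05) -> ReportBundle:
    """Run the complete analysis: diversity and environment contrasts per
    stratum, dominance tables for all axes, the species Venn partition and PCA.
    Deterministic given the inputs."""
    if design is None:
        design = survey.SurveyDesign()
    log = []

    def _log(op, **params):
        log.append({"op": op, **params})

    obs = survey.validate_observations(obs)
    traits = survey.validate_traits(traits)
    env = survey.validate_environment(env)
    missing = set(obs["species"]) - set(traits["species"])
    if missing:
        raise survey.ValidationError(f"species without trait rows: {sorted(missing)}")
    _log("validate", n_obs=len(obs), n_species=obs["species"].nunique(), n_units=env["unit"].nunique())

    per_unit = unit_diversity(obs, design, level=level)
    _log("unit_diversity", level=level, n_units=len(per_unit))

    env_units = env.copy()
    if level == "quadrat":
        env_units["unit"] = env_units["unit"].map(survey.quadrat_key)
        env_units = env_units.groupby("unit", as_index=False).mean(numeric_only=True)
    meta = per_unit[["unit", "forest", "treatment"]]
    env_units = env_units.merge(meta, on="unit", validate="one_to_one")

    div_cmp = comparison_table(per_unit, DIVERSITY_VARIABLES, design, alpha=alpha)
    env_cmp = comparison_table(env_units, ENVIRONMENT_VARIABLES, design, alpha=alpha)
    _log("comparisons", diversity_rows=len(div_cmp), environment_rows=len(env_cmp))

    grazed = survey.aggregate_counts(obs, design, treatment="grazed", level=level)
    ungrazed = survey.aggregate_counts(obs, design, treatment="ungrazed", level=level)
    venn = survey.venn_partition(grazed.pooled, ungrazed.pooled)
    _log("venn", **venn)

    dom = dominance_tables(obs, traits, design, level=level)
    _log("dominance", axes=list(dom))

    pca_results = pca_by_stratum(per_unit, env, design, level=level)
    _log("pca", strata=list(pca_results))

    return ReportBundle(
        diversity_comparison=div_cmp,
        environment_comparison=env_cmp,
        dominance=dom,
        venn=venn,
        pca=pca_results,
        per_unit_diversity=per_unit,
        log=log,
    )


def recover_effects(config, level="subquadrat", alpha=0.05) -> dict:
    """Generate a dataset from ``config`` and return the pooled conclusions for
    the three headline variables: per-unit richness, total litterfall and
    plant-remains abundance."""
    from mycograze.simulate import generate_dataset

    obs, traits, env, truth = generate_dataset(config)
    design = config.design
    per_unit = unit_diversity(obs, design, level=level)
    meta = per_unit[["unit", "forest", "treatment"]]
    env_units = env.merge(meta, on="unit", validate="one_to_one")

    out = {}
    for name, df, col in (
        ("richness", per_unit, "Ric"),
        ("litterfall", env_units, "lays_cm"),
        ("remains", env_units, "remains_level"),
    ):
        samples = _split(df, design, GENERAL, col)
        x = samples["ungrazed"]
        y = samples["grazed"]
        out[name] = comparison.classify_change(x[~np.isnan(x)], y[~np.isnan(y)], alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_markdown(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    """Minimal GitHub-style markdown table."""
    cols = list(df.columns)

    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v) if not math.isnan(v) else ""
        return str(v)

    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def write_bundle(bundle: ReportBundle, outdir):
    """Write the bundle as CSVs plus a markdown overview; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _save(df, name):
        p = outdir / name
        df.to_csv(p, index=False)
        paths.append(p)

    _save(bundle.diversity_comparison, "diversity_comparison.csv")
    _save(bundle.environment_comparison, "environment_comparison.csv")
    _save(bundle.per_unit_diversity, "per_unit_diversity.csv")
    for axis, df in bundle.dominance.items():
        _save(df, f"dominance_{axis}.csv")
    for stratum, res in bundle.pca.items():
        tag = stratum.replace("/", "_")
        _save(res.loadings.reset_index(names="variable"), f"pca_loadings_{tag}.csv")
        _save(res.scores.reset_index(names="unit"), f"pca_scores_{tag}.csv")
        _save(
            pd.DataFrame(
                {"component": [f"PC{i + 1}" for i in range(len(res.explained))], "explained_fraction": res.explained}
            ),
            f"pca_explained_{tag}.csv",
        )
    (outdir / "venn.json").write_text(json.dumps(bundle.venn, indent=2))
    md = [
        "# Survey analysis report",
        "",
        "## Species pools",
        "",
        "```json",
        json.dumps(bundle.venn, indent=2),
        "```",
        "",
        "## Diversity indices, grazed vs ungrazed",
        "",
        render_markdown(bundle.diversity_comparison),
        "",
        "## Environmental factors, grazed vs ungrazed",
        "",
        render_markdown(bundle.environment_comparison),
        "",
        f"Run digest: `{bundle.digest()}`",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(md))
    paths.append(outdir / "report.md")
    return paths
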