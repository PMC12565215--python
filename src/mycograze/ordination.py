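"""PCA ordination of diversity indices against environmental covariates.

The feature matrix joins, per sampling unit, the three diversity indices
(Div, Eve, Ric) with the litterfall-layer thicknesses (Lay-1/2/3, their sum
Lays) and the ordinal abundance of large plant remains (Rem).  Variables mix
centimeters, ordinal levels and unitless indices, so the PCA standardizes
columns to zero mean and unit variance (correlation PCA).  Zero-variance
columns must be dropped beforehand and are reported.  Component signs follow a
deterministic convention (largest-magnitude loading positive) so results are
bit-for-bit reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_COLUMNS = ("Div", "Eve", "Ric", "Lay-1", "Lay-2", "Lay-3", "Lays", "Rem")


def assemble_matrix(
    diversity: pd.DataFrame,
    environment: pd.DataFrame,
    eve_policy: str = "impute",
) -> pd.DataFrame:
    """Join per-unit diversity (unit, Div, Eve, Ric) with environment records.

    Units with undefined evenness (single-species units) have Eve imputed as 0
    with a warning by default (``eve_policy="impute"``); ``"drop"`` removes
    those rows instead.  A key mismatch raises, naming the orphan units.
    The imputation count is stored in ``result.attrs["eve_imputed"]``.
    """
    div = diversity.set_index("unit")
    env = environment.set_index("unit")
    only_div = sorted(set(div.index) - set(env.index))
    only_env = sorted(set(env.index) - set(div.index))
    if only_div or only_env:
        raise ValueError(
            f"unit keys do not align: missing environment for {only_div}, "
            f"missing diversity for {only_env}"
        )
    m = pd.DataFrame(
        {
            "Div": div["Div"].astype(float),
            "Eve": div["Eve"].astype(float),
            "Ric": div["Ric"].astype(float),
            "Lay-1": env["lay1_cm"].astype(float),
            "Lay-2": env["lay2_cm"].astype(float),
            "Lay-3": env["lay3_cm"].astype(float),
            "Rem": env["remains_level"].astype(float),
        }
    )
    m["Lays"] = m["Lay-1"] + m["Lay-2"] + m["Lay-3"]
    m = m[list(FEATURE_COLUMNS)]
    undefined = m["Eve"].isna()
    n_undef = int(undefined.sum())
    if n_undef:
        if eve_policy == "impute":
            warnings.warn(
                f"imputed Eve=0 for {n_undef} unit(s) with S<=1", stacklevel=2
            )
            m.loc[undefined, "Eve"] = 0.0
        elif eve_policy == "drop":
            m = m[~undefined]
        else:
            raise ValueError(f"eve_policy must be 'impute' or 'drop', got {eve_policy!r}")
    m.attrs["eve_imputed"] = n_undef if eve_policy == "impute" else 0
    return m


def drop_zero_variance(m: pd.DataFrame):
    """Remove constant columns; returns (matrix, exclusion report)."""
    if len(m) < 2:
        raise ValueError("need at least 2 rows to assess variance")
    excluded = []
    keep = []
    for col in m.columns:
        if float(m[col].var(ddof=1)) == 0.0:
            excluded.append({"column": col, "reason": "zero variance"})
        else:
            keep.append(col)
    if not keep:
        raise ValueError("all columns have zero variance")
    out = m[keep].copy()
    out.attrs.update(m.attrs)
    return out, excluded


@dataclass
class PcaResult:
    """Loadings (variables x components), scores (units x components) and
    explained-variance fractions of a correlation PCA."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: np.ndarray
    excluded: list = field(default_factory=list)
    standardized: pd.DataFrame | None = None


def pca(m: pd.DataFrame, excluded=None) -> PcaResult:
    """Correlation PCA via SVD of the standardized matrix.

    All min(n-1, p) components are retained, so explained fractions sum to 1
    and ``scores @ loadings.T`` reconstructs the standardized matrix.
    """
    if len(m) < 2:
        raise ValueError("PCA requires at least 2 rows")
    X = m.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = [c for c, s in zip(m.columns, sd) if s == 0]
        raise ValueError(f"zero-variance column(s) reached PCA: {cols}; drop them first")
    Z = (X - mu) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic signs: largest-magnitude loading of each component positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    comps = [f"PC{j + 1}" for j in range(len(s))]
    ss = s**2
    explained = ss / ss.sum()
    return PcaResult(
        loadings=pd.DataFrame(vt.T, index=m.columns, columns=comps),
        scores=pd.DataFrame(u * s, index=m.index, columns=comps),
        explained=explained,
        excluded=list(excluded or []),
        standardized=pd.DataFrame(Z, index=m.index, columns=m.columns),
    )


def correlation_summary(m: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p and sign/strength labels.

    Labels combine the sign of r with 'significant' (p < alpha) or 'slight'.
    Constant columns yield an 'undefined' label.
    """
    rows = []
    cols = list(m.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            xa = m[a].to_numpy(dtype=float)
            xb = m[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rows.append({"var1": a, "var2": b, "r": math.nan, "p": math.nan, "label": "undefined"})
                continue
            r, p = stats.pearsonr(xa, xb)
            sign = "positive" if r >= 0 else "negative"
            strength = "significant" if p < alpha else "slight"
            rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p), "label": f"{sign} {strength}"})
    return pd.DataFrame(rows)
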