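"""Mann-Whitney U, Cliff's delta, magnitude banding and conclusion coding.

The grazed/ungrazed contrast for each variable is tested with a two-sided
Mann-Whitney U test (alpha = 0.05) and summarized by Cliff's delta derived
from the U statistic,

    delta = 2 U / (n1 n2) - 1,

with |delta| banded as negligible (< 0.147), minor (< 0.33), moderate
(< 0.474) or large (>= 0.474).  The reported U is min(U1, U2), which makes the
reported delta <= 0; the direction of change is carried separately by the
conclusion code (up/no change/down arrow, a star for p < 0.05, and -/+/++/+++
for the magnitude band).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

ALPHA = 0.05

MAGNITUDE_BANDS = (
    (0.147, "negligible"),
    (0.33, "minor"),
    (0.474, "moderate"),
)

EFFECT_SYMBOL = {"negligible": "−", "minor": "+", "moderate": "++", "large": "+++"}
DIRECTION_UP, DIRECTION_NONE, DIRECTION_DOWN = "↑", "|", "↓"


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U test.

    Returns (u1, u2, p) where u1 counts (x > y) pairs with half credit for
    ties and u2 = n1*n2 - u1.  The p-value uses the exact permutation
    distribution when the pooled sample is tie-free and has at most 25 values,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and len(pooled) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return u1, u2, float(res.pvalue)


def cliffs_delta_from_u(u_report: float, n1: int, n2: int) -> float:
    """Cliff's delta from a U statistic: 2U/(n1 n2) - 1, evaluated exactly."""
    if n1 * n2 == 0:
        raise ValueError("n1 and n2 must be positive")
    if not 0 <= u_report <= n1 * n2:
        raise ValueError(f"U must lie in [0, {n1 * n2}], got {u_report}")
    return float(2 * Fraction(u_report) / (n1 * n2) - 1)


def round_half_away(value: float, decimals: int = 3) -> float:
    """Round with exact halves going away from zero (so -0.8125 -> -0.813)."""
    frac = Fraction(value).limit_denominator(10**9) * 10**decimals
    whole = int(frac)
    rem = frac - whole
    if rem >= Fraction(1, 2):
        whole += 1
    elif rem <= Fraction(-1, 2):
        whole -= 1
    return whole / 10**decimals


def format_delta(delta: float) -> str:
    """Render delta to 3 decimals, keeping 4 when the 3-d.p. rounding is
    ambiguous (an exact half at the fourth decimal, e.g. -0.6875)."""
    frac = Fraction(delta).limit_denominator(10**9) * 1000
    if frac.denominator == 2:
        return f"{delta:.4f}"
    return f"{round_half_away(delta, 3):.3f}"


def cliffs_delta_signed(x, y) -> float:
    """Signed Cliff's delta (#(x>y) - #(x<y)) / (n1 n2) by direct comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / diff.size)


def magnitude_class(delta: float) -> str:
    """Band |delta| into negligible / minor / moderate / large."""
    mag = abs(delta)
    if mag > 1:
        raise ValueError(f"|delta| must be <= 1, got {delta}")
    for bound, label in MAGNITUDE_BANDS:
        if mag < bound:
            return label
    return "large"


def _median(sample) -> float:
    return float(np.median(np.asarray(sample, dtype=float)))


@dataclass(frozen=True)
class ComparisonResult:
    """One grazed-vs-ungrazed contrast for one variable in one stratum."""

    median_ungrazed: float
    median_grazed: float
    u1: float
    u2: float
    u_report: float
    p_two_sided: float
    delta: float
    delta_signed: float
    magnitude: str
    direction: str
    significant: bool

    @property
    def conclusion(self) -> str:
        parts = [self.direction]
        if self.significant:
            parts.append("*")
        parts.append(EFFECT_SYMBOL[self.magnitude])
        return " ".join(parts)


def classify_change(x_ungrazed, y_grazed, alpha: float = ALPHA) -> ComparisonResult:
    """Full contrast: medians, U, p, delta, magnitude band and conclusion code.

    Direction comes from the sign of (median grazed - median ungrazed); on an
    exact median tie, from the sign of the mean-rank difference; "no change"
    only when both are zero.
    """
    x = np.asarray(x_ungrazed, dtype=float)
    y = np.asarray(y_grazed, dtype=float)
    u1, u2, p = mann_whitney(x, y)
    u_report = min(u1, u2)
    delta = cliffs_delta_from_u(u_report, x.size, y.size)
    med_x, med_y = _median(x), _median(y)

    diff = med_y - med_x
    if diff == 0:
        ranks = stats.rankdata(np.concatenate([x, y]))
        diff = ranks[x.size:].mean() - ranks[: x.size].mean()
    if diff > 0:
        direction = DIRECTION_UP
    elif diff < 0:
        direction = DIRECTION_DOWN
    else:
        direction = DIRECTION_NONE

    return ComparisonResult(
        median_ungrazed=med_x,
        median_grazed=med_y,
        u1=u1,
        u2=u2,
        u_report=u_report,
        p_two_sided=p,
        delta=delta,
        delta_signed=cliffs_delta_signed(x, y),
        magnitude=magnitude_class(delta),
        direction=direction,
        significant=p < alpha,
    )
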