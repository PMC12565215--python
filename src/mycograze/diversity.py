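"""Alpha-diversity indices: Simpson's diversity, Pielou's evenness, Margalef's richness.

All three are computed from an abundance vector (species -> individual number
n_i, with N = sum n_i and S the number of species present):

* Div = 1 - sum (n_i/N)^2, in [0, 1]
* Eve = -sum[(n_i/N) ln(n_i/N)] / ln S, in [0, 1]; undefined (NaN) for S <= 1
* Ric = (S - 1) / ln N, >= 0; defined as 0 at N = 1

Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _clean(v) -> dict:
    if hasattr(v, "items"):
        items = dict(v)
    else:
        items = {i: n for i, n in enumerate(v)}
    items = {k: int(n) for k, n in items.items() if n}
    if any(n < 0 for n in items.values()):
        raise ValueError("abundances must be non-negative integers")
    if not items:
        raise ValueError("empty abundance vector")
    return items


def simpson_div(v) -> float:
    """Simpson's index of diversity, the probability that two randomly drawn
    individuals belong to different species."""
    items = _clean(v)
    n_total = sum(items.values())
    return 1.0 - sum((n / n_total) ** 2 for n in items.values())


def pielou_eve(v) -> float:
    """Pielou's evenness (Shannon entropy over ln S).  NaN when S <= 1."""
    items = _clean(v)
    s = len(items)
    if s <= 1:
        return math.nan
    n_total = sum(items.values())
    h = -sum((n / n_total) * math.log(n / n_total) for n in items.values())
    return h / math.log(s)


def margalef_ric(v) -> float:
    """Margalef's richness (S - 1)/ln N; 0 when N = 1 (which forces S = 1)."""
    items = _clean(v)
    n_total = sum(items.values())
    if n_total == 1:
        return 0.0
    return (len(items) - 1) / math.log(n_total)


@dataclass(frozen=True)
class DiversityProfile:
    """The three indices plus the N, S they were computed from."""

    div: float
    eve: float
    ric: float
    N: int
    S: int


def diversity_profile(v) -> DiversityProfile:
    items = _clean(v)
    return DiversityProfile(
        div=simpson_div(items),
        eve=pielou_eve(items),
        ric=margalef_ric(items),
        N=sum(items.values()),
        S=len(items),
    )
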