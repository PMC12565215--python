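"""Dominance (importance-value) index over species or trait partitions.

For a group j of species within one stratum the index averages the group's
occupancy share and abundance share:

    Dom_j = [ (q_j/Q) / sum_i(q_i/Q) + n_j/N ] / 2,   in [0, 100%]

where q_i is the number of sampling units occupied by species i, Q the total
number of units, n_i the individual number and N its total.  With group
occupancy taken additively over member species (q_j = sum of member q_i), the
values over any complete partition of the community sum to exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DOMINANCE_AXES = ("species", "order", "trophic", "attachment", "sporocarp", "geographic", "edibility")


@dataclass
class DominanceInput:
    """Per-species occupancy/abundance with a grouping over one classification axis.

    ``grouping`` maps species -> group label (identity for axis="species").
    ``presence_units`` (species -> set of occupied unit keys) is only required
    for the literal occupancy variant.
    """

    q: dict
    n: dict
    Q: int
    axis: str = "species"
    grouping: dict | None = None
    presence_units: dict | None = None

    def __post_init__(self):
        if set(self.q) != set(self.n):
            raise ValueError("q and n must cover the same species")
        if not self.q:
            raise ValueError("empty stratum")
        for sp, qi in self.q.items():
            if not 0 < qi <= self.Q:
                raise ValueError(f"q[{sp!r}]={qi} outside (0, Q={self.Q}]")
            if self.n[sp] < 1:
                raise ValueError(f"n[{sp!r}]={self.n[sp]} must be >= 1")
        if self.grouping is None:
            self.grouping = {sp: sp for sp in self.q}
        missing = set(self.q) - set(self.grouping)
        if missing:
            raise ValueError(f"species without a group on axis {self.axis!r}: {sorted(missing)}")

    @classmethod
    def from_counts(cls, counts, traits: pd.DataFrame | None = None, axis: str = "species"):
        """Build from a :class:`~mycograze.survey.StratumCounts` and a trait catalog."""
        if axis not in DOMINANCE_AXES:
            raise ValueError(f"axis must be one of {DOMINANCE_AXES}, got {axis!r}")
        grouping = None
        if axis != "species":
            if traits is None:
                raise ValueError(f"axis {axis!r} requires a trait catalog")
            table = traits.set_index("species")[axis]
            missing = set(counts.pooled) - set(table.index)
            if missing:
                raise ValueError(f"species missing from trait catalog: {sorted(missing)}")
            grouping = {sp: table[sp] for sp in counts.pooled}
        return cls(
            q=dict(counts.occupancy),
            n=dict(counts.pooled),
            Q=counts.Q,
            axis=axis,
            grouping=grouping,
            presence_units={sp: set(u) for sp, u in counts.presence_units.items()},
        )

    def members(self, group) -> list:
        return [sp for sp, g in self.grouping.items() if g == group]


def dominance_index(inp: DominanceInput, group, occupancy: str = "additive") -> float:
    """Dom_j for one group, as a percentage in [0, 100].

    ``occupancy="additive"`` (default) sums member q_i; ``"literal"`` counts
    units where any member occurs (requires presence_units) — under the literal
    reading complete partitions need not sum to 100%.
    """
    members = inp.members(group)
    if not members:
        raise ValueError(f"group {group!r} has no member species in this stratum")
    n_total = sum(inp.n.values())
    q_total = sum(inp.q.values())
    if n_total == 0 or q_total == 0:
        raise ValueError("stratum has no individuals or no occupancies")
    n_j = sum(inp.n[sp] for sp in members)
    if occupancy == "additive":
        q_j = sum(inp.q[sp] for sp in members)
    elif occupancy == "literal":
        if inp.presence_units is None:
            raise ValueError("literal occupancy requires presence_units")
        q_j = len(set().union(*(inp.presence_units[sp] for sp in members)))
    else:
        raise ValueError(f"occupancy must be 'additive' or 'literal', got {occupancy!r}")
    return 100.0 * (q_j / q_total + n_j / n_total) / 2.0


@dataclass
class DominanceTable:
    """Ranked dominance values for the groups of one axis in one stratum."""

    axis: str
    table: pd.DataFrame  # columns: rank, group, dominance_pct, tied
    tied_ranks: list = field(default_factory=list)

    def render(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["dominance_pct"] = out["dominance_pct"].round(decimals)
        return out


def dominance_table(inp: DominanceInput, k: int = 3, occupancy: str = "additive") -> DominanceTable:
    """Top-k dominance table; exact ties share a rank and extend the list.

    Ranking uses unrounded values; ties are broken for display by group label
    but flagged as joint ranks.
    """
    groups = sorted(set(inp.grouping[sp] for sp in inp.q))
    values = {g: dominance_index(inp, g, occupancy=occupancy) for g in groups}
    ordered = sorted(groups, key=lambda g: (-values[g], str(g)))

    rows = []
    tied_ranks = []
    rank = 0
    prev = None
    for pos, g in enumerate(ordered, start=1):
        if prev is None or values[g] != prev:
            rank = pos
        rows.append({"rank": rank, "group": g, "dominance_pct": values[g]})
        prev = values[g]
    df = pd.DataFrame(rows)
    counts = df["rank"].value_counts()
    df["tied"] = df["rank"].map(counts).gt(1)
    tied_ranks = sorted(counts[counts > 1].index)
    if k is not None and len(df) > k:
        # keep the top k rows, extending through rank ties at the boundary
        cutoff_rank = df.iloc[k - 1]["rank"]
        df = df[df["rank"] <= cutoff_rank]
    return DominanceTable(axis=inp.axis, table=df.reset_index(drop=True), tied_ranks=tied_ranks)
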