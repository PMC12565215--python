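"""Convert conspecific sporocarp point patterns into individual-number codes.

Sporocarps of one species within one sampling unit are grouped by
single-linkage clustering: pairs chained by steps of at most the separation
distance (default 2 m) form one group, anything farther is another individual.
Each group is then coded 1-4 by how tightly its members are chained:

==== =======================================================
code within-group adjacency (largest connecting step, meters)
==== =======================================================
1    single sporocarp
2    <= 0.5
3    <= 1
4    <= 2
==== =======================================================

The species' individual number for the unit is the sum of group codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

DEFAULT_SEPARATION = 2.0
# inclusive upper bounds on the within-group adjacency gap for codes 2, 3, 4
CODE_GAPS = ((2, 0.5), (3, 1.0), (4, 2.0))


@dataclass(frozen=True)
class SporocarpPoint:
    """One sporocarp at local (x, y) meters within its subquadrat."""

    species_id: str
    unit_key: str
    x: float
    y: float


@dataclass(frozen=True)
class IndividualCode:
    """A coded sporocarp group: member count, code 1-4, largest adjacency gap."""

    members: int
    code: int
    max_gap: float


def _as_coords(points) -> np.ndarray:
    coords = np.asarray(
        [(p.x, p.y) if isinstance(p, SporocarpPoint) else tuple(p) for p in points],
        dtype=float,
    )
    if coords.size and not np.isfinite(coords).all():
        raise ValueError("sporocarp coordinates must be finite")
    return coords


def _gap_code(gap: float) -> int:
    for code, bound in CODE_GAPS:
        if gap <= bound:
            return code
    raise ValueError(f"within-group gap {gap} exceeds the separation threshold")


def cluster_individuals(points, separation: float = DEFAULT_SEPARATION):
    """Group conspecific sporocarps of one unit and code each group.

    Single-linkage clusters are cut at ``separation`` (steps <= separation
    chain points into one group; > separation splits).  Within a group the
    adjacency gap is the largest step needed to connect all members (the
    maximum edge of the group's minimum spanning tree); it maps to the code
    via the inclusive 0.5 / 1 / 2 m bounds.
    """
    coords = _as_coords(points)
    n = len(coords)
    if n == 0:
        raise ValueError("cluster_individuals requires at least one point")
    if n == 1:
        return [IndividualCode(members=1, code=1, max_gap=0.0)]

    labels = fcluster(linkage(coords, method="single"), t=separation, criterion="distance")
    dmat = squareform(pdist(coords))
    codes = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) == 1:
            codes.append(IndividualCode(members=1, code=1, max_gap=0.0))
            continue
        sub = dmat[np.ix_(idx, idx)]
        mst = minimum_spanning_tree(sub)
        gap = float(mst.toarray().max())
        codes.append(IndividualCode(members=len(idx), code=_gap_code(gap), max_gap=gap))
    return codes


def individual_number(points, separation: float = DEFAULT_SEPARATION, combine: str = "sum") -> int:
    """Estimated individual number for one species in one unit.

    ``combine="sum"`` (default) adds the codes of all groups; ``combine="max"``
    keeps only the largest group's code.
    """
    codes = cluster_individuals(points, separation=separation)
    values = [c.code for c in codes]
    if combine == "sum":
        return int(sum(values))
    if combine == "max":
        return int(max(values))
    raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")


def observations_from_points(points, combine: str = "sum"):
    """Aggregate a list of :class:`SporocarpPoint` into long observation records.

    Returns a list of dicts with keys unit, species, individual_number, one per
    (unit, species) pair, suitable for building an observation table.
    """
    groups: dict = {}
    for p in points:
        groups.setdefault((p.unit_key, p.species_id), []).append(p)
    return [
        {
            "unit": unit,
            "species": sp,
            "individual_number": individual_number(pts, combine=combine),
        }
        for (unit, sp), pts in sorted(groups.items())
    ]
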