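"""Spore-measurement summaries in the mycological range notation.

A batch of spore measurements (recorded on a 0.5 µm grid by default) is
summarized as

    {a/b/c} (d) e–f (g) [h ± i, j]

where a spores from b sporocarps in c collections were measured, the closed
interval e–f covers at least 90% of the values, d/g are the extreme minimum
and maximum (printed only when they fall outside e–f), h is the arithmetic
mean, i the sample standard deviation and j the mode.  The per-spore
length/width shape ratio (Q) is summarized the same way without grid snapping.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mycograze.comparison import round_half_away

EN_DASH = "–"
PLUS_MINUS = "±"


class NotationParseError(ValueError):
    """Raised when a notation string is malformed; carries the failing position."""

    def __init__(self, message, position):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class NotationSummary:
    """The parsed/derived components of one notation instance (µm or unitless)."""

    a: int  # spores measured
    b: int  # sporocarps
    c: int  # collections
    d: float  # minimum extreme
    e: float  # lower bound of the >=90% interval
    f: float  # upper bound of the >=90% interval
    g: float  # maximum extreme
    h: float  # mean (2 d.p.)
    i: float  # sample SD (2 d.p.)
    j: float  # mode

    def __post_init__(self):
        if not (self.d <= self.e <= self.f <= self.g):
            raise ValueError(f"require d <= e <= f <= g, got {self.d}, {self.e}, {self.f}, {self.g}")
        if self.i < 0:
            raise ValueError("standard deviation must be >= 0")


def _snap(value: float, grid: float, up: bool) -> float:
    steps = value / grid
    k = math.ceil(round(steps, 9)) if up else math.floor(round(steps, 9))
    return round(k * grid, 10)


def _bounds(vs: np.ndarray, coverage: float, grid, mode: str):
    """Choose [e, f] covering >= coverage of the sorted values.

    ``symmetric``: trim an equal count from both tails, snap outward to the
    grid.  ``optimal``: the minimal-width grid-aligned interval that still
    covers, ties broken toward symmetry then the smaller lower bound.
    """
    n = len(vs)
    allowed = n - math.ceil(coverage * n)

    def lo(v):
        return v if grid is None else _snap(v, grid, up=False)

    def hi(v):
        return v if grid is None else _snap(v, grid, up=True)

    if mode == "symmetric":
        k = allowed // 2
        return lo(vs[k]), hi(vs[n - 1 - k])
    if mode != "optimal":
        raise ValueError(f"mode must be 'symmetric' or 'optimal', got {mode!r}")

    best = None
    for drop_lo in range(allowed + 1):
        e = lo(vs[drop_lo])
        below = int(np.searchsorted(vs, e, side="left"))
        room = allowed - below
        f = hi(vs[n - 1 - room]) if room >= 0 else hi(vs[-1])
        above = n - int(np.searchsorted(vs, f, side="right"))
        if below + above > allowed:
            continue
        key = (f - e, abs(below - above), e)
        if best is None or key < best[0]:
            best = (key, e, f)
    _, e, f = best
    return e, f


def summarize(
    values,
    coverage: float = 0.90,
    grid: float | None = 0.5,
    a: int | None = None,
    b: int = 1,
    c: int = 1,
    mode: str = "symmetric",
) -> NotationSummary:
    """Summarize raw measurements into the range notation.

    e and f are trimmed-range bounds snapped outward to the recording grid so
    that [e, f] holds at least ``coverage`` of the values; d/g are the extremes;
    the mean and sample SD are reported to 2 d.p.; the mode is the most
    frequent grid value (smallest on ties).
    """
    vs = np.sort(np.asarray(values, dtype=float))
    if vs.size < 2:
        raise ValueError("summarize requires at least 2 values")
    if np.any(vs <= 0):
        raise ValueError("measurements must be positive")
    e, f = _bounds(vs, coverage, grid, mode)
    tallied = vs if grid is not None else np.round(vs, 2)
    counts = Counter(tallied.tolist())
    top = max(counts.values())
    j = min(v for v, k in counts.items() if k == top)
    # extremes are reported at grid resolution, like the bounds
    d = float(vs[0]) if grid is None else _snap(float(vs[0]), grid, up=False)
    g = float(vs[-1]) if grid is None else _snap(float(vs[-1]), grid, up=True)
    return NotationSummary(
        a=int(a if a is not None else vs.size),
        b=int(b),
        c=int(c),
        d=d,
        e=float(e),
        f=float(f),
        g=g,
        h=round_half_away(float(vs.mean()), 2),
        i=round_half_away(float(vs.std(ddof=1)), 2),
        j=float(j),
    )


def _fmt_bound(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_notation(s: NotationSummary) -> str:
    """Render ``{a/b/c} (d) e–f (g) [h ± i, j]``; extremes only when outside e–f."""
    parts = [f"{{{s.a}/{s.b}/{s.c}}}"]
    if s.d < s.e:
        parts.append(f"({_fmt_bound(s.d)})")
    parts.append(f"{_fmt_bound(s.e)}{EN_DASH}{_fmt_bound(s.f)}")
    if s.g > s.f:
        parts.append(f"({_fmt_bound(s.g)})")
    parts.append(f"[{s.h:.2f} {PLUS_MINUS} {s.i:.2f}, {s.j:.2f}]")
    return " ".join(parts)


_TOKENS = [
    ("header", re.compile(r"\{(\d+)/(\d+)/(\d+)\}\s*")),
    ("d", re.compile(r"(?:\((\d+(?:\.\d+)?)\)\s*)?")),
    ("ef", re.compile(rf"(\d+(?:\.\d+)?)\s*[{EN_DASH}—-]\s*(\d+(?:\.\d+)?)")),
    ("g", re.compile(r"(?:\s*\((\d+(?:\.\d+)?)\))?")),
    ("hij", re.compile(rf"\s*\[(\d+(?:\.\d+)?)\s*(?:{PLUS_MINUS}|\+/?-)\s*(\d+(?:\.\d+)?),\s*(\d+(?:\.\d+)?)\]\s*$")),
]


def parse_notation(text: str) -> NotationSummary:
    """Parse a notation string back into its components.

    Extremes default to e/f when not printed.  Raises
    :class:`NotationParseError` with the failing position on malformed input.
    """
    pos = 0
    groups = {}
    for name, rx in _TOKENS:
        m = rx.match(text, pos)
        if m is None:
            raise NotationParseError(f"malformed notation near {text[pos:pos + 15]!r}", pos)
        groups[name] = m.groups()
        pos = m.end()
    if pos != len(text):
        raise NotationParseError(f"trailing text {text[pos:]!r}", pos)
    a, b, c = (int(x) for x in groups["header"])
    e, f = (float(x) for x in groups["ef"])
    d = float(groups["d"][0]) if groups["d"][0] is not None else e
    g = float(groups["g"][0]) if groups["g"][0] is not None else f
    h, i, j = (float(x) for x in groups["hij"])
    return NotationSummary(a=a, b=b, c=c, d=d, e=e, f=f, g=g, h=h, i=i, j=j)


@dataclass
class MeasurementSet:
    """Paired per-spore lengths/widths with sporocarp and collection provenance."""

    lengths: list
    widths: list
    sporocarp_ids: list
    collection_ids: list
    grid: float = 0.5

    def __post_init__(self):
        n = len(self.lengths)
        if not (len(self.widths) == len(self.sporocarp_ids) == len(self.collection_ids) == n):
            raise ValueError("lengths, widths, sporocarp_ids, collection_ids must align")
        if any(v <= 0 for v in self.lengths) or any(v <= 0 for v in self.widths):
            raise ValueError("lengths and widths must be positive")

    @property
    def a(self) -> int:
        return len(self.lengths)

    @property
    def b(self) -> int:
        return len(set(self.sporocarp_ids))

    @property
    def c(self) -> int:
        return len(set(self.collection_ids))

    def _summary(self, values, grid, mode):
        return summarize(values, grid=grid, a=self.a, b=self.b, c=self.c, mode=mode)

    def length_summary(self, mode: str = "symmetric") -> NotationSummary:
        return self._summary(self.lengths, self.grid, mode)

    def width_summary(self, mode: str = "symmetric") -> NotationSummary:
        return self._summary(self.widths, self.grid, mode)

    def describe(self, mode: str = "symmetric") -> str:
        """Full printed description: length x width µm, Q = ratio."""
        return (
            f"{format_notation(self.length_summary(mode))} × "
            f"{format_notation(self.width_summary(mode))[len(f'{{{self.a}/{self.b}/{self.c}}} '):]} µm, "
            f"Q = {format_notation(shape_ratio(self, mode))[len(f'{{{self.a}/{self.b}/{self.c}}} '):]}"
        )


def shape_ratio(mset: MeasurementSet, mode: str = "symmetric") -> NotationSummary:
    """Summary of per-spore length/width ratios (Q), reported to 2 d.p. without
    grid snapping."""
    widths = np.asarray(mset.widths, dtype=float)
    if np.any(widths == 0):
        raise ValueError("spore width must be nonzero")
    ratios = np.round(np.asarray(mset.lengths, dtype=float) / widths, 2)
    return summarize(ratios, grid=None, a=mset.a, b=mset.b, c=mset.c, mode=mode)


def read_measurements(path, delimiter=None) -> MeasurementSet:
    """Read a measurements CSV (collection, sporocarp, length_um, width_um)."""
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    df = pd.read_csv(path, sep=sep)
    for col in ("collection", "sporocarp", "length_um", "width_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return MeasurementSet(
        lengths=df["length_um"].astype(float).tolist(),
        widths=df["width_um"].astype(float).tolist(),
        sporocarp_ids=df["sporocarp"].tolist(),
        collection_ids=df["collection"].tolist(),
    )
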