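"""Sector-level aggregation of an organization network and fourfold
connection-strength coding.

The organization-level adjacency is collapsed onto the roster's sector
partition: for each unordered pair of distinct sectors A ≠ B, the fraction
of realized ties among the |A|·|B| possible cross-pairs; for each sector A,
the within-sector fraction over |A|·(|A|−1)/2 pairs (reported separately —
the sector diagram shows between-sector connections).

Fractions are binned into a fourfold strength code:

====================  ====  ===================
fraction of possible  code  reading
====================  ====  ===================
[0, 0.2)              0     no relation
[0.2, 0.4)            1     weak connection
[0.4, 0.6)            2     average connection
[0.6, 1]              3     strong connection
====================  ====  ===================

The bin edges are half-open with exact boundaries taking the higher code
("at least 60%" is a strong connection, so 20%/40%/60% round up); the
choice is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .build import Adjacency
from .errors import DataError, ValidationError
from .ingest import Roster

#: Lower bin edges of the strength coding (upper boundary inclusive at 1).
STRENGTH_EDGES = (0.0, 0.2, 0.4, 0.6)
STRENGTH_LABELS = {0: "none", 1: "weak", 2: "average", 3: "strong"}
BOUNDARY_RULE = "half-open; exact boundaries 0.2/0.4/0.6 take the higher code"


def code_strength(fraction: float) -> int:
    """Map a tie fraction in [0, 1] to the 0–3 connection-strength code."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    code = 0
    for c, edge in enumerate(STRENGTH_EDGES):
        if fraction >= edge:
            code = c
    return code


@dataclass(frozen=True)
class SectorGraph:
    """Sector-pair tie fractions and strength codes for one network × layer.

    ``between`` has one row per unordered pair of distinct sectors,
    ``within`` one row per sector; both carry possible/present counts, the
    realized fraction and the strength code.
    """

    sectors: tuple[str, ...]
    between: pd.DataFrame
    within: pd.DataFrame
    layer: str

    def edges(self, min_strength: int = 1, include_within: bool = False) -> pd.DataFrame:
        """Sector pairs at or above ``min_strength`` (the diagram's edge set)."""
        frames = [self.between]
        if include_within:
            w = self.within.rename(columns={"sector": "sector_a"})
            w = w.assign(sector_b=w["sector_a"])
            frames.append(w[self.between.columns])
        table = pd.concat(frames, ignore_index=True)
        return table[table["strength"] >= min_strength].reset_index(drop=True)

    def total_present(self) -> int:
        """Σ present over all pairs incl. within-sector; equals the network's
        undirected edge count (tie conservation)."""
        return int(self.between["present"].sum() + self.within["present"].sum())

    def to_csv(self, path) -> None:
        w = self.within.rename(columns={"sector": "sector_a"})
        w = w.assign(sector_b=w["sector_a"])
        table = pd.concat([self.between, w[self.between.columns]], ignore_index=True)
        table = table.assign(boundary_rule=BOUNDARY_RULE)
        table.to_csv(path, index=False)

    def to_dot(self, path=None, min_strength: int = 1) -> str:
        """Graphviz DOT with edge width/shade encoding connection strength."""
        widths = {1: 1.0, 2: 2.5, 3: 4.5}
        greys = {1: "grey70", 2: "grey45", 3: "grey10"}
        lines = [f'graph "{self.layer}" {{', "  node [shape=box];"]
        for s in self.sectors:
            lines.append(f'  "{s}";')
        for rec in self.edges(min_strength=min_strength).itertuples(index=False):
            lines.append(
                f'  "{rec.sector_a}" -- "{rec.sector_b}" '
                f'[penwidth={widths[rec.strength]}, color={greys[rec.strength]}, '
                f'label="{rec.strength}"];'
            )
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def aggregate_to_sectors(adj: Adjacency, roster: Roster) -> SectorGraph:
    """Collapse an organization adjacency onto the roster's sector partition.

    Counts are over organization pairs with distinct members; sectors with no
    organization in the network do not appear.  Requires at least two
    distinct sectors.
    """
    orgs = {o.org_id: o for o in roster}
    try:
        sector_of = np.array([orgs[i].sector for i in adj.org_ids])
    except KeyError as exc:
        raise DataError(f"organization {exc.args[0]!r} has no roster entry/sector") from exc
    sectors = tuple(dict.fromkeys(sector_of))  # first-appearance order
    if len(sectors) < 2:
        raise DataError("sector aggregation needs at least 2 sectors present")

    members = {s: np.flatnonzero(sector_of == s) for s in sectors}
    m = adj.matrix
    between_rows = []
    for a_pos, a in enumerate(sectors):
        for b in sectors[a_pos + 1:]:
            ia, ib = members[a], members[b]
            possible = len(ia) * len(ib)
            present = int(m[np.ix_(ia, ib)].sum())
            fraction = present / possible
            between_rows.append(
                {
                    "sector_a": a,
                    "sector_b": b,
                    "possible": possible,
                    "present": present,
                    "fraction": fraction,
                    "strength": code_strength(fraction),
                }
            )
    within_rows = []
    for s in sectors:
        ia = members[s]
        possible = len(ia) * (len(ia) - 1) // 2
        present = int(np.triu(m[np.ix_(ia, ia)], k=1).sum())
        fraction = present / possible if possible else 0.0
        within_rows.append(
            {
                "sector": s,
                "possible": possible,
                "present": present,
                "fraction": fraction,
                "strength": code_strength(fraction),
            }
        )
    return SectorGraph(
        sectors,
        pd.DataFrame(between_rows),
        pd.DataFrame(within_rows),
        adj.layer,
    )
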