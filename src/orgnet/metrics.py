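"""Whole-network integration metrics and degree centralities.

All quantities are computed directly from the symmetric 0/1 adjacency with
numpy arithmetic — no graph library sits in the computation path, so every
definition is exactly the one stated here:

* **ties** are counted as ordered pairs (i, j), i ≠ j, with adj[i, j] = 1,
  i.e. twice the number of undirected edges.  This is the convention under
  which the standard panel identities hold: density = ties / (n·(n−1)) and
  average degree = ties / n.
* **density** — realized ties over possible ties, in [0, 1].
* **average degree centrality** — mean number of connections per organization.
* **isolates / active organizations** — organizations with zero / nonzero
  degree; the active percentage is rounded half-up to an integer.
* **degree centralization** — Freeman's index for undirected graphs,
  Σᵢ (d_max − dᵢ) / ((n−1)(n−2)), which is 0 for any regular graph and 1
  for a star.  Isolates are included in n.
* **degree centrality** per organization, normalized by n−1.

Rounding happens only at reporting time (density 3 dp, average degree 2 dp,
centralization 2–3 dp, percentages to integers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .build import Adjacency
from .errors import UndefinedMetricError, ValidationError
from .ingest import Roster


def _as_matrix(adj) -> np.ndarray:
    """Accept an :class:`Adjacency` or a raw square array; validate shape."""
    m = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"adjacency must be square, got shape {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("adjacency entries must be 0/1")
    if (m != m.T).any():
        raise ValidationError("adjacency must be symmetric")
    if np.diagonal(m).any():
        raise ValidationError("adjacency has a nonzero diagonal")
    return m


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def count_ties(adj) -> int:
    """Number of ordered pairs (i, j), i ≠ j, with a tie (2 × undirected edges)."""
    return int(_as_matrix(adj).sum())


def density(adj) -> float:
    """Realized ties divided by the n·(n−1) possible ordered pairs."""
    m = _as_matrix(adj)
    n = m.shape[0]
    if n < 2:
        raise UndefinedMetricError("density is undefined for networks with fewer than 2 nodes")
    return float(m.sum() / (n * (n - 1)))


def average_degree(adj) -> float:
    """Mean number of connections per organization (= ties / n)."""
    m = _as_matrix(adj)
    n = m.shape[0]
    if n == 0:
        raise UndefinedMetricError("average degree is undefined for an empty network")
    return float(m.sum() / n)


def degrees(adj) -> np.ndarray:
    """Undirected degree per organization (row sums)."""
    return _as_matrix(adj).sum(axis=1).astype(int)


def isolates_and_active(adj) -> tuple[int, int, int]:
    """(isolates, active organizations, active percentage rounded to integer)."""
    d = degrees(adj)
    n = len(d)
    isolates = int((d == 0).sum())
    active = n - isolates
    pct = _round_half_up(100.0 * active / n) if n else 0
    return isolates, active, pct


def degree_centralization(adj) -> float:
    """Freeman degree centralization: Σᵢ (d_max − dᵢ) / ((n−1)(n−2))."""
    d = degrees(adj)
    n = len(d)
    if n < 3:
        raise UndefinedMetricError(
            "degree centralization is undefined for networks with fewer than 3 nodes"
        )
    return float((d.max() - d).sum() / ((n - 1) * (n - 2)))


@dataclass(frozen=True)
class NodeCentrality:
    org_id: str
    degree: int
    normalized_degree: float


def degree_centrality(adj) -> list[NodeCentrality]:
    """Per-organization degree and degree/(n−1), sorted by (−degree, org_id)."""
    m = _as_matrix(adj)
    n = m.shape[0]
    if n < 2:
        raise UndefinedMetricError("degree centrality needs at least 2 nodes")
    if isinstance(adj, Adjacency):
        ids = adj.org_ids
    else:
        ids = tuple(str(i) for i in range(n))
    d = m.sum(axis=1).astype(int)
    out = [NodeCentrality(ids[i], int(d[i]), d[i] / (n - 1)) for i in range(n)]
    out.sort(key=lambda c: (-c.degree, c.org_id))
    return out


def top_k_central(adj: Adjacency, roster: Roster, k: int) -> pd.DataFrame:
    """Table of the k most-connected organizations with sector/task annotation.

    Gatekeeper organizations are flagged, mirroring the ranked central-actor
    tables used to check whether the legally designated referral gatekeepers
    actually hold central positions.  Ties in degree are broken by org_id.
    """
    if k > adj.n:
        raise ValidationError(f"k={k} exceeds network size {adj.n}")
    orgs = {o.org_id: o for o in roster}
    rows = []
    for rank, c in enumerate(degree_centrality(adj)[:k], start=1):
        org = orgs.get(c.org_id)
        if org is None:
            raise ValidationError(f"organization {c.org_id!r} missing from roster")
        rows.append(
            {
                "rank": rank,
                "org_id": c.org_id,
                "name": org.name,
                "sector": org.sector,
                "tasks": ";".join(sorted(org.tasks)),
                "gatekeeper": "gatekeeper" in org.tasks,
                "degree": c.degree,
                "normalized_degree": c.normalized_degree,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetricsPanel:
    """The integration panel for one network × layer.

    Satisfies the arithmetic identities
    ``density == ties_ordered / (n_orgs·(n_orgs−1))`` and
    ``avg_degree == ties_ordered / n_orgs`` exactly (rounding is applied
    only when rendering).
    """

    n_orgs: int
    n_sectors: int
    active_orgs: int
    active_pct: int
    isolates: int
    ties_ordered: int
    density: float
    avg_degree: float
    centralization: float

    def identities_hold(self, tol: float = 1e-12) -> bool:
        return (
            self.active_orgs + self.isolates == self.n_orgs
            and self.ties_ordered % 2 == 0
            and abs(self.density * self.n_orgs * (self.n_orgs - 1) - self.ties_ordered) < tol
            and abs(self.avg_degree * self.n_orgs - self.ties_ordered) < tol
        )

    def rounded(self) -> dict[str, object]:
        """Report-precision rendering: density 3 dp, avg degree 2 dp,
        centralization 3 dp, percentage integer."""
        return {
            "n_orgs": self.n_orgs,
            "n_sectors": self.n_sectors,
            "active_orgs": self.active_orgs,
            "active_pct": self.active_pct,
            "isolates": self.isolates,
            "ties_ordered": self.ties_ordered,
            "density": round(self.density, 3),
            "avg_degree": round(self.avg_degree, 2),
            "centralization": round(self.centralization, 3),
        }


def compute_panel(adj: Adjacency, roster: Roster | None = None) -> MetricsPanel:
    """Assemble the full integration panel for one adjacency.

    ``n_sectors`` counts the sectors present on the roster (0 when no roster
    is supplied, e.g. for bare matrices read from CSV).
    """
    isolates, active, pct = isolates_and_active(adj)
    return MetricsPanel(
        n_orgs=adj.n,
        n_sectors=len(roster.sectors()) if roster is not None else 0,
        active_orgs=active,
        active_pct=pct,
        isolates=isolates,
        ties_ordered=count_ties(adj),
        density=density(adj),
        avg_degree=average_degree(adj),
        centralization=degree_centralization(adj),
    )
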