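"""From directed report matrices to analysis-ready symmetric adjacencies.

Two operations, applied in pipeline order:

1. **Labeled reconstruction** of nonresponse: a nonrespondent's outgoing-tie
   row is filled with the incoming reports of respondents about it (the
   transpose of its column).  A tie between two nonrespondents is
   unrecoverable and stays 0.
2. **Union ("any link") symmetrization**: an undirected tie exists if either
   party reported it — adj[i, j] = max(report[i, j], report[j, i]).

For this union rule the two operations commute (reconstruction only copies
values across the diagonal, and the elementwise max is insensitive to which
side carries the 1); a property test asserts that coincidence.

Cell provenance is tracked on the result: a cell is *observed* when at least
one of its endpoints responded (so some respondent could have reported it)
and *reconstructed-unrecoverable* when neither did, which lets reports state
the share of dyads the survey could not see at all.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ingest import ReportMatrix, Roster, write_square_csv


@dataclass(frozen=True)
class Adjacency:
    """Symmetric 0/1 organization network for one relational layer.

    ``observed[i, j]`` is True when at least one of i, j responded to the
    survey; off-diagonal cells with ``observed == False`` are fixed at 0 by
    construction (both endpoints silent).
    """

    org_ids: tuple[str, ...]
    matrix: np.ndarray
    layer: str
    observed: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        n = len(self.org_ids)
        if m.shape != (n, n):
            raise ValidationError(f"adjacency shape {m.shape} does not match index size {n}")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        if (m != m.T).any():
            raise ValidationError("adjacency must be symmetric")
        if np.diagonal(m).any():
            raise ValidationError("adjacency has a nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.org_ids)

    def reconstructed_share(self) -> float:
        """Fraction of off-diagonal unordered dyads invisible to the survey
        (neither endpoint responded)."""
        n = self.n
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float((~self.observed[iu]).sum() / len(iu[0]))


def labeled_reconstruction(report: ReportMatrix) -> ReportMatrix:
    """Fill nonrespondents' rows from respondents' incoming reports.

    For every organization i with ``responded[i] == False``, row i is
    replaced by column i restricted to responding reporters:
    ``row_i[j] = report[j][i]`` if j responded, else 0.  Responding rows are
    unchanged.  Filled rows are flagged in ``reconstructed_rows``.
    """
    m = report.matrix.copy()
    responded = report.responded
    missing = ~responded
    # column i restricted to responding reporters, transposed into row i
    incoming = (m * responded[:, None]).T
    m[missing, :] = incoming[missing, :]
    np.fill_diagonal(m, 0)
    return ReportMatrix(
        report.org_ids, m, responded, report.layer, reconstructed_rows=missing.copy()
    )


def symmetrize_union(report: ReportMatrix) -> Adjacency:
    """Union ("any link") symmetrization: adj = elementwise max(report, reportᵀ)."""
    m = np.asarray(report.matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("symmetrization requires a binary report matrix")
    adj = np.maximum(m, m.T).astype(np.int8)
    np.fill_diagonal(adj, 0)
    responded = report.responded
    observed = responded[:, None] | responded[None, :]
    return Adjacency(report.org_ids, adj, report.layer, observed)


def build_adjacency(report: ReportMatrix) -> Adjacency:
    """Pipeline composition: labeled reconstruction, then union symmetrization."""
    return symmetrize_union(labeled_reconstruction(report))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_adjacency_csv(adj: Adjacency, path) -> None:
    write_square_csv(path, adj.org_ids, adj.matrix)


def edge_list(adj: Adjacency) -> pd.DataFrame:
    """Undirected edge list (each unordered tie once, source < target by index)."""
    src, dst = np.triu_indices(adj.n, k=1)
    present = adj.matrix[src, dst] == 1
    return pd.DataFrame(
        {
            "source": [adj.org_ids[i] for i in src[present]],
            "target": [adj.org_ids[j] for j in dst[present]],
        }
    )


def write_edge_list_csv(adj: Adjacency, path) -> None:
    edge_list(adj).to_csv(path, index=False)


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(adj: Adjacency, path, roster: Roster | None = None) -> None:
    """Write the undirected network as GraphML, optionally with sector and
    task node attributes for external viewers."""
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    keys = {"sector": "d0", "tasks": "d1"}
    if roster is not None:
        for attr, kid in keys.items():
            key = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key", id=kid)
            key.set("for", "node")
            key.set("attr.name", attr)
            key.set("attr.type", "string")
    graph = ET.SubElement(
        root, f"{{{_GRAPHML_NS}}}graph", id=adj.layer, edgedefault="undirected"
    )
    orgs = {o.org_id: o for o in roster} if roster is not None else {}
    for org_id in adj.org_ids:
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=org_id)
        org = orgs.get(org_id)
        if org is not None:
            for attr, kid in keys.items():
                data = ET.SubElement(node, f"{{{_GRAPHML_NS}}}data", key=kid)
                data.text = org.sector if attr == "sector" else ";".join(sorted(org.tasks))
    for rec in edge_list(adj).itertuples(index=False):
        ET.SubElement(
            graph, f"{{{_GRAPHML_NS}}}edge", source=rec.source, target=rec.target
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def adjacency_from_matrix(
    org_ids: Sequence[str], matrix: np.ndarray, layer: str = "contact"
) -> Adjacency:
    """Wrap a fully observed symmetric 0/1 matrix as an :class:`Adjacency`."""
    n = len(org_ids)
    observed = np.ones((n, n), dtype=bool)
    return Adjacency(tuple(org_ids), np.asarray(matrix, dtype=np.int8), layer, observed)
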