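"""Survey ingestion: rosters, respondent-level tie reports and their collapse
to organization-level report matrices.

The unit of observation in a whole-network survey is the *boundary spanner* —
an employee answering for their organization.  The unit of analysis is the
organization.  This module reads the roster (one row per organization, with
sector, task and respondent metadata), the respondent-level tie reports (one
row per claimed tie per relational layer) and the response records (which
respondents returned the questionnaire at all), applies boundary filters, and
collapses respondents to a directed organization-by-organization 0/1 report
matrix with an explicit responded/missing row mask.

An organization counts as *responding* when at least one of its boundary
spanners returned the questionnaire; a response with zero reported ties is
therefore distinguishable from nonresponse, which is why responses are
tracked separately from tie records.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

#: The closed set of organizational tasks.
TASKS = frozenset({"gatekeeper", "signaling", "providing_services"})

#: The closed set of relational layers.
LAYERS = ("contact", "referral")

_LIST_SEP = ";"


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Organization:
    """One network member.

    Parameters
    ----------
    org_id
        Unique token identifying the organization.
    name
        Human-readable name.
    sector
        Sector label (e.g. ``"specialized_youth_care"``).
    tasks
        Subset of :data:`TASKS`.
    attributes
        Numeric attributes, e.g. ``{"clients_2017": 12}``.
    respondent_ids
        Boundary spanners invited to answer for this organization.
    """

    org_id: str
    name: str
    sector: str
    tasks: frozenset[str] = frozenset()
    attributes: Mapping[str, float] = field(default_factory=dict)
    respondent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sector:
            raise ValidationError(f"organization {self.org_id!r} has an empty sector")
        unknown = set(self.tasks) - TASKS
        if unknown:
            raise ValidationError(
                f"organization {self.org_id!r} has unknown tasks {sorted(unknown)}"
            )


@dataclass(frozen=True)
class Roster:
    """An ordered collection of organizations with unique ids and respondents."""

    organizations: tuple[Organization, ...]

    def __post_init__(self) -> None:
        ids = [o.org_id for o in self.organizations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate org_ids on roster: {dupes}")
        resp = [r for o in self.organizations for r in o.respondent_ids]
        if len(set(resp)) != len(resp):
            dupes = sorted({r for r in resp if resp.count(r) > 1})
            raise ValidationError(f"respondent ids shared across organizations: {dupes}")

    def __len__(self) -> int:
        return len(self.organizations)

    def __iter__(self):
        return iter(self.organizations)

    @property
    def org_ids(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations)

    @property
    def index(self) -> dict[str, int]:
        return {o.org_id: i for i, o in enumerate(self.organizations)}

    def by_id(self, org_id: str) -> Organization:
        for o in self.organizations:
            if o.org_id == org_id:
                return o
        raise KeyError(org_id)

    def sectors(self) -> tuple[str, ...]:
        """Sector labels present, in first-appearance order."""
        seen: dict[str, None] = {}
        for o in self.organizations:
            seen.setdefault(o.sector, None)
        return tuple(seen)

    def respondent_to_org(self) -> dict[str, str]:
        return {r: o.org_id for o in self.organizations for r in o.respondent_ids}

    @property
    def respondent_ids(self) -> tuple[str, ...]:
        return tuple(r for o in self.organizations for r in o.respondent_ids)

    # -- frame / CSV interchange ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        attr_names = sorted({k for o in self.organizations for k in o.attributes})
        rows = []
        for o in self.organizations:
            row: dict[str, object] = {
                "org_id": o.org_id,
                "name": o.name,
                "sector": o.sector,
                "tasks": _LIST_SEP.join(sorted(o.tasks)),
                "respondent_ids": _LIST_SEP.join(o.respondent_ids),
            }
            for a in attr_names:
                row[a] = o.attributes.get(a, np.nan)
            rows.append(row)
        cols = ["org_id", "name", "sector", "tasks", "respondent_ids", *attr_names]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Roster":
        required = {"org_id", "name", "sector", "tasks", "respondent_ids"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"roster is missing columns {sorted(missing)}")
        attr_names = [c for c in frame.columns if c not in required]
        orgs = []
        for _, row in frame.iterrows():
            attrs = {
                a: float(row[a]) for a in attr_names if pd.notna(row[a])
            }
            orgs.append(
                Organization(
                    org_id=str(row["org_id"]),
                    name=str(row["name"]),
                    sector=str(row["sector"]),
                    tasks=frozenset(_split(row["tasks"])),
                    attributes=attrs,
                    respondent_ids=tuple(_split(row["respondent_ids"])),
                )
            )
        return cls(tuple(orgs))

    @classmethod
    def from_csv(cls, path) -> "Roster":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def _split(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or pd.isna(cell):
        return []
    text = str(cell).strip()
    return [t for t in (p.strip() for p in text.split(_LIST_SEP)) if t]


# ---------------------------------------------------------------------------
# Tie reports
# ---------------------------------------------------------------------------

_REPORT_COLS = ["respondent_id", "reporter_org", "target_org", "layer"]


@dataclass(frozen=True)
class TieReportSet:
    """Respondent-level directed tie claims plus questionnaire response records.

    ``ties`` has one row per (respondent, reporter_org, target_org, layer);
    ``responded`` maps respondent_id -> bool and is the only place where an
    all-negative response (respondent answered, reported nothing) is encoded.
    """

    ties: pd.DataFrame
    responded: Mapping[str, bool]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, str]],
        responded: Mapping[str, bool] | None = None,
    ) -> "TieReportSet":
        frame = pd.DataFrame(list(records), columns=_REPORT_COLS)
        if responded is None:
            # Without response records, assume every reporting respondent
            # responded; nonresponse is then inferred from silence.
            responded = {r: True for r in frame["respondent_id"].unique()}
        return cls(frame, dict(responded))

    def __len__(self) -> int:
        return len(self.ties)

    def layer(self, layer: str) -> pd.DataFrame:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        return self.ties[self.ties["layer"] == layer]

    def validate(self, roster: Roster) -> None:
        """Check every record against the roster; raise :class:`DataError` on the first violation."""
        if list(self.ties.columns) != _REPORT_COLS:
            raise DataError(f"tie reports must have columns {_REPORT_COLS}")
        org_ids = set(roster.org_ids)
        resp_org = roster.respondent_to_org()
        bad_layer = set(self.ties["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown layer labels {sorted(bad_layer)}")
        for rec in self.ties.itertuples(index=False):
            if rec.reporter_org == rec.target_org:
                raise ValidationError(
                    f"self-report by {rec.respondent_id}: {rec.reporter_org} -> itself"
                )
            for org in (rec.reporter_org, rec.target_org):
                if org not in org_ids:
                    raise DataError(f"report names organization {org!r} absent from the roster")
            if resp_org.get(rec.respondent_id) != rec.reporter_org:
                raise DataError(
                    f"respondent {rec.respondent_id!r} does not belong to {rec.reporter_org!r}"
                )
            if not self.responded.get(rec.respondent_id, False):
                raise DataError(
                    f"respondent {rec.respondent_id!r} has tie records but no response record"
                )

    def restrict(self, roster: Roster) -> "TieReportSet":
        """Drop records referencing organizations absent from ``roster``.

        Used after boundary/threshold filtering, where dangling references are
        expected rather than erroneous.
        """
        org_ids = set(roster.org_ids)
        keep = self.ties["reporter_org"].isin(org_ids) & self.ties["target_org"].isin(org_ids)
        respondents = set(roster.respondent_ids)
        responded = {r: v for r, v in self.responded.items() if r in respondents}
        return TieReportSet(self.ties[keep].reset_index(drop=True), responded)

    # -- CSV interchange ---------------------------------------------------

    def to_csv(self, ties_path, responses_path=None) -> None:
        self.ties.to_csv(ties_path, index=False)
        if responses_path is not None:
            frame = pd.DataFrame(
                sorted((r, int(v)) for r, v in self.responded.items()),
                columns=["respondent_id", "responded"],
            )
            frame.to_csv(responses_path, index=False)

    @classmethod
    def from_csv(cls, ties_path, responses_path=None) -> "TieReportSet":
        ties = pd.read_csv(ties_path, dtype=str)
        missing = set(_REPORT_COLS) - set(ties.columns)
        if missing:
            raise DataError(f"tie report file is missing columns {sorted(missing)}")
        ties = ties[_REPORT_COLS]
        responded = None
        if responses_path is not None:
            resp = pd.read_csv(responses_path, dtype={"respondent_id": str, "responded": int})
            if not {"respondent_id", "responded"} <= set(resp.columns):
                raise DataError("responses file needs columns respondent_id, responded")
            responded = {
                str(r.respondent_id): bool(r.responded) for r in resp.itertuples(index=False)
            }
        return cls.from_records(
            ties.itertuples(index=False, name=None), responded=responded
        )


# ---------------------------------------------------------------------------
# Report matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportMatrix:
    """Directed organization-level 0/1 report matrix with a response mask.

    ``matrix[i, j] == 1`` means at least one respondent of organization ``i``
    reported a tie to organization ``j``.  ``responded[i]`` is False for
    organizations with no responding boundary spanner; such rows are all
    zeros until labeled reconstruction fills them.  ``reconstructed_rows``
    marks rows filled by reconstruction (all False on a freshly collapsed
    matrix).
    """

    org_ids: tuple[str, ...]
    matrix: np.ndarray
    responded: np.ndarray
    layer: str
    reconstructed_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        n = len(self.org_ids)
        if m.shape != (n, n):
            raise ValidationError(f"matrix shape {m.shape} does not match roster size {n}")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("report matrix entries must be 0/1")
        if np.diagonal(m).any():
            raise ValidationError("report matrix has nonzero diagonal")
        resp = np.asarray(self.responded, dtype=bool)
        if resp.shape != (n,):
            raise ValidationError("responded mask length does not match roster size")
        recon = self.reconstructed_rows
        unfilled = ~resp if recon is None else (~resp) & ~np.asarray(recon, dtype=bool)
        if m[unfilled].any():
            raise ValidationError("nonresponding (unreconstructed) rows must be all zero")

    @property
    def n(self) -> int:
        return len(self.org_ids)


def apply_threshold_filter(
    roster: Roster,
    attribute: str,
    minimum: float,
    sectors: Iterable[str],
) -> Roster:
    """Drop organizations in ``sectors`` whose ``attribute`` falls below ``minimum``.

    Mirrors boundary specification by caseload threshold: peripheral providers
    with very few clients in treatment are excluded from the network roster.
    Organizations outside the targeted sectors are untouched.  An organization
    in a targeted sector with the attribute missing is a data error (silent
    exclusion could mask a join problem upstream).
    """
    sectors = set(sectors)
    if not sectors:
        return roster
    kept = []
    for org in roster:
        if org.sector in sectors:
            if attribute not in org.attributes:
                raise DataError(
                    f"organization {org.org_id!r} in sector {org.sector!r} "
                    f"lacks attribute {attribute!r} required by the threshold filter"
                )
            if org.attributes[attribute] < minimum:
                continue
        kept.append(org)
    return Roster(tuple(kept))


def collapse_respondents(roster: Roster, reports: TieReportSet, layer: str) -> ReportMatrix:
    """Aggregate respondent-level reports to the organization level by logical OR.

    Cell (i, j) is 1 iff at least one boundary spanner of organization i
    reported a ``layer`` tie to organization j.  An organization is marked as
    responded iff at least one of its respondents returned the questionnaire,
    regardless of how many ties (possibly zero) they reported.
    """
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    reports.validate(roster)
    n = len(roster)
    idx = roster.index
    matrix = np.zeros((n, n), dtype=np.int8)
    for rec in reports.layer(layer).itertuples(index=False):
        matrix[idx[rec.reporter_org], idx[rec.target_org]] = 1
    np.fill_diagonal(matrix, 0)
    responded = np.zeros(n, dtype=bool)
    for org in roster:
        responded[idx[org.org_id]] = any(
            reports.responded.get(r, False) for r in org.respondent_ids
        )
    matrix[~responded, :] = 0  # defensive: validated reports cannot place ties here
    return ReportMatrix(roster.org_ids, matrix, responded, layer)


# ---------------------------------------------------------------------------
# Square adjacency CSV interchange
# ---------------------------------------------------------------------------

def write_square_csv(path, org_ids: Sequence[str], matrix: np.ndarray) -> None:
    """Write a square 0/1 matrix as CSV with org_id header row and column."""
    frame = pd.DataFrame(np.asarray(matrix, dtype=int), index=org_ids, columns=org_ids)
    frame.to_csv(path, index_label="org_id")


def read_square_csv(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a square CSV adjacency; returns (org_ids, matrix)."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise DataError("square CSV must have identical org_id row and column headers")
    matrix = frame.to_numpy()
    if not np.isin(matrix, (0, 1)).all():
        raise ValidationError("square CSV entries must be 0/1")
    return tuple(frame.index), matrix.astype(np.int8)
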