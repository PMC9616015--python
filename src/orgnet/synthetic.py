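"""Synthetic roster and tie-report generator.

Raw whole-network survey data on interorganizational service delivery
systems are essentially never deposited (respondent anonymity), so this
module generates rosters and respondent-level tie reports with the
statistical structure the downstream analysis assumes:

* 65–135 organizations across up to 11 sectors with a fixed sector→task map;
* a core–periphery contact layer drawn from a two-block Bernoulli graph,
  whose block probabilities put density in the empirically observed
  0.12–0.35 range and degree centralization in the 0.4–0.7 range;
* a client-referral layer that is an entrywise subset of the contact layer
  (a referral presupposes contact), obtained by independently retaining each
  contact tie;
* partial response (default 57% of organizations, within the observed
  52–68% band), drawn at the organization level because response rates are
  reported per organization;
* multi-respondent organizations in sectors whose boundary spanners have a
  limited working area (education, municipality, general practitioners,
  childcare), where each respondent observes each incident true tie
  imperfectly so OR-aggregation across respondents is exercised.

All randomness flows from ``SyntheticConfig.seed``; each generation stage
uses an independent stream derived from it, so stages are individually
deterministic.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ValidationError
from .ingest import Organization, Roster, TieReportSet

#: Sector → task assignment of the child service delivery system.
DEFAULT_TASK_ASSIGNMENT: dict[str, frozenset[str]] = {
    "center_youth_family": frozenset({"gatekeeper"}),
    "municipality": frozenset({"signaling"}),
    "basic_social": frozenset({"signaling", "providing_services"}),
    "education": frozenset({"signaling"}),
    "general_practitioners": frozenset({"gatekeeper"}),
    "health_prevention": frozenset({"signaling", "gatekeeper"}),
    "childcare_nursery": frozenset({"signaling", "providing_services"}),
    "specialized_youth_care": frozenset({"providing_services"}),
    "protection_rehabilitation": frozenset({"providing_services"}),
    "safety": frozenset({"signaling", "providing_services"}),
    "volunteer": frozenset({"signaling", "providing_services"}),
}

#: Default sector mix.  Specialized youth care dominates numerically (as in
#: real rosters, where most network members are specialized providers); the
#: center for youth and family is a single hub organization per network.
DEFAULT_SECTOR_WEIGHTS: dict[str, float] = {
    "center_youth_family": 0.01,
    "municipality": 0.05,
    "basic_social": 0.08,
    "education": 0.10,
    "general_practitioners": 0.06,
    "health_prevention": 0.03,
    "childcare_nursery": 0.08,
    "specialized_youth_care": 0.45,
    "protection_rehabilitation": 0.04,
    "safety": 0.06,
    "volunteer": 0.04,
}

#: Sectors whose boundary spanners cover only part of the municipality and
#: therefore get several respondents each.
DEFAULT_MULTI_RESPONDENT_SECTORS = frozenset(
    {"municipality", "education", "general_practitioners", "childcare_nursery"}
)

_STREAM_ROSTER, _STREAM_TRUTH, _STREAM_REPORTS = 11, 13, 17


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic survey.

    Defaults emulate a mid-sized network: 86 organizations, 11 sectors,
    57% organization-level response, a 15% core with dense internal and
    core–periphery ties, and 60% of contact ties carrying client referral.
    """

    n_orgs: int = 86
    sector_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_WEIGHTS)
    )
    task_assignment: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_TASK_ASSIGNMENT)
    )
    response_rate: float = 0.57
    hub_fraction: float = 0.15
    p_core_core: float = 0.9
    p_core_periphery: float = 0.7
    p_periphery_periphery: float = 0.1
    referral_retention: float = 0.6
    multi_respondent_sectors: frozenset[str] = DEFAULT_MULTI_RESPONDENT_SECTORS
    respondent_observation: float = 0.8
    report_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orgs < 2:
            raise ConfigurationError("n_orgs must be at least 2")
        if not self.sector_weights:
            raise ConfigurationError("sector_weights must name at least one sector")
        for name, p in (
            ("response_rate", self.response_rate),
            ("hub_fraction", self.hub_fraction),
            ("p_core_core", self.p_core_core),
            ("p_core_periphery", self.p_core_periphery),
            ("p_periphery_periphery", self.p_periphery_periphery),
            ("referral_retention", self.referral_retention),
            ("respondent_observation", self.respondent_observation),
            ("report_noise", self.report_noise),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability in [0, 1]")
        weights = np.array(list(self.sector_weights.values()), dtype=float)
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("sector_weights must be nonnegative and sum to 1")
        missing = set(self.sector_weights) - set(self.task_assignment)
        if missing:
            raise ConfigurationError(f"sectors without task assignment: {sorted(missing)}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def n_core(self) -> int:
        return int(round(self.hub_fraction * self.n_orgs))


@dataclass(frozen=True)
class GroundTruth:
    """True symmetric adjacency per layer plus the core/periphery labels."""

    org_ids: tuple[str, ...]
    contact: np.ndarray
    referral: np.ndarray
    core: np.ndarray

    def __post_init__(self) -> None:
        for name, m in (("contact", self.contact), ("referral", self.referral)):
            m = np.asarray(m)
            if not np.isin(m, (0, 1)).all():
                raise ValidationError(f"{name} layer must be 0/1")
            if np.diagonal(m).any():
                raise ValidationError(f"{name} layer has a nonzero diagonal")
            if (m != m.T).any():
                raise ValidationError(f"{name} layer must be symmetric")
        if ((self.referral == 1) & (self.contact == 0)).any():
            raise ValidationError("referral layer must be a subset of the contact layer")

    def layer(self, name: str) -> np.ndarray:
        if name == "contact":
            return self.contact
        if name == "referral":
            return self.referral
        raise ValidationError(f"unknown layer {name!r}")


def generate_roster(config: SyntheticConfig) -> Roster:
    """Draw a roster of ``config.n_orgs`` organizations.

    When the roster is at least as large as the sector list, every sector
    with positive weight receives at least one organization (each network in
    the field spans its full institutional sector list); the remaining
    organizations are drawn i.i.d. from ``sector_weights``.  Sectors in
    ``multi_respondent_sectors`` get 2–5 boundary spanners, all others one.
    Specialized-care providers receive a heavy-tailed ``clients_2017`` count
    so caseload threshold filters are exercisable.
    """
    rng = config._rng(_STREAM_ROSTER)
    sectors = [s for s, w in config.sector_weights.items() if w > 0]
    if not sectors:
        raise ConfigurationError("all sector weights are zero")
    weights = np.array([config.sector_weights[s] for s in sectors], dtype=float)
    weights = weights / weights.sum()

    n = config.n_orgs
    if n >= len(sectors):
        assignment = list(sectors)
        assignment += list(rng.choice(sectors, size=n - len(sectors), p=weights))
    else:
        assignment = list(rng.choice(sectors, size=n, p=weights))
    rng.shuffle(assignment)

    width = max(3, len(str(n)))
    orgs = []
    for i, sector in enumerate(assignment):
        org_id = f"O{i + 1:0{width}d}"
        attributes: dict[str, float] = {}
        if sector == "specialized_youth_care":
            # heavy-tailed caseload: many providers treat only a handful of clients
            attributes["clients_2017"] = float(rng.geometric(0.08))
        if sector in config.multi_respondent_sectors:
            n_resp = int(rng.integers(2, 6))
        else:
            n_resp = 1
        respondents = tuple(f"{org_id}-r{j + 1}" for j in range(n_resp))
        orgs.append(
            Organization(
                org_id=org_id,
                name=f"{sector.replace('_', ' ').title()} {i + 1}",
                sector=sector,
                tasks=frozenset(config.task_assignment[sector]),
                attributes=attributes,
                respondent_ids=respondents,
            )
        )
    return Roster(tuple(orgs))


def generate_truth(roster: Roster, config: SyntheticConfig) -> GroundTruth:
    """Draw the true two-layer network for ``roster``.

    The contact layer is a two-block (core/periphery) Bernoulli graph:
    ``n_core = round(hub_fraction * n)`` organizations are designated core,
    and each unordered pair is tied independently with the block probability
    (core–core, core–periphery or periphery–periphery).  The referral layer
    retains each contact tie independently with ``referral_retention``.
    """
    if len(roster) == 0:
        raise ValidationError("roster is empty")
    rng = config._rng(_STREAM_TRUTH)
    n = len(roster)
    core = np.zeros(n, dtype=bool)
    core_idx = rng.choice(n, size=min(config.n_core, n), replace=False)
    core[core_idx] = True

    p = np.where(
        core[:, None] & core[None, :],
        config.p_core_core,
        np.where(
            core[:, None] | core[None, :],
            config.p_core_periphery,
            config.p_periphery_periphery,
        ),
    )
    upper = np.triu(rng.random((n, n)) < p, k=1)
    contact = (upper | upper.T).astype(np.int8)

    keep = np.triu(rng.random((n, n)) < config.referral_retention, k=1)
    keep = keep | keep.T
    referral = (contact.astype(bool) & keep).astype(np.int8)
    return GroundTruth(roster.org_ids, contact, referral, core)


def expected_contact_density(config: SyntheticConfig) -> float:
    """Closed-form expected density of the contact layer given block sizes."""
    n = config.n_orgs
    nc = min(config.n_core, n)
    npr = n - nc
    exp_edges = (
        nc * (nc - 1) / 2 * config.p_core_core
        + nc * npr * config.p_core_periphery
        + npr * (npr - 1) / 2 * config.p_periphery_periphery
    )
    return 2 * exp_edges / (n * (n - 1))


def generate_reports(
    truth: GroundTruth, roster: Roster, config: SyntheticConfig
) -> TieReportSet:
    """Simulate the questionnaire.

    Each organization participates with probability ``response_rate``
    (response is an organizational decision; all its boundary spanners then
    return the questionnaire).  A responding respondent reports, for every
    true contact tie incident to their organization, a directed record
    reporter → target; if the tie also carries referral, a referral record
    too.  In organizations with several respondents, each respondent
    observes each incident tie independently with probability
    ``respondent_observation`` (sole respondents report perfectly).  With
    ``report_noise > 0``, spurious contact reports to untied organizations
    are added at that per-pair rate.
    """
    if truth.org_ids != roster.org_ids:
        raise ValidationError("ground truth and roster index different organizations")
    rng = config._rng(_STREAM_REPORTS)
    n = len(roster)
    org_ids = roster.org_ids
    participates = rng.random(n) < config.response_rate

    records: list[tuple[str, str, str, str]] = []
    responded: dict[str, bool] = {}
    for i, org in enumerate(roster):
        for resp in org.respondent_ids:
            responded[resp] = bool(participates[i])
        if not participates[i]:
            continue
        neighbors = np.flatnonzero(truth.contact[i])
        sole = len(org.respondent_ids) == 1
        for resp in org.respondent_ids:
            for j in neighbors:
                if not sole and rng.random() >= config.respondent_observation:
                    continue
                records.append((resp, org.org_id, org_ids[j], "contact"))
                if truth.referral[i, j]:
                    records.append((resp, org.org_id, org_ids[j], "referral"))
            if config.report_noise > 0:
                non_neighbors = np.flatnonzero((truth.contact[i] == 0))
                for j in non_neighbors:
                    if j != i and rng.random() < config.report_noise:
                        records.append((resp, org.org_id, org_ids[j], "contact"))
    return TieReportSet.from_records(records, responded=responded)


def generate_survey(
    config: SyntheticConfig,
) -> tuple[Roster, GroundTruth, TieReportSet]:
    """Convenience wrapper: roster, truth and reports in one call."""
    roster = generate_roster(config)
    truth = generate_truth(roster, config)
    reports = generate_reports(truth, roster, config)
    return roster, truth, reports
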