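# Methods

## The pipeline and its assumptions

`orgnet` analyzes bounded interorganizational networks measured by roster
survey: every member organization appears on a fixed roster, and one or
more *boundary spanners* per organization tick, from the full list of
members, the organizations theirs has contact with (layer `contact`) and
refers clients to or from (layer `referral`). The analysis runs per network
and layer:

1. roster ingest and boundary filters;
2. respondent → organization collapse (logical OR);
3. labeled reconstruction of nonresponse;
4. union ("any link") symmetrization;
5. the integration metric panel and degree-centrality ranking;
6. sector-level aggregation with fourfold strength coding.

The pipeline assumes the roster is complete (whole-network design: no
organizations outside the roster can be named), that ties are binary per
layer, and that a referral tie presupposes a contact tie. Reports are
directed claims; the final adjacency is undirected.

### Respondent collapse and the meaning of "responding"

Cell (i, j) of the directed report matrix is 1 iff at least one respondent
of organization i reported a tie to j. An organization counts as
*responding* when at least one of its boundary spanners returned the
questionnaire — a deliberate interpretation for the case where some of an
organization's respondents answer and others do not. Response records are
kept separate from tie records so that a returned questionnaire with zero
ties (all-negative response) is distinguishable from nonresponse; when no
response file is supplied, response is inferred from the presence of tie
records and all-negative responses become indistinguishable from
nonresponse (documented limitation of that input form).

### Labeled reconstruction

For a nonresponding organization i, the outgoing row is unobserved. Labeled
reconstruction fills row i with the transpose of column i restricted to
responding reporters: `row_i[j] = R[j][i]` if j responded, else 0. Dyads
between two nonrespondents are unrecoverable and fixed at 0; the adjacency
carries a per-cell `observed` flag (at least one endpoint responded) and
reports state the share of such survey-invisible dyads, which is the
quantity a reader needs to judge how much of the network rests on one-sided
reports.

### Symmetrization and operation order

Union symmetrization codes an undirected tie when either party reports it:
`A = max(R, Rᵀ)` elementwise. The pipeline applies reconstruction first and
symmetrization second. For this union rule the order is immaterial:
reconstruction only copies values across the diagonal and the elementwise
max is insensitive to which side carries the 1. The test suite asserts this
coincidence on random report matrices rather than assuming it.

## The metric panel

With n organizations and ties counted as ordered pairs (T = 2 × undirected
edges):

| quantity | definition | report precision |
|---|---|---|
| ties | T | integer |
| density | T / (n(n−1)) | 3 dp |
| average degree | T / n | 2 dp |
| isolates / active | degree-0 rows / rest | integer, % half-up |
| degree centrality | d_i, normalized d_i/(n−1) | 3 dp |
| degree centralization | Σ_i (d_max − d_i) / ((n−1)(n−2)) | 3 dp |

The ordered-pair tie convention is forced by internal consistency of the
panel identities (density·n(n−1) = T and avg_degree·n = T must hold with
the same T). Centralization is Freeman's undirected degree index — the
symmetric default of the classic UCINET workflow — with isolates included
in n; it is 0 for any regular graph and 1 for a star. Published
centralization values for the real networks cannot be recomputed without
the raw adjacency matrices, so the formula is validated instead by
naive-loop oracle equivalence, a graph-library cross-check (tests only),
star/regular closed forms, and an exhaustive sweep of all graphs on ≤ 5
nodes. All rounding happens at rendering time; percentages round half-up
(62.5% → 63).

## Sector aggregation

For each unordered pair of distinct sectors A ≠ B the fraction of realized
ties among |A|·|B| possible cross-pairs is computed; within-sector
fractions (over |A|(|A|−1)/2 pairs) are reported in a separate table
because the sector diagram is about between-sector connections (a flag
includes them in the edge set). Fractions are binned 0–3 at 20/40/60% of
possible ties. The source binning ranges overlap at the boundaries; this
package uses half-open intervals with exact boundaries taking the higher
code ("at least 60%" ⇒ strong), and writes the rule into the CSV metadata.
Sectors with no organizations in a network are not emitted. Σ present over
all sector pairs (incl. within) equals the network's undirected edge count
(tie conservation, asserted in tests).

## The synthetic survey generator

The generator exists so every downstream stage can be tested against a
known ground truth; its defaults emulate the study conditions of the
networks this pipeline targets.

* **Roster**: `n_orgs` (default 86, the mid-range of the 65–135 band)
  across 11 sectors with a fixed sector → task map (gatekeeper / signaling
  / providing services). When the roster is at least as large as the
  sector list, every positive-weight sector gets at least one organization
  (each real network spans its full institutional sector list); the rest
  are drawn i.i.d. from the sector weights, which make specialized youth
  care numerically dominant. Specialized providers get a heavy-tailed
  `clients_2017` caseload (geometric, mean 12.5) so threshold filters are
  exercisable; the real caseload distribution is unpublished and this
  choice only needs to straddle the filter boundary.
* **Contact layer**: a two-block core–periphery Bernoulli graph —
  `round(hub_fraction·n)` core organizations (default 15%), tie
  probabilities 0.9 (core–core), 0.7 (core–periphery), 0.1
  (periphery–periphery). The networks being emulated are not described
  generatively; this family was chosen because two blocks suffice to land
  simultaneously in the observed density (≈ 0.12–0.35) and degree
  centralization (≈ 0.4–0.7) ranges, as the defaults do. The closed-form
  expected density (block sizes × probabilities) is exposed as
  `expected_contact_density` and checked to 3 Monte-Carlo SEs.
* **Referral layer**: each contact tie independently retained with
  `referral_retention` (default 0.6, matching observed referral/contact
  density ratios ≈ 0.55–0.62), guaranteeing referral ⊆ contact.
* **Response**: each organization participates with `response_rate`
  (default 0.57, inside the observed 52–68% band). Response is drawn at the
  organization level because response rates are reported per organization
  and the generator's own response-count checks are stated at that level.
* **Multi-respondent organizations**: sectors whose boundary spanners have
  a limited working area (municipality, education, general practitioners,
  childcare) get 2–5 respondents — the per-organization count is
  unpublished, 2–5 is a free choice. Each respondent of a multi-respondent
  organization observes each incident true tie with probability 0.8, so
  OR-aggregation across respondents is exercised nontrivially; sole
  respondents report perfectly, which keeps the full-response round trip
  exact for single-respondent rosters (round-trip tests otherwise set the
  observation probability to 1).
* **Noise**: `report_noise` (default 0) adds false-positive contact reports
  per (respondent, untied organization) pair; noise is contact-only so it
  can never violate referral ⊆ contact.

Randomness: all stages derive independent streams from the single config
seed, so each stage is individually deterministic and reruns are
byte-identical.

What the generator does **not** emulate: informant disagreement biased by
organizational position, name confusion between similar organizations,
longitudinal evolution, or any association between sector and core status.
Passing tests therefore show that the pipeline arithmetic is correct under
honest-but-incomplete reporting, not that the block model is a faithful
model of any real service delivery system.

## Numerical choices and degenerate inputs

* Density requires n ≥ 2, centralization n ≥ 3; smaller networks raise
  `UndefinedMetricError` rather than returning NaN.
* Centrality rankings break degree ties by `org_id`, so output ordering is
  deterministic.
* An all-missing report matrix is legal and reconstructs to the zero
  matrix; a matrix with no edges has centralization 0.
* Self-reports and unknown layer labels are validation errors, not silently
  dropped; reports naming organizations that a boundary filter removed are
  dropped explicitly via `TieReportSet.restrict`.
* Problem sizes in the test and acceptance runs (random graphs n ≤ 25,
  block-model calibration at n = 200 with 50 replicates) were chosen as the
  smallest sizes at which the Monte-Carlo checks have meaningful power.

## Known limitations

* The "any link" rule cannot distinguish a false positive from a
  one-sided true report; with nonresponse it systematically underestimates
  ties between nonrespondents (fixed at 0 and flagged) — both properties
  are inherited from the survey design, not artifacts of this
  implementation.
* Betweenness and closeness centrality are deliberately out of scope: the
  adjacency is undirected, the networks of interest have isolates (making
  closeness undefined), and local degree is less sensitive to missing rows.
* No statistical inference across networks is performed; the comparison
  report is descriptive.
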