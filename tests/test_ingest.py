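"""Roster/report ingestion, boundary threshold filtering and the
respondent-to-organization collapse."""

import numpy as np
import pandas as pd
import pytest

from orgnet import (
    DataError,
    Organization,
    Roster,
    TieReportSet,
    ValidationError,
    apply_threshold_filter,
    collapse_respondents,
    read_square_csv,
    write_square_csv,
)


def make_specialized_roster(n: int, n_above: int, minimum: float = 6.0) -> Roster:
    """n specialized-care orgs of which exactly n_above have caseload >= minimum."""
    orgs = []
    for i in range(n):
        clients = minimum + i if i < n_above else minimum - 1
        orgs.append(
            Organization(f"S{i:03d}", f"Provider {i}", "specialized_youth_care",
                         frozenset({"providing_services"}), {"clients_2017": clients},
                         (f"S{i:03d}-r1",))
        )
    orgs.append(
        Organization("GP", "Family Doctors", "general_practitioners",
                     frozenset({"gatekeeper"}), {}, ("GP-r1",))
    )
    return Roster(tuple(orgs))


class TestRosterValidation:
    def test_duplicate_org_ids_rejected(self):
        org = Organization("A", "x", "education", frozenset(), {}, ("r1",))
        dup = Organization("A", "y", "safety", frozenset(), {}, ("r2",))
        with pytest.raises(ValidationError, match="duplicate"):
            Roster((org, dup))

    def test_respondents_shared_across_orgs_rejected(self):
        a = Organization("A", "x", "education", frozenset(), {}, ("r1",))
        b = Organization("B", "y", "safety", frozenset(), {}, ("r1",))
        with pytest.raises(ValidationError, match="respondent"):
            Roster((a, b))

    def test_unknown_task_rejected(self):
        with pytest.raises(ValidationError, match="unknown tasks"):
            Organization("A", "x", "education", frozenset({"janitor"}), {}, ())

    def test_roster_csv_round_trip(self, small_roster, tmp_path):
        path = tmp_path / "roster.csv"
        small_roster.to_csv(path)
        back = Roster.from_csv(path)
        assert back.org_ids == small_roster.org_ids
        for a, b in zip(small_roster, back):
            assert (a.sector, a.tasks, a.respondent_ids, a.attributes) == (
                b.sector, b.tasks, b.respondent_ids, b.attributes
            )


class TestThresholdFilter:
    def test_caseload_threshold_retains_exactly_qualifying_orgs(self):
        # 162 specialized providers, exactly 94 with >= 6 clients in treatment
        roster = make_specialized_roster(162, 94)
        filtered = apply_threshold_filter(
            roster, "clients_2017", 6.0, {"specialized_youth_care"}
        )
        specialized = [o for o in filtered if o.sector == "specialized_youth_care"]
        assert len(specialized) == 94
        # the untargeted gatekeeper sector is untouched
        assert any(o.org_id == "GP" for o in filtered)

    def test_minimum_zero_keeps_everything(self):
        roster = make_specialized_roster(20, 5)
        assert apply_threshold_filter(
            roster, "clients_2017", 0.0, {"specialized_youth_care"}
        ).org_ids == roster.org_ids

    def test_empty_sector_set_is_a_no_op(self):
        roster = make_specialized_roster(20, 5)
        assert apply_threshold_filter(roster, "clients_2017", 6.0, set()) is roster

    def test_missing_attribute_names_the_organization(self):
        bad = Organization("X1", "No caseload", "specialized_youth_care",
                           frozenset({"providing_services"}), {}, ("X1-r1",))
        roster = Roster((bad,))
        with pytest.raises(DataError, match="X1"):
            apply_threshold_filter(roster, "clients_2017", 6.0, {"specialized_youth_care"})


class TestReportValidation:
    def test_self_report_rejected(self, small_roster):
        reports = TieReportSet.from_records([("A-r1", "A", "A", "contact")])
        with pytest.raises(ValidationError, match="self-report"):
            reports.validate(small_roster)

    def test_unknown_organization_rejected(self, small_roster):
        reports = TieReportSet.from_records([("A-r1", "A", "ZZZ", "contact")])
        with pytest.raises(DataError, match="ZZZ"):
            reports.validate(small_roster)

    def test_respondent_org_mismatch_rejected(self, small_roster):
        reports = TieReportSet.from_records([("A-r1", "B", "C", "contact")])
        with pytest.raises(DataError, match="A-r1"):
            reports.validate(small_roster)

    def test_unknown_layer_rejected(self, small_roster):
        reports = TieReportSet.from_records([("A-r1", "A", "B", "friendship")])
        with pytest.raises(ValidationError, match="layer"):
            reports.validate(small_roster)

    def test_tie_record_without_response_record_rejected(self, small_roster):
        reports = TieReportSet.from_records(
            [("A-r1", "A", "B", "contact")], responded={"A-r1": False}
        )
        with pytest.raises(DataError, match="response record"):
            reports.validate(small_roster)

    def test_restrict_drops_dangling_reports(self, small_roster):
        reports = TieReportSet.from_records(
            [("A-r1", "A", "B", "contact"), ("A-r1", "A", "ZZZ", "contact")]
        )
        kept = reports.restrict(small_roster)
        assert len(kept) == 1
        kept.validate(small_roster)


class TestCollapse:
    def test_or_rule_over_respondents(self, small_roster):
        # one of B's two respondents reports the tie, the other does not
        reports = TieReportSet.from_records(
            [("B-r1", "B", "A", "contact")],
            responded={"B-r1": True, "B-r2": True},
        )
        matrix = collapse_respondents(small_roster, reports, "contact")
        i, j = small_roster.index["B"], small_roster.index["A"]
        assert matrix.matrix[i, j] == 1

    def test_nonresponding_org_row_zero_and_flagged(self, small_roster):
        reports = TieReportSet.from_records(
            [("A-r1", "A", "B", "contact")], responded={"A-r1": True}
        )
        matrix = collapse_respondents(small_roster, reports, "contact")
        for org in "BCDE":
            row = small_roster.index[org]
            assert not matrix.responded[row]
            assert matrix.matrix[row].sum() == 0

    def test_all_negative_response_is_not_nonresponse(self, small_roster):
        # C responded but reported zero ties: responded True, row zero
        reports = TieReportSet.from_records([], responded={"C-r1": True})
        matrix = collapse_respondents(small_roster, reports, "contact")
        i = small_roster.index["C"]
        assert matrix.responded[i] and matrix.matrix[i].sum() == 0

    def test_collapse_equals_brute_force_or_oracle(self, rng):
        orgs = []
        for i in range(8):
            n_resp = int(rng.integers(1, 4))
            orgs.append(
                Organization(f"G{i}", f"org {i}", "education", frozenset(),
                             {}, tuple(f"G{i}-r{k}" for k in range(n_resp)))
            )
        roster = Roster(tuple(orgs))
        records, responded = [], {}
        for org in roster:
            for resp in org.respondent_ids:
                responded[resp] = bool(rng.random() < 0.8)
                if not responded[resp]:
                    continue
                for other in roster:
                    if other.org_id != org.org_id and rng.random() < 0.3:
                        records.append((resp, org.org_id, other.org_id, "contact"))
        reports = TieReportSet.from_records(records, responded=responded)
        matrix = collapse_respondents(roster, reports, "contact")

        # oracle: explicit per-respondent incidence matrices, OR-ed in a loop
        idx = roster.index
        expected = np.zeros((8, 8), dtype=int)
        for resp, reporter, target, layer in records:
            per = np.zeros((8, 8), dtype=int)
            per[idx[reporter], idx[target]] = 1
            expected = expected | per
        assert (matrix.matrix == expected).all()
        assert matrix.matrix.sum(axis=1).max() <= len(roster) - 1

    def test_collapse_order_independent_and_idempotent(self, small_roster, rng):
        records = [
            ("A-r1", "A", "B", "contact"),
            ("B-r1", "B", "C", "contact"),
            ("B-r2", "B", "A", "contact"),
            ("E-r1", "E", "A", "contact"),
        ]
        base = collapse_respondents(
            small_roster, TieReportSet.from_records(records), "contact"
        )
        shuffled = list(records)
        rng.shuffle(shuffled)
        again = collapse_respondents(
            small_roster, TieReportSet.from_records(shuffled + shuffled), "contact"
        )
        assert (base.matrix == again.matrix).all()

    def test_referral_collapse_subset_of_contact_collapse(self, small_roster):
        records = [
            ("A-r1", "A", "B", "contact"),
            ("A-r1", "A", "C", "contact"),
            ("A-r1", "A", "C", "referral"),
        ]
        reports = TieReportSet.from_records(records)
        contact = collapse_respondents(small_roster, reports, "contact")
        referral = collapse_respondents(small_roster, reports, "referral")
        assert ((referral.matrix == 1) <= (contact.matrix == 1)).all()


class TestCsvInterchange:
    def test_reports_csv_round_trip(self, small_roster, tmp_path):
        reports = TieReportSet.from_records(
            [("A-r1", "A", "B", "contact"), ("B-r2", "B", "A", "referral")],
            responded={"A-r1": True, "B-r1": False, "B-r2": True, "C-r1": True},
        )
        reports.to_csv(tmp_path / "t.csv", tmp_path / "q.csv")
        back = TieReportSet.from_csv(tmp_path / "t.csv", tmp_path / "q.csv")
        pd.testing.assert_frame_equal(back.ties, reports.ties)
        assert back.responded == reports.responded

    def test_square_csv_round_trip(self, tmp_path, rng):
        ids = tuple(f"O{i}" for i in range(6))
        m = (rng.random((6, 6)) < 0.4).astype(int)
        np.fill_diagonal(m, 0)
        write_square_csv(tmp_path / "adj.csv", ids, m)
        back_ids, back = read_square_csv(tmp_path / "adj.csv")
        assert back_ids == ids
        assert (back == m).all()

    def test_square_csv_header_mismatch_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("org_id,A,B\nA,0,1\nC,1,0\n")
        with pytest.raises(DataError, match="header"):
            read_square_csv(tmp_path / "bad.csv")
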