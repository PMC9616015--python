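import numpy as np
import pytest

from orgnet import Organization, ReportMatrix, Roster


def graph_with_edges(n: int, n_edges: int, n_isolates: int = 0) -> np.ndarray:
    """Deterministic symmetric 0/1 matrix with exactly ``n_edges`` undirected
    edges among the first ``n - n_isolates`` nodes (upper triangle filled
    row by row)."""
    active = n - n_isolates
    if n_edges > active * (active - 1) // 2:
        raise ValueError("too many edges for the active node count")
    m = np.zeros((n, n), dtype=np.int8)
    left = n_edges
    for i in range(active):
        for j in range(i + 1, active):
            if left == 0:
                return m
            m[i, j] = m[j, i] = 1
            left -= 1
    return m


def random_report_matrix(rng: np.random.Generator, n: int, p: float = 0.3,
                         response: float = 0.6, layer: str = "contact") -> ReportMatrix:
    """Random directed report matrix with a random responded mask; rows of
    nonrespondents are zeroed, as a collapsed survey guarantees."""
    m = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(m, 0)
    responded = rng.random(n) < response
    m[~responded, :] = 0
    ids = tuple(f"O{i:02d}" for i in range(n))
    return ReportMatrix(ids, m, responded, layer)


@pytest.fixture
def rng():
    return np.random.default_rng(20180901)


@pytest.fixture
def small_roster():
    """Five organizations, three sectors, one multi-respondent organization."""
    return Roster(
        (
            Organization("A", "Youth and Family Center", "center_youth_family",
                         frozenset({"gatekeeper"}), {}, ("A-r1",)),
            Organization("B", "Care Coordinators", "education",
                         frozenset({"signaling"}), {}, ("B-r1", "B-r2")),
            Organization("C", "Youth Mental Health", "specialized_youth_care",
                         frozenset({"providing_services"}), {"clients_2017": 40.0},
                         ("C-r1",)),
            Organization("D", "Orthopedagogy Practice", "specialized_youth_care",
                         frozenset({"providing_services"}), {"clients_2017": 3.0},
                         ("D-r1",)),
            Organization("E", "Primary School Support", "education",
                         frozenset({"signaling"}), {}, ("E-r1",)),
        )
    )
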