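"""Participant-normalized co-mention matrix: weighting, conservation, export."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reasonnet import (
    Codebook,
    Reason,
    build_matrix,
    export_network,
    import_edge_list,
    import_graphml,
    participant_weights,
    to_graph,
)

from conftest import make_response_set


class TestParticipantWeights:
    def test_sole_mention_gets_unit_self_weight(self):
        assert participant_weights({"a"}) == {("a", "a"): Fraction(1)}

    def test_two_reasons_one_pair_weight_one(self):
        assert participant_weights({"a", "b"}) == {("a", "b"): Fraction(1)}

    def test_three_reasons_each_pair_one_third(self):
        w = participant_weights({"a", "b", "c"})
        assert w == {
            ("a", "b"): Fraction(1, 3),
            ("a", "c"): Fraction(1, 3),
            ("b", "c"): Fraction(1, 3),
        }
        assert sum(w.values()) == 1

    def test_four_reasons_each_pair_one_sixth(self):
        w = participant_weights({"a", "b", "c", "d"})
        assert len(w) == 6
        assert set(w.values()) == {Fraction(1, 6)}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one reason"):
            participant_weights(set())

    @given(st.sets(st.sampled_from("abcdefghij"), min_size=1, max_size=10))
    def test_weights_always_sum_to_exactly_one(self, reasons):
        assert sum(participant_weights(reasons).values()) == 1


class TestBuildMatrix:
    def test_two_respondent_enumeration(self, acceptance_cb, tiny_rs):
        M = build_matrix(tiny_rs)
        i = M.index("disease_risk")
        j = M.index("protecting_others")
        assert M.A[i, i] == 1.0  # sole mention of disease_risk
        assert M.A[i, j] == M.A[j, i] == 1.0  # one co-mention pair
        assert M.A[j, j] == 0.0
        assert M.total_mass == pytest.approx(2.0, abs=1e-12)

    def test_hundred_identical_triples_accumulate_thirds(self, acceptance_cb):
        sets = [{"disease_risk", "protecting_others", "convenience"}] * 100
        rs = make_response_set(acceptance_cb, sets)
        M = build_matrix(rs)
        i, j, k = (M.index(c) for c in ("disease_risk", "protecting_others", "convenience"))
        for a, b in [(i, j), (i, k), (j, k)]:
            assert M.A[a, b] == pytest.approx(100 / 3, abs=1e-9)
        assert M.total_mass == pytest.approx(100.0, abs=1e-9)

    def test_sole_mentions_only_gives_diagonal_matrix(self, acceptance_cb):
        rs = make_response_set(acceptance_cb, [{"disease_risk"}, {"convenience"}, {"incentives"}])
        M = build_matrix(rs)
        assert np.allclose(M.A, np.diag(np.diag(M.A)))
        assert M.total_mass == pytest.approx(3.0)

    def test_zero_diagonal_mode_moves_sole_weight_aside(self, acceptance_cb, tiny_rs):
        M = build_matrix(tiny_rs, diagonal_mode="zero")
        assert np.all(np.diag(M.A) == 0)
        assert M.self_weights[M.index("disease_risk")] == 1.0
        # conservation still counts the side vector
        assert M.total_mass == pytest.approx(2.0)

    def test_empty_set_rejected(self, acceptance_cb):
        rs = make_response_set(acceptance_cb, [])
        with pytest.raises(ValueError, match="empty"):
            build_matrix(rs)

    def test_additivity_over_concatenation(self, acceptance_cb):
        sets1 = [{"disease_risk"}, {"disease_risk", "convenience"}]
        sets2 = [{"incentives", "convenience", "social_norms"}]
        M1 = build_matrix(make_response_set(acceptance_cb, sets1))
        M2 = build_matrix(make_response_set(acceptance_cb, sets2))
        M12 = build_matrix(make_response_set(acceptance_cb, sets1 + sets2))
        assert np.allclose(M12.A, M1.A + M2.A, atol=1e-12)

    def test_permutation_equivariance(self, acceptance_cb):
        sets = [{"disease_risk", "convenience"}, {"incentives"},
                {"disease_risk", "incentives", "social_norms"}]
        M = build_matrix(make_response_set(acceptance_cb, sets))
        perm = list(reversed(range(len(acceptance_cb))))
        shuffled = Codebook(
            group="acceptance",
            reasons=tuple(acceptance_cb.reasons[i] for i in perm),
        )
        Mp = build_matrix(make_response_set(shuffled, sets))
        P = np.eye(len(perm))[perm]
        assert np.allclose(Mp.A, P @ M.A @ P.T, atol=1e-12)


@st.composite
def random_reason_sets(draw):
    codes = list("abcdefgh")
    n = draw(st.integers(min_value=1, max_value=30))
    return [draw(st.sets(st.sampled_from(codes), min_size=1, max_size=8)) for _ in range(n)]


def _toy_codebook():
    return Codebook(
        group="acceptance",
        reasons=tuple(
            Reason(code=c, label=c.upper(), group="acceptance", categories=frozenset({"confidence"}))
            for c in "abcdefgh"
        ),
    )


class TestConservation:
    @settings(max_examples=150, deadline=None)
    @given(random_reason_sets())
    def test_total_mass_equals_n_respondents(self, sets):
        """Each respondent contributes exactly total weight 1 to the matrix."""
        rs = make_response_set(_toy_codebook(), sets)
        M = build_matrix(rs)
        assert abs(M.total_mass - len(sets)) < 1e-9
        assert np.allclose(M.A, M.A.T)
        assert (M.A >= 0).all()


class TestExport:
    def test_edge_list_contents(self, acceptance_cb, tiny_rs, tmp_path):
        M = build_matrix(tiny_rs)
        path = tmp_path / "net.csv"
        export_network(M, "edge_list_csv", path)
        import pandas as pd

        edges = pd.read_csv(path)
        assert len(edges) == 1
        assert set(edges.loc[0, ["source", "target"]]) == {"disease_risk", "protecting_others"}
        assert edges.loc[0, "weight"] == 1.0
        nodes = pd.read_csv(tmp_path / "net.nodes.csv").set_index("code")
        assert nodes.loc["disease_risk", "self_weight"] == 1.0

    def test_diagonal_only_matrix_has_no_edges(self, acceptance_cb, tmp_path):
        rs = make_response_set(acceptance_cb, [{"disease_risk"}, {"convenience"}])
        M = build_matrix(rs)
        path = tmp_path / "net.csv"
        export_network(M, "edge_list_csv", path)
        import pandas as pd

        assert len(pd.read_csv(path)) == 0
        assert len(pd.read_csv(tmp_path / "net.nodes.csv")) == len(acceptance_cb)

    def test_edge_list_round_trip(self, acceptance_cb, tmp_path):
        sets = [{"disease_risk", "convenience", "incentives"}, {"disease_risk"},
                {"convenience", "social_norms"}]
        M = build_matrix(make_response_set(acceptance_cb, sets))
        path = tmp_path / "net.csv"
        export_network(M, "edge_list_csv", path)
        M2 = import_edge_list(path, M.reasons, M.n_respondents)
        assert np.allclose(M2.A, M.A, atol=1e-12)

    def test_graphml_round_trip(self, acceptance_cb, tmp_path):
        sets = [{"disease_risk", "convenience"}, {"incentives"}]
        M = build_matrix(make_response_set(acceptance_cb, sets))
        path = tmp_path / "net.graphml"
        export_network(M, "graphml", path)
        M2 = import_graphml(path)
        assert tuple(M2.reasons) == tuple(M.reasons)
        assert np.allclose(M2.A, M.A, atol=1e-12)
        assert M2.n_respondents == M.n_respondents

    def test_self_loops_never_exported_as_edges(self, acceptance_cb, tiny_rs, tmp_path):
        M = build_matrix(tiny_rs)
        export_network(M, "graphml", tmp_path / "net.graphml")
        G = to_graph(M)
        assert not any(u == v for u, v in G.edges())

    def test_unsupported_format_rejected(self, acceptance_cb, tiny_rs, tmp_path):
        M = build_matrix(tiny_rs)
        with pytest.raises(ValueError, match="unsupported"):
            export_network(M, "gexf", tmp_path / "x")
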