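"""The log-odds weighting score and candidate ranking."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from labrec.errors import DomainError
from labrec.records_io import PatientCase, TestUniverse
from labrec.smoothing import SmoothingConfig
from labrec.training import build_training_matrix
from labrec.weighting import (
    ProbabilityEstimates,
    Recommendation,
    WeightConfig,
    estimate_alpha,
    estimate_beta,
    estimate_gamma,
    evidence_term,
    prior_term,
    rank_candidates,
    weight,
)


def _case(tests, cid="x"):
    return PatientCase(cid, frozenset(tests), cid)


def _matrix(sets, codes):
    cases = [_case(s, f"c{i}") for i, s in enumerate(sets)]
    return build_training_matrix(cases, TestUniverse.from_codes(codes))


class TestEstimates:
    def test_alpha_gamma_are_marginal_ratios(self, four_case_matrix):
        assert estimate_alpha(four_case_matrix, "B") == 0.5
        assert estimate_gamma(four_case_matrix, "A") == 0.75
        m = _matrix([{"A"}], "AB")
        assert estimate_alpha(m, "B") == 0.0
        assert estimate_alpha(m, "A") == 1.0

    def test_beta_is_joint_over_conditioning_marginal(self, four_case_matrix):
        assert estimate_beta(four_case_matrix, "A", "B") == 1.0
        assert estimate_beta(four_case_matrix, "B", "A") == pytest.approx(2 / 3)
        assert estimate_beta(four_case_matrix, "B", "C") == 0.0

    def test_beta_undefined_for_unseen_conditioning_test(self):
        m = _matrix([{"A"}], "AB")
        with pytest.raises(DomainError, match="'B'"):
            estimate_beta(m, "A", "B")


class TestPriorAndEvidenceTerms:
    def test_prior_vanishes_at_k_one(self):
        assert prior_term(0.3, 0.2, 1) == 0.0
        assert prior_term(0.9, 0.0, 1) == 0.0

    def test_prior_symmetry_and_value(self):
        assert prior_term(0.5, 0.0, 3) == 0.0
        assert prior_term(0.2, 0.0, 2) == pytest.approx(math.log(4), abs=1e-9)

    def test_exact_evidence_zero_under_independence(self):
        for alpha in (0.1, 0.5, 0.9):
            est = ProbabilityEstimates(alpha=alpha, gamma=0.4, beta=0.4)
            assert evidence_term(est, "exact", 1e-12) == pytest.approx(0.0)

    def test_exact_evidence_value(self):
        est = ProbabilityEstimates(alpha=0.5, gamma=0.4, beta=0.6)
        assert evidence_term(est, "exact", 1e-12) == pytest.approx(math.log(3))

    def test_literal_evidence_value(self):
        est = ProbabilityEstimates(alpha=0.9, gamma=0.5, beta=0.2)
        assert evidence_term(est, "literal", 1e-12) == pytest.approx(
            math.log(0.2 / 0.3)
        )

    def test_literal_negative_denominator_floored_finite(self):
        # positively associated pair: gamma < beta makes the printed
        # denominator negative; the floor keeps the term finite
        est = ProbabilityEstimates(alpha=0.5, gamma=0.3, beta=0.9)
        v = evidence_term(est, "literal", 1e-12)
        assert math.isfinite(v) and v > 0


class TestWeight:
    def test_reference_weights_and_ranking(self, four_case_matrix, raw_config):
        w_b = weight("B", _case({"A"}), four_case_matrix, raw_config)
        w_c = weight("C", _case({"A"}), four_case_matrix, raw_config)
        assert w_b == pytest.approx(math.log(2), abs=1e-9)
        assert w_c == pytest.approx(-math.log(2), abs=1e-9)
        rec = rank_candidates(_case({"A"}), four_case_matrix, raw_config)
        assert rec.top(2) == ("B", "C")

    def test_full_jm_smoothing_collapses_to_prior(self, four_case_matrix):
        # lambda = 1 replaces beta by gamma, so every exact evidence term is 0;
        # for this candidate alpha = 0.5, so the prior log-odds vanishes too
        cfg = WeightConfig(smoothing=SmoothingConfig("jelinek_mercer", 1.0, 0.0))
        assert weight("B", _case({"A"}), four_case_matrix, cfg) == pytest.approx(0.0)
        # in the literal composition the k=1 prior term is identically zero
        assert prior_term(estimate_alpha(four_case_matrix, "B"), 0.3, 1) == 0.0

    def test_candidate_already_taken_rejected(self, four_case_matrix, raw_config):
        with pytest.raises(DomainError):
            weight("A", _case({"A"}), four_case_matrix, raw_config)

    def test_no_candidates_rejected(self, four_case_matrix, raw_config):
        with pytest.raises(DomainError):
            rank_candidates(_case({"A", "B", "C"}), four_case_matrix, raw_config)

    def test_single_candidate_ranking(self, four_case_matrix, raw_config):
        rec = rank_candidates(_case({"A", "B"}), four_case_matrix, raw_config)
        assert len(rec.ranked) == 1 and rec.ranked[0][0] == "C"

    def test_exact_ties_break_lexicographically(self, raw_config):
        # B and C are exchangeable with respect to A by construction
        m = _matrix([{"A", "B"}, {"A", "C"}, {"B"}, {"C"}], "ABC")
        rec = rank_candidates(_case({"A"}), m, raw_config)
        assert rec.ranked[0][1] == pytest.approx(rec.ranked[1][1])
        assert rec.top(2) == ("B", "C")

    def test_ranking_covers_universe_minus_taken(self, four_case_matrix, raw_config):
        rec = rank_candidates(_case({"B"}), four_case_matrix, raw_config)
        assert {c for c, _ in rec.ranked} == {"A", "C"}
        assert all(np.isfinite(w) for _, w in rec.ranked)

    def test_taken_test_unseen_in_training_is_skipped(self, caplog):
        m = _matrix([{"A", "B"}, {"A"}], "ABZ")  # Z never observed
        cfg = WeightConfig(smoothing=SmoothingConfig("jelinek_mercer", 0.2, 0.5))
        with caplog.at_level(logging.WARNING):
            w_with = weight("B", _case({"A", "Z"}), m, cfg)
        w_without = weight("B", _case({"A"}), m, cfg)
        # evidence from Z contributes nothing; only the literal k changes,
        # and in exact mode the weight is insensitive to the skipped test
        assert w_with == pytest.approx(w_without)
        assert any("unseen" in msg for msg in caplog.messages)

    def test_unseen_candidate_is_rankable_with_smoothing(self):
        m = _matrix([{"A", "B"}, {"A"}], "ABZ")
        cfg = WeightConfig(smoothing=SmoothingConfig("jelinek_mercer", 0.2, 0.5))
        rec = rank_candidates(_case({"A"}), m, cfg)
        assert {c for c, _ in rec.ranked} == {"B", "Z"}
        assert all(math.isfinite(w) for _, w in rec.ranked)
        assert rec.top(1) == ("B",)  # the observed partner outranks the unseen test


class TestProperties:
    @given(
        st.integers(min_value=1, max_value=10),
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=0, max_value=8),
    )
    def test_exact_evidence_monotone_in_joint_count(self, base, j1_raw, j2_raw):
        """More co-occurrence with the candidate never lowers the score."""
        j1, j2 = sorted((min(j1_raw, base), min(j2_raw, base)))
        n = base + 10
        alpha, gamma = base / n, (base + 5) / n
        def term(joint):
            beta = joint / base
            den = gamma - alpha * beta
            if beta <= 0 or den <= 0:
                return None
            return evidence_term(
                ProbabilityEstimates(alpha, gamma, beta), "exact", 1e-12
            )
        t1, t2 = term(j1), term(j2)
        if t1 is not None and t2 is not None:
            assert t2 >= t1 - 1e-12

    @given(
        st.lists(
            st.frozensets(st.sampled_from(list("ABCDE")), min_size=1, max_size=5),
            min_size=2,
            max_size=15,
        ),
        st.sampled_from(["jelinek_mercer", "dirichlet", "absolute_discounting"]),
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=0.05, max_value=1.0),
        st.sampled_from(["exact", "literal"]),
    )
    def test_weights_always_finite_with_positive_smoothing(
        self, sets, method, param, theta, mode
    ):
        m = _matrix(sets, "ABCDE")
        cfg = WeightConfig(
            smoothing=SmoothingConfig(method, param, theta), evidence_mode=mode
        )
        taken = sets[0]
        if len(taken) == 5:
            taken = frozenset(list(taken)[:4])
        rec = rank_candidates(_case(taken), m, cfg)
        assert all(math.isfinite(w) for _, w in rec.ranked)

    def test_scalar_weight_agrees_with_ranking_weights(self, four_case_matrix):
        cfg = WeightConfig(smoothing=SmoothingConfig("dirichlet", 0.3, 0.4))
        rec = rank_candidates(_case({"C"}), four_case_matrix, cfg)
        for code, w in rec.ranked:
            assert weight(code, _case({"C"}), four_case_matrix, cfg) == pytest.approx(w)


def test_recommendation_tsv_format(tmp_path, four_case_matrix, raw_config):
    from labrec.weighting import write_recommendations

    rec = rank_candidates(_case({"A"}, "case-1"), four_case_matrix, raw_config)
    out = tmp_path / "rec.tsv"
    with open(out, "w") as fh:
        write_recommendations([rec], fh)
    lines = out.read_text().splitlines()
    assert lines[0] == "case_id\trank\ttest_code\tweight"
    assert lines[1] == f"case-1\t1\tB\t{math.log(2):.6f}"
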