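"""The naive-Bayes log-odds weighting score and per-case candidate ranking.

For a candidate test ``test0`` and a case that already contains tests
``t_1 ... t_k``, the score is the posterior log-odds that the candidate
belongs to the "taken" rather than the "not-taken" class, under a
naive-Bayes factorisation over the taken tests.  Writing

* ``alpha``  — prior probability of the candidate, ``marginal[test0] / n``;
* ``gamma_i`` — marginal probability of taken test i, ``marginal[t_i] / n``;
* ``beta_i`` — conditional probability of taken test i given the candidate,
  ``joint[t_i, test0] / marginal[test0]`` (smoothed per config);

two algebraically distinct compositions are offered:

``exact`` (default)
    The genuine posterior log-odds
    ``log((alpha + theta) / (1 - alpha + theta))
    + sum_i log(beta_i (1 - alpha) / (gamma_i - alpha beta_i))``,
    whose evidence denominator ``gamma - alpha*beta`` is the probability of
    the taken test co-occurring with the candidate's *absence*.  This form
    is equal, term by term, to the Bayes-rule expansion of the posterior
    odds and is what the equivalence tests check against brute force.

``literal``
    The historical printed form
    ``(k - 1) * log((1 - alpha + theta) / (alpha + theta))
    + sum_i log(beta_i / (gamma_i - beta_i))``,
    kept selectable because published parameter studies used it; its
    denominator goes negative exactly for positively associated test pairs,
    so both numerator and denominator are floored at ``epsilon`` before the
    log (each floor event is counted and logged).

Only the ranking induced by the score is contractual, not its scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from labrec import smoothing as sm
from labrec.errors import ConsistencyError, DomainError, ParameterError
from labrec.records_io import PatientCase
from labrec.training import TrainingMatrix

log = logging.getLogger(__name__)

EVIDENCE_MODES = ("exact", "literal")


@dataclass(frozen=True)
class ProbabilityEstimates:
    """The (alpha, gamma, beta) triple entering one evidence term."""

    alpha: float
    gamma: float
    beta: float


@dataclass(frozen=True)
class WeightConfig:
    """Smoothing choice, evidence composition, and the log floor."""

    smoothing: sm.SmoothingConfig = field(default_factory=sm.SmoothingConfig)
    evidence_mode: str = "exact"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.evidence_mode not in EVIDENCE_MODES:
            raise ParameterError(f"unknown evidence mode {self.evidence_mode!r}")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


@dataclass(frozen=True)
class Recommendation:
    """Ranked candidate tests for one case, best first.

    ``ranked`` pairs (test code, weight), sorted by weight descending with
    ties broken by test code ascending, covering exactly the universe minus
    the case's taken tests.
    """

    case_id: str
    ranked: tuple[tuple[str, float], ...]

    def top(self, x: int) -> tuple[str, ...]:
        return tuple(code for code, _ in self.ranked[:x])


def estimate_alpha(matrix: TrainingMatrix, test0: str) -> float:
    """Prior probability of the candidate test: marginal count over cases."""
    return matrix.counts(test0) / matrix.n_cases


def estimate_gamma(matrix: TrainingMatrix, testi: str) -> float:
    """Marginal probability of a taken test."""
    return matrix.counts(testi) / matrix.n_cases


def estimate_beta(matrix: TrainingMatrix, testi: str, test0: str) -> float:
    """Conditional probability of ``testi`` given ``test0``: joint over marginal."""
    base = matrix.counts(test0)
    if base == 0:
        raise DomainError(
            f"conditioning test {test0!r} unseen in training; smooth or skip"
        )
    return matrix.counts(testi, test0) / base


def prior_term(alpha: float, theta: float, k: int) -> float:
    """``(k - 1) * log((1 - alpha + theta) / (alpha + theta))``.

    The prior component of the literal composition: minus (k - 1) times the
    Laplace-smoothed log-odds of the candidate.  Zero whenever k == 1.
    """
    return -(k - 1) * sm.laplace_log_odds(alpha, theta)


def evidence_term(est: ProbabilityEstimates, mode: str, epsilon: float) -> float:
    """One taken test's contribution to the evidence sum.

    exact:   ``log(beta (1 - alpha) / (gamma - alpha beta))``
    literal: ``log(beta / (gamma - beta))``

    Non-positive numerators or denominators are floored at ``epsilon``
    before the log, so the result is always finite.
    """
    if mode not in EVIDENCE_MODES:
        raise ParameterError(f"unknown evidence mode {mode!r}")
    if mode == "exact":
        num = est.beta * (1.0 - est.alpha)
        den = est.gamma - est.alpha * est.beta
    else:
        num = est.beta
        den = est.gamma - est.beta
    if num <= 0.0 or den <= 0.0:
        log.debug(
            "evidence floor: mode=%s alpha=%g gamma=%g beta=%g", mode,
            est.alpha, est.gamma, est.beta,
        )
    return math.log(max(num, epsilon) / max(den, epsilon))


def _case_weights(
    matrix: TrainingMatrix,
    taken: frozenset[str],
    candidates: list[str],
    config: WeightConfig,
) -> np.ndarray:
    """Vectorised weights of ``candidates`` for one case's taken set."""
    n = matrix.n_cases
    diag = matrix.marginal.astype(np.float64)
    cand_idx = np.fromiter((matrix.idx(c) for c in candidates), dtype=np.intp)

    taken_sorted = sorted(taken)
    taken_idx_all = [matrix.idx(t) for t in taken_sorted]
    seen = [i for i in taken_idx_all if diag[i] > 0]
    if len(seen) < len(taken_idx_all):
        unseen = [matrix.universe.tests[i] for i in taken_idx_all if diag[i] == 0]
        log.warning(
            "skipping taken tests unseen in training (gamma = 0): %s", unseen
        )
    taken_idx = np.asarray(seen, dtype=np.intp)

    marg_c = diag[cand_idx]
    alpha = marg_c / n
    cfg = config.smoothing
    theta, eps = cfg.theta, config.epsilon

    if taken_idx.size:
        gamma = (diag[taken_idx] / n)[:, None]  # |S| x 1
        J = matrix.joint[np.ix_(taken_idx, cand_idx)].astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_raw = np.where(marg_c > 0, J / np.where(marg_c > 0, marg_c, 1.0), 0.0)
        if cfg.method == "none":
            beta = beta_raw
        elif cfg.method == "jelinek_mercer":
            beta = (1.0 - cfg.param) * beta_raw + cfg.param * gamma
        elif cfg.method == "dirichlet":
            beta = (beta_raw + cfg.param * gamma) / (1.0 + cfg.param)
        else:  # absolute discounting works on counts, with a pure-gamma fallback
            disc = np.where(marg_c > 0, np.maximum(J - cfg.param, 0.0) /
                            np.where(marg_c > 0, marg_c, 1.0), 0.0)
            beta = disc + cfg.param * gamma

        if config.evidence_mode == "exact":
            num = beta * (1.0 - alpha)
            den = gamma - alpha * beta
        else:
            num = beta
            den = gamma - beta
        floors = int(np.count_nonzero(num <= 0.0) + np.count_nonzero(den <= 0.0))
        if floors:
            log.debug("evidence floors applied: %d term(s)", floors)
        evidence = np.log(np.maximum(num, eps) / np.maximum(den, eps)).sum(axis=0)
    else:
        evidence = np.zeros(cand_idx.size)

    k = len(taken)
    if config.evidence_mode == "exact":
        prior = np.array([sm.laplace_log_odds(a, theta) for a in alpha])
    else:
        prior = np.array([prior_term(a, theta, k) for a in alpha])
    return prior + evidence


def weight(
    test0: str,
    case: PatientCase,
    matrix: TrainingMatrix,
    config: WeightConfig | None = None,
) -> float:
    """Score one candidate test for one case; higher means more recommended."""
    config = config or WeightConfig()
    if matrix.universe.M == 0:
        raise ConsistencyError("empty test universe")
    if test0 in case.taken_tests:
        raise DomainError(f"candidate {test0!r} already taken in case {case.case_id!r}")
    return float(_case_weights(matrix, case.taken_tests, [test0], config)[0])


def rank_candidates(
    case: PatientCase,
    matrix: TrainingMatrix,
    config: WeightConfig | None = None,
) -> Recommendation:
    """Rank every not-yet-taken test in the universe for this case."""
    config = config or WeightConfig()
    candidates = [t for t in matrix.universe.tests if t not in case.taken_tests]
    if not candidates:
        raise DomainError(f"case {case.case_id!r} has no candidate tests")
    weights = _case_weights(matrix, case.taken_tests, candidates, config)
    order = sorted(zip(candidates, weights), key=lambda cw: (-cw[1], cw[0]))
    return Recommendation(
        case_id=case.case_id, ranked=tuple((c, float(w)) for c, w in order)
    )


def write_recommendations(recs: list[Recommendation], stream) -> None:
    """TSV export: case_id, rank, test_code, weight (6 decimals)."""
    stream.write("case_id\trank\ttest_code\tweight\n")
    for rec in recs:
        for pos, (code, w) in enumerate(rec.ranked, start=1):
            stream.write(f"{rec.case_id}\t{pos}\t{code}\t{w:.6f}\n")
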