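"""Leave-one-test-out evaluation: split, label removal, CorrectRate_X.

The harness mirrors how such recommenders are validated without user
interaction: cases are split patient-wise into training and validation
sets; from each validation case one test is removed uniformly at random and
becomes the golden-standard label; the recommender, trained only on the
training side, ranks all candidate tests for the reduced case; and
``CorrectRate_X`` is the fraction of validation cases whose label lands in
the top X of the ranking.  Because the top-1 position is contained in the
top-3 prefix, CorrectRate_1 <= CorrectRate_3 on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from labrec.errors import ConsistencyError, EmptyInputError, ParameterError
from labrec.records_io import PatientCase, TestUniverse
from labrec.training import build_training_matrix
from labrec.weighting import Recommendation, WeightConfig, rank_candidates

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationPair:
    """A reduced validation case and the removed golden-standard test."""

    input_case: PatientCase
    label: str


@dataclass
class CaseOutcome:
    case_id: str
    label: str
    rank_of_label: int
    tops: dict[int, int]


@dataclass
class EvaluationResult:
    """Per-case hit indicators and the aggregate CorrectRate_X values."""

    per_case: list[CaseOutcome]
    correct_rates: dict[int, float]
    n: int
    excluded: int = 0
    xs: tuple[int, ...] = (1, 3)

    @property
    def correct_rate_1(self) -> float:
        return self.correct_rates[1]

    @property
    def correct_rate_3(self) -> float:
        return self.correct_rates[3]


def split_cases(
    cases: list[PatientCase],
    train_fraction: float,
    seed: int,
    by_patient: bool = True,
) -> tuple[list[PatientCase], list[PatientCase]]:
    """Randomly partition cases into training and validation sets.

    Targets ``round(train_fraction * N)`` training cases.  With
    ``by_patient`` (default) all cases of one patient land on the same side,
    so with multi-visit patients the achieved size is the closest the
    grouping allows.  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(cases) < 2:
        raise EmptyInputError("need at least 2 cases to split")

    rng = np.random.default_rng(seed)
    if by_patient:
        groups: dict[str, list[PatientCase]] = {}
        for case in cases:
            groups.setdefault(case.patient_id or case.case_id, []).append(case)
        keys = sorted(groups)
        order = rng.permutation(len(keys))
        target = round(train_fraction * len(cases))
        train: list[PatientCase] = []
        validation: list[PatientCase] = []
        for gi in order:
            bucket = groups[keys[gi]]
            if len(train) < target:
                train.extend(bucket)
            else:
                validation.extend(bucket)
        if not validation:  # degenerate grouping: give the last group back
            validation = groups[keys[order[-1]]]
            train = [c for c in train if c not in validation]
    else:
        order = rng.permutation(len(cases))
        target = round(train_fraction * len(cases))
        target = min(max(target, 1), len(cases) - 1)
        train = [cases[i] for i in order[:target]]
        validation = [cases[i] for i in order[target:]]
    if not train or not validation:
        raise EmptyInputError("split produced an empty side; adjust train_fraction")
    return train, validation


def remove_labels(
    validation: list[PatientCase], seed: int
) -> tuple[list[ValidationPair], int]:
    """Remove one uniformly chosen test per case as the golden standard.

    Cases with fewer than two tests are excluded (removal would leave no
    evidence) and counted; the exclusion count is returned alongside the
    pairs.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pairs: list[ValidationPair] = []
    excluded = 0
    for case in validation:
        if case.k < 2:
            excluded += 1
            continue
        tests = sorted(case.taken_tests)
        label = tests[rng.integers(len(tests))]
        reduced = PatientCase(
            case_id=case.case_id,
            taken_tests=case.taken_tests - {label},
            patient_id=case.patient_id,
        )
        pairs.append(ValidationPair(input_case=reduced, label=label))
    if not pairs:
        raise EmptyInputError("label removal excluded every validation case")
    if excluded:
        log.info("remove_labels: excluded %d single-test cases", excluded)
    return pairs, excluded


def correct_rate(rankings: list[Recommendation], labels: list[str], x: int) -> float:
    """Fraction of cases whose label appears among the top ``x`` candidates."""
    if x < 1:
        raise ParameterError(f"X must be >= 1, got {x}")
    if len(rankings) != len(labels) or not rankings:
        raise ConsistencyError(
            f"rankings ({len(rankings)}) and labels ({len(labels)}) must align and be non-empty"
        )
    hits = sum(1 for rec, label in zip(rankings, labels) if label in rec.top(x))
    return hits / len(rankings)


def run_experiment(
    cases: list[PatientCase],
    weight_config: WeightConfig | None = None,
    train_fraction: float = 0.6,
    split_seed: int = 0,
    label_seed: int = 1,
    xs: tuple[int, ...] = (1, 3),
    universe: TestUniverse | None = None,
) -> EvaluationResult:
    """The full pipeline: split, remove labels, train, rank, score.

    The training matrix is built over the universe of *all* cases so that
    validation-only tests are rankable candidates (with zero counts, they
    survive only through smoothing).  Fully reproducible from the two seeds.
    """
    weight_config = weight_config or WeightConfig()
    universe = universe or TestUniverse.from_codes(
        t for c in cases for t in c.taken_tests
    )
    try:
        train, validation = split_cases(cases, train_fraction, split_seed)
    except EmptyInputError as exc:
        raise EmptyInputError(f"split stage: {exc}") from exc
    pairs, excluded = remove_labels(validation, label_seed)
    matrix = build_training_matrix(train, universe)

    outcomes: list[CaseOutcome] = []
    rankings: list[Recommendation] = []
    for pair in pairs:
        rec = rank_candidates(pair.input_case, matrix, weight_config)
        rankings.append(rec)
        codes = [c for c, _ in rec.ranked]
        rank_of_label = codes.index(pair.label) + 1
        outcomes.append(
            CaseOutcome(
                case_id=pair.input_case.case_id,
                label=pair.label,
                rank_of_label=rank_of_label,
                tops={x: int(rank_of_label <= x) for x in xs},
            )
        )
    labels = [p.label for p in pairs]
    rates = {x: correct_rate(rankings, labels, x) for x in xs}
    return EvaluationResult(
        per_case=outcomes, correct_rates=rates, n=len(pairs), excluded=excluded, xs=xs
    )


def parameter_sweep(
    cases: list[PatientCase],
    method: str,
    grid: list[float],
    base_config: WeightConfig | None = None,
    train_fraction: float = 0.6,
    split_seed: int = 0,
    label_seed: int = 1,
) -> pd.DataFrame:
    """One experiment per grid value of the smoothing parameter.

    The split and label seeds are identical across grid points, so rows
    differ only through the parameter.  Returns a DataFrame with columns
    method, param, correct_rate_1, correct_rate_3.
    """
    from labrec.smoothing import SmoothingConfig

    base_config = base_config or WeightConfig()
    rows = []
    for param in grid:
        if not 0.0 <= param <= 1.0:
            raise ParameterError(f"grid value {param} outside [0, 1]")
        cfg = WeightConfig(
            smoothing=SmoothingConfig(
                method=method, param=param, theta=base_config.smoothing.theta
            ),
            evidence_mode=base_config.evidence_mode,
            epsilon=base_config.epsilon,
        )
        result = run_experiment(
            cases, cfg, train_fraction, split_seed, label_seed, xs=(1, 3)
        )
        rows.append(
            {
                "method": cfg.smoothing.method,
                "param": param,
                "correct_rate_1": result.correct_rate_1,
                "correct_rate_3": result.correct_rate_3,
            }
        )
    return pd.DataFrame(rows)


def write_metrics(result: EvaluationResult, stream) -> None:
    """Aggregate metrics TSV: X, correct_rate, n, excluded_count."""
    stream.write("X\tcorrect_rate\tn\texcluded_count\n")
    for x in result.xs:
        stream.write(f"{x}\t{result.correct_rates[x]:.6f}\t{result.n}\t{result.excluded}\n")


def write_per_case(result: EvaluationResult, stream) -> None:
    """Per-case TSV: case_id, label, rank_of_label, TOP_x columns."""
    xs = result.xs
    stream.write("case_id\tlabel\trank_of_label\t" + "\t".join(f"TOP_{x}" for x in xs) + "\n")
    for oc in result.per_case:
        tops = "\t".join(str(oc.tops[x]) for x in xs)
        stream.write(f"{oc.case_id}\t{oc.label}\t{oc.rank_of_label}\t{tops}\n")
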