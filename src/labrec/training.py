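"""The symmetric test-by-test co-occurrence training matrix.

The matrix summarises the training cases once so that scoring never has to
re-scan the raw records: entry (i, j), i != j, counts the cases in which
tests i and j were taken together; the diagonal stores the per-test
marginal count (how many cases contain the test), which also makes the
conditional probability of a test given itself equal 1.  All counts are
case-level and binary — a pair co-occurring twice in one case still adds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np

from labrec.errors import ConsistencyError, EmptyInputError, FormatError, TestLookupError
from labrec.records_io import PatientCase, TestUniverse


@dataclass
class TrainingMatrix:
    """Co-occurrence counts over a fixed test universe.

    ``joint`` is a dense symmetric ``M x M`` integer array with the marginal
    counts on the diagonal; ``n_cases`` is the number of cases the counts
    were accumulated from (the "number of patients" denominator).
    """

    universe: TestUniverse
    n_cases: int
    joint: np.ndarray

    def __post_init__(self) -> None:
        self._index = self.universe.index()

    @property
    def marginal(self) -> np.ndarray:
        return np.diagonal(self.joint)

    def idx(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise TestLookupError(f"unknown test code {code!r}") from None

    def counts(self, i: str, j: str | None = None) -> int:
        """Marginal count of ``i``, or joint count of ``i`` and ``j``."""
        ii = self.idx(i)
        if j is None:
            return int(self.joint[ii, ii])
        return int(self.joint[ii, self.idx(j)])


def build_training_matrix(
    cases: list[PatientCase], universe: TestUniverse
) -> TrainingMatrix:
    """Accumulate the co-occurrence matrix from a list of cases.

    Equivalent to ``X.T @ X`` for the binary case-by-test incidence matrix
    ``X``: each unordered pair of distinct tests taken together in a case
    adds 1 to both symmetric entries, and each taken test adds 1 to its
    diagonal (marginal) entry.
    """
    if not cases:
        raise EmptyInputError("cannot build a training matrix from zero cases")
    index = universe.index()
    M = universe.M
    joint = np.zeros((M, M), dtype=np.int64)
    for case in cases:
        try:
            ix = np.fromiter(
                (index[t] for t in sorted(case.taken_tests)), dtype=np.intp
            )
        except KeyError:
            bad = sorted(set(case.taken_tests) - set(universe.tests))
            raise ConsistencyError(
                f"case {case.case_id!r} contains tests outside the universe: {bad}"
            ) from None
        joint[np.ix_(ix, ix)] += 1
    return TrainingMatrix(universe=universe, n_cases=len(cases), joint=joint)


def save_matrix(matrix: TrainingMatrix, stream: TextIO) -> None:
    """Serialize as plain text: ``M n_cases``, the codes, then M count rows."""
    stream.write(f"{matrix.universe.M}\t{matrix.n_cases}\n")
    stream.write("\t".join(matrix.universe.tests) + "\n")
    for row in matrix.joint:
        stream.write("\t".join(str(int(v)) for v in row) + "\n")


def load_matrix(stream: TextIO) -> TrainingMatrix:
    """Inverse of :func:`save_matrix`; round-trips bit-exactly."""
    header = stream.readline().split()
    if len(header) != 2:
        raise FormatError("matrix file: first line must be 'M n_cases'")
    M, n_cases = int(header[0]), int(header[1])
    codes = stream.readline().rstrip("\n").split("\t")
    if len(codes) != M:
        raise FormatError(f"matrix file: expected {M} test codes, got {len(codes)}")
    joint = np.zeros((M, M), dtype=np.int64)
    for i in range(M):
        row = stream.readline().split("\t")
        if len(row) != M:
            raise FormatError(f"matrix file: row {i} has {len(row)} entries, expected {M}")
        joint[i] = [int(v) for v in row]
    if not np.array_equal(joint, joint.T):
        raise FormatError("matrix file: counts are not symmetric")
    return TrainingMatrix(
        universe=TestUniverse(tests=tuple(codes)), n_cases=n_cases, joint=joint
    )
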