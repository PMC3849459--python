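"""Synthetic patient cases with planted test-panel structure.

Real ordering data couples tests through latent clinical conditions — a
patient investigated for diabetes tends to receive the hemoglobin and
fasting-glucose tests in the same visit.  The generator emulates exactly
that mechanism: each case independently carries each of ``n_conditions``
latent conditions with probability ``p_condition``; a carried condition
fires each test of its (disjoint) panel with probability ``p_panel_test``;
and every test outside the fired panels appears independently with
probability ``noise_rate``.  With no conditions the data are pure
independent noise, which calibrates the chance-level baseline.

Each synthetic case is a single visit of its own patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np

from labrec.errors import GenerationError, ParameterError
from labrec.records_io import PatientCase, TestUniverse

_RESAMPLE_BUDGET = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults plant 4 disjoint panels of 5 tests in a 20-test universe;
    each case carries each condition with probability 0.5, fires each panel
    test with probability 0.9, and adds each off-panel test with
    probability 0.02.
    """

    n_cases: int = 500
    M: int = 20
    n_conditions: int = 4
    panel_size: int = 5
    p_condition: float = 0.5
    p_panel_test: float = 0.9
    noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.M < 1:
            raise ParameterError("n_cases and M must be positive")
        if self.n_conditions < 0 or self.panel_size < 1:
            raise ParameterError("n_conditions must be >= 0 and panel_size >= 1")
        if self.n_conditions * self.panel_size > self.M:
            raise ParameterError(
                f"{self.n_conditions} panels of {self.panel_size} do not fit in M={self.M}"
            )
        for name in ("p_condition", "p_panel_test", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    def panels(self) -> list[tuple[int, ...]]:
        """Disjoint panels: condition c owns tests [c*s, (c+1)*s)."""
        s = self.panel_size
        return [tuple(range(c * s, (c + 1) * s)) for c in range(self.n_conditions)]


def _test_code(i: int, width: int) -> str:
    return f"T{i:0{width}d}"


def generate_cases(
    config: SyntheticConfig,
) -> tuple[list[PatientCase], TestUniverse, list[tuple[int, ...]]]:
    """Sample cases; returns (cases, universe, per-case condition tuples).

    Cases that come out empty are resampled (bounded budget per case), so
    every returned case has at least one test.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.M - 1))
    codes = [_test_code(i, width) for i in range(config.M)]
    universe = TestUniverse(tests=tuple(sorted(codes)))
    panels = config.panels()

    cases: list[PatientCase] = []
    truth: list[tuple[int, ...]] = []
    for j in range(config.n_cases):
        for _ in range(_RESAMPLE_BUDGET):
            held = tuple(
                c for c in range(config.n_conditions)
                if rng.random() < config.p_condition
            )
            taken: set[int] = set()
            panel_tests = set()
            for c in held:
                for t in panels[c]:
                    panel_tests.add(t)
                    if rng.random() < config.p_panel_test:
                        taken.add(t)
            for t in range(config.M):
                if t not in panel_tests and rng.random() < config.noise_rate:
                    taken.add(t)
            if taken:
                break
        else:
            raise GenerationError(
                f"case {j}: no non-empty sample in {_RESAMPLE_BUDGET} tries; "
                "the configuration is degenerate"
            )
        pid = f"P{j:05d}"
        cases.append(
            PatientCase(
                case_id=pid,
                taken_tests=frozenset(codes[t] for t in taken),
                patient_id=pid,
            )
        )
        truth.append(held)
    return cases, universe, truth


def random_baseline(M: int, k: int, X: int) -> float:
    """Chance that a uniformly random ranking hits the label in the top X.

    A case with ``k`` taken tests has ``M - k`` candidates, one of which is
    the removed label, so a random ranking succeeds with probability
    ``X / (M - k)``.
    """
    if k >= M:
        raise ParameterError(f"k={k} leaves no candidates in a universe of M={M}")
    if not 1 <= X <= M - k:
        raise ParameterError(f"X={X} outside [1, M-k={M - k}]")
    return X / (M - k)


def write_records_csv(
    cases: list[PatientCase], stream: TextIO, service_date: str = "2013-01-15"
) -> None:
    """Write cases in the raw record layout so the normal reader ingests them.

    All cases share one service date (each is one visit of its own
    patient); the non-consumed columns are padded with placeholders.
    """
    header = [
        "SDTE", "REQ#", "PNUM", "PNAM", "PSEX", "BDTE",
        "TSEQ", "TEST", "DESC", "RSLT", "NORM", "REXP", "EXRS",
    ]
    stream.write(",".join(header) + "\n")
    for j, case in enumerate(cases):
        for seq, code in enumerate(sorted(case.taken_tests), start=1):
            row = [
                service_date, f"R{j:06d}", case.patient_id, "SYNTHETIC", "U",
                "1970-01-01", str(seq), code, f"synthetic test {code}",
                "", "", "N", "N",
            ]
            stream.write(",".join(row) + "\n")
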