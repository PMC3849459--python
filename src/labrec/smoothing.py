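"""Smoothing of the count-ratio probabilities used by the weighting score.

Raw count ratios put zero probability on any test pair never seen together
in training, which makes the log-odds score diverge.  The fixes are the
standard language-model smoothers, specialised to two quantities:

* the conditional probability ``beta`` of a taken test given the candidate
  test, shrunk toward the taken test's marginal probability ``gamma``
  (Jelinek-Mercer interpolation, a Dirichlet-prior mixture with the
  concentration normalised into [0, 1], or absolute discounting of the
  joint count); and
* the prior log-odds of the candidate, additively (Laplace) smoothed so it
  stays finite when the candidate was never / always seen.

All smoothers are pure functions; :func:`apply` dispatches on a
:class:`SmoothingConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from labrec.errors import DegeneratePriorError, ParameterError

#: Recognised method names (plus common short forms accepted by configs).
METHODS = ("none", "jelinek_mercer", "dirichlet", "absolute_discounting")
_SHORT = {"jm": "jelinek_mercer", "dir": "dirichlet", "ad": "absolute_discounting"}


@dataclass(frozen=True)
class SmoothingConfig:
    """Choice of beta-smoother and the Laplace prior parameter.

    ``param`` is the method's own parameter (lambda for Jelinek-Mercer,
    the normalised mu for Dirichlet, delta for absolute discounting), all
    constrained to [0, 1]; ``theta`` in [0, 1] is the additive-smoothing
    parameter for the prior log-odds.
    """

    method: str = "none"
    param: float = 0.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        method = _SHORT.get(self.method, self.method)
        object.__setattr__(self, "method", method)
        if method not in METHODS:
            raise ParameterError(f"unknown smoothing method {self.method!r}")
        if not 0.0 <= self.param <= 1.0:
            raise ParameterError(f"smoothing param must be in [0, 1], got {self.param}")
        if not 0.0 <= self.theta <= 1.0:
            raise ParameterError(f"theta must be in [0, 1], got {self.theta}")


def jelinek_mercer(beta: float, gamma: float, lam: float) -> float:
    """Linear interpolation ``(1 - lam) * beta + lam * gamma``."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    return (1.0 - lam) * beta + lam * gamma


def dirichlet(beta: float, gamma: float, mu: float) -> float:
    """Dirichlet-prior mixture ``(beta + mu * gamma) / (1 + mu)``.

    This is the classical count-space form with both numerator and
    denominator divided by the conditioning count, so the concentration
    ``mu`` lives on [0, 1] rather than in absolute counts.
    """
    if mu < 0.0:
        raise ParameterError(f"mu must be non-negative, got {mu}")
    return (beta + mu * gamma) / (1.0 + mu)


def absolute_discounting(
    joint_count: float, base_count: float, delta: float, gamma: float
) -> float:
    """Discount the joint count by ``delta`` and add back ``delta * gamma``.

    ``joint_count`` is the co-occurrence count of the taken test with the
    candidate, ``base_count`` the candidate's marginal count.  With
    ``base_count == 0`` (candidate never seen) the discounted term is
    dropped entirely and ``delta * gamma`` is all that remains.  The output
    is not renormalised over tests and may slightly exceed 1; downstream
    flooring in the log keeps scores finite.
    """
    if not 0.0 <= delta <= 1.0:
        raise ParameterError(f"delta must be in [0, 1], got {delta}")
    if base_count == 0:
        return delta * gamma
    return max(joint_count - delta, 0.0) / base_count + delta * gamma


def laplace_log_odds(alpha: float, theta: float) -> float:
    """Additively smoothed log-odds ``log((alpha + theta) / (1 - alpha + theta))``.

    Natural logarithm.  With ``theta == 0`` this is the raw log-odds and is
    undefined at alpha exactly 0 or 1.
    """
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta must be in [0, 1], got {theta}")
    num, den = alpha + theta, 1.0 - alpha + theta
    if num <= 0.0 or den <= 0.0:
        raise DegeneratePriorError(
            f"log-odds undefined at alpha={alpha} with theta={theta}"
        )
    return math.log(num / den)


def apply(
    config: SmoothingConfig,
    beta: float,
    gamma: float,
    joint_count: float = 0.0,
    base_count: float = 0.0,
) -> float:
    """Dispatch to the configured beta-smoother.

    ``joint_count`` / ``base_count`` are only consulted by absolute
    discounting, which works on counts rather than on the ratio.
    """
    if config.method == "none":
        return beta
    if config.method == "jelinek_mercer":
        return jelinek_mercer(beta, gamma, config.param)
    if config.method == "dirichlet":
        return dirichlet(beta, gamma, config.param)
    return absolute_discounting(joint_count, base_count, config.param, gamma)
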