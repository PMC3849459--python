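"""YAML configuration for the smoothing and weighting knobs.

Layout::

    smoothing:
      method: jelinek_mercer   # none | jelinek_mercer | dirichlet | absolute_discounting
      param: 0.2               # lambda / mu / delta
      theta: 0.5               # Laplace parameter for the prior log-odds
    weighting:
      evidence_mode: exact     # exact | literal
      epsilon: 1.0e-12

Command-line flags override file values.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from labrec.smoothing import SmoothingConfig
from labrec.weighting import WeightConfig


def load_weight_config(path: str | Path) -> WeightConfig:
    """Read a :class:`WeightConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    smooth = raw.get("smoothing", {}) or {}
    weigh = raw.get("weighting", {}) or {}
    return WeightConfig(
        smoothing=SmoothingConfig(
            method=smooth.get("method", "none"),
            param=float(smooth.get("param", 0.0)),
            theta=float(smooth.get("theta", 0.5)),
        ),
        evidence_mode=weigh.get("evidence_mode", "exact"),
        epsilon=float(weigh.get("epsilon", 1e-12)),
    )


def dump_weight_config(config: WeightConfig) -> dict:
    """The YAML-serialisable form of a config (used in run manifests)."""
    return {
        "smoothing": {
            "method": config.smoothing.method,
            "param": config.smoothing.param,
            "theta": config.smoothing.theta,
        },
        "weighting": {
            "evidence_mode": config.evidence_mode,
            "epsilon": config.epsilon,
        },
    }
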