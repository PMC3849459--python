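"""Sensitivity of the hit rates to the Jelinek-Mercer parameter.

One experiment per lambda on a fixed split (identical seeds across grid
points), mirroring the usual smoothing-parameter sensitivity study: some
interpolation toward the marginal helps sparse pairs, too much makes the
ranking ignore the patient entirely.
"""

from labrec import SyntheticConfig, generate_cases
from labrec.evaluation import parameter_sweep
from labrec.smoothing import SmoothingConfig
from labrec.weighting import WeightConfig

cases, _, _ = generate_cases(SyntheticConfig(seed=7))
base = WeightConfig(smoothing=SmoothingConfig("none", 0.0, 0.5))

table = parameter_sweep(
    cases,
    method="jelinek_mercer",
    grid=[round(0.1 * i, 1) for i in range(11)],
    base_config=base,
    train_fraction=0.6,
    split_seed=1,
    label_seed=2,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nCorrectRate_1 stays below CorrectRate_3 on every row; lambda = 1\n"
    "replaces the conditional by the marginal, so the ranking degrades\n"
    "toward popularity ordering."
)
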