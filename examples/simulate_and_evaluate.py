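"""Full pipeline on synthetic data: simulate, split, remove labels, score.

The generator plants 4 disjoint 5-test panels (latent conditions) in a
20-test universe.  The leave-one-test-out harness removes one test per
validation case and asks the recommender to find it; CorrectRate_X is the
fraction of cases where the removed test lands in the top X.
"""

import numpy as np

from labrec import (
    SmoothingConfig,
    SyntheticConfig,
    WeightConfig,
    generate_cases,
    random_baseline,
    run_experiment,
)
from labrec.evaluation import remove_labels, split_cases

config = SyntheticConfig(seed=7)  # 500 cases, M=20, 4 panels of 5
cases, universe, _ = generate_cases(config)

weight_config = WeightConfig(
    smoothing=SmoothingConfig(method="jelinek_mercer", param=0.2, theta=0.5)
)
result = run_experiment(
    cases, weight_config, train_fraction=0.6, split_seed=1, label_seed=2
)

train, val = split_cases(cases, 0.6, seed=1)
pairs, _ = remove_labels(val, seed=2)
chance_1 = np.mean([random_baseline(universe.M, p.input_case.k, 1) for p in pairs])

print(f"cases: {len(cases)}  evaluated: {result.n}  excluded (k<2): {result.excluded}")
print(f"CorrectRate_1 = {result.correct_rate_1:.4f}   (chance ≈ {chance_1:.4f})")
print(f"CorrectRate_3 = {result.correct_rate_3:.4f}")
print(
    "\nThe removed test is recovered in the top 3 for the vast majority of\n"
    "visits, far above the uniform-ranking chance level, because same-panel\n"
    "tests co-occur strongly in the training matrix."
)
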