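"""Generate the reference non-stationary feature stream.

Builds the default two-class scenario (120 stationary training trials,
160 test trials, one covariate shift of 1.5 pooled within-class SDs at
test trial 80), draws the stream, and prints what actually changed at the
change point: the feature means move, while the error rate of the fixed
labelling rule — a direct probe of P(y|x) — stays at the label-noise
level in both segments.
"""

import numpy as np

from driftbci.synthgen import (
    default_feature_scenario,
    pooled_within_class_sd,
    simulate_feature_stream,
)
from driftbci.synthgen import _base_covariance, _rule_and_offset

scenario = default_feature_scenario(seed=0)
stream = simulate_feature_stream(scenario)
cp = scenario.change_points[0]

print(f"trials: {scenario.n_trials} ({scenario.n_train} train, "
      f"{scenario.n_trials - scenario.n_train} test)")
print(f"change point at trial {cp} "
      f"(= test trial {cp - scenario.n_train})")
print(f"pooled within-class SD per feature: "
      f"{np.round(pooled_within_class_sd(scenario), 3)}")

delta = stream.features.X[cp:].mean(0) - stream.features.X[:cp].mean(0)
print(f"observed mean shift per feature:    {np.round(delta, 3)}")

rule = _rule_and_offset(scenario, _base_covariance(scenario))
pred = rule.apply(stream.features.X)
err_pre = np.mean(pred[:cp] != stream.labels[:cp])
err_post = np.mean(pred[cp:] != stream.labels[cp:])
print(f"rule error pre-shift  {err_pre:.3f} (label noise = 0.05)")
print(f"rule error post-shift {err_post:.3f}  -> P(y|x) unchanged: "
      "the shift is a pure covariate shift")
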