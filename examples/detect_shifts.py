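"""Two-stage covariate-shift estimation on a synthetic stream.

Calibrates the EWMA chart on the stationary training prefix (smoothing
constant by 1-step-ahead SSE grid search, residual SDs for the control
limits), then streams the test trials through the detector: stage-I
warnings where the prediction error exceeds L·sigma_e, stage-II Hotelling
T² confirmation of each warning against a sample of training features.
"""

from driftbci import cli_io
from driftbci.features import FeatureStream, pca_fit_reduce
from driftbci.shiftdetect import (
    EwmaMonitor,
    isolated_shift_refractory,
    run_cse,
)
from driftbci.synthgen import default_feature_scenario, simulate_feature_stream

scenario = default_feature_scenario(seed=3, shift=2.0)
stream = simulate_feature_stream(scenario)
train, test, _, _ = stream.train_test()
true_cp = scenario.change_points[0] - scenario.n_train

profile = cli_io.prompt_detection_profile()
pca, _ = pca_fit_reduce(FeatureStream(train.X), profile.pca_variance)
monitor = EwmaMonitor.calibrate(pca.transform(train.X), L=profile.L)
print(f"selected lambda*: {monitor.lam:.2f}   "
      f"monitored PCA components: {monitor.n_components}")

events = run_cse(monitor, pca.transform(test.X), pca.transform(train.X),
                 alpha=profile.alpha, n_w=profile.n_w,
                 refractory=isolated_shift_refractory(profile.n_w), seed=3)

print(f"true change point: test trial {true_cp}")
n_warn = sum(e.stage == "warning" for e in events)
print(f"{n_warn} stage-I warnings; stage-II outcomes:")
for e in events:
    if e.stage != "warning":
        print(f"  trial {e.trial:3d}: {e.stage:11s} "
              f"T2={e.t2:7.2f}  p={e.p_value:.2e}")
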