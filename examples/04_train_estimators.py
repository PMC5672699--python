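"""Train the quadratic regression and the backprop network on one cohort.

Simulates a small cohort, featurizes every frame, fits both learned
estimators on a random half of the frames and reports held-out accuracy.
"""

import numpy as np

from lvvol import (
    BPNetConfig,
    CohortSpec,
    SplitPlan,
    fit_bpnet,
    fit_quadratic,
    make_cohort,
    predict_bpnet,
    predict_quadratic,
    radial_distances,
    split_cohort,
)

cohort, _ = make_cohort(CohortSpec(n_cases=10, seed=4))
features, volumes = [], []
for cyc in cohort:
    for fr in cyc.frames:
        features.append(radial_distances(fr.border).distances)
        volumes.append(fr.volume_ml)
features = np.vstack(features)
volumes = np.asarray(volumes)

train, test = split_cohort(cohort, SplitPlan(fraction_train=0.5, seed=0))
flat = {(i, j): k for k, (i, j) in enumerate(
    (i, j) for i, cyc in enumerate(cohort) for j in range(len(cyc))
)}
tr = [flat[p] for p in train]
te = [flat[p] for p in test]

quad = fit_quadratic(features[tr], volumes[tr])
net, report = fit_bpnet(features[tr], volumes[tr],
                        BPNetConfig(max_epochs=8000, seed=0))

pred_q = np.array([predict_quadratic(quad, f) for f in features[te]])
pred_n = predict_bpnet(net, features[te])
for name, pred in (("quadratic regression", pred_q), ("backprop net", pred_n)):
    rmse = float(np.sqrt(np.mean((pred - volumes[te]) ** 2)))
    print(f"{name:21s}: held-out RMSE = {rmse * 1000:.1f} µl "
          f"on {len(te)} frames")
print(f"network trained {len(report.losses)} epochs, "
      f"final training MSE = {report.losses[-1]:.2e} ml^2")
print("Both models learn the distance-to-volume mapping from reference "
      "volumes; the RMSE reflects the 0.3 mm delineation jitter in the "
      "simulated borders.")
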