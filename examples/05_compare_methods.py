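"""Compare ranking methods statistically and by feature-set overlap.

The combined 5x2cv F-test checks whether the error rates of the
best-performing ranking differ significantly from each other ranking at
the same feature count; the Jaccard index measures how much the selected
top-k feature sets overlap between methods.
"""

from ictalsel import (
    SynthConfig, band_decompose, extract_features, filter_recording,
    generate_recording, prune_correlated, rebalance, segment,
)
from ictalsel.evaluate import CLASSIFIER_CONFIGS, f_test_5x2cv, run_5x2cv
from ictalsel.fsm import FsmConfig, LimeConfig, ShapConfig
from ictalsel.pipeline import compute_rankings
from ictalsel.similarity import pairwise_similarity

from ictalsel.synth import IctalComponent

config = SynthConfig(
    n_channels=4, duration=600.0, n_seizures=4, seizure_duration=30.0,
    seizure_jitter=5.0,
    ictal_spec=(IctalComponent(0, "theta", 4.0, 6.0),), seed=7,
)
epochs = band_decompose(rebalance(segment(filter_recording(generate_recording(config)))))
fm, _ = prune_correlated(extract_features(epochs))

fsm_config = FsmConfig(lime=LimeConfig(n_explain=25, seed=3),
                       shap=ShapConfig(n_explain=8, n_coalitions=300, seed=3))
rankings = compute_rankings(
    fm, CLASSIFIER_CONFIGS["FS1"]["RF"], fsm_config,
    ("dt", "svm", "lime", "shap", "erf", "rr"), seed=11)

k = 12
clf = CLASSIFIER_CONFIGS["FS1"]["RF"]
results = {m: run_5x2cv(fm, r, k, clf, seed=0) for m, r in rankings.items()}
best = max(results.values(), key=lambda r: (r.f1, r.sensitivity, r.accuracy))
print(f"best ranking at k={k}: {best.fsm} (F1={best.f1:.3f})\n")

print(f"{'vs':>5}  {'F1':>6}  {'F':>7}  {'p':>6}  sig")
for method, res in results.items():
    if method == best.fsm:
        continue
    test = f_test_5x2cv(best.fold_errors, res.fold_errors)
    print(f"{method:>5}  {res.f1:6.3f}  {test['F']:7.2f}  {test['p']:6.3f}  "
          f"{'*' if test['significant'] else ''}")

print(f"\nJaccard similarity of top-{k} feature sets (floored to 2 decimals):")
sim = pairwise_similarity(list(rankings.values()), k=k)
print(sim.to_frame(presentation=True).to_string())
# A '*' marks p < 0.05: the fold-wise error rates of that ranking differ
# significantly from the best one.  High Jaccard entries mean two methods
# selected largely the same features.
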