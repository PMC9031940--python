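"""Stepwise feature elimination under 5x2 cross-validation.

Keeps the top-k features of the permutation-importance ranking and
re-evaluates a random forest at each cutoff of the elimination schedule
(multiples of 50, then 25, 12, 6, 1).  The F1-score is computed for the
ictal (minority) class.
"""

from ictalsel import (
    SynthConfig, band_decompose, extract_features, filter_recording,
    generate_recording, prune_correlated, rebalance, segment,
)
from ictalsel.evaluate import CLASSIFIER_CONFIGS, elimination_schedule, run_5x2cv
from ictalsel.fsm import FsmConfig
from ictalsel.pipeline import compute_rankings
from ictalsel.synth import IctalComponent

config = SynthConfig(
    n_channels=4, duration=600.0, n_seizures=4, seizure_duration=30.0,
    seizure_jitter=5.0,
    ictal_spec=(IctalComponent(0, "theta", 4.0, 6.0),), seed=7,
)
epochs = band_decompose(rebalance(segment(filter_recording(generate_recording(config)))))
fm, _ = prune_correlated(extract_features(epochs))

ranking = compute_rankings(
    fm, CLASSIFIER_CONFIGS["FS1"]["RF"], FsmConfig(), ("erf",), seed=11)["erf"]
clf = CLASSIFIER_CONFIGS["FS1"]["RF"]

print(f"{'kept':>5}  {'F1':>6}  {'Se':>6}  {'Acc':>6}  {'err':>6}")
for k in elimination_schedule(fm.n_features):
    res = run_5x2cv(fm, ranking, k, clf, seed=0)
    print(f"{k:>5}  {res.f1:6.3f}  {res.sensitivity:6.3f}  "
          f"{res.accuracy:6.3f}  {res.fold_errors.mean():6.3f}")
# F1 stays near its full-feature value down to a handful of features and
# only collapses once the planted discriminative features are eliminated
# -- large reductions of the feature vector cost little performance.
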