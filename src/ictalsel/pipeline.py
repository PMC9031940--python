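"""One-command orchestration of the full evaluation study.

``run_pipeline`` chains the stages: simulate (or load) a recording ->
preprocess (montage/filter/epoch/rebalance/band-decompose) -> extract and
prune features -> rank with every configured FSM per classifier ->
5x2cv elimination curves -> F-test comparison tables -> feature-set
similarity matrices.  All artifacts are plain CSV plus a JSON manifest
echoing the resolved configuration, and every stage derives its seed from
the global one, so a rerun with the same config is bit-identical for the
deterministic stages.

Feature extraction is cached inside the run directory keyed on a hash of
the configuration that affects it, so re-running with a different
classifier list does not recompute features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import fsm as fsm_mod
from .features import FeatureConfig, FeatureMatrix, extract_features, prune_correlated
from .fsm import FsmConfig, Ranking
from .preprocess import PreprocessConfig, band_decompose, filter_recording, rebalance, segment
from .similarity import pairwise_similarity, top_features_report
from .synth import Recording, SynthConfig, generate_recording

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("ictalsel")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    fsm: FsmConfig = field(default_factory=FsmConfig)
    classifiers: tuple[str, ...] = ("RF",)
    fsm_methods: tuple[str, ...] = fsm_mod.FSM_METHODS
    schedule: tuple[int, ...] | None = None       # None = automatic schedule
    similarity_ks: tuple[int, ...] = (10,)
    prune: bool = True
    seed: int = 0

    def sub_seed(self, label: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _config_hash(*parts: Any) -> str:
    payload = json.dumps([_to_jsonable(p) for p in parts], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_rankings(
    fm: FeatureMatrix,
    clf_config: ev.ClassifierConfig,
    config: FsmConfig,
    methods: tuple[str, ...],
    seed: int,
) -> dict[str, Ranking]:
    """All requested rankings for one classifier pairing.

    A seeded stratified 50% subsample of the data, min-max scaled, is used
    wherever ranking needs model training; LIME and kernel SHAP explain
    the classifier family later evaluated with the ranking; the
    permutation ranker trains on half the subsample and measures on the
    disjoint other half.
    """
    X_sub, y_sub = fsm_mod.ranking_subsample(
        fm.values, fm.labels, config.ranking_subsample_fraction, seed
    )
    Xs, _ = ev.minmax_scale(X_sub, X_sub)
    names = fm.feature_names
    rankings: dict[str, Ranking] = {}

    model = None
    if "lime" in methods or "shap" in methods:
        model = ev.build_classifier(clf_config.with_seed(seed)).fit(Xs, y_sub)

    for method in methods:
        if method == "dt":
            rankings["dt"] = fsm_mod.rank_dt_gini(Xs, y_sub, names, config)
        elif method == "svm":
            rankings["svm"] = fsm_mod.rank_svm_weights(Xs, y_sub, names, config)
        elif method == "lime":
            rankings["lime"] = fsm_mod.rank_lime(Xs, y_sub, model, names, config)
        elif method == "shap":
            rankings["shap"] = fsm_mod.rank_kernel_shap(Xs, y_sub, model, names, config)
        elif method == "erf":
            half = len(y_sub) // 2
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(y_sub))
            tr, ho = perm[:half], perm[half:]
            rankings["erf"] = fsm_mod.rank_erf_permutation(
                Xs[tr], y_sub[tr], names, Xs[ho], y_sub[ho], config
            )
        elif method != "rr":
            raise ValueError(f"unknown FSM method {method!r}")
    if "rr" in methods:
        base = [rankings[m] for m in ("dt", "svm", "lime", "shap", "erf") if m in rankings]
        if not base:
            raise ValueError("reciprocal rank fusion needs base rankings")
        rankings["rr"] = fsm_mod.reciprocal_rank_fusion(base)
    return rankings


def _best_fsm(results: list[ev.EvalResult]) -> ev.EvalResult:
    # ties on F1 break by sensitivity then accuracy
    return max(results, key=lambda r: (r.f1, r.sensitivity, r.accuracy))


def run_pipeline(
    config: PipelineConfig,
    out_dir: Path,
    recording: Recording | None = None,
    stages: tuple[str, ...] = ("simulate", "extract", "rank", "evaluate", "compare"),
) -> dict[str, Any]:
    """Execute the study and write artifacts under ``out_dir``.

    Returns a dict with the in-memory artifacts (recording, feature
    matrix, rankings, evaluation table, F-tests, similarity matrices).
    On a stage failure a partial manifest is still written and
    :class:`PipelineError` names the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _to_jsonable(config),
        "stages_completed": [],
    }
    artifacts: dict[str, Any] = {"manifest": manifest}

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        stage = "simulate"
        if recording is None:
            recording = generate_recording(config.synth)
        artifacts["recording"] = recording
        manifest["n_seizures"] = len(recording.seizures)
        log.info("simulate: %d channels, %.0f s, %d seizures",
                 recording.n_channels, recording.duration, len(recording.seizures))
        finish_stage(stage)
        if "extract" not in stages:
            return artifacts

        stage = "extract"
        feat_hash = _config_hash(config.synth, config.preprocess, config.features,
                                 config.prune, config.seed)
        cache = out_dir / f"features_{feat_hash}.csv"
        if cache.exists():
            fm = FeatureMatrix.from_csv(cache)
            audit: list = []
            log.info("extract: reused cache %s (%d features)", cache.name, fm.n_features)
        else:
            filtered = filter_recording(recording, config.preprocess)
            epochs = segment(filtered, config.preprocess)
            epochs = rebalance(epochs, dataclasses.replace(
                config.preprocess, seed=config.sub_seed("rebalance")))
            epochs = band_decompose(epochs, config.preprocess)
            fm = extract_features(epochs, config.features)
            manifest["n_features_pre_prune"] = fm.n_features
            if config.prune:
                fm, audit = prune_correlated(fm, config.features.corr_threshold)
                dropped = [a.name for a in audit if a.reason == "correlated"]
                manifest["n_features_pruned"] = len(dropped)
                log.info("extract: pruned %d correlated features", len(dropped))
            else:
                audit = []
            fm.to_csv(cache)
        manifest["n_epochs"] = int(fm.values.shape[0])
        manifest["n_ictal"] = int(fm.labels.sum())
        manifest["n_features"] = fm.n_features
        artifacts["features"] = fm
        artifacts["prune_audit"] = audit
        finish_stage(stage)
        if "rank" not in stages:
            return artifacts

        stage = "rank"
        fs = config.features.feature_set
        all_rankings: dict[str, dict[str, Ranking]] = {}
        for kind in config.classifiers:
            clf_config = ev.CLASSIFIER_CONFIGS[fs][kind].with_seed(
                config.sub_seed(f"clf:{kind}"))
            rankings = compute_rankings(
                fm, clf_config, config.fsm, config.fsm_methods,
                config.sub_seed(f"rank:{kind}"),
            )
            all_rankings[kind] = rankings
            for method, ranking in rankings.items():
                ranking.to_csv(out_dir / f"ranking_{kind}_{method}.csv")
                sidecar = {
                    "method": method, "classifier": kind,
                    "fsm_config": _to_jsonable(config.fsm),
                    "tie_policy": ranking.tie_policy,
                }
                (out_dir / f"ranking_{kind}_{method}.json").write_text(
                    json.dumps(sidecar, indent=2))
        artifacts["rankings"] = all_rankings
        finish_stage(stage)
        if "evaluate" not in stages:
            return artifacts

        stage = "evaluate"
        schedule = (list(config.schedule) if config.schedule is not None
                    else ev.elimination_schedule(fm.n_features))
        schedule = [k for k in schedule if k <= fm.n_features]
        manifest["schedule"] = schedule
        rows = []
        results: dict[tuple[str, str, int], ev.EvalResult] = {}
        for kind in config.classifiers:
            clf_config = ev.CLASSIFIER_CONFIGS[fs][kind].with_seed(
                config.sub_seed(f"clf:{kind}"))
            for method, ranking in all_rankings[kind].items():
                for k in schedule:
                    res = ev.run_5x2cv(fm, ranking, k, clf_config,
                                       seed=config.sub_seed("cv"))
                    results[(kind, method, k)] = res
                    for rep in range(res.fold_errors.shape[0]):
                        for fold in range(2):
                            rows.append({
                                "classifier": kind, "fsm": method,
                                "feature_set": fs, "n_features": k,
                                "repetition": rep, "fold": fold,
                                "error": res.fold_errors[rep, fold],
                            })
            log.info("evaluate: %s done (%d FSMs x %d cutoffs)",
                     kind, len(all_rankings[kind]), len(schedule))
        errors_df = pd.DataFrame(rows)
        errors_df.to_csv(out_dir / "fold_errors.csv", index=False)
        summary = pd.DataFrame([
            {"classifier": kind, "fsm": method, "feature_set": fs,
             "n_features": k, "f1": r.f1, "sensitivity": r.sensitivity,
             "accuracy": r.accuracy, "mean_error": float(r.fold_errors.mean())}
            for (kind, method, k), r in results.items()
        ])
        summary.to_csv(out_dir / "summary.csv", index=False)
        artifacts["results"] = results
        artifacts["summary"] = summary
        finish_stage(stage)
        if "compare" not in stages:
            return artifacts

        stage = "compare"
        ftest_rows = []
        for kind in config.classifiers:
            for k in schedule:
                here = [results[(kind, m, k)] for m in all_rankings[kind]]
                best = _best_fsm(here)
                for other in here:
                    if other.fsm == best.fsm:
                        continue
                    test = ev.f_test_5x2cv(best.fold_errors, other.fold_errors)
                    ftest_rows.append({
                        "classifier": kind, "n_features": k,
                        "best_fsm": best.fsm, "other_fsm": other.fsm,
                        "F": test["F"], "p": test["p"],
                        "significant": test["significant"],
                        "degenerate": test["degenerate"],
                    })
        ftests = pd.DataFrame(ftest_rows)
        ftests.to_csv(out_dir / "ftests.csv", index=False)
        artifacts["ftests"] = ftests

        sims = {}
        for kind in config.classifiers:
            ranks = list(all_rankings[kind].values())
            for k in config.similarity_ks:
                if k > fm.n_features:
                    continue
                sim = pairwise_similarity(ranks, k)
                sim.to_csv(out_dir / f"similarity_{kind}_k{k}.csv", presentation=True)
                sims[(kind, k)] = sim
            for method, ranking in all_rankings[kind].items():
                top_features_report(ranking, min(10, fm.n_features)).to_csv(
                    out_dir / f"top_features_{kind}_{method}.csv", index=False)
        artifacts["similarity"] = sims
        finish_stage(stage)
        return artifacts
    except PipelineError:
        raise
    except Exception as exc:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc
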