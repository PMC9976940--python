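"""Cross-validated evaluation: fold planning, APE pooling, summaries.

Swallows are randomly partitioned into k equal folds (swallow-level, as
in the measurement protocol; an optional group argument supports the
stricter patient-level split).  Each fold is held out once, the model is
trained on the remainder, and the held-out absolute percentage errors
are pooled into a single report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model as M

__all__ = ["FoldPlan", "EvaluationReport", "make_folds", "cross_validate",
           "summarize_ape", "simulate_model_inputs"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (30.0, 50.0)


@dataclass
class FoldPlan:
    fold_assignments: dict     # swallow_id -> fold index
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [sid for sid, f in self.fold_assignments.items() if f == fold]


@dataclass
class EvaluationReport:
    apes: np.ndarray                   # per-swallow APE (%), pooled over folds
    swallow_ids: list
    predictions: np.ndarray
    truths: np.ndarray
    mean_ape: float
    sd_ape: float
    pct_within: dict                   # threshold (%) -> % of swallows at/below
    fold_histories: list = field(default_factory=list)


def make_folds(ids, k: int, seed: int = 0, groups=None) -> FoldPlan:
    """Seeded shuffle + round-robin assignment into k folds (sizes differ
    by at most one).

    ``groups`` (id -> group label, e.g. patient) keeps all swallows of a
    group in the same fold — a stricter split than the swallow-level
    default, useful to rule out within-patient leakage.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    if groups is None:
        if k > len(ids):
            raise ValueError("more folds than swallows")
        order = rng.permutation(len(ids))
        assignments = {ids[j]: int(i % k) for i, j in enumerate(order)}
    else:
        labels = sorted({groups[sid] for sid in ids})
        if k > len(labels):
            raise ValueError("more folds than groups")
        order = rng.permutation(len(labels))
        group_fold = {labels[j]: int(i % k) for i, j in enumerate(order)}
        assignments = {sid: group_fold[groups[sid]] for sid in ids}
    return FoldPlan(fold_assignments=assignments, k=k, seed=seed)


def summarize_ape(apes, thresholds=DEFAULT_THRESHOLDS):
    """Mean, SD and fraction of swallows at/below each APE threshold (%)."""
    apes = np.asarray(list(apes), dtype=float)
    if apes.size == 0:
        raise ValueError("empty APE list")
    pct = {float(t): float(np.mean(apes <= t) * 100.0) for t in thresholds}
    return dict(mean_ape=float(np.mean(apes)), sd_ape=float(np.std(apes)),
                pct_within=pct)


def simulate_model_inputs(spec, use_measured_targets: bool = True,
                          fl: float = 3.0):
    """Full front end on simulated data: simulate swallows, fit
    device-noise models from a simulated zero-input recording, run the
    denoising chain, measure the planted landmarks, and assemble
    model-ready samples.

    Targets come from the geometry measurement of the (pixel-quantized)
    landmark sets when ``use_measured_targets`` is set, exactly as the
    clinical ground truth would, and from the planted ratios otherwise.
    Swallows whose manifest rows cannot be assembled (or that are too
    short for the spline stage's knot rule) are skipped with a logged
    reason.  Returns ``(samples, manifest, swallows)``.
    """
    from . import datasets as ds
    from . import preprocessing as pp
    from . import synthetic as syn
    from . import vfss

    spec_pp = pp.SplineConfig(fl=fl)
    swallows, manifest = syn.generate_dataset(spec)
    zero = syn.generate_zero_input(spec, seed=spec.seed + 1)
    models = pp.fit_device_noise_models(pp.downsample(zero, spec.fs_work))
    signals, targets = {}, {}
    for sw in swallows:
        try:
            signals[sw.swallow_id] = pp.preprocess(
                sw.recording, models, spec_pp, target_fs=spec.fs_work)
        except ValueError as err:
            log.warning("preprocessing failed for %s: %s", sw.swallow_id, err)
            continue
        if use_measured_targets:
            m = vfss.measure_frame(sw.landmark_set)
            targets[sw.swallow_id] = m.normalized_ratio
        else:
            targets[sw.swallow_id] = sw.truth_ratio
    samples, skipped = ds.assemble(manifest, signals, targets, fps=spec.fps)
    for sid, reason in skipped:
        log.info("skipped %s: %s", sid, reason)
    return samples, manifest, swallows


def _default_train_fn(train_samples, config, seed):
    params, history = M.train(train_samples, config, seed=seed)
    return (lambda samples: M.predict(samples, params, config)), history


def cross_validate(samples, config: M.ModelConfig | None = None,
                   plan: FoldPlan | None = None, k: int = 10, seed: int = 0,
                   thresholds=DEFAULT_THRESHOLDS,
                   train_fn=None) -> EvaluationReport:
    """k-fold holdout evaluation pooling every swallow's APE exactly once.

    ``train_fn(train_samples, config, seed) -> (predict_fn, history)``
    defaults to full network training; tests can substitute cheaper
    predictors to check the pooling contract in isolation.
    """
    config = config or M.ModelConfig()
    by_id = {s.swallow_id: s for s in samples}
    if len(by_id) != len(samples):
        raise ValueError("swallow ids must be unique")
    if plan is None:
        plan = make_folds(list(by_id), k, seed)
    train_fn = train_fn or _default_train_fn

    ids, preds, truths = [], [], []
    histories = []
    for fold in range(plan.k):
        test_ids = plan.fold_ids(fold)
        train_ids = [sid for sid, f in plan.fold_assignments.items() if f != fold]
        if not test_ids or not train_ids:
            raise ValueError(f"fold {fold} leaves an empty train or test set")
        assert not set(test_ids) & set(train_ids), "fold leakage"
        predict_fn, history = train_fn([by_id[sid] for sid in train_ids],
                                       config, seed + fold)
        test_samples = [by_id[sid] for sid in test_ids]
        fold_preds = np.asarray(predict_fn(test_samples), dtype=float)
        ids.extend(test_ids)
        preds.extend(fold_preds.tolist())
        truths.extend(s.target_ratio for s in test_samples)
        histories.append(history)

    if sorted(ids) != sorted(by_id):
        raise AssertionError("holdout contract violated: predictions do not "
                             "cover every swallow exactly once")
    preds = np.array(preds)
    truths = np.array(truths)
    apes = M.ape(preds, truths)
    stats = summarize_ape(apes, thresholds)
    return EvaluationReport(apes=apes, swallow_ids=ids, predictions=preds,
                            truths=truths, mean_ape=stats["mean_ape"],
                            sd_ape=stats["sd_ape"],
                            pct_within=stats["pct_within"],
                            fold_histories=histories)
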