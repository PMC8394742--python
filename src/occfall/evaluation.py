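"""Experimental protocols: ROC sweep, k-fold grid search, ensemble, ablation.

The evaluation contract is one-class throughout: models see ADL feature
vectors only during training; falls appear exclusively at test time.  A
trained scorer is swept over 2500 linearly spaced decision thresholds
spanning the pooled test scores; a movement is called a fall when its
anomaly score is >= the threshold.  Sensitivity (Se, fraction of falls
detected), specificity (Sp, fraction of ADLs not misclassified) and their
geometric mean G = sqrt(Se * Sp) are traced along the sweep; the optimal
cut-point tau* maximizes G, and AUC is the trapezoidal area under the
(1 - Sp, Se) curve with the (0, 0) and (1, 1) endpoints included.

Protocols:

- :func:`run_fair_experiment` — 5-fold cross-validation with ADLs
  stratified by activity type ("fair": every movement type is represented
  in every training partition), grid search over hyperparameters and
  feature sets, winner by mean G.
- :func:`run_ensemble` — majority vote of the three best configurations,
  each voting with its own per-fold optimal threshold.
- :func:`run_ablation` — leave-one-ADL-category-out: train on two
  intensity categories, test on the third plus all falls, classify with
  the fair-case threshold (median of the per-fold tau*), and report
  Loss = G(ablation) - G(fair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Manifest, ValidationError, load_traces
from .features import (apply_normalizer, features_frame, fit_normalizer,
                       resolve_feature_set)
from .models import default_grid, train_model

N_THRESHOLDS = 2500


def geometric_mean(se: float, sp: float) -> float:
    """G = sqrt(Se * Sp), the sensitivity/specificity trade-off metric."""
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValidationError("Se and Sp must lie in [0, 1]")
    return float(np.sqrt(se * sp))


@dataclass
class ROCResult:
    """Threshold sweep of one trained scorer on one test split."""

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    tau_star: float
    se_star: float
    sp_star: float
    g_star: float


def sweep_roc(scores_adl, scores_fall,
              n_thresholds: int = N_THRESHOLDS) -> ROCResult:
    """Sweep linearly spaced thresholds over the pooled score range.

    Decision rule: anomaly score >= tau -> fall.  The lowest threshold
    (pooled minimum) attains Se = 1, and a point just above the pooled
    maximum (appended for the AUC endpoints) attains Sp = 1.  tau* is the
    smallest threshold maximizing G on ties.
    """
    scores_adl = np.asarray(scores_adl, dtype=float)
    scores_fall = np.asarray(scores_fall, dtype=float)
    if scores_adl.size == 0 or scores_fall.size == 0:
        raise ValidationError("both score vectors must be non-empty")
    if not (np.isfinite(scores_adl).all() and np.isfinite(scores_fall).all()):
        raise ValidationError("scores must be finite")
    pooled = np.concatenate([scores_adl, scores_fall])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + max(abs(lo), 1.0) * 1e-9
    thresholds = np.linspace(lo, hi, n_thresholds)

    adl_sorted = np.sort(scores_adl)
    fall_sorted = np.sort(scores_fall)
    n_adl, n_fall = adl_sorted.size, fall_sorted.size
    # fall scores >= tau / adl scores < tau, via binary search
    se = 1.0 - np.searchsorted(fall_sorted, thresholds, side="left") / n_fall
    sp = np.searchsorted(adl_sorted, thresholds, side="left") / n_adl

    g = np.sqrt(se * sp)
    best = int(np.argmax(g))   # thresholds ascending -> first max = smallest

    # ROC with endpoints: tau below min -> (1, 1); tau above max -> (0, 0)
    fpr = np.concatenate([[1.0], 1.0 - sp, [0.0]])
    tpr = np.concatenate([[1.0], se, [0.0]])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    return ROCResult(
        thresholds=thresholds, se=se, sp=sp, auc=auc,
        tau_star=float(thresholds[best]), se_star=float(se[best]),
        sp_star=float(sp[best]), g_star=float(g[best]))


# ---------------------------------------------------------------------------
# folding

@dataclass
class FoldSplit:
    """k disjoint ADL partitions; falls are test-only in every fold."""

    partitions: list[list[str]]
    fall_ids: list[str]
    mode: str = "fair"
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.partitions)

    def train_adl_ids(self, fold: int) -> list[str]:
        return [tid for j, part in enumerate(self.partitions)
                if j != fold for tid in part]

    def test_adl_ids(self, fold: int) -> list[str]:
        return list(self.partitions[fold])


def make_folds(manifest: Manifest, k: int = 5, mode: str = "fair",
               seed: int = 0) -> FoldSplit:
    """Stratified ADL partitioning for one-class cross-validation.

    ADLs are grouped by activity type, shuffled within type, and dealt
    round-robin across the k partitions with a running cursor, so every
    activity type with >= k traces appears in all partitions and partition
    sizes stay balanced.  Falls never enter any training partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    adls = manifest.adls()
    if len(adls) < k:
        raise ValidationError(f"need at least {k} ADL traces for {k} folds")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    for e in adls:
        by_type.setdefault(e.activity_type, []).append(e.trace_id)
    partitions: list[list[str]] = [[] for _ in range(k)]
    cursor = 0
    for atype in sorted(by_type):
        ids = sorted(by_type[atype])
        rng.shuffle(ids)
        for tid in ids:
            partitions[cursor % k].append(tid)
            cursor += 1
    fall_ids = [e.trace_id for e in manifest.falls()]
    return FoldSplit(partitions=partitions, fall_ids=fall_ids,
                     mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# fair-case grid search

@dataclass
class FoldMetrics:
    auc: float
    se: float
    sp: float
    g: float
    threshold: float


@dataclass
class ComboResult:
    """Cross-validated metrics of one hyperparameter x feature-set combo."""

    model_kind: str
    params: dict
    feature_set: str
    folds: list[FoldMetrics] = field(default_factory=list)
    failed: bool = False
    error: str | None = None

    def _mean(self, attr):
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    def _sd(self, attr):
        return float(np.std([getattr(f, attr) for f in self.folds], ddof=1))

    @property
    def auc_mean(self): return self._mean("auc")

    @property
    def se_mean(self): return self._mean("se")

    @property
    def sp_mean(self): return self._mean("sp")

    @property
    def g_mean(self): return self._mean("g")

    @property
    def g_sd(self): return self._sd("g")

    @property
    def fold_thresholds(self):
        return [f.threshold for f in self.folds]

    @property
    def fair_threshold(self) -> float:
        """Single threshold distilled from the folds (median of tau*)."""
        return float(np.median(self.fold_thresholds))


@dataclass
class EvalReport:
    """Grid-search outcome for one model kind on one dataset."""

    model_kind: str
    combos: list[ComboResult]
    best: ComboResult
    seed: int
    k: int
    n_adl: int
    n_fall: int


def _fold_matrices(frame, feature_ids, split, fold):
    """(train ADL matrix, test matrix, test labels) for one fold."""
    cols = list(feature_ids)
    train_ids = split.train_adl_ids(fold)
    test_ids = split.test_adl_ids(fold) + split.fall_ids
    x_train = frame.loc[train_ids, cols].to_numpy(dtype=float)
    x_test = frame.loc[test_ids, cols].to_numpy(dtype=float)
    is_fall = frame.loc[test_ids, "label"].to_numpy() == "FALL"
    return x_train, x_test, is_fall


def _evaluate_combo(frame, split, model_kind, params, feature_set, seed,
                    n_thresholds=N_THRESHOLDS, honest=False):
    combo = ComboResult(model_kind=model_kind, params=dict(params),
                        feature_set=feature_set)
    ids = resolve_feature_set(feature_set)
    for fold in range(split.k):
        x_train, x_test, is_fall = _fold_matrices(frame, ids, split, fold)
        norm = fit_normalizer(x_train)
        model = train_model(model_kind, norm.transform(x_train), params, seed)
        scores = model.score(norm.transform(x_test))
        if honest:
            metrics = _honest_fold_metrics(
                scores, is_fall, seed + fold, n_thresholds)
        else:
            roc = sweep_roc(scores[~is_fall], scores[is_fall], n_thresholds)
            metrics = FoldMetrics(auc=roc.auc, se=roc.se_star, sp=roc.sp_star,
                                  g=roc.g_star, threshold=roc.tau_star)
        combo.folds.append(metrics)
    return combo


def _honest_fold_metrics(scores, is_fall, seed, n_thresholds):
    """Select tau* on an inner split, report metrics on the held-out rest.

    Falls are split in half; the selection half (plus 20% of the test
    ADLs) drives the sweep, the reporting half gives Se at tau*.  AUC is
    still computed on the full test split.
    """
    rng = np.random.default_rng(seed)
    adl_idx = np.flatnonzero(~is_fall)
    fall_idx = np.flatnonzero(is_fall)
    rng.shuffle(adl_idx)
    rng.shuffle(fall_idx)
    n_sel_adl = max(1, len(adl_idx) // 5)
    n_sel_fall = max(1, len(fall_idx) // 2)
    sel_adl, rep_adl = adl_idx[:n_sel_adl], adl_idx[n_sel_adl:]
    sel_fall, rep_fall = fall_idx[:n_sel_fall], fall_idx[n_sel_fall:]
    if rep_adl.size == 0 or rep_fall.size == 0:
        raise ValidationError("too few test traces for honest thresholding")
    sel_roc = sweep_roc(scores[sel_adl], scores[sel_fall], n_thresholds)
    tau = sel_roc.tau_star
    se = float(np.mean(scores[rep_fall] >= tau))
    sp = float(np.mean(scores[rep_adl] < tau))
    full_roc = sweep_roc(scores[~is_fall], scores[is_fall], n_thresholds)
    return FoldMetrics(auc=full_roc.auc, se=se, sp=sp,
                       g=geometric_mean(se, sp), threshold=tau)


def run_fair_experiment(manifest: Manifest, model_kind: str,
                        grid: list[dict] | None = None,
                        feature_sets=("BCDFGIK", "ABCDEFGHIJKL"),
                        k: int = 5, seed: int = 0,
                        n_thresholds: int = N_THRESHOLDS,
                        honest: bool = False,
                        frame=None) -> EvalReport:
    """Grid search under fair 5-fold cross-validation.

    For every hyperparameter x feature-set combination, per fold: fit the
    z-score normalizer on the training ADLs only, train the model, score
    the reserved ADL partition plus all falls, and sweep the ROC.  The
    winner maximizes mean G (ties: higher mean AUC, then grid order).
    Combinations whose training fails on any fold are disqualified but
    kept in the report with their error.
    """
    if grid is None:
        grid = default_grid(model_kind)
    traces = load_traces(manifest) if frame is None else None
    if frame is None:
        frame = features_frame(traces, "ABCDEFGHIJKL")
    if not (frame["label"] == "FALL").any():
        raise ValidationError("manifest contains no falls to test on")
    split = make_folds(manifest, k=k, seed=seed)
    combos = []
    for feature_set in feature_sets:
        for params in grid:
            try:
                combo = _evaluate_combo(frame, split, model_kind, params,
                                        feature_set, seed, n_thresholds,
                                        honest)
            except Exception as exc:   # disqualify, keep the reason
                combo = ComboResult(model_kind=model_kind,
                                    params=dict(params),
                                    feature_set=feature_set,
                                    failed=True, error=str(exc))
            combos.append(combo)
    valid = [c for c in combos if not c.failed]
    if not valid:
        raise ValidationError(
            f"every {model_kind} combination failed to train")
    # max keeps the first maximum, so full ties fall back to grid order
    best = max(valid, key=lambda c: (c.g_mean, c.auc_mean))
    return EvalReport(model_kind=model_kind, combos=combos, best=best,
                      seed=seed, k=k, n_adl=len(manifest.adls()),
                      n_fall=len(manifest.falls()))


# ---------------------------------------------------------------------------
# ensemble

@dataclass
class EnsembleReport:
    members: list[ComboResult]
    folds: list[FoldMetrics]
    se_mean: float
    sp_mean: float
    g_mean: float
    g_sd: float
    seed: int
    k: int


def run_ensemble(manifest: Manifest, top3: list[ComboResult],
                 seed: int = 0, k: int = 5, frame=None) -> EnsembleReport:
    """Majority vote of the three best configurations.

    Per fold, each base learner is retrained on the fold's training ADLs
    (under its own feature set and normalizer) and votes "fall" when its
    anomaly score reaches its own per-fold optimal threshold; the ensemble
    label follows the majority (two or three votes).
    """
    if len(top3) < 3:
        raise ValueError("ensemble needs three base configurations")
    top3 = list(top3)[:3]
    if frame is None:
        frame = features_frame(load_traces(manifest), "ABCDEFGHIJKL")
    split = make_folds(manifest, k=k, seed=seed)
    folds = []
    for fold in range(split.k):
        votes = []
        is_fall = None
        for combo in top3:
            ids = resolve_feature_set(combo.feature_set)
            x_train, x_test, is_fall = _fold_matrices(frame, ids, split, fold)
            norm = fit_normalizer(x_train)
            model = train_model(combo.model_kind,
                                norm.transform(x_train), combo.params, seed)
            scores = model.score(norm.transform(x_test))
            votes.append(scores >= combo.folds[fold].threshold)
        vote_count = np.sum(votes, axis=0)
        predicted_fall = vote_count >= 2
        se = float(np.mean(predicted_fall[is_fall]))
        sp = float(np.mean(~predicted_fall[~is_fall]))
        folds.append(FoldMetrics(auc=float("nan"), se=se, sp=sp,
                                 g=geometric_mean(se, sp),
                                 threshold=float("nan")))
    g_vals = [f.g for f in folds]
    return EnsembleReport(
        members=top3, folds=folds,
        se_mean=float(np.mean([f.se for f in folds])),
        sp_mean=float(np.mean([f.sp for f in folds])),
        g_mean=float(np.mean(g_vals)), g_sd=float(np.std(g_vals, ddof=1)),
        seed=seed, k=k)


def top_combos(reports: list[EvalReport], n: int = 3) -> list[ComboResult]:
    """The n best valid combinations across model kinds, by mean G."""
    combos = [c for r in reports for c in r.combos if not c.failed]
    combos.sort(key=lambda c: (-c.g_mean, -c.auc_mean))
    return combos[:n]


# ---------------------------------------------------------------------------
# ADL-category ablation

@dataclass
class AblationRow:
    category: str
    se: float
    sp: float
    g: float
    loss: float
    n_test_adl: int


@dataclass
class AblationReport:
    model_kind: str
    params: dict
    feature_set: str
    threshold: float
    fair_g: float
    fair_sp: float
    rows: dict[str, AblationRow]


def run_ablation(manifest: Manifest, combo: ComboResult, seed: int = 0,
                 frame=None) -> AblationReport:
    """Leave-one-ADL-category-out evaluation with the fair-case threshold.

    For each intensity category c: train on the ADLs of the other
    categories (normalizer refit on that training set), test on all falls
    plus the ADLs of c, classify with the fair-case threshold (median of
    the per-fold tau* of ``combo``), and report Se, Sp, G and
    Loss = G - G_fair.  Categories with no ADLs are skipped with a
    warning.
    """
    if frame is None:
        frame = features_frame(load_traces(manifest), "ABCDEFGHIJKL")
    adl = frame[frame["label"] == "ADL"]
    categories = [c for c in ("basic", "standard", "sporting")
                  if (adl["category"] == c).any()]
    if len(categories) < 2:
        raise ValidationError(
            "ablation needs at least 2 non-empty ADL categories")
    ids = list(resolve_feature_set(combo.feature_set))
    tau = combo.fair_threshold
    fall_matrix = frame[frame["label"] == "FALL"][ids].to_numpy(dtype=float)
    rows = {}
    for held_out in ("basic", "standard", "sporting"):
        if held_out not in categories:
            warnings.warn(f"ADL category {held_out!r} is empty; skipped")
            continue
        train_rows = adl[adl["category"] != held_out]
        test_rows = adl[adl["category"] == held_out]
        x_train = train_rows[ids].to_numpy(dtype=float)
        norm = fit_normalizer(x_train)
        model = train_model(combo.model_kind, norm.transform(x_train),
                            combo.params, seed)
        adl_scores = model.score(
            norm.transform(test_rows[ids].to_numpy(dtype=float)))
        fall_scores = model.score(norm.transform(fall_matrix))
        se = float(np.mean(fall_scores >= tau))
        sp = float(np.mean(adl_scores < tau))
        g = geometric_mean(se, sp)
        rows[held_out] = AblationRow(
            category=held_out, se=se, sp=sp, g=g, loss=g - combo.g_mean,
            n_test_adl=len(test_rows))
    return AblationReport(
        model_kind=combo.model_kind, params=combo.params,
        feature_set=combo.feature_set, threshold=tau,
        fair_g=combo.g_mean, fair_sp=combo.sp_mean, rows=rows)
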