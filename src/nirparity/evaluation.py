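"""Measurement apparatus: splits, Monte-Carlo CV, confusion metrics, ROC.

The evaluation protocol mirrors field practice for NIRS parity models:
the labeled dataset is randomised and split 75/25 (unstratified), a
pipeline is fitted on the training partition and scored on the held-out
quarter, and the whole procedure is repeated ten times with fresh random
splits (Monte-Carlo cross-validation); metrics are reported as mean ±
sample standard deviation across repeats.

Metric definitions, with P = TP + FN actual parous and N = TN + FP
actual nulliparous in the evaluated set:

    sensitivity = TP / P          specificity = TN / N
    accuracy    = (TP + TN) / (P + N)
    precision   = TP / (TP + FP)

The ROC curve sweeps the decision threshold over the distinct score
values; AUC is the trapezoidal area, which with tied scores grouped
equals the pairwise concordance statistic (ties counted 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset, get_labels
from .errors import (
    DegenerateTestSetError,
    LabelValueError,
    SingleClassError,
    SplitError,
    WindowMismatchError,
)
from .pipeline import ModelBundle, PipelineConfig, fit_pipeline, predict_bundle
from .preprocessing import preprocess

__all__ = [
    "ConfusionMatrix",
    "EvaluationMetrics",
    "RepeatRecord",
    "MccvResult",
    "split",
    "confusion",
    "metrics",
    "roc_auc",
    "monte_carlo_cv",
    "cross_cohort_eval",
    "child_seed",
]


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for a binary parity prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise LabelValueError(f"confusion count {name} is negative")

    @property
    def p(self) -> int:
        """Actual parous count."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Actual nulliparous count."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass
class EvaluationMetrics:
    """The four confusion-derived proportions plus optional ROC/AUC.

    All values are proportions in [0, 1] (multiply by 100 to report as
    percentages).  ``precision`` is ``None`` — undefined, not zero —
    when nothing was predicted parous.  ``auc`` is present only when
    scores were supplied.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float | None
    auc: float | None = None
    roc_points: np.ndarray | None = None
    cm: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "auc": self.auc,
        }
        if self.cm is not None:
            d["confusion"] = self.cm.to_dict()
        return d


# ---------------------------------------------------------------------------
def split(dataset: SpectralDataset, train_fraction: float = 0.75,
          seed: int = 0, stratified: bool = False):
    """Random 75/25 (by default) partition of a dataset.

    The merged dataset is permuted uniformly at random under ``seed``
    and cut at ``floor(train_fraction * N)``; unstratified by default.
    Partitions are disjoint, exhaustive, and tagged with a split id so
    downstream fitting can detect leakage.
    """
    if not (0 < train_fraction < 1):
        raise SplitError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = dataset.n_samples
    n_train = math.floor(train_fraction * n)
    if n_train < 1 or n - n_train < 1:
        raise SplitError(
            f"cannot split {n} samples at fraction {train_fraction}: each "
            "partition needs at least one sample"
        )
    rng = np.random.default_rng(int(seed))
    if stratified:
        labels = get_labels(dataset)
        train_idx: list[int] = []
        for cls in (0, 1):
            members = np.flatnonzero(labels == cls)
            perm = rng.permutation(members)
            k = math.floor(train_fraction * members.size)
            train_idx.extend(perm[:k].tolist())
        train_set = set(train_idx)
        order = rng.permutation(n)
        tr = [i for i in order if i in train_set]
        te = [i for i in order if i not in train_set]
        tr, te = np.asarray(tr), np.asarray(te)
    else:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
    sid = f"split-{seed}-{train_fraction:g}"
    return (
        dataset.subset(tr, split_id=sid, partition="train"),
        dataset.subset(te, split_id=sid, partition="test"),
    )


def confusion(predicted, actual) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with parous = positive class."""
    predicted = np.asarray(predicted).ravel()
    actual = np.asarray(actual).ravel()
    if predicted.shape != actual.shape:
        raise LabelValueError(
            f"{predicted.size} predictions for {actual.size} actual labels"
        )
    for name, arr in (("predicted", predicted), ("actual", actual)):
        if not np.isin(arr, (0, 1)).all():
            raise LabelValueError(f"{name} labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((predicted == 1) & (actual == 1))),
        fp=int(np.sum((predicted == 1) & (actual == 0))),
        tn=int(np.sum((predicted == 0) & (actual == 0))),
        fn=int(np.sum((predicted == 0) & (actual == 1))),
    )


def metrics(cm: ConfusionMatrix, scores=None, actual=None,
            allow_degenerate: bool = False) -> EvaluationMetrics:
    """Sensitivity, specificity, accuracy, precision (+ ROC/AUC).

    Requires both classes present in the evaluated set unless
    ``allow_degenerate`` is set, in which case the undefined proportions
    are reported as ``None``-like NaN-free omissions (accuracy is always
    defined for a non-empty set).
    """
    if cm.total == 0:
        raise DegenerateTestSetError("empty evaluated set")
    if not allow_degenerate:
        if cm.p == 0:
            raise DegenerateTestSetError("evaluated set has no parous samples")
        if cm.n == 0:
            raise DegenerateTestSetError("evaluated set has no nulliparous samples")
    sensitivity = cm.tp / cm.p if cm.p > 0 else float("nan")
    specificity = cm.tn / cm.n if cm.n > 0 else float("nan")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = (cm.tp / (cm.tp + cm.fp)) if (cm.tp + cm.fp) > 0 else None
    auc = None
    roc = None
    if scores is not None:
        if actual is None:
            raise LabelValueError("ROC needs the actual labels alongside scores")
        if len(set(np.asarray(actual).ravel().tolist())) == 2:
            auc, roc = roc_auc(scores, actual)
        elif not allow_degenerate:
            raise SingleClassError("ROC requested on a single-class set")
    return EvaluationMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        precision=precision,
        auc=auc,
        roc_points=roc,
        cm=cm,
    )


def roc_auc(scores, actual):
    """ROC by threshold sweep over distinct scores; trapezoidal AUC.

    Grouping tied scores before integrating makes the trapezoidal area
    identical to the pairwise concordance statistic with ties worth 1/2.
    Returns ``(auc, points)`` with points an (m, 2) array of
    (false-positive rate, true-positive rate) from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    actual = np.asarray(actual).ravel()
    if scores.shape != actual.shape:
        raise LabelValueError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise LabelValueError("scores contain non-finite values")
    pos = int(np.sum(actual == 1))
    neg = int(np.sum(actual == 0))
    if pos == 0 or neg == 0:
        raise SingleClassError("ROC/AUC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = actual[order]
    # group tied scores: cumulative counts at the end of each tie block
    distinct_end = np.flatnonzero(np.diff(s_sorted) != 0).tolist() + [scores.size - 1]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    tpr = np.concatenate([[0.0], tps[distinct_end] / pos, [1.0]])
    fpr = np.concatenate([[0.0], fps[distinct_end] / neg, [1.0]])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, points


# ---------------------------------------------------------------------------
@dataclass
class RepeatRecord:
    """One Monte-Carlo repeat: its seed, counts, metrics and partitions."""

    repeat: int
    seed: int
    cm: ConfusionMatrix
    metrics: EvaluationMetrics
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    fitted_on_ids: list[str] = field(default_factory=list)


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "auc")


@dataclass
class MccvResult:
    """Per-repeat records and their mean ± sd summary."""

    per_repeat: list[RepeatRecord]
    summary: dict[str, tuple[float, float]]
    config_hash: str = ""
    seed: int | None = None

    def metric_values(self, name: str) -> list[float]:
        vals = []
        for rec in self.per_repeat:
            v = getattr(rec.metrics, name)
            if v is not None:
                vals.append(float(v))
        return vals

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary.items()},
            "per_repeat": [
                {
                    "repeat": r.repeat,
                    "seed": r.seed,
                    "confusion": r.cm.to_dict(),
                    **{k: getattr(r.metrics, k) for k in METRIC_NAMES},
                }
                for r in self.per_repeat
            ],
        }


def summarise(records: list[RepeatRecord]) -> dict[str, tuple[float, float]]:
    """Mean and sample (n-1) standard deviation per metric across repeats."""
    out: dict[str, tuple[float, float]] = {}
    for name in METRIC_NAMES:
        vals = [
            float(getattr(r.metrics, name))
            for r in records
            if getattr(r.metrics, name) is not None
        ]
        if not vals:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (mean, sd)
    return out


def child_seed(seed: int, repeat: int) -> int:
    """Deterministic per-repeat seed: base seed plus repeat index."""
    return int(seed) + int(repeat)


def monte_carlo_cv(dataset: SpectralDataset, config: PipelineConfig | None = None,
                   repeats: int | None = None, seed: int = 0) -> MccvResult:
    """Ten-repeat (by default) Monte-Carlo cross-validation of a pipeline.

    Each repeat r: split 75/25 under ``child_seed(seed, r)``, fit the
    scaler (and autoencoder for the encoded pipeline) on the training
    partition only, train the classifier, and score the held-out
    quarter.  Under ``leakage_mode="paper-faithful"`` the scaler and
    autoencoder are instead fitted once on the full dataset before
    splitting — the encode-then-split ordering some studies use, kept
    for comparison.
    """
    config = config if config is not None else PipelineConfig()
    repeats = config.repeats if repeats is None else int(repeats)
    if repeats < 1:
        raise SplitError("repeats must be >= 1")
    get_labels(dataset)  # fail early if unlabeled

    pp = preprocess(dataset, config.preprocess)

    shared_bundle: ModelBundle | None = None
    if config.leakage_mode == "paper-faithful":
        shared_bundle = fit_pipeline(pp, config, seed=seed)

    records: list[RepeatRecord] = []
    for r in range(repeats):
        cseed = child_seed(seed, r)
        train, test = split(pp, config.train_fraction, cseed,
                            stratified=config.stratified)
        try:
            if shared_bundle is None:
                bundle = fit_pipeline(train, config, seed=cseed)
                fitted_on = list(train.sample_ids)
            else:
                # refit only the classifier on this repeat's training codes
                bundle = _refit_classifier(shared_bundle, train, config, cseed)
                fitted_on = list(pp.sample_ids)
            scores, pred = predict_bundle(bundle, test)
            cm = confusion(pred, test.labels)
            m = metrics(cm, scores, test.labels)
        except Exception as exc:
            raise type(exc)(f"[repeat {r}] {exc}") from exc
        records.append(RepeatRecord(
            repeat=r, seed=cseed, cm=cm, metrics=m,
            train_ids=list(train.sample_ids), test_ids=list(test.sample_ids),
            fitted_on_ids=fitted_on,
        ))
    return MccvResult(
        per_repeat=records,
        summary=summarise(records),
        config_hash=config.config_hash(),
        seed=int(seed),
    )


def _refit_classifier(shared: ModelBundle, train: SpectralDataset,
                      config: PipelineConfig, seed: int) -> ModelBundle:
    from . import autoencoder as ae
    from .ann import AnnClassifier, lm_fit
    from .preprocessing import apply_scaler

    scaled = apply_scaler(preprocess(train, shared.preprocessing),
                          shared.preprocessing)
    features = (ae.encode(shared.autoencoder, scaled)
                if shared.autoencoder is not None else scaled)
    init = AnnClassifier.initialize(features.n_features, config.hidden_units,
                                    seed=seed, threshold=config.threshold)
    clf, _ = lm_fit(init, features, config.lm_config)
    return ModelBundle(
        classifier=clf,
        preprocessing=shared.preprocessing,
        autoencoder=shared.autoencoder,
        seed=seed,
        created=shared.created,
        config_hash=shared.config_hash,
        pipeline=shared.pipeline,
    )


def cross_cohort_eval(train_cohort: SpectralDataset, test_cohort: SpectralDataset,
                      config: PipelineConfig | None = None,
                      seed: int = 0) -> EvaluationMetrics:
    """Independent testing on a different cohort.

    The scaler, autoencoder and classifier are fitted on the full
    training cohort; the training cohort's encoder is then applied to
    the test cohort (the only deployable choice) and metrics are
    computed on the entire test cohort.  A single-class test cohort
    yields the defined subset of metrics and omits AUC.
    """
    config = config if config is not None else PipelineConfig()
    from .errors import GridSpacingError, WindowCoverageError

    grids_differ = not np.array_equal(train_cohort.wavelengths_nm,
                                      test_cohort.wavelengths_nm)
    try:
        pp_train = preprocess(train_cohort, config.preprocess)
        pp_test = preprocess(test_cohort, config.preprocess)
    except (WindowCoverageError, GridSpacingError) as exc:
        if grids_differ:
            raise WindowMismatchError(
                "cohorts are sampled on different wavelength windows: "
                f"{exc}"
            ) from exc
        raise
    if not np.array_equal(pp_train.wavelengths_nm, pp_test.wavelengths_nm):
        raise WindowMismatchError(
            "training and test cohorts do not share the same preprocessed "
            "wavelength window"
        )
    bundle = fit_pipeline(pp_train, config, seed=seed)
    scores, pred = predict_bundle(bundle, pp_test)
    actual = get_labels(pp_test)
    cm = confusion(pred, actual)
    single_class = len(set(actual.tolist())) < 2
    return metrics(cm, scores, actual, allow_degenerate=single_class)
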