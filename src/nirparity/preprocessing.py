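"""Wavelength windowing, replicate handling and per-feature scaling.

Raw scans cover roughly 350-2500 nm on a 1 nm grid.  The models consume a
fixed analysis window (default 500-2350 nm inclusive, i.e. 1851 features).
Replicate scans sharing a sample id are averaged by default.  A min-max
scaler, fitted on training data only, maps each retained wavelength to
[0, 1] so that logistic autoencoder units see bounded inputs; test values
outside the training range are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import SpectralDataset
from .errors import (
    ConfigError,
    DimensionMismatchError,
    GridSpacingError,
    LeakageError,
    NotFittedError,
    ReplicateError,
    WindowCoverageError,
)

__all__ = ["PreprocessSpec", "ScalingStats", "preprocess", "fit_scaler", "apply_scaler"]

REPLICATE_POLICIES = ("average", "forbid")
SCALING_MODES = ("minmax", "none")


@dataclass
class ScalingStats:
    """Per-feature min/max learned from a training partition."""

    minima: np.ndarray
    maxima: np.ndarray
    fitted_on_split: str | None = None

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=np.float64)
        self.maxima = np.asarray(self.maxima, dtype=np.float64)
        if self.minima.shape != self.maxima.shape:
            raise ConfigError("scaling stats minima/maxima shape mismatch")
        if np.any(self.minima > self.maxima):
            raise ConfigError("scaling stats require min <= max per feature")


@dataclass
class PreprocessSpec:
    """Configuration of the windowing/replicate/scaling stage.

    ``window_high_nm - window_low_nm + 1`` is the output dimension;
    the default window 500-2350 nm gives the 1851-point feature space.
    """

    window_low_nm: int = 500
    window_high_nm: int = 2350
    replicate_policy: str = "average"
    scaling: str = "minmax"
    scaling_stats: ScalingStats | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.window_high_nm <= self.window_low_nm:
            problems.append("window_high_nm must exceed window_low_nm")
        if self.replicate_policy not in REPLICATE_POLICIES:
            problems.append(
                f"replicate_policy must be one of {REPLICATE_POLICIES}"
            )
        if self.scaling not in SCALING_MODES:
            problems.append(f"scaling must be one of {SCALING_MODES}")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def output_dim(self) -> int:
        return int(self.window_high_nm - self.window_low_nm + 1)

    def to_dict(self) -> dict:
        d = {
            "window_low_nm": int(self.window_low_nm),
            "window_high_nm": int(self.window_high_nm),
            "replicate_policy": self.replicate_policy,
            "scaling": self.scaling,
        }
        if self.scaling_stats is not None:
            d["scaling_stats"] = {
                "minima": self.scaling_stats.minima.tolist(),
                "maxima": self.scaling_stats.maxima.tolist(),
                "fitted_on_split": self.scaling_stats.fitted_on_split,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        stats = None
        if d.get("scaling_stats") is not None:
            s = d["scaling_stats"]
            stats = ScalingStats(
                minima=np.asarray(s["minima"]),
                maxima=np.asarray(s["maxima"]),
                fitted_on_split=s.get("fitted_on_split"),
            )
        return cls(
            window_low_nm=d["window_low_nm"],
            window_high_nm=d["window_high_nm"],
            replicate_policy=d.get("replicate_policy", "average"),
            scaling=d.get("scaling", "minmax"),
            scaling_stats=stats,
        )


def _window(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    wl = dataset.wavelengths_nm
    lo, hi = spec.window_low_nm, spec.window_high_nm
    if wl[0] > lo or wl[-1] < hi:
        raise WindowCoverageError(
            f"grid [{wl[0]:g}, {wl[-1]:g}] nm does not cover the window "
            f"[{lo}, {hi}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    kept = wl[mask]
    expected = np.arange(lo, hi + 1, dtype=np.float64)
    if kept.size != expected.size or not np.array_equal(kept, expected):
        raise GridSpacingError(
            f"grid inside [{lo}, {hi}] nm is not sampled at 1 nm "
            f"({kept.size} points found, {expected.size} expected)"
        )
    return dataset.with_absorbance(dataset.absorbance[:, mask], kept)


def _merge_replicates(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    ids = dataset.sample_ids
    if len(set(ids)) == len(ids):
        return dataset
    if spec.replicate_policy == "forbid":
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ReplicateError(f"replicate rows present for ids {dupes[:10]}")
    # average, preserving first-occurrence order
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(ids):
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(i)
    rows, labels, cohorts = [], [], []
    for s in order:
        idx = groups[s]
        rows.append(dataset.absorbance[idx].mean(axis=0))
        if dataset.labels is not None:
            vals = set(dataset.labels[idx].tolist())
            if len(vals) > 1:
                raise ReplicateError(f"replicates of id {s!r} disagree on label")
            labels.append(vals.pop())
        if dataset.cohort is not None:
            vals = set(dataset.cohort[idx].tolist())
            if len(vals) > 1:
                raise ReplicateError(f"replicates of id {s!r} disagree on cohort")
            cohorts.append(vals.pop())
    return SpectralDataset(
        wavelengths_nm=dataset.wavelengths_nm,
        absorbance=np.vstack(rows),
        sample_ids=order,
        labels=np.asarray(labels) if dataset.labels is not None else None,
        cohort=np.asarray(cohorts, dtype=object) if dataset.cohort is not None else None,
        split_id=dataset.split_id,
        partition=dataset.partition,
    )


def preprocess(dataset: SpectralDataset, spec: PreprocessSpec | None = None) -> SpectralDataset:
    """Window the grid to the analysis range and merge replicate scans.

    The output has exactly ``spec.output_dim`` wavelengths (1851 by
    default), one row per distinct sample id, labels carried through
    unchanged.  Idempotent: applying it twice equals applying it once.
    """
    spec = spec if spec is not None else PreprocessSpec()
    return _merge_replicates(_window(dataset, spec), spec)


def fit_scaler(
    train: SpectralDataset,
    spec: PreprocessSpec | None = None,
    *,
    allow_test_partition: bool = False,
) -> PreprocessSpec:
    """Learn per-feature min/max from a training partition.

    Refuses a dataset tagged as a held-out test partition unless
    ``allow_test_partition=True`` — fitting scaling statistics on test
    data would leak its range into the model.
    """
    spec = spec if spec is not None else PreprocessSpec()
    if train.partition == "test" and not allow_test_partition:
        raise LeakageError(
            f"refusing to fit the scaler on the test partition of split "
            f"{train.split_id!r}; pass allow_test_partition=True to override"
        )
    stats = ScalingStats(
        minima=train.absorbance.min(axis=0),
        maxima=train.absorbance.max(axis=0),
        fitted_on_split=train.split_id,
    )
    return replace(spec, scaling_stats=stats)


def apply_scaler(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    """Map each feature to [0, 1] using fitted stats; clip out-of-range.

    Constant training features (min == max) map to 0.
    """
    if spec.scaling == "none":
        return dataset
    stats = spec.scaling_stats
    if stats is None:
        raise NotFittedError("apply_scaler called before fit_scaler")
    if stats.minima.size != dataset.n_features:
        raise DimensionMismatchError(
            f"scaler fitted on {stats.minima.size} features, dataset has "
            f"{dataset.n_features}"
        )
    span = stats.maxima - stats.minima
    safe = np.where(span > 0, span, 1.0)
    scaled = (dataset.absorbance - stats.minima) / safe
    scaled[:, span == 0] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return dataset.with_absorbance(scaled)
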