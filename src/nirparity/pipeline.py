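"""End-to-end pipelines: preprocess -> scale -> (encode) -> classify.

Two pipelines are supported:

* ``raw-ann`` — the classifier is trained directly on the scaled
  windowed spectra (1851 inputs by default);
* ``encoded-ann`` — an autoencoder stack is trained first and the
  classifier consumes its 10-dimensional codes.

:func:`fit_pipeline` fits every stage on the dataset it is given (a
training partition or a whole training cohort) and returns a
:class:`ModelBundle`; :func:`predict_bundle` applies a bundle to new
spectra.  Bundles serialise to a portable JSON container via
:mod:`nirparity.io`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from . import autoencoder as ae
from .ann import AnnClassifier, LmConfig, lm_fit, predict
from .autoencoder import AeConfig, AutoencoderStack
from .dataset import SpectralDataset
from .errors import BundleConsistencyError, ConfigError
from .preprocessing import PreprocessSpec, apply_scaler, fit_scaler, preprocess

__all__ = ["PipelineConfig", "ModelBundle", "fit_pipeline", "predict_bundle"]

PIPELINES = ("raw-ann", "encoded-ann")
LEAKAGE_MODES = ("repeat-internal", "paper-faithful")


@dataclass
class PipelineConfig:
    """Everything needed to fit and evaluate one pipeline run."""

    pipeline: str = "encoded-ann"
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    step_dims: tuple[int, ...] = ae.DEFAULT_STEP_DIMS
    ae_config: AeConfig = field(default_factory=AeConfig)
    lm_config: LmConfig = field(default_factory=LmConfig)
    hidden_units: int = 10
    threshold: float = 0.5
    train_fraction: float = 0.75
    repeats: int = 10
    leakage_mode: str = "repeat-internal"
    stratified: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.pipeline not in PIPELINES:
            problems.append(f"pipeline must be one of {PIPELINES}")
        if not (0 < self.train_fraction < 1):
            problems.append("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            problems.append("repeats must be >= 1")
        if self.leakage_mode not in LEAKAGE_MODES:
            problems.append(f"leakage_mode must be one of {LEAKAGE_MODES}")
        if self.hidden_units < 1:
            problems.append("hidden_units must be >= 1")
        if problems:
            raise ConfigError("; ".join(problems))
        self.step_dims = tuple(int(k) for k in self.step_dims)

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "preprocess": self.preprocess.to_dict(),
            "step_dims": list(self.step_dims),
            "ae_config": vars(self.ae_config).copy(),
            "lm_config": vars(self.lm_config).copy(),
            "hidden_units": self.hidden_units,
            "threshold": self.threshold,
            "train_fraction": self.train_fraction,
            "repeats": self.repeats,
            "leakage_mode": self.leakage_mode,
            "stratified": self.stratified,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            pipeline=d.get("pipeline", "encoded-ann"),
            preprocess=PreprocessSpec.from_dict(d["preprocess"])
            if "preprocess" in d else PreprocessSpec(),
            step_dims=tuple(d.get("step_dims", ae.DEFAULT_STEP_DIMS)),
            ae_config=AeConfig(**d.get("ae_config", {})),
            lm_config=LmConfig(**d.get("lm_config", {})),
            hidden_units=d.get("hidden_units", 10),
            threshold=d.get("threshold", 0.5),
            train_fraction=d.get("train_fraction", 0.75),
            repeats=d.get("repeats", 10),
            leakage_mode=d.get("leakage_mode", "repeat-internal"),
            stratified=d.get("stratified", False),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModelBundle:
    """A fitted pipeline: preprocessing descriptor, optional encoder stack,
    classifier, and creation metadata.

    Invariant: the classifier's input dimension equals the stack's final
    code dimension when a stack is present, else the preprocessing output
    dimension.
    """

    classifier: AnnClassifier
    preprocessing: PreprocessSpec
    autoencoder: AutoencoderStack | None = None
    seed: int | None = None
    created: str = ""
    config_hash: str = ""
    pipeline: str = "encoded-ann"

    def __post_init__(self) -> None:
        expected = (self.autoencoder.code_dim if self.autoencoder is not None
                    else self.preprocessing.output_dim)
        if self.classifier.n_inputs != expected:
            raise BundleConsistencyError(
                f"classifier expects {self.classifier.n_inputs} inputs but the "
                f"{'encoder emits' if self.autoencoder else 'preprocessing yields'} "
                f"{expected}"
            )


def fit_pipeline(train: SpectralDataset, config: PipelineConfig,
                 seed: int = 0) -> ModelBundle:
    """Fit scaler, (optionally) autoencoder, and classifier on ``train``.

    Every statistic is learned from ``train`` alone; apply the returned
    bundle to held-out spectra with :func:`predict_bundle`.
    """
    pp = preprocess(train, config.preprocess)
    spec = fit_scaler(pp, config.preprocess)
    scaled = apply_scaler(pp, spec)

    stack = None
    if config.pipeline == "encoded-ann":
        stack = ae.train_autoencoder(scaled, config.step_dims,
                                     config.ae_config, seed=seed)
        features = ae.encode(stack, scaled)
    else:
        features = scaled

    init = AnnClassifier.initialize(
        features.n_features, config.hidden_units, seed=seed,
        threshold=config.threshold,
    )
    clf, _ = lm_fit(init, features, config.lm_config)
    return ModelBundle(
        classifier=clf,
        preprocessing=spec,
        autoencoder=stack,
        seed=int(seed),
        created=datetime.now(timezone.utc).isoformat(),
        config_hash=config.config_hash(),
        pipeline=config.pipeline,
    )


def predict_bundle(bundle: ModelBundle, dataset: SpectralDataset):
    """Apply a fitted bundle to spectra; returns ``(scores, labels)``."""
    pp = preprocess(dataset, bundle.preprocessing)
    scaled = apply_scaler(pp, bundle.preprocessing)
    features = (ae.encode(bundle.autoencoder, scaled)
                if bundle.autoencoder is not None else scaled)
    return predict(bundle.classifier, features)
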