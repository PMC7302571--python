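"""Reading and writing spectral tables and trained model bundles.

Spectral tables are plain CSV, one sample per row: optional ``id``,
``label`` and ``cohort`` columns followed by one column per wavelength,
named by its value in nm (the supplementary-data convention of a column
header holding wavelengths in nm).  Values round-trip exactly because
Python's shortest-repr float formatting is used on write.

A trained pipeline serialises to a single self-describing JSON bundle:
a manifest (format version, dimensions, activations, configuration) plus
all weight arrays with explicit shapes, written with sorted keys so that
serialise -> deserialise -> serialise is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import AnnClassifier
from .autoencoder import AutoencoderStack, AutoencoderStep
from .dataset import EncodedDataset, SpectralDataset
from .errors import (
    BundleConsistencyError,
    BundleFormatError,
    BundleVersionError,
    DuplicateWavelengthError,
    LabelValueError,
    NonNumericWavelengthError,
    RaggedRowError,
    SpectraFormatError,
)
from .pipeline import ModelBundle
from .preprocessing import PreprocessSpec

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_encoded",
    "save_bundle",
    "load_bundle",
    "LABEL_ALIASES",
]

BUNDLE_FORMAT = "nirparity-bundle"
BUNDLE_VERSION = 1

# Human-readable label spellings accepted on read; written files always
# use the integer coding 0 = nulliparous, 1 = parous.
LABEL_ALIASES = {
    "0": 0, "1": 1,
    "nulliparous": 0, "parous": 1,
    "n": 0, "p": 1,
}

_META_COLUMNS = ("id", "label", "cohort")


def _parse_label(value, row: int):
    if pd.isna(value):
        raise LabelValueError(f"row {row}: missing label value")
    text = str(value).strip().lower()
    if text.endswith(".0"):
        text = text[:-2]
    if text not in LABEL_ALIASES:
        raise LabelValueError(
            f"row {row}: label {value!r} is not 0/1 (or a recognised alias)"
        )
    return LABEL_ALIASES[text]


def read_spectra(
    path,
    label_column: str | None = "label",
    id_column: str = "id",
    cohort_column: str = "cohort",
) -> SpectralDataset:
    """Read a CSV spectral table into a :class:`SpectralDataset`.

    Columns named ``id_column``/``label_column``/``cohort_column`` are
    routed to metadata when present; every other column must have a
    numeric wavelength header.  Wavelength columns are sorted ascending
    regardless of on-disk order; row order is preserved.  Missing ids
    are auto-generated as ``s0000, s0001, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such spectral table: {path}")
    # check the raw header before pandas mangles duplicate column names
    import csv

    with open(path, newline="") as fh:
        try:
            raw_header = next(csv.reader(fh))
        except StopIteration:
            raise SpectraFormatError(f"{path}: empty file") from None
    seen: set[str] = set()
    dupes = sorted({c for c in raw_header if c in seen or seen.add(c)})
    if dupes:
        raise DuplicateWavelengthError(
            f"{path}: duplicate columns {dupes[:10]}"
        )
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise RaggedRowError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise SpectraFormatError(f"{path}: empty file")

    meta_names = {id_column, cohort_column}
    if label_column is not None:
        meta_names.add(label_column)

    wavelengths: list[tuple[float, str]] = []
    for col in frame.columns:
        if col in meta_names:
            continue
        try:
            wavelengths.append((float(col), col))
        except ValueError:
            raise NonNumericWavelengthError(
                f"{path}: column {col!r} is neither a configured metadata "
                "column nor a numeric wavelength"
            ) from None
    if not wavelengths:
        raise SpectraFormatError(f"{path}: no wavelength columns found")
    values = [w for w, _ in wavelengths]
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise DuplicateWavelengthError(
            f"{path}: duplicate wavelength columns {dupes[:10]}"
        )
    wavelengths.sort(key=lambda t: t[0])
    wl = np.asarray([w for w, _ in wavelengths])
    cols = [c for _, c in wavelengths]

    spectral = frame[cols]
    if spectral.isna().any().any():
        bad_rows = np.flatnonzero(spectral.isna().any(axis=1).to_numpy())
        raise RaggedRowError(
            f"{path}: rows {bad_rows[:10].tolist()} are missing spectral values"
        )
    try:
        absorbance = spectral.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric absorbance value ({exc})") from exc

    n = len(frame)
    if id_column in frame.columns:
        ids = [str(v) for v in frame[id_column]]
    else:
        ids = [f"s{i:04d}" for i in range(n)]

    labels = None
    if label_column is not None and label_column in frame.columns:
        labels = np.asarray(
            [_parse_label(v, i) for i, v in enumerate(frame[label_column])]
        )

    cohort = None
    if cohort_column in frame.columns:
        cohort = frame[cohort_column].astype(object).to_numpy()

    return SpectralDataset(
        wavelengths_nm=wl,
        absorbance=absorbance,
        sample_ids=ids,
        labels=labels,
        cohort=cohort,
    )


def _format_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def write_spectra(dataset: SpectralDataset, path) -> None:
    """Write a dataset as CSV: id [, label] [, cohort], then wavelengths
    ascending.  Numeric values are written at full (round-trip) precision."""
    path = Path(path)
    columns: dict[str, object] = {"id": dataset.sample_ids}
    if dataset.labels is not None:
        columns["label"] = dataset.labels
    if dataset.cohort is not None:
        columns["cohort"] = dataset.cohort
    frame = pd.DataFrame(columns)
    spectral = pd.DataFrame(
        dataset.absorbance,
        columns=[_format_wavelength(w) for w in dataset.wavelengths_nm],
    )
    pd.concat([frame, spectral], axis=1).to_csv(path, index=False)


def write_encoded(encoded: EncodedDataset, path) -> None:
    """Write an encoded dataset as CSV with ``code_0..code_{k-1}`` columns."""
    path = Path(path)
    columns: dict[str, object] = {"id": encoded.sample_ids}
    if encoded.labels is not None:
        columns["label"] = encoded.labels
    if encoded.cohort is not None:
        columns["cohort"] = encoded.cohort
    frame = pd.DataFrame(columns)
    codes = pd.DataFrame(
        encoded.codes,
        columns=[f"code_{j}" for j in range(encoded.n_features)],
    )
    pd.concat([frame, codes], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
def _array_to_json(arr: np.ndarray) -> dict:
    arr = np.asarray(arr, dtype=np.float64)
    return {"shape": list(arr.shape), "data": arr.ravel().tolist()}


def _array_from_json(obj: dict) -> np.ndarray:
    try:
        return np.asarray(obj["data"], dtype=np.float64).reshape(obj["shape"])
    except (KeyError, TypeError, ValueError) as exc:
        raise BundleFormatError(f"malformed array record: {exc}") from exc


def _bundle_to_dict(bundle: ModelBundle) -> dict:
    clf = bundle.classifier
    doc = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "pipeline": bundle.pipeline,
        "metadata": {
            "seed": bundle.seed,
            "created": bundle.created,
            "config_hash": bundle.config_hash,
        },
        "preprocessing": bundle.preprocessing.to_dict(),
        "classifier": {
            "hidden_units": clf.hidden_units,
            "n_inputs": clf.n_inputs,
            "threshold": clf.threshold,
            "W1": _array_to_json(clf.W1),
            "b1": _array_to_json(clf.b1),
            "W2": _array_to_json(clf.W2),
            "b2": _array_to_json(clf.b2),
        },
        "autoencoder": None,
    }
    if bundle.autoencoder is not None:
        stack = bundle.autoencoder
        doc["autoencoder"] = {
            "step_dims": list(stack.step_dims),
            "input_dim": stack.input_dim,
            "step_mse": [float(m) for m in stack.step_mse],
            "seed": stack.seed,
            "steps": [
                {
                    "encoder_activation": s.encoder_activation,
                    "decoder_activation": s.decoder_activation,
                    "W_enc": _array_to_json(s.W_enc),
                    "b_enc": _array_to_json(s.b_enc),
                    "W_dec": _array_to_json(s.W_dec),
                    "b_dec": _array_to_json(s.b_dec),
                }
                for s in stack.steps
            ],
        }
    return doc


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialise a fitted pipeline to a self-describing JSON container."""
    doc = _bundle_to_dict(bundle)
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"
    )


def load_bundle(path) -> ModelBundle:
    """Load a bundle, validating version and dimensional consistency."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such bundle: {path}")
    text = path.read_text()
    if not text.strip():
        raise BundleFormatError(f"{path}: empty or truncated bundle file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BundleFormatError(f"{path}: truncated or invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != BUNDLE_FORMAT:
        raise BundleFormatError(f"{path}: not a {BUNDLE_FORMAT} file")
    if doc.get("version") != BUNDLE_VERSION:
        raise BundleVersionError(
            f"{path}: bundle version {doc.get('version')!r}, expected "
            f"{BUNDLE_VERSION}"
        )

    c = doc["classifier"]
    clf = AnnClassifier(
        W1=_array_from_json(c["W1"]),
        b1=_array_from_json(c["b1"]),
        W2=_array_from_json(c["W2"]),
        b2=_array_from_json(c["b2"]),
        threshold=float(c["threshold"]),
    )
    if clf.n_inputs != c["n_inputs"] or clf.hidden_units != c["hidden_units"]:
        raise BundleConsistencyError(
            f"{path}: classifier arrays disagree with declared dimensions"
        )

    stack = None
    if doc.get("autoencoder") is not None:
        a = doc["autoencoder"]
        steps = [
            AutoencoderStep(
                W_enc=_array_from_json(s["W_enc"]),
                b_enc=_array_from_json(s["b_enc"]),
                W_dec=_array_from_json(s["W_dec"]),
                b_dec=_array_from_json(s["b_dec"]),
                encoder_activation=s["encoder_activation"],
                decoder_activation=s["decoder_activation"],
            )
            for s in a["steps"]
        ]
        stack = AutoencoderStack(
            steps=steps,
            step_mse=[float(m) for m in a.get("step_mse", [])],
            seed=a.get("seed"),
        )
        if list(stack.step_dims) != list(a["step_dims"]) or stack.input_dim != a["input_dim"]:
            raise BundleConsistencyError(
                f"{path}: autoencoder arrays disagree with declared step_dims"
            )

    spec = PreprocessSpec.from_dict(doc["preprocessing"])
    meta = doc.get("metadata", {})
    try:
        return ModelBundle(
            classifier=clf,
            preprocessing=spec,
            autoencoder=stack,
            seed=meta.get("seed"),
            created=meta.get("created", ""),
            config_hash=meta.get("config_hash", ""),
            pipeline=doc.get("pipeline", "encoded-ann"),
        )
    except BundleConsistencyError:
        raise
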