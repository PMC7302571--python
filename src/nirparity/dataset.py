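"""In-memory containers for spectral and encoded datasets.

The interchange object throughout the package is :class:`SpectralDataset`:
a wavelength grid (nm), an N x D absorbance matrix, optional binary parity
labels (0 = nulliparous, 1 = parous), unique sample identifiers and an
optional per-sample cohort tag.  :class:`EncodedDataset` is its low-
dimensional counterpart produced by an autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import LabelValueError, SpectraFormatError

__all__ = ["SpectralDataset", "EncodedDataset", "as_matrix", "get_labels"]


def _validate_labels(labels: np.ndarray | None, n: int) -> np.ndarray | None:
    if labels is None:
        return None
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise SpectraFormatError(
            f"labels have shape {labels.shape}, expected ({n},)"
        )
    if not np.isin(labels, (0, 1)).all():
        bad = np.flatnonzero(~np.isin(labels, (0, 1)))
        raise LabelValueError(
            f"labels must be coded 0 (nulliparous) or 1 (parous); "
            f"offending rows: {bad[:10].tolist()}"
        )
    return labels.astype(np.int64)


@dataclass
class SpectralDataset:
    """One absorbance spectrum per mosquito plus labels and metadata.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, length D.
    absorbance
        N x D matrix of absorbance values (dimensionless), all finite.
    sample_ids
        N unique identifiers.
    labels
        Optional length-N array of {0, 1} parity labels.
    cohort
        Optional length-N array of cohort tags (e.g. a collection site).
    split_id, partition
        Set by :func:`nirparity.evaluation.split` to tag a dataset as the
        ``"train"`` or ``"test"`` partition of a particular split; used by
        the scaler's leakage guard.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    cohort: np.ndarray | None = None
    split_id: str | None = None
    partition: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=np.float64))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths_nm.ndim != 1:
            raise SpectraFormatError("wavelengths_nm must be one-dimensional")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise SpectraFormatError("wavelengths_nm must be strictly increasing")
        n, d = self.absorbance.shape
        if d != self.wavelengths_nm.size:
            raise SpectraFormatError(
                f"absorbance has {d} columns but {self.wavelengths_nm.size} "
                "wavelengths were given"
            )
        if not np.isfinite(self.absorbance).all():
            raise SpectraFormatError("absorbance contains non-finite values")
        if len(self.sample_ids) != n:
            raise SpectraFormatError(
                f"{len(self.sample_ids)} sample_ids for {n} spectra"
            )
        # duplicate sample_ids are tolerated here: they denote replicate
        # scans of the same mosquito and are merged by preprocess(); after
        # preprocessing ids are unique.
        self.labels = _validate_labels(self.labels, n)
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != (n,):
                raise SpectraFormatError("cohort must have one tag per sample")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_features(self) -> int:
        return self.absorbance.shape[1]

    @property
    def X(self) -> np.ndarray:
        """The feature matrix consumed by models."""
        return self.absorbance

    def class_counts(self) -> tuple[int, int]:
        """(n_nulliparous, n_parous); requires labels."""
        if self.labels is None:
            raise LabelValueError("dataset has no labels")
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset(
        self,
        indices: Sequence[int] | np.ndarray,
        *,
        split_id: str | None = None,
        partition: str | None = None,
    ) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return SpectralDataset(
            wavelengths_nm=self.wavelengths_nm.copy(),
            absorbance=self.absorbance[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx].copy(),
            cohort=None if self.cohort is None else self.cohort[idx].copy(),
            split_id=split_id if split_id is not None else self.split_id,
            partition=partition if partition is not None else self.partition,
        )

    def with_absorbance(self, absorbance: np.ndarray,
                        wavelengths_nm: np.ndarray | None = None) -> "SpectralDataset":
        """Copy of this dataset with a new absorbance matrix (and grid)."""
        return replace(
            self,
            absorbance=np.asarray(absorbance, dtype=np.float64),
            wavelengths_nm=(self.wavelengths_nm if wavelengths_nm is None
                            else np.asarray(wavelengths_nm, dtype=np.float64)),
        )

    def equals(self, other: "SpectralDataset") -> bool:
        """Field-by-field equality of the scientific content (not split tags)."""
        if not isinstance(other, SpectralDataset):
            return False
        same_labels = (
            (self.labels is None and other.labels is None)
            or (self.labels is not None and other.labels is not None
                and np.array_equal(self.labels, other.labels))
        )
        same_cohort = (
            (self.cohort is None and other.cohort is None)
            or (self.cohort is not None and other.cohort is not None
                and list(self.cohort) == list(other.cohort))
        )
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.absorbance, other.absorbance)
            and self.sample_ids == other.sample_ids
            and same_labels
            and same_cohort
        )


@dataclass
class EncodedDataset:
    """Low-dimensional codes for a set of spectra.

    Carries the source dataset's labels, ids and cohort unchanged, plus a
    fingerprint of the autoencoder stack that produced the codes.
    """

    codes: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    cohort: np.ndarray | None = None
    encoder_fingerprint: str = ""
    split_id: str | None = None
    partition: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=np.float64))
        n = self.codes.shape[0]
        if len(self.sample_ids) != n:
            raise SpectraFormatError(
                f"{len(self.sample_ids)} sample_ids for {n} code rows"
            )
        self.labels = _validate_labels(self.labels, n)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.codes


def as_matrix(data) -> np.ndarray:
    """Extract the N x D feature matrix from a dataset or array-like."""
    if hasattr(data, "X"):
        return np.asarray(data.X, dtype=np.float64)
    return np.atleast_2d(np.asarray(data, dtype=np.float64))


def get_labels(data) -> np.ndarray:
    """Extract binary labels from a dataset, raising if absent."""
    labels = getattr(data, "labels", None)
    if labels is None:
        raise LabelValueError("labels are required but absent")
    return np.asarray(labels, dtype=np.int64)
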