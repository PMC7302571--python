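"""Synthetic NIR-like mosquito spectra with a controllable parity effect.

Each spectrum is a smooth continuum (a low-order polynomial in normalised
wavelength, jittered per sample) plus a fixed set of Gaussian absorption
bands and additive Gaussian noise, on the full 350-2500 nm grid at 1 nm.
A small subset of bands carries the class signal: their depth in parous
samples is multiplied by ``1 + effect_size``, mimicking the subtle
compositional differences (cuticular lipids, protein/chitin turnover)
that distinguish egg-laid from never-laid females — a weak, distributed
signal rather than gross spectral separation, which is what makes
feature reduction genuinely useful.  ``effect_size = 0`` makes the two
classes exchangeable by construction.

A cohort shift (constant baseline offset plus a rigid band-centre
displacement) emulates instrument/site differences for cross-cohort
experiments.  Everything is deterministic under a seed.

The absorbance scale stays in a plausible 0-2 range so the min-max
scaler is exercised meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectralDataset
from .errors import ConfigError

__all__ = [
    "Band",
    "CohortShift",
    "SyntheticConfig",
    "generate",
    "generate_cohort_pair",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: centre and width in nm, depth in AU."""

    center_nm: float
    width_nm: float
    depth: float


# Twelve bands at plausible NIR positions (overtones/combination bands of
# O-H, C-H and N-H); three carry the parity effect by default.
DEFAULT_BANDS = (
    Band(450.0, 40.0, 0.10),
    Band(700.0, 50.0, 0.06),
    Band(970.0, 30.0, 0.12),   # class band (water / O-H 2nd overtone)
    Band(1150.0, 35.0, 0.08),
    Band(1450.0, 40.0, 0.25),
    Band(1550.0, 60.0, 0.07),
    Band(1720.0, 25.0, 0.10),  # class band (C-H 1st overtone, lipids)
    Band(1940.0, 45.0, 0.30),
    Band(2100.0, 50.0, 0.12),
    Band(2250.0, 40.0, 0.08),
    Band(2310.0, 20.0, 0.09),  # class band (C-H combination, cuticle)
    Band(2450.0, 45.0, 0.05),
)
DEFAULT_CLASS_BANDS = (2, 6, 10)


@dataclass(frozen=True)
class CohortShift:
    """Systematic difference applied to a whole cohort."""

    baseline_offset: float = 0.0
    center_shift_nm: float = 0.0


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a balanced, moderately separable
    dataset on the full-range grid."""

    n_parous: int = 100
    n_nulliparous: int = 100
    grid_low_nm: int = 350
    grid_high_nm: int = 2500
    grid_step_nm: int = 1
    baseline_mean: tuple[float, float, float] = (0.35, 0.9, -0.25)
    baseline_sd: tuple[float, float, float] = (0.03, 0.04, 0.02)
    bands: tuple[Band, ...] = DEFAULT_BANDS
    class_bands: tuple[int, ...] = DEFAULT_CLASS_BANDS
    effect_size: float = 1.0
    band_jitter_sd: float = 0.05
    noise_sd: float = 0.01
    cohort: str = "synthetic"
    cohort_shift: CohortShift = field(default_factory=CohortShift)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_parous < 0 or self.n_nulliparous < 0:
            problems.append("class sizes must be non-negative")
        if self.n_parous + self.n_nulliparous == 0:
            problems.append("at least one sample is required")
        if self.grid_high_nm <= self.grid_low_nm:
            problems.append("grid_high_nm must exceed grid_low_nm")
        if self.grid_step_nm < 1:
            problems.append("grid_step_nm must be >= 1")
        if self.effect_size < 0:
            problems.append("effect_size must be non-negative")
        if self.noise_sd < 0:
            problems.append("noise_sd must be non-negative")
        for i in self.class_bands:
            if not (0 <= i < len(self.bands)):
                problems.append(f"class_bands index {i} out of range")
        for b in self.bands:
            if not (self.grid_low_nm <= b.center_nm <= self.grid_high_nm):
                problems.append(
                    f"band centre {b.center_nm} nm lies outside the grid"
                )
            if b.depth < 0 or b.width_nm <= 0:
                problems.append(
                    f"band at {b.center_nm} nm needs positive width and "
                    "non-negative depth"
                )
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.grid_low_nm, self.grid_high_nm + 1,
                         self.grid_step_nm, dtype=np.float64)


def _band_profile(wl: np.ndarray, band: Band, center_shift: float) -> np.ndarray:
    c = band.center_nm + center_shift
    return np.exp(-0.5 * ((wl - c) / band.width_nm) ** 2)


def generate(config: SyntheticConfig) -> SpectralDataset:
    """Draw one labeled synthetic cohort; deterministic under the seed."""
    rng = np.random.default_rng(int(config.seed))
    wl = config.wavelengths
    x = (wl - wl[0]) / (wl[-1] - wl[0])  # normalised position in [0, 1]
    n = config.n_nulliparous + config.n_parous
    labels = np.concatenate([
        np.zeros(config.n_nulliparous, dtype=np.int64),
        np.ones(config.n_parous, dtype=np.int64),
    ])
    shift = config.cohort_shift

    profiles = np.stack([
        _band_profile(wl, b, shift.center_shift_nm) for b in config.bands
    ])  # (n_bands, D)

    spectra = np.empty((n, wl.size))
    for i in range(n):
        a0, a1, a2 = (
            rng.normal(m, s)
            for m, s in zip(config.baseline_mean, config.baseline_sd)
        )
        baseline = a0 + a1 * x + a2 * x * x + shift.baseline_offset
        depths = np.array([b.depth for b in config.bands])
        # per-sample biological variation of band intensities
        depths = depths * (1.0 + config.band_jitter_sd * rng.standard_normal(depths.size))
        if labels[i] == 1:
            for j in config.class_bands:
                depths[j] *= 1.0 + config.effect_size
        spectrum = baseline + depths @ profiles
        spectrum += rng.normal(0.0, config.noise_sd, size=wl.size)
        spectra[i] = spectrum

    ids = [f"{config.cohort}-{i:04d}" for i in range(n)]
    return SpectralDataset(
        wavelengths_nm=wl,
        absorbance=spectra,
        sample_ids=ids,
        labels=labels,
        cohort=np.asarray([config.cohort] * n, dtype=object),
    )


def generate_cohort_pair(config: SyntheticConfig,
                         shift: CohortShift | None = None):
    """Two cohorts sharing the class-effect structure.

    Cohort B gets independent noise (a derived seed) and the given
    systematic shift; with a zero shift the cohorts are statistically
    exchangeable.
    """
    shift = shift if shift is not None else CohortShift()
    cfg_a = replace(config, cohort=f"{config.cohort}-A")
    cfg_b = replace(
        config,
        cohort=f"{config.cohort}-B",
        cohort_shift=shift,
        seed=int(config.seed) + 1_000_003,
    )
    return generate(cfg_a), generate(cfg_b)


# ---------------------------------------------------------------------------
# Named presets used by the CLI and the test-suite.  "separable" is the
# strongly class-separated 400-sample draw (effect_size 2); "null" removes
# the class effect entirely; "muleba-imbalance" mirrors a 119:21
# nulliparous:parous field collection.
PRESETS: dict[str, SyntheticConfig] = {
    "balanced-easy": SyntheticConfig(n_parous=100, n_nulliparous=100,
                                     effect_size=2.0, cohort="balanced-easy"),
    "separable": SyntheticConfig(n_parous=200, n_nulliparous=200,
                                 effect_size=2.0, cohort="separable"),
    "moderate": SyntheticConfig(n_parous=100, n_nulliparous=100,
                                effect_size=1.0, cohort="moderate"),
    "null": SyntheticConfig(n_parous=200, n_nulliparous=200,
                            effect_size=0.0, cohort="null"),
    "muleba-imbalance": SyntheticConfig(n_parous=21, n_nulliparous=119,
                                        effect_size=1.0,
                                        cohort="muleba-imbalance"),
}


def preset(name: str, seed: int | None = None) -> SyntheticConfig:
    """Look up a preset by name, optionally overriding its seed."""
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]
    return replace(cfg, seed=int(seed)) if seed is not None else replace(cfg)
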