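"""Seeded generator of SERS-like serum cohorts.

Real serum SERS spectra are sharp vibrational peaks riding on a broad
autofluorescent background, with large between-subject variation in band
intensities and modest additive detector noise.  The generator emulates
exactly that structure for a two-group (Target / Control) case–control
cohort: each subject receives a multiplicative amplitude factor and
per-peak amplitude jitter shared by all of its replicate spectra, the
Target group's peaks inside configured *effect bands* are scaled by a
common ratio, and every spectrum gets its own additive Gaussian noise.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CONTROL, TARGET, SpectralDataset, Spectrum
from .errors import ConfigurationError

__all__ = [
    "PeakSpec",
    "CohortConfig",
    "make_axis",
    "synth_spectrum",
    "generate_cohort",
    "DEFAULT_SHARED_PEAKS",
    "DEFAULT_EFFECT_BANDS",
]

_LN2x4 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: center and FWHM in cm^-1, amplitude in a.u."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ConfigurationError(f"peak at {self.center}: fwhm must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError(f"peak at {self.center}: amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-amplitude line shape evaluated on ``axis``, scaled by amplitude."""
        d = (axis - self.center) / self.fwhm
        if self.shape == "lorentzian":
            return self.amplitude / (1.0 + 4.0 * d * d)
        return self.amplitude * np.exp(-_LN2x4 * d * d)


# Common serum SERS band positions (cm^-1); amplitudes are plausible relative
# intensities, not measurements.  Positions are configuration, not constants.
# The effect bands (632 / 725 / 1062) carry a modest share (~15%) of the total
# peak intensity so that between-group differences stay concentrated at those
# bands even after per-spectrum SNV rescaling.
DEFAULT_SHARED_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(495.0, 18.0, 0.30),
    PeakSpec(560.0, 16.0, 0.25),
    PeakSpec(590.0, 16.0, 0.35),
    PeakSpec(632.0, 14.0, 0.30),
    PeakSpec(680.0, 16.0, 0.20),
    PeakSpec(725.0, 16.0, 0.32),
    PeakSpec(810.0, 18.0, 0.30),
    PeakSpec(888.0, 18.0, 0.35),
    PeakSpec(960.0, 16.0, 0.40),
    PeakSpec(1005.0, 12.0, 0.60),
    PeakSpec(1062.0, 18.0, 0.28),
    PeakSpec(1135.0, 18.0, 0.35),
    PeakSpec(1208.0, 16.0, 0.30),
    PeakSpec(1270.0, 18.0, 0.25),
    PeakSpec(1330.0, 22.0, 0.50),
    PeakSpec(1445.0, 22.0, 0.55),
    PeakSpec(1525.0, 18.0, 0.20),
    PeakSpec(1585.0, 20.0, 0.40),
    PeakSpec(1655.0, 22.0, 0.45),
)

#: (center, fwhm) of the bands where the Target group differs from Control
DEFAULT_EFFECT_BANDS: tuple[tuple[float, float], ...] = (
    (632.0, 14.0),
    (728.0, 14.0),
    (1062.0, 18.0),
)


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one synthetic cohort.

    The defaults reproduce the study design this package targets: 48 Target
    and 30 Control subjects with 3 replicate spectra each on a 400–1800
    cm^-1 axis at 2 cm^-1 spacing (701 channels), a twofold Target/Control
    amplitude ratio at the three effect bands, additive noise giving a
    signal-to-noise ratio on the order of 50, and subject-level amplitude
    heterogeneity that survives per-spectrum normalization.
    """

    n_target: int = 48
    n_control: int = 30
    replicates_per_subject: int = 3
    axis_start: float = 400.0
    axis_stop: float = 1800.0
    axis_step: float = 2.0
    shared_peaks: tuple[PeakSpec, ...] = DEFAULT_SHARED_PEAKS
    effect_bands: tuple[tuple[float, float], ...] = DEFAULT_EFFECT_BANDS
    effect_ratio: float = 2.0
    subject_sd: float = 0.15
    peak_jitter_sd: float = 0.35
    noise_sd: float = 0.02
    baseline_scale: float = 1.5
    drop_spectra: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_target, self.n_control, self.replicates_per_subject) < 1:
            raise ConfigurationError("subject and replicate counts must be >= 1")
        if self.axis_step <= 0 or self.axis_start >= self.axis_stop:
            raise ConfigurationError("axis requires step > 0 and start < stop")
        if self.effect_ratio <= 0:
            raise ConfigurationError("effect_ratio must be > 0")
        if self.noise_sd < 0 or self.subject_sd < 0 or self.peak_jitter_sd < 0:
            raise ConfigurationError("noise_sd, subject_sd, peak_jitter_sd must be >= 0")
        if self.drop_spectra < 0:
            raise ConfigurationError("drop_spectra must be >= 0")
        object.__setattr__(self, "shared_peaks", tuple(self.shared_peaks))
        object.__setattr__(
            self, "effect_bands", tuple((float(c), float(f)) for c, f in self.effect_bands)
        )
        axis = self.axis()
        for pk in self.shared_peaks:
            if not (axis[0] <= pk.center <= axis[-1]):
                raise ConfigurationError(f"peak center {pk.center} outside axis range")

    def axis(self) -> np.ndarray:
        return make_axis(self.axis_start, self.axis_stop, self.axis_step)

    def with_(self, **kw) -> "CohortConfig":
        """Copy with fields replaced (dataclasses.replace wrapper)."""
        return replace(self, **kw)


def make_axis(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform wavenumber axis: start, start+step, ... (last point <= stop)."""
    if step <= 0:
        raise ConfigurationError(f"axis step must be > 0, got {step}")
    if start >= stop:
        raise ConfigurationError(f"axis start {start} must be < stop {stop}")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def _in_effect_band(pk: PeakSpec, bands) -> bool:
    return any(abs(pk.center - c) <= f / 2.0 for c, f in bands)


def _baseline_shape(axis: np.ndarray) -> np.ndarray:
    """Fixed smooth autofluorescence shape on [0, 1]-rescaled axis, unit scale."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    poly = 0.6 + 0.3 * u - 0.25 * u * u
    bump = 0.8 * np.exp(-((u - 0.25) ** 2) / (2 * 0.35**2))
    return poly + bump


def synth_spectrum(
    cfg: CohortConfig,
    group: str,
    subject_factor: float,
    seed: int | np.random.SeedSequence,
    peak_factors: np.ndarray | None = None,
    baseline_factor: float = 1.0,
) -> Spectrum:
    """One spectrum: baseline + subject_factor * sum(peaks) + noise.

    Peaks whose centers fall inside an effect band have their amplitudes
    multiplied by ``cfg.effect_ratio`` iff ``group == "Target"``.
    ``peak_factors`` (one per shared peak) carries subject-level band
    jitter; ``baseline_factor`` scales the autofluorescence for this
    subject.  Deterministic given ``seed``.
    """
    if subject_factor <= 0:
        raise ConfigurationError("subject_factor must be > 0")
    axis = cfg.axis()
    if peak_factors is None:
        peak_factors = np.ones(len(cfg.shared_peaks))
    signal = np.zeros_like(axis)
    for pk, jitter in zip(cfg.shared_peaks, peak_factors):
        amp = jitter
        if group == TARGET and _in_effect_band(pk, cfg.effect_bands):
            amp *= cfg.effect_ratio
        signal += amp * pk.profile(axis)
    intensities = cfg.baseline_scale * baseline_factor * _baseline_shape(axis)
    intensities = intensities + subject_factor * signal
    rng = np.random.default_rng(seed)
    intensities = intensities + rng.normal(0.0, cfg.noise_sd, len(axis))
    return Spectrum(axis=axis, intensities=intensities)


def generate_cohort(cfg: CohortConfig) -> SpectralDataset:
    """Generate the full cohort described by ``cfg``.

    Each subject draws one log-normal amplitude factor, one log-normal
    baseline factor and one per-peak jitter vector, all shared by its
    replicate spectra — so replicates are correlated within subject and
    subject-level train/test splitting genuinely matters downstream.
    ``cfg.drop_spectra`` removes one replicate from each of the last
    ``drop_spectra`` Control subjects (to mimic cohorts where a few
    recordings were discarded), never emptying a subject.
    """
    axis = cfg.axis()
    subjects = [(f"T{i + 1:02d}", TARGET) for i in range(cfg.n_target)]
    subjects += [(f"C{i + 1:02d}", CONTROL) for i in range(cfg.n_control)]
    if cfg.drop_spectra and cfg.replicates_per_subject < 2:
        raise ConfigurationError("drop_spectra requires >= 2 replicates per subject")
    if cfg.drop_spectra > cfg.n_control:
        raise ConfigurationError("drop_spectra cannot exceed the number of Control subjects")
    drop_from = {f"C{cfg.n_control - i:02d}" for i in range(cfg.drop_spectra)}

    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(len(subjects))
    rows, sids, groups, spec_ids = [], [], [], []
    for (sid, grp), ss in zip(subjects, subject_seeds):
        srng = np.random.default_rng(ss)
        subject_factor = math.exp(srng.normal(0.0, cfg.subject_sd))
        baseline_factor = math.exp(srng.normal(0.0, cfg.subject_sd))
        peak_factors = np.exp(srng.normal(0.0, cfg.peak_jitter_sd, len(cfg.shared_peaks)))
        n_rep = cfg.replicates_per_subject - (1 if sid in drop_from else 0)
        rep_seeds = ss.spawn(n_rep)
        for r, rseed in enumerate(rep_seeds):
            sp = synth_spectrum(
                cfg,
                grp,
                subject_factor,
                seed=rseed,
                peak_factors=peak_factors,
                baseline_factor=baseline_factor,
            )
            rows.append(sp.intensities)
            sids.append(sid)
            groups.append(grp)
            spec_ids.append(f"{sid}_r{r + 1}")
    return SpectralDataset(
        axis=axis,
        intensities=np.vstack(rows),
        subject_id=np.array(sids, dtype=object),
        group=np.array(groups, dtype=object),
        spectrum_id=np.array(spec_ids, dtype=object),
    )
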