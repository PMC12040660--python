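"""Spectral preprocessing: smoothing, baseline removal, SNV, SNR.

The chain applied to every spectrum, in fixed order, is

1. Savitzky–Golay smoothing (window 15 channels, polynomial order 1, no
   derivative) — local least-squares smoothing, length-preserving;
2. autofluorescence removal by an iterative clipped polynomial baseline
   fit of degree 15 (modified-polyfit scheme: points above the current
   fit are clipped to it before refitting, so the polynomial settles
   under the peaks);
3. Standard Normal Variate (SNV): per-spectrum centering and scaling to
   unit sample standard deviation.

Sample standard deviation (n-1 denominator) is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev
from scipy.signal import savgol_filter

from .dataset import SpectralDataset
from .errors import DataError, DegenerateInputError, ParameterError

__all__ = [
    "PreprocessConfig",
    "savgol_smooth",
    "baseline_correct",
    "snv",
    "estimate_snr",
    "preprocess_dataset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three-stage chain; defaults are the standard protocol."""

    sg_window: int = 15
    sg_polyorder: int = 1
    sg_deriv: int = 0
    baseline_degree: int = 15
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-3
    baseline_iterative: bool = True

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ParameterError(f"sg_window must be odd and >= 3, got {self.sg_window}")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ParameterError("sg_polyorder must satisfy 0 <= polyorder < window")
        if self.sg_deriv > self.sg_polyorder or self.sg_deriv < 0:
            raise ParameterError("sg_deriv must satisfy 0 <= deriv <= polyorder")
        if self.baseline_degree < 0:
            raise ParameterError("baseline_degree must be >= 0")
        if self.baseline_max_iter < 1 or self.baseline_tol <= 0:
            raise ParameterError("baseline_max_iter >= 1 and baseline_tol > 0 required")


def savgol_smooth(
    spectrum: np.ndarray, window: int = 15, polyorder: int = 1, deriv: int = 0
) -> np.ndarray:
    """Savitzky–Golay smoothing, length-preserving.

    Each interior point is replaced by the center value of the local
    least-squares polynomial of degree ``polyorder`` over ``window``
    channels; for ``polyorder <= 1`` this is the centered moving average.
    Edges are handled by evaluating the edge-window polynomial fit at the
    boundary channels, so polynomial signals of degree <= ``polyorder``
    (in particular any affine signal) pass through unchanged everywhere.
    """
    y = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > len(y):
        raise ParameterError(f"window {window} exceeds spectrum length {len(y)}")
    if polyorder >= window:
        raise ParameterError("polyorder must be < window")
    return savgol_filter(y, window, polyorder, deriv=deriv, mode="interp")


def baseline_correct(
    spectrum: np.ndarray,
    degree: int = 15,
    max_iter: int = 100,
    tol: float = 1e-3,
    iterative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial background estimation; returns ``(corrected, baseline)``.

    The baseline is a degree-``degree`` polynomial fitted in a Chebyshev
    basis on the channel index rescaled to [-1, 1] (a raw-wavenumber
    monomial Vandermonde at degree 15 is numerically singular).  In the
    iterative (default) scheme, after each fit the working signal is
    clipped from above to the fit and refitted; iteration stops when the
    relative change of the residual standard deviation drops below
    ``tol`` or after ``max_iter`` rounds.  On peak-free input the scheme
    degrades to the plain least-squares fit.  ``corrected = spectrum -
    baseline`` exactly, so ``baseline + corrected`` reconstructs the
    input to the last bit.
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("spectrum contains non-finite values")
    n = len(y)
    if degree >= n:
        raise ParameterError(f"baseline degree {degree} must be < {n} channels")
    x = np.linspace(-1.0, 1.0, n)
    work = y.copy()
    fit = work
    prev_sd = np.inf
    n_rounds = max_iter if iterative else 1
    for _ in range(n_rounds):
        coeffs = chebyshev.chebfit(x, work, degree)
        fit = chebyshev.chebval(x, coeffs)
        resid_sd = float(np.std(work - fit, ddof=1)) if n > 1 else 0.0
        if resid_sd == 0.0:
            break
        if np.isfinite(prev_sd) and abs(resid_sd - prev_sd) / prev_sd < tol:
            break
        prev_sd = resid_sd
        work = np.minimum(work, fit)
    baseline = fit
    return y - baseline, baseline


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: center, then scale to unit sample sd."""
    y = np.asarray(spectrum, dtype=float)
    if len(y) < 2:
        raise DegenerateInputError("SNV requires at least 2 channels")
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("SNV undefined for a constant spectrum (sd = 0)")
    return (y - y.mean()) / sd


def estimate_snr(raw: np.ndarray, smoothed: np.ndarray) -> float:
    """Peak-to-peak amplitude of the smoothed signal over the residual sd.

    The residual ``raw - smoothed`` estimates the noise; a noise-free
    spectrum (zero residual sd) yields ``+inf`` by contract.
    """
    raw = np.asarray(raw, dtype=float)
    smoothed = np.asarray(smoothed, dtype=float)
    if raw.shape != smoothed.shape:
        raise DataError(f"length mismatch: raw {raw.shape} vs smoothed {smoothed.shape}")
    noise_sd = float(np.std(raw - smoothed, ddof=1)) if len(raw) > 1 else 0.0
    signal = float(np.ptp(smoothed))
    if noise_sd == 0.0:
        return float("inf")
    return signal / noise_sd


def preprocess_dataset(
    ds: SpectralDataset, cfg: PreprocessConfig | None = None
) -> SpectralDataset:
    """Apply smooth -> baseline-correct -> SNV to every row independently.

    Axis and metadata are carried over unchanged.  Errors raised by any
    stage are re-raised annotated with the failing row's spectrum id.
    """
    cfg = cfg or PreprocessConfig()
    if ds.n_spectra == 0:
        return ds
    out = np.empty_like(ds.intensities)
    snrs = np.empty(ds.n_spectra)
    for i in range(ds.n_spectra):
        raw = ds.intensities[i]
        if not np.all(np.isfinite(raw)):
            raise DataError(f"spectrum {ds.spectrum_id[i]!r}: non-finite intensities")
        try:
            smoothed = savgol_smooth(raw, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
            corrected, _ = baseline_correct(
                smoothed,
                cfg.baseline_degree,
                cfg.baseline_max_iter,
                cfg.baseline_tol,
                cfg.baseline_iterative,
            )
            out[i] = snv(corrected)
        except Exception as exc:
            raise type(exc)(f"spectrum {ds.spectrum_id[i]!r}: {exc}") from exc
        snrs[i] = estimate_snr(raw, smoothed)
    log.info(
        "preprocessed %d spectra (SNR min %.1f, median %.1f)",
        ds.n_spectra,
        np.min(snrs),
        np.median(snrs),
    )
    return SpectralDataset(
        axis=ds.axis,
        intensities=out,
        subject_id=ds.subject_id,
        group=ds.group,
        spectrum_id=ds.spectrum_id,
    )
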