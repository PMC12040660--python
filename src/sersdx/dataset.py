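"""In-memory containers for spectra and labelled spectral cohorts.

A :class:`Spectrum` is one wavenumber axis plus one intensity vector; a
:class:`SpectralDataset` is an intensity matrix whose rows share a single
axis, together with per-row subject ids and group labels.  Datasets
round-trip losslessly through a pair of delimited-text files: a wide
spectra CSV (header = wavenumbers, one row per spectrum) and a companion
metadata CSV with columns ``spectrum_id, subject_id, group``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError

TARGET = "Target"
CONTROL = "Control"
GROUPS = (TARGET, CONTROL)

#: float format preserving full double precision in text round-trips
_FLOAT_FMT = "%.17g"


class Spectrum(NamedTuple):
    """A single spectrum: wavenumber axis (cm^-1) and intensities (a.u.)."""

    axis: np.ndarray
    intensities: np.ndarray


@dataclass
class SpectralDataset:
    """Intensity matrix aligned to one shared wavenumber axis.

    Parameters
    ----------
    axis
        Strictly increasing wavenumber vector (cm^-1), length = n_channels.
    intensities
        (n_spectra, n_channels) matrix, arbitrary units.
    subject_id
        Per-row subject identifier.
    group
        Per-row group label, each in ``{"Target", "Control"}``.
    spectrum_id
        Per-row unique spectrum identifier; generated if not given.
    """

    axis: np.ndarray
    intensities: np.ndarray
    subject_id: np.ndarray
    group: np.ndarray
    spectrum_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        arr = np.asarray(self.intensities, dtype=float)
        self.intensities = arr.reshape(0, len(self.axis)) if arr.size == 0 else np.atleast_2d(arr)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        n = self.intensities.shape[0]
        if self.spectrum_id is None:
            self.spectrum_id = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
        else:
            self.spectrum_id = np.asarray(self.spectrum_id, dtype=object)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        n, p = self.intensities.shape if self.intensities.size else (0, len(self.axis))
        if self.intensities.size and p != len(self.axis):
            raise DataError(
                f"intensity matrix has {p} columns but axis has {len(self.axis)} channels"
            )
        for name, arr in (
            ("subject_id", self.subject_id),
            ("group", self.group),
            ("spectrum_id", self.spectrum_id),
        ):
            if len(arr) != n:
                raise DataError(f"{name} has length {len(arr)}, expected {n} rows")
        if len(self.axis) > 1 and not np.all(np.diff(self.axis) > 0):
            raise DataError("wavenumber axis must be strictly increasing")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)!r}")
        # every subject maps to exactly one group
        seen: dict[object, object] = {}
        for sid, grp in zip(self.subject_id, self.group):
            if seen.setdefault(sid, grp) != grp:
                raise DataError(f"subject {sid!r} appears in more than one group")
        if len(set(self.spectrum_id)) != n:
            raise DataError("spectrum_id values must be unique")

    # -- convenience --------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return 0 if self.intensities.size == 0 else self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.axis)

    def subjects(self) -> pd.DataFrame:
        """One row per subject with its group label, in first-appearance order."""
        df = pd.DataFrame({"subject_id": self.subject_id, "group": self.group})
        return df.drop_duplicates("subject_id").reset_index(drop=True)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset sharing the same axis."""
        mask = np.asarray(mask)
        return SpectralDataset(
            axis=self.axis,
            intensities=self.intensities[mask],
            subject_id=self.subject_id[mask],
            group=self.group[mask],
            spectrum_id=self.spectrum_id[mask],
        )

    def y(self) -> np.ndarray:
        """Dummy-coded response: Target = 1, Control = 0."""
        return (self.group == TARGET).astype(float)

    # -- text I/O ------------------------------------------------------------
    def to_csv(self, spectra_path: str | Path, meta_path: str | Path) -> None:
        """Write the wide spectra CSV and the companion metadata CSV."""
        wide = pd.DataFrame(self.intensities, columns=[_FLOAT_FMT % w for w in self.axis])
        wide.insert(0, "spectrum_id", self.spectrum_id)
        wide.to_csv(spectra_path, index=False, float_format=_FLOAT_FMT)
        meta = pd.DataFrame(
            {
                "spectrum_id": self.spectrum_id,
                "subject_id": self.subject_id,
                "group": self.group,
            }
        )
        meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path: str | Path, meta_path: str | Path) -> "SpectralDataset":
        """Load a dataset written by :meth:`to_csv` (lossless round-trip)."""
        wide = pd.read_csv(spectra_path, float_precision="round_trip")
        if "spectrum_id" not in wide.columns:
            raise DataError("spectra CSV must contain a 'spectrum_id' column")
        meta = pd.read_csv(meta_path)
        required = {"spectrum_id", "subject_id", "group"}
        if not required.issubset(meta.columns):
            raise DataError(f"metadata CSV must contain columns {sorted(required)}")
        meta = meta.set_index("spectrum_id")
        ids = wide["spectrum_id"].astype(str).to_numpy(dtype=object)
        try:
            meta = meta.loc[ids]
        except KeyError as exc:
            raise DataError(f"metadata missing spectrum ids: {exc}") from exc
        axis = np.array([float(c) for c in wide.columns[1:]])
        return cls(
            axis=axis,
            intensities=wide.iloc[:, 1:].to_numpy(dtype=float),
            subject_id=meta["subject_id"].to_numpy(dtype=object),
            group=meta["group"].to_numpy(dtype=object),
            spectrum_id=ids,
        )
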