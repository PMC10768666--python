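"""Shared primitive types for LC-MS/MS features and spectra.

A *feature* is the atomic unit of untargeted LC-MS metabolomics: an ion
characterized by its m/z, retention time and intensity, optionally carrying
the MS/MS (fragmentation) spectrum acquired on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PROTON_MASS = 1.007276
ISOTOPE_SPACING = 1.003355  # Da, averaged 13C-12C spacing


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS scan: precursor m/z, retention time and a fragment peak list.

    Peaks are stored as parallel arrays sorted by ascending m/z; intensities
    are non-negative and on an arbitrary scale (similarity scoring normalizes
    them).
    """

    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensities: np.ndarray
    charge: int = 1

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if mz.shape != it.shape:
            raise ValueError("mz and intensities must have the same shape")
        if np.any(it < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", it[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensities.tolist()))


@dataclass
class SampleFeature:
    """A detected ion in one sample x replicate injection."""

    feature_id: str
    sample_id: str
    replicate: int
    mz: float
    rt: float
    intensity: float
    spectrum: Optional[Spectrum] = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if self.intensity < 0:
            raise ValueError(f"feature {self.feature_id}: negative intensity")


def ppm_diff(mz_a: float, mz_b: float) -> float:
    """Relative mass difference in parts per million, on the mean mass."""
    mean = 0.5 * (mz_a + mz_b)
    return abs(mz_a - mz_b) / mean * 1e6
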