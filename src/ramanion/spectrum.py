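"""The Spectrum container: one Raman acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """A single Raman spectrum.

    Parameters
    ----------
    wavenumbers
        Strictly increasing Raman shifts in cm^-1.
    intensities
        Detector counts (arbitrary units), same length as ``wavenumbers``.
    metadata
        Free-form acquisition context (z position, group, solute,
        concentration, replicate ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis length mismatch: {self.wavenumbers.size} wavenumbers "
                f"vs {self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities, metadata preserved."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        dict(self.metadata))

    def integral(self, window: tuple[float, float] | None = None) -> float:
        """Trapezoidal integrated intensity, optionally over a window."""
        if window is None:
            return float(np.trapezoid(self.intensities, self.wavenumbers))
        lo, hi = window
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window {window} contains fewer than 2 points")
        return float(np.trapezoid(self.intensities[mask], self.wavenumbers[mask]))
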