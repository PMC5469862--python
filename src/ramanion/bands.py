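"""Raman band catalogue and pseudo-Voigt line shapes.

The high-wavenumber window (2400-4200 cm^-1) of a Raman spectrum collected
from a hydrated epithelial cell is modelled as a sum of pseudo-Voigt bands:

* five O-H stretching sub-bands of liquid water, assigned to hydrogen-bond
  cluster classes of the water molecule (DAA, DDAA, DA, DDA and free O-H,
  where D = hydrogen-bond donor and A = acceptor);
* C-H stretching bands of lipids and proteins (cytosol);
* aromatic C-H stretching bands of the polycarbonate permeable support the
  cells grow on, visible when the probe sits near the basal surface.

The DDAA band (~3221 cm^-1) tracks tetrahedrally coordinated, "ice-like"
water; the DA band (~3429 cm^-1) tracks partially hydrogen-bonded water.
Their integrated-intensity ratio r = I_DA / I_DDAA rises with
structure-breaking solutes (Cl-, HEPES, glucose, proteins) and falls with
structure makers (Mg2+, Ca2+), which makes it usable as an ionic-activity
index inside cells.

A pseudo-Voigt here is the standard area-normalised linear mix of a
Lorentzian and a Gaussian sharing one FWHM:

    pV(x; A, x0, w, eta) = A * [eta * L(x; x0, w) + (1 - eta) * G(x; x0, w)]

with unit-area L and G, so the ``area`` parameter is exactly the integrated
band intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandTemplate",
    "BAND_TABLE",
    "WATER_LABELS",
    "CELL_ONLY_LABELS",
    "band_set",
    "template",
    "gaussian_profile",
    "lorentzian_profile",
    "pseudo_voigt",
    "pseudo_voigt_gradient",
    "sum_bands",
]

_K = 4.0 * np.log(2.0)                    # Gaussian FWHM factor
_CG = 2.0 * np.sqrt(np.log(2.0) / np.pi)  # unit-area Gaussian peak * fwhm

WAVENUMBER_MIN = 2400.0
WAVENUMBER_MAX = 4200.0


@dataclass(frozen=True)
class BandTemplate:
    """One spectral band: assignment plus default line-shape parameters.

    ``width`` is the FWHM in cm^-1, ``shape_fraction`` the Lorentzian
    fraction of the pseudo-Voigt (0 = pure Gaussian, 1 = pure Lorentzian)
    and ``area`` the default integrated intensity used by the synthetic
    generator (arbitrary units).
    """

    label: str
    center: float
    width: float
    shape_fraction: float
    area: float
    assignment: str
    category: str  # "water" | "lipid_protein" | "substrate"

    def __post_init__(self) -> None:
        if not (WAVENUMBER_MIN <= self.center <= WAVENUMBER_MAX):
            raise ValueError(
                f"band {self.label!r}: center {self.center} cm^-1 outside "
                f"[{WAVENUMBER_MIN}, {WAVENUMBER_MAX}]"
            )
        if self.width <= 0:
            raise ValueError(f"band {self.label!r}: width must be > 0")
        if not 0.0 <= self.shape_fraction <= 1.0:
            raise ValueError(f"band {self.label!r}: shape_fraction outside [0, 1]")
        if self.area < 0:
            raise ValueError(f"band {self.label!r}: area must be >= 0")


# The twelve bands observed in cell scans, ordered by center.  Widths,
# shape fractions and default areas are generator conventions (the line
# widths of the O-H sub-bands are broad, 100-250 cm^-1, the C-H and
# substrate bands narrow, 30-60 cm^-1); centers are the standard
# assignments for this spectral window.
BAND_TABLE: tuple[BandTemplate, ...] = (
    BandTemplate("CH2_sym_2855", 2855.0, 45.0, 0.5, 6.0,
                 "CH2 symmetric stretch, lipids/proteins", "lipid_protein"),
    BandTemplate("CH3_sym_2874", 2874.0, 40.0, 0.5, 5.0,
                 "CH3 symmetric stretch and R3C-H, lipids/proteins", "lipid_protein"),
    BandTemplate("CH_asym_2900", 2900.0, 50.0, 0.5, 4.0,
                 "CH2 asymmetric stretch (lipids/proteins) and CH3 asymmetric stretch (polycarbonate)",
                 "lipid_protein"),
    BandTemplate("CH3_asym_2933", 2933.0, 55.0, 0.5, 5.0,
                 "CH3 asymmetric stretch, lipids/proteins", "lipid_protein"),
    BandTemplate("PC_2980", 2980.0, 30.0, 0.5, 9.0,
                 "aromatic C-H stretch, polycarbonate", "substrate"),
    BandTemplate("PC_3000", 3000.0, 30.0, 0.5, 8.0,
                 "aromatic C-H stretch, polycarbonate", "substrate"),
    BandTemplate("DAA", 3016.0, 180.0, 0.3, 8.0,
                 "O-H stretch, water, DAA cluster", "water"),
    BandTemplate("PC_3072", 3072.0, 35.0, 0.5, 6.0,
                 "aromatic C-H stretch, polycarbonate", "substrate"),
    BandTemplate("DDAA", 3221.0, 220.0, 0.3, 46.0,
                 "O-H stretch, water, DDAA cluster (tetrahedral)", "water"),
    BandTemplate("DA", 3429.0, 190.0, 0.3, 62.7,
                 "O-H stretch, water, DA cluster", "water"),
    BandTemplate("DDA", 3572.0, 110.0, 0.3, 15.0,
                 "O-H stretch, water, DDA cluster", "water"),
    BandTemplate("free_OH", 3636.0, 100.0, 0.3, 4.0,
                 "O-H stretch, water, free O-H", "water"),
)

WATER_LABELS: tuple[str, ...] = ("DAA", "DDAA", "DA", "DDA", "free_OH")
CELL_ONLY_LABELS: tuple[str, ...] = tuple(
    b.label for b in BAND_TABLE if b.category != "water"
)

_BY_LABEL = {b.label: b for b in BAND_TABLE}


def template(label: str) -> BandTemplate:
    """Return the catalogue entry for ``label``."""
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown band label {label!r}") from None


def band_set(context: str) -> tuple[BandTemplate, ...]:
    """Band templates fitted in a given context.

    ``"solution"`` uses the five water O-H sub-bands only; ``"cell"`` adds
    the lipid/protein C-H and polycarbonate bands that overlap the O-H
    envelope between 2800 and 3200 cm^-1.
    """
    if context == "solution":
        return tuple(b for b in BAND_TABLE if b.category == "water")
    if context == "cell":
        return BAND_TABLE
    raise ValueError(f"unknown context {context!r}; expected 'solution' or 'cell'")


def gaussian_profile(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian with the given FWHM."""
    u = (x - center) / fwhm
    return (_CG / fwhm) * np.exp(-_K * u * u)


def lorentzian_profile(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian with the given FWHM."""
    u = 2.0 * (x - center) / fwhm
    return (2.0 / (np.pi * fwhm)) / (1.0 + u * u)


def pseudo_voigt(
    x: np.ndarray, area: float, center: float, fwhm: float, eta: float
) -> np.ndarray:
    """Area-parametrised pseudo-Voigt profile (eta = Lorentzian fraction)."""
    return area * (
        eta * lorentzian_profile(x, center, fwhm)
        + (1.0 - eta) * gaussian_profile(x, center, fwhm)
    )


def pseudo_voigt_gradient(
    x: np.ndarray, area: float, center: float, fwhm: float, eta: float
) -> np.ndarray:
    """Partial derivatives of the pseudo-Voigt wrt (area, center, fwhm, eta).

    Returns an array of shape (4, x.size).  Used as the analytic Jacobian of
    the multi-band least-squares fit, where finite differencing over dozens
    of parameters would dominate the runtime.
    """
    G = gaussian_profile(x, center, fwhm)
    L = lorentzian_profile(x, center, fwhm)
    u = x - center
    w2 = fwhm * fwhm
    denom = 1.0 + 4.0 * u * u / w2
    shape = eta * L + (1.0 - eta) * G
    dG_dc = G * (2.0 * _K * u / w2)
    dG_dw = G * (-1.0 / fwhm + 2.0 * _K * u * u / (w2 * fwhm))
    dL_dc = L * (8.0 * u / w2) / denom
    dL_dw = L * (-1.0 / fwhm + (8.0 * u * u / (w2 * fwhm)) / denom)
    return np.stack(
        [
            shape,
            area * (eta * dL_dc + (1.0 - eta) * dG_dc),
            area * (eta * dL_dw + (1.0 - eta) * dG_dw),
            area * (L - G),
        ]
    )


def sum_bands(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of pseudo-Voigt bands; ``params`` has rows (area, center, fwhm, eta)."""
    params = np.atleast_2d(params)
    y = np.zeros_like(x, dtype=float)
    for area, center, fwhm, eta in params:
        y += pseudo_voigt(x, area, center, fwhm, eta)
    return y


def _gl_matrices(x: np.ndarray, centers: np.ndarray, fwhms: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Broadcast unit-area Gaussian/Lorentzian profiles for many bands.

    Returns (G, L, u, denom) with shape (n_bands, x.size); ``u`` is the
    offset from each center and ``denom`` the Lorentzian denominator,
    both reused by the gradient assembly.
    """
    c = centers[:, None]
    w = fwhms[:, None]
    u = x[None, :] - c
    G = (_CG / w) * np.exp(-_K * (u / w) ** 2)
    denom = 1.0 + 4.0 * u * u / (w * w)
    L = (2.0 / (np.pi * w)) / denom
    return G, L, u, denom


def pseudo_voigt_bands(
    x: np.ndarray, areas: np.ndarray, centers: np.ndarray,
    fwhms: np.ndarray, etas: np.ndarray,
) -> np.ndarray:
    """Vectorised model: sum over bands of area-parametrised pseudo-Voigts."""
    G, L, _, _ = _gl_matrices(x, centers, fwhms)
    e = etas[:, None]
    return (areas[:, None] * (e * L + (1.0 - e) * G)).sum(axis=0)


def pseudo_voigt_bands_gradient(
    x: np.ndarray, areas: np.ndarray, centers: np.ndarray,
    fwhms: np.ndarray, etas: np.ndarray,
) -> np.ndarray:
    """Vectorised Jacobian blocks, shape (n_bands, 4, x.size).

    Per band the rows are the partials wrt (area, center, fwhm, eta).
    """
    G, L, u, denom = _gl_matrices(x, centers, fwhms)
    a = areas[:, None]
    w = fwhms[:, None]
    e = etas[:, None]
    w2 = w * w
    shape = e * L + (1.0 - e) * G
    dG_dc = G * (2.0 * _K * u / w2)
    dG_dw = G * (-1.0 / w + 2.0 * _K * u * u / (w2 * w))
    dL_dc = L * (8.0 * u / w2) / denom
    dL_dw = L * (-1.0 / w + (8.0 * u * u / (w2 * w)) / denom)
    out = np.empty((areas.size, 4, x.size))
    out[:, 0, :] = shape
    out[:, 1, :] = a * (e * dL_dc + (1.0 - e) * dG_dc)
    out[:, 2, :] = a * (e * dL_dw + (1.0 - e) * dG_dw)
    out[:, 3, :] = a * (L - G)
    return out
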