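"""Depth profiles of r, thickness, Delta[Na+](z), flux and current.

Coordinates follow the acquisition convention: z = 0 at the permeable
polycarbonate support (basolateral side), increasing through the cytosol
to the apical membrane at z = t and into the bath beyond.  The flux
formula uses the opposite (apical-to-basolateral) axis, so the sign flip
is applied inside :func:`sodium_flux` only; stored data stay in
acquisition order.

The physical chain is:

* r(z) profiles are averaged across cells per group;
* the apical membrane is located where r settles onto the extracellular
  plateau;
* the treated-minus-control difference Delta r(z) in the cytosol is
  converted to Delta[Na+](z) through the NaCl calibration slope (with
  electroneutrality, Delta[Cl-] = Delta[Na+]);
* a line fitted to Delta[Na+](z) gives the aldosterone-induced gradient;
* the mean concentration change is the integral of that line over the cell
  thickness divided by t (analytically intercept + slope*t/2);
* Fick's first law converts the gradient to a flux
  Delta J_Na = -D_Na * d(Delta[Na+])/dz  (apical->basolateral axis);
* the equivalent short-circuit current is Delta I_sc = Delta J_Na * F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "D_NA_CM2_S",
    "FARADAY_C_PER_MOL",
    "ZProfile",
    "DeltaProfile",
    "GradientFit",
    "FluxResult",
    "PlateauNotFoundError",
    "average_profiles",
    "estimate_thickness",
    "per_depth_ttest",
    "delta_profile",
    "fit_gradient",
    "mean_concentration_change",
    "sodium_flux",
    "short_circuit_current",
]

#: Sodium diffusion coefficient at 25 C used in the flux estimate
#: (cm^2 s^-1).  Kept at the value adopted by the source analysis even
#: though it is low relative to aqueous-diffusion literature;
#: overridable wherever it is consumed.
D_NA_CM2_S = 1.33e-8

#: Faraday constant (C mol^-1).
FARADAY_C_PER_MOL = 96485.332


class PlateauNotFoundError(RuntimeError):
    """The r(z) profile never settles onto the extracellular plateau."""


@dataclass
class ZProfile:
    """Mean depth profile of r for one group of cells."""

    z: np.ndarray          # um, strictly increasing
    r_mean: np.ndarray
    r_sd: np.ndarray
    n_cells: int
    r_cells: np.ndarray    # (n_cells, n_z) per-cell values, kept for t-tests

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class DeltaProfile:
    """Treated-minus-control difference profile restricted to the cytosol."""

    z: np.ndarray
    delta_r: np.ndarray
    delta_na: np.ndarray       # mM (= Delta[Cl-] by electroneutrality)
    p_values: np.ndarray
    significant: np.ndarray    # p <= alpha mask
    alpha: float = 0.05


@dataclass(frozen=True)
class GradientFit:
    """Line fitted to Delta[Na+](z) in acquisition coordinates."""

    slope: float       # mM/um, basolateral -> apical axis
    intercept: float   # mM at z = 0
    pearson_r: float
    z_range: tuple[float, float]
    n_points: int
    pearson_defined: bool = True


@dataclass(frozen=True)
class FluxResult:
    """Eqs for mean change, Fick flux and equivalent short-circuit current."""

    mean_delta_conc: float            # mM, cytosol average of Delta[Na+]
    gradient_instrument: float        # mM/um, basolateral -> apical
    gradient_paper_convention: float  # mM/um, apical -> basolateral (negated)
    d_na: float                       # cm^2/s
    flux: float                       # mol s^-1 cm^-2
    faraday: float                    # C/mol
    i_sc: float                       # uA cm^-2
    thickness: float                  # um
    pearson_r: float = float("nan")


def average_profiles(
    cells: Sequence[tuple[np.ndarray, np.ndarray]] | Sequence[np.ndarray],
    z: np.ndarray | None = None,
) -> ZProfile:
    """Pointwise mean and SD of per-cell r(z) profiles sharing one z grid.

    ``cells`` is either a list of (z, r) pairs or a list of r arrays with
    the shared grid passed separately.
    """
    if len(cells) == 0:
        raise ValueError("no cells to average")
    first = cells[0]
    if isinstance(first, tuple) or (isinstance(first, (list,)) and len(first) == 2):
        z0 = np.asarray(first[0], dtype=float)
        rs = []
        for zc, rc in cells:  # type: ignore[misc]
            zc = np.asarray(zc, dtype=float)
            if zc.shape != z0.shape or not np.allclose(zc, z0):
                raise ValueError("cells do not share the same z grid")
            rs.append(np.asarray(rc, dtype=float))
    else:
        if z is None:
            raise ValueError("z grid required when passing bare r arrays")
        z0 = np.asarray(z, dtype=float)
        rs = [np.asarray(rc, dtype=float) for rc in cells]
        for rc in rs:
            if rc.shape != z0.shape:
                raise ValueError("cells do not share the same z grid")
    mat = np.vstack(rs)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(z0.size)
    return ZProfile(z0, mat.mean(axis=0), sd, mat.shape[0], mat)


def estimate_thickness(
    p: ZProfile, r_extracellular: float, tol: float = 0.01
) -> float:
    """First grid depth from which r stays on the extracellular plateau.

    Returns the smallest sampled z* such that
    ``|r_mean(z) - r_extracellular| <= tol * r_extracellular`` for every
    z >= z*.  For a scan of a cell of thickness t this lands at the first
    sample past the apical membrane (the axial PSF delays the plateau
    onset by up to one grid step; the membrane itself sits one step below,
    a correction applied by the pipeline, not here).
    """
    dev = np.abs(p.r_mean - r_extracellular) <= tol * r_extracellular
    if not dev[-1]:
        raise PlateauNotFoundError(
            "profile never reaches the extracellular plateau within the scan"
        )
    # last index where the plateau condition fails, +1
    failing = np.nonzero(~dev)[0]
    idx = 0 if failing.size == 0 else failing[-1] + 1
    return float(p.z[idx])


def per_depth_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> float:
    """Two-sided unpaired t-test p-value at a single depth.

    Student's (equal-variance) form by default, matching the classical
    reading of an unpaired t-test with five cells per group; Welch via
    ``equal_var=False``.  Degenerate zero-variance data with equal means
    gives p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def delta_profile(
    treated: ZProfile,
    control: ZProfile,
    t: float,
    cal_nacl,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> DeltaProfile:
    """Cytosolic difference profile and its conversion to Delta[Na+](z).

    For each depth strictly inside the cytosol (0 < z < t) the difference
    of group means is divided by the NaCl calibration slope (which jointly
    encodes the Na+ and Cl- effect on r) and a per-depth unpaired t-test
    compares the two groups of cells.
    """
    if treated.z.shape != control.z.shape or not np.allclose(treated.z, control.z):
        raise ValueError("treated and control profiles do not share a z grid")
    if cal_nacl.slope == 0:
        raise ValueError("NaCl calibration slope is zero")
    mask = (treated.z > 0) & (treated.z < t)
    if not np.any(mask):
        raise ValueError(f"no cytosolic grid points strictly inside (0, {t})")
    z = treated.z[mask]
    dr = treated.r_mean[mask] - control.r_mean[mask]
    dna = dr / cal_nacl.slope
    idx = np.nonzero(mask)[0]
    pvals = np.array([
        per_depth_ttest(treated.r_cells[:, i], control.r_cells[:, i],
                        equal_var=equal_var)
        for i in idx
    ])
    return DeltaProfile(z, dr, dna, pvals, pvals <= alpha, alpha)


def fit_gradient(
    dp: DeltaProfile,
    z_min: float | None = None,
    z_max: float | None = None,
) -> GradientFit:
    """Least-squares line through Delta[Na+](z) with Pearson correlation.

    Operates on the per-depth mean values, in acquisition coordinates.
    A constant profile is degenerate: slope 0 is returned with the
    Pearson coefficient flagged undefined.
    """
    mask = np.ones(dp.z.size, dtype=bool)
    if z_min is not None:
        mask &= dp.z >= z_min
    if z_max is not None:
        mask &= dp.z <= z_max
    z = dp.z[mask]
    y = dp.delta_na[mask]
    if z.size < 3:
        raise ValueError(f"need >= 3 cytosolic points to fit a gradient, got {z.size}")
    if np.ptp(y) == 0:
        return GradientFit(0.0, float(y[0]) if y.size else 0.0, 0.0,
                           (float(z[0]), float(z[-1])), int(z.size),
                           pearson_defined=False)
    res = stats.linregress(z, y)
    return GradientFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        z_range=(float(z[0]), float(z[-1])),
        n_points=int(z.size),
    )


def mean_concentration_change(fit: GradientFit, t: float) -> float:
    """Cytosol-average concentration change from the fitted line.

    Analytic integral of (intercept + slope*z) over [0, t] divided by t:
    intercept + slope * t / 2.  (The mean of a linear profile is its
    midpoint value.)
    """
    if t <= 0:
        raise ValueError("thickness must be positive")
    return fit.intercept + fit.slope * t / 2.0


def sodium_flux(gradient_instrument: float, d: float = D_NA_CM2_S) -> float:
    """Fick's-law Na+ flux from the measured concentration gradient.

    ``gradient_instrument`` is d(Delta[Na+])/dz in mM/um on the
    acquisition axis (basolateral -> apical).  The flux convention uses
    the opposite axis, so the gradient is negated before applying
    Delta J = -D * d(Delta[Na+])/dz; with the unit conversion
    1 mM/um = 1e-2 mol/cm^4 this reduces to D * gradient_instrument * 1e-2
    in mol s^-1 cm^-2.
    """
    if not np.isfinite(gradient_instrument) or not np.isfinite(d):
        raise ValueError("gradient and D must be finite")
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    return d * gradient_instrument * 1.0e-2


def short_circuit_current(j: float, faraday: float = FARADAY_C_PER_MOL) -> float:
    """Equivalent short-circuit current density Delta I_sc = Delta J_Na * F.

    ``j`` in mol s^-1 cm^-2 gives A cm^-2; returned in uA cm^-2.
    """
    if not np.isfinite(j):
        raise ValueError("flux must be finite")
    return j * faraday * 1.0e6
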