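"""Spectral processing: baseline, normalization, band deconvolution, r.

The measurement chain for every spectrum is

    subtract_baseline -> normalize_total -> deconvolve -> compute_r

where ``deconvolve`` performs a bound-constrained nonlinear least-squares
fit of pseudo-Voigt bands (five water O-H sub-bands in solution spectra;
those plus lipid/protein C-H and polycarbonate bands in cell spectra) and
``compute_r`` forms the ionic-activity index r = I_DA / I_DDAA from the
integrated band areas.  Areas rather than peak heights are used as the
band "intensities": the sub-bands overlap heavily and integrated areas are
robust to the Gaussian/Lorentzian shape mix.

Centers are initialised at the catalogue values and bounded to +/-30 cm^-1,
which also pins each sub-band to its assignment (the bounds of adjacent
O-H sub-bands do not overlap, so fitted centers cannot swap).  Amplitudes
are non-negative.  Initial areas come from a non-negative linear solve
with the catalogue shapes, after which all parameters are refined by a
trust-region reflective solver with an analytic Jacobian; on a failed fit
the solver is restarted from jittered initial values (fixed jitter seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .bands import (BandTemplate, band_set, pseudo_voigt, pseudo_voigt_bands,
                    pseudo_voigt_bands_gradient)
from .spectrum import Spectrum

__all__ = [
    "FittedBand",
    "BandFit",
    "RValue",
    "FitError",
    "DEFAULT_ANCHORS",
    "subtract_baseline",
    "normalize_total",
    "deconvolve",
    "compute_r",
    "r_from_spectrum",
]

#: Flat spectral tails used to anchor the linear baseline (cm^-1).
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((2400.0, 2500.0), (4100.0, 4200.0))

DEFAULT_CENTER_WINDOW = 30.0       # cm^-1, +/- bound on fitted centers
DEFAULT_WIDTH_BOUNDS = (20.0, 400.0)  # cm^-1, FWHM bounds


class FitError(RuntimeError):
    """Deconvolution failed to converge (after restarts)."""


@dataclass(frozen=True)
class FittedBand:
    """Converged parameters of one band."""

    label: str
    center: float
    fwhm: float
    shape_fraction: float
    area: float
    amplitude: float  # peak height at the fitted center


@dataclass
class BandFit:
    """Result of deconvolving one spectrum into pseudo-Voigt bands.

    ``baseline`` holds the (offset, slope) of the residual linear term
    co-fitted with the bands; it absorbs what a preceding anchor-window
    subtraction cannot know about, such as band wings reaching into the
    anchors.
    """

    bands: list[FittedBand]
    residual_norm: float
    converged: bool
    context: str
    n_points: int
    baseline: tuple[float, float] = (0.0, 0.0)
    area_covariance: np.ndarray | None = None  # ordered as ``bands``

    def area(self, label: str) -> float:
        for b in self.bands:
            if b.label == label:
                return b.area
        raise KeyError(f"no band {label!r} in this fit")

    def _index(self, label: str) -> int:
        for i, b in enumerate(self.bands):
            if b.label == label:
                return i
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [b.label for b in self.bands],
                "center_cm1": [b.center for b in self.bands],
                "fwhm_cm1": [b.fwhm for b in self.bands],
                "shape_fraction": [b.shape_fraction for b in self.bands],
                "area": [b.area for b in self.bands],
                "amplitude": [b.amplitude for b in self.bands],
            }
        )


@dataclass(frozen=True)
class RValue:
    """The DA/DDAA intensity ratio with (optional) propagated uncertainty."""

    r: float
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")


def _window_points(wn: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in windows:
        if hi < wn[0] or lo > wn[-1]:
            raise ValueError(
                f"anchor window ({lo}, {hi}) lies outside the spectrum range "
                f"[{wn[0]}, {wn[-1]}]"
            )
        mask |= (wn >= lo) & (wn <= hi)
    return mask


def subtract_baseline(
    s: Spectrum, anchor_windows=DEFAULT_ANCHORS
) -> Spectrum:
    """Remove the straight line fitted to the anchor windows.

    The line is a least-squares fit to the points inside the anchor
    windows (band-free spectral tails by default); after subtraction the
    anchor-window mean of the result is ~0.
    """
    mask = _window_points(s.wavenumbers, anchor_windows)
    for lo, hi in anchor_windows:
        if np.sum((s.wavenumbers >= lo) & (s.wavenumbers <= hi)) < 3:
            raise ValueError(f"anchor window ({lo}, {hi}) contains fewer than 3 points")
    coeffs = np.polynomial.polynomial.polyfit(
        s.wavenumbers[mask], s.intensities[mask], 1
    )
    baseline = coeffs[0] + coeffs[1] * s.wavenumbers
    return s.with_intensities(s.intensities - baseline)


def normalize_total(
    s: Spectrum, target: float = 100.0, window: tuple[float, float] | None = None
) -> Spectrum:
    """Rescale so the total integrated intensity equals ``target``.

    Matches the convention of normalising each spectrum's integral to 100
    before comparing band intensities across acquisitions.
    """
    total = s.integral(window)
    if total <= 0:
        raise ValueError(
            f"non-positive integrated intensity ({total:g}); cannot normalize"
        )
    return s.with_intensities(s.intensities * (target / total))


def _initial_linear(
    x: np.ndarray, y: np.ndarray, templates: tuple[BandTemplate, ...],
    fit_baseline: bool,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Initial areas (non-negative) and baseline from a linear solve with
    catalogue shapes fixed."""
    cols = [pseudo_voigt(x, 1.0, b.center, b.width, b.shape_fraction)
            for b in templates]
    n = len(cols)
    lo = [0.0] * n
    hi = [np.inf] * n
    if fit_baseline:
        cols += [np.ones_like(x), x - x[0]]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]
    res = lsq_linear(np.column_stack(cols), y, bounds=(lo, hi))
    areas = res.x[:n]
    base = (float(res.x[n]), float(res.x[n + 1])) if fit_baseline else (0.0, 0.0)
    return areas, base


def deconvolve(
    s: Spectrum,
    context: str = "solution",
    templates: tuple[BandTemplate, ...] | None = None,
    mode: str = "free",
    center_window: float = DEFAULT_CENTER_WINDOW,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    restarts: int = 3,
    jitter_seed: int = 0,
    fit_baseline: bool = True,
) -> BandFit:
    """Fit pseudo-Voigt bands to a baseline-subtracted spectrum.

    Parameters
    ----------
    s
        Spectrum, ideally baseline-subtracted and normalized.
    context
        ``"solution"`` fits the five O-H sub-bands; ``"cell"`` adds the
        lipid/protein C-H and polycarbonate substrate bands.
    templates
        Explicit band templates, overriding ``context``.
    mode
        ``"free"`` refines every band parameter (characterization).
        ``"constrained"`` pins widths and shape fractions to the template
        values and refines only areas, centers and the baseline — the
        standard choice when quantifying relative intensity changes over
        many replicate spectra, where the heavy overlap of the O-H
        sub-bands makes fully free shapes trade off against each other
        and inflate the variance of the area ratio by an order of
        magnitude.
    restarts
        Number of jittered restarts attempted if the solver fails.
    fit_baseline
        Co-fit a residual linear baseline with the bands (default).  The
        anchor-window subtraction removes the bulk of the background, but
        the broad O-H band wings reach into any anchor window one can
        choose; the residual linear term absorbs exactly that.

    Raises
    ------
    ValueError
        If the spectrum window does not cover all band centers.
    FitError
        If the solver fails to converge after all restarts.
    """
    if mode not in ("free", "constrained"):
        raise ValueError(f"unknown mode {mode!r}")
    bands = templates if templates is not None else band_set(context)
    x, y = s.wavenumbers, s.intensities

    for b in bands:
        if not (x[0] <= b.center <= x[-1]):
            raise ValueError(
                f"band {b.label!r} at {b.center} cm^-1 lies outside the "
                f"spectrum window [{x[0]}, {x[-1]}]"
            )

    peak = float(np.max(np.abs(y))) if y.size else 0.0
    if peak > 0 and float(y.min()) < -0.05 * peak:
        warnings.warn(
            "spectrum has substantial negative intensity; the baseline may "
            "have been over-subtracted (anchors inside a band?)",
            UserWarning,
            stacklevel=2,
        )

    n = len(bands)
    nb = 2 if fit_baseline else 0
    npar = 4 * n + nb
    areas0, base0 = _initial_linear(x, y, bands, fit_baseline)
    p_full = np.empty(npar)
    lower = np.empty(npar)
    upper = np.empty(npar)
    free = np.ones(npar, dtype=bool)
    for i, b in enumerate(bands):
        p_full[4 * i: 4 * i + 4] = (max(areas0[i], 1e-6), b.center, b.width,
                                    b.shape_fraction)
        lower[4 * i: 4 * i + 4] = (0.0, b.center - center_window, width_bounds[0], 0.0)
        upper[4 * i: 4 * i + 4] = (np.inf, b.center + center_window, width_bounds[1], 1.0)
        if mode == "constrained":
            free[4 * i + 2] = False  # width
            free[4 * i + 3] = False  # shape fraction
    if fit_baseline:
        p_full[-2:] = base0
        lower[-2:] = -np.inf
        upper[-2:] = np.inf
    p_full = np.clip(p_full, lower, upper)
    x0_off = x - x[0]

    def expand(q: np.ndarray) -> np.ndarray:
        p = p_full.copy()
        p[free] = q
        return p

    def residuals(q: np.ndarray) -> np.ndarray:
        p = expand(q)
        out = pseudo_voigt_bands(x, p[0:4 * n:4], p[1:4 * n:4],
                                 p[2:4 * n:4], p[3:4 * n:4]) - y
        if fit_baseline:
            out += p[-2] + p[-1] * x0_off
        return out

    def jacobian(q: np.ndarray) -> np.ndarray:
        p = expand(q)
        blocks = pseudo_voigt_bands_gradient(x, p[0:4 * n:4], p[1:4 * n:4],
                                             p[2:4 * n:4], p[3:4 * n:4])
        J = np.empty((x.size, npar))
        J[:, :4 * n] = blocks.reshape(4 * n, x.size).T
        if fit_baseline:
            J[:, -2] = 1.0
            J[:, -1] = x0_off
        return J[:, free]

    x_scale_full = np.tile([max(peak, 1e-3) * 50.0, 10.0, 30.0, 0.3], n)
    if fit_baseline:
        x_scale_full = np.concatenate(
            [x_scale_full, [max(peak, 1e-3), max(peak, 1e-3) / (x[-1] - x[0])]]
        )
    rng = np.random.default_rng(jitter_seed)
    best = None
    for attempt in range(restarts + 1):
        start = p_full.copy()
        if attempt > 0:
            start[1:4 * n:4] += rng.uniform(-5.0, 5.0, n)
            if mode == "free":
                start[2:4 * n:4] *= rng.uniform(0.8, 1.25, n)
            start[0:4 * n:4] *= rng.uniform(0.5, 2.0, n)
            start = np.clip(start, lower, upper)
        res = least_squares(
            residuals, start[free], jac=jacobian,
            bounds=(lower[free], upper[free]),
            method="trf", x_scale=x_scale_full[free],
            ftol=1e-9, xtol=1e-9, gtol=1e-9, max_nfev=600,
        )
        if res.status > 0 and np.all(np.isfinite(res.x)):
            if best is None or res.cost < best.cost:
                best = res
            break  # first converged solve wins; restarts are for failures only
    if best is None:
        raise FitError(
            f"deconvolution did not converge after {restarts + 1} attempts"
        )

    p = expand(best.x)
    fitted = []
    for i, b in enumerate(bands):
        a, c, w, e = p[4 * i: 4 * i + 4]
        amp = float(pseudo_voigt(np.array([c]), a, c, w, e)[0])
        fitted.append(FittedBand(b.label, float(c), float(w), float(e), float(a), amp))

    area_cov = _area_covariance(best, x.size, free, n)
    return BandFit(
        bands=fitted,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=True,
        context=context if templates is None else "custom",
        n_points=x.size,
        baseline=(float(p[-2]), float(p[-1])) if fit_baseline else (0.0, 0.0),
        area_covariance=area_cov,
    )


def _area_covariance(res, m: int, free: np.ndarray, n_bands: int) -> np.ndarray | None:
    """Linearised covariance of the fitted areas (may be None if singular)."""
    n_free = int(free.sum())
    if m <= n_free:
        return None
    try:
        J = res.jac
        s2 = 2.0 * res.cost / (m - n_free)
        cov_free = np.linalg.pinv(J.T @ J) * s2
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    # positions of the area parameters within the free-parameter vector
    free_idx = np.nonzero(free)[0]
    pos = {orig: k for k, orig in enumerate(free_idx)}
    area_pos = [pos[4 * i] for i in range(n_bands)]  # areas are always free
    return cov_free[np.ix_(area_pos, area_pos)]


def compute_r(fit: BandFit) -> RValue:
    """The intensity ratio r = I_DA / I_DDAA from a converged band fit."""
    if not fit.converged:
        raise ValueError("cannot compute r from a non-converged fit")
    a_da = fit.area("DA")
    a_ddaa = fit.area("DDAA")
    if a_ddaa <= 0:
        raise ValueError(f"DDAA area is {a_ddaa:g}; r is undefined")
    r = a_da / a_ddaa
    unc = None
    if fit.area_covariance is not None:
        i, j = fit._index("DA"), fit._index("DDAA")
        var_da = fit.area_covariance[i, i]
        var_ddaa = fit.area_covariance[j, j]
        cov = fit.area_covariance[i, j]
        var_r = r * r * (
            var_da / a_da**2 + var_ddaa / a_ddaa**2 - 2.0 * cov / (a_da * a_ddaa)
        )
        if np.isfinite(var_r) and var_r >= 0:
            unc = float(np.sqrt(var_r))
    return RValue(float(r), unc)


def r_from_spectrum(
    s: Spectrum,
    context: str = "solution",
    anchor_windows=DEFAULT_ANCHORS,
    normalize_target: float = 100.0,
    mode: str = "constrained",
    **deconvolve_kwargs,
) -> RValue:
    """Full single-spectrum chain: baseline -> normalize -> fit -> r.

    Uses the constrained fit mode by default: when the goal is the
    DA/DDAA area ratio across many replicate spectra, the line shapes are
    held at their reference values and only areas, centers and the
    residual baseline are refined (see :func:`deconvolve`).
    """
    s = subtract_baseline(s, anchor_windows)
    s = normalize_total(s, normalize_target)
    fit = deconvolve(s, context=context, mode=mode, **deconvolve_kwargs)
    return compute_r(fit)
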