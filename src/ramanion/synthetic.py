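"""Synthetic Raman data with known ground truth.

Real acquisitions of this experiment (calibration solutions and confocal
z-line scans of renal epithelial cells on permeable supports) are not
distributed with the package, so every downstream stage is exercised
against phenomenological synthetic spectra whose generating parameters are
known exactly:

* solution spectra are sums of the five water O-H pseudo-Voigt sub-bands on
  a linear baseline, with the DA/DDAA area ratio r set directly;
* calibration series put r on a line r = r0 + slope * c per solute, with the
  qualitative slope ordering observed experimentally (NaCl and KCl equal;
  MgCl2 and CaCl2 equal per cation, i.e. half per Cl-; NaHCO3 smallest;
  HEPES, glucose and protein largest);
* cell z-scans sweep the probe from the polycarbonate support (z = 0)
  through the cytosol to the bath, with substrate and lipid/protein C-H
  bands appearing where they physically would, an imposed intracellular
  r(z) profile, axial blurring by the confocal point-spread function, and
  additive Gaussian noise.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical spec + seed reproduces outputs
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bands import BAND_TABLE, WATER_LABELS, pseudo_voigt, template
from .spectrum import Spectrum

__all__ = [
    "WaterSpectrumConfig",
    "SoluteSpec",
    "CellScanSpec",
    "GroundTruth",
    "DEFAULT_R0",
    "DEFAULT_SOLUTES",
    "ISOTONIC_BUFFER",
    "buffer_r_true",
    "make_water_spectrum",
    "make_calibration_series",
    "make_cell_zscan",
    "make_cell_group",
    "make_r_replicates",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Pure-water intercept of every calibration line.  A single shared
#: intercept makes solute contributions exactly additive in the generated
#: world; its value is fixed so that the additive prediction for the
#: isotonic test buffer (below) equals the measured buffer ratio 1.363.
DEFAULT_R0 = 1.28325


@dataclass(frozen=True)
class SoluteSpec:
    """A calibration series: one solute at several concentrations.

    ``slope`` is the generating sensitivity of r per mM (per mg/mL for
    protein); positive for structure breakers, which raise the DA
    population at the expense of tetrahedral DDAA water.
    """

    name: str
    slope: float
    concentrations: tuple[float, ...]
    unit: str = "mM"
    anions_per_formula: int = 1  # Cl- per formula unit, for the anion axis

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0:
            raise ValueError(f"{self.name}: empty concentration list")
        if np.any(c <= 0):
            raise ValueError(f"{self.name}: concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError(f"{self.name}: concentrations must be increasing")


#: The eight experimental series (concentrations in mM; protein in mg/mL).
#: Slopes are generator conventions that respect the qualitative ordering
#: found experimentally; they are configuration, not measured claims.
DEFAULT_SOLUTES: dict[str, SoluteSpec] = {
    s.name: s
    for s in (
        SoluteSpec("NaCl", 5.0e-4, (24.0, 96.0, 144.0, 192.0)),
        SoluteSpec("KCl", 5.0e-4, (24.0, 96.0, 144.0, 192.0)),
        SoluteSpec("MgCl2", 5.0e-4, (24.0, 48.0, 96.0), anions_per_formula=2),
        SoluteSpec("CaCl2", 5.0e-4, (24.0, 48.0, 96.0), anions_per_formula=2),
        SoluteSpec("NaHCO3", 1.5e-4, (24.0, 96.0, 144.0, 192.0)),
        SoluteSpec("Hepes", 1.2e-3, (10.0, 24.0, 48.0, 96.0)),
        SoluteSpec("Glucose", 1.0e-3, (24.0, 48.0, 96.0)),
        SoluteSpec("Protein", 1.5e-3, (10.0, 50.0, 100.0), unit="mg/mL"),
    )
}

#: Isotonic test buffer bathing the cells (mM), pH 7.4.
ISOTONIC_BUFFER: dict[str, float] = {
    "NaCl": 120.0,
    "KCl": 3.5,
    "CaCl2": 1.0,
    "MgCl2": 1.0,
    "Glucose": 5.0,
    "Hepes": 10.0,
}


def buffer_r_true(
    composition: Mapping[str, float] | None = None,
    solutes: Mapping[str, SoluteSpec] | None = None,
    r0: float = DEFAULT_R0,
) -> float:
    """Generating r of a mixture under the additive model r0 + sum(s_i c_i)."""
    composition = ISOTONIC_BUFFER if composition is None else composition
    solutes = DEFAULT_SOLUTES if solutes is None else solutes
    return r0 + sum(solutes[name].slope * c for name, c in composition.items())


@dataclass(frozen=True)
class WaterSpectrumConfig:
    """Grid, baseline, noise and band-shape settings for solution spectra.

    ``noise_sd`` is the standard deviation of additive Gaussian noise as a
    fraction of the noise-free spectrum maximum.  The linear baseline is
    deliberately small relative to the O-H envelope, as in a
    background-corrected confocal measurement.
    """

    wn_start: float = 2400.0
    wn_stop: float = 4200.0
    wn_step: float = 1.0
    noise_sd: float = 0.005
    baseline_offset: float = 0.02
    baseline_slope: float = 1.0e-5
    water_areas: Mapping[str, float] | None = None  # overrides catalogue areas

    def grid(self) -> np.ndarray:
        if self.wn_stop <= self.wn_start or self.wn_step <= 0:
            raise ValueError("empty wavenumber grid")
        n = int(round((self.wn_stop - self.wn_start) / self.wn_step)) + 1
        return self.wn_start + self.wn_step * np.arange(n)


DEFAULT_CONFIG = WaterSpectrumConfig()


def _water_band_params(r_target: float,
                       config: WaterSpectrumConfig) -> np.ndarray:
    """Rows (area, center, fwhm, eta) for the five O-H sub-bands.

    The DA area is slaved to the DDAA area so that area_DA / area_DDAA
    equals ``r_target`` exactly by construction.
    """
    overrides = dict(config.water_areas or {})
    rows = []
    area_ddaa = overrides.get("DDAA", template("DDAA").area)
    for label in WATER_LABELS:
        b = template(label)
        if label == "DA":
            area = r_target * area_ddaa
        else:
            area = overrides.get(label, b.area)
        rows.append((area, b.center, b.width, b.shape_fraction))
    return np.array(rows)


def _synthesize(
    x: np.ndarray,
    band_params: np.ndarray,
    config: WaterSpectrumConfig,
    rng: np.random.Generator | None,
    noise_sd: float,
) -> np.ndarray:
    y = np.zeros_like(x)
    for area, center, fwhm, eta in band_params:
        if area > 0:
            y += pseudo_voigt(x, area, center, fwhm, eta)
    y += config.baseline_offset + config.baseline_slope * (x - x[0])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd * y.max(), size=x.size)
    return y


def make_water_spectrum(
    r_target: float,
    config: WaterSpectrumConfig | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> Spectrum:
    """Synthesize one solution spectrum with a prescribed DA/DDAA ratio.

    The spectrum is the sum of the five O-H pseudo-Voigt sub-bands plus a
    linear baseline plus (optional) Gaussian noise; the generating band
    areas satisfy area_DA / area_DDAA = ``r_target`` exactly.
    """
    if not np.isfinite(r_target) or r_target <= 0:
        raise ValueError(f"r_target must be positive, got {r_target}")
    config = config or DEFAULT_CONFIG
    x = config.grid()
    rng = np.random.default_rng(seed)
    params = _water_band_params(r_target, config)
    y = _synthesize(x, params, config, rng, config.noise_sd)
    return Spectrum(x, y, {"kind": "solution", "r_target": float(r_target)})


def make_calibration_series(
    solute: str | SoluteSpec,
    r0: float = DEFAULT_R0,
    replicates: int = 20,
    config: WaterSpectrumConfig | None = None,
    seed: int | None = None,
) -> dict[float, list[Spectrum]]:
    """Generate a full calibration series for one solute.

    For each concentration c the generating ratio is r0 + slope * c and
    ``replicates`` independent noisy spectra are synthesized (the default
    20 matches the experimental design of 20 spectra per solution).
    """
    if isinstance(solute, str):
        try:
            solute = DEFAULT_SOLUTES[solute]
        except KeyError:
            raise ValueError(f"unknown solute {solute!r}") from None
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or DEFAULT_CONFIG
    children = np.random.SeedSequence(seed).spawn(len(solute.concentrations))
    out: dict[float, list[Spectrum]] = {}
    for c, child in zip(solute.concentrations, children):
        rng = np.random.default_rng(child)
        specs = []
        for rep in range(replicates):
            s = make_water_spectrum(r0 + solute.slope * c, config, rng)
            s.metadata.update(
                solute=solute.name, concentration=float(c), replicate=rep,
                unit=solute.unit,
            )
            specs.append(s)
        out[float(c)] = specs
    return out


@dataclass(frozen=True)
class CellScanSpec:
    """Everything needed to generate one confocal z-line scan of a cell.

    The coordinate convention is the acquisition one: z = 0 at the
    polycarbonate support (basolateral side), increasing toward the apical
    membrane at ``thickness`` and into the bath beyond it.

    The untreated intracellular r(z) baseline is highest at the basolateral
    side and decays (length ``basal_decay_um``) to a small apical offset
    above the extracellular value.  Treated scans superpose a linear
    aldosterone-induced Delta[Na+](z) profile, negative basolaterally and
    positive apically, converted to r through the NaCl sensitivity.

    ``noise_sd`` defaults to the level that reproduces the per-depth
    scatter of the published difference profiles (Pearson ~0.92 for the
    fitted gradient); see docs/methods.md.
    """

    thickness: float = 15.0
    z_start: float = 0.0
    z_stop: float = 30.0
    z_step: float = 1.0
    group: str = "control"
    delta_na_mean: float = 4.3       # mM, cytosol average of the imposed change
    delta_na_slope: float = 1.47     # mM/um, in acquisition coordinates
    r_extracellular: float = 1.363
    apical_offset: float = 0.05      # cytosolic r excess just under the apical membrane
    basal_offset: float = 0.15       # cytosolic r excess at the basolateral side
    basal_decay_um: float = 3.0
    nacl_slope: float = DEFAULT_SOLUTES["NaCl"].slope
    psf_axial_fwhm: float = 1.14     # um
    noise_sd: float = 0.005
    seed: int | None = None
    config: WaterSpectrumConfig = field(default_factory=WaterSpectrumConfig)
    ch_area_scale: float = 1.0       # lipid/protein band intensity inside the cell
    pc_area_scale: float = 1.0       # polycarbonate band intensity at the support

    def __post_init__(self) -> None:
        if self.group not in ("control", "treated"):
            raise ValueError(f"group must be 'control' or 'treated', got {self.group!r}")
        if not (self.z_start < self.thickness < self.z_stop):
            raise ValueError(
                f"thickness {self.thickness} um outside the scanned range "
                f"({self.z_start}, {self.z_stop})"
            )
        if self.psf_axial_fwhm <= 0:
            raise ValueError("psf_axial_fwhm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")

    def z_grid(self) -> np.ndarray:
        n = int(round((self.z_stop - self.z_start) / self.z_step)) + 1
        return self.z_start + self.z_step * np.arange(n)


@dataclass(frozen=True)
class GroundTruth:
    """Generating quantities of a z-scan, the oracle for recovery tests."""

    z: np.ndarray
    r_ideal: np.ndarray          # before PSF blurring
    r_blurred: np.ndarray        # profile actually encoded in the spectra
    delta_na: np.ndarray         # mM, imposed change (zero for control / outside cytosol)
    true_slope: float            # mM/um, acquisition coordinates
    true_mean_delta_na: float    # mM
    true_thickness: float        # um
    spec: CellScanSpec


def _ideal_r(z: np.ndarray, spec: CellScanSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (unblurred) r(z) and Delta[Na+](z) on an arbitrary z grid."""
    r = np.full_like(z, spec.r_extracellular, dtype=float)
    delta_na = np.zeros_like(z, dtype=float)
    cytosol = (z > 0) & (z < spec.thickness)
    zc = z[cytosol]
    r_cyto = (
        spec.r_extracellular
        + spec.apical_offset
        + (spec.basal_offset - spec.apical_offset) * np.exp(-zc / spec.basal_decay_um)
    )
    if spec.group == "treated":
        dna = spec.delta_na_mean + spec.delta_na_slope * (zc - spec.thickness / 2.0)
        delta_na[cytosol] = dna
        r_cyto = r_cyto + spec.nacl_slope * dna
    r[cytosol] = r_cyto
    return r, delta_na


def _blur(profile: np.ndarray, dz: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA / dz
    if sigma < 1e-3:  # delta-kernel limit
        return profile.copy()
    return gaussian_filter1d(profile, sigma, mode="nearest")


def make_cell_zscan(spec: CellScanSpec) -> tuple[list[tuple[float, Spectrum]], GroundTruth]:
    """Generate one z-line scan: spectra at each depth plus ground truth.

    The ideal r(z) step/ramp profile is convolved along z with a Gaussian
    of FWHM ``psf_axial_fwhm`` (the confocal axial response) before the
    spectrum at each sampled depth is synthesized.  Substrate bands appear
    near z = 0 and lipid/protein C-H bands inside the cytosol, both with
    weights given by the same axial blurring of their occupancy profiles.
    """
    z = spec.z_grid()
    dz_fine = 0.05
    pad = max(5.0, 4.0 * spec.psf_axial_fwhm)
    z_fine = np.arange(spec.z_start - pad, spec.z_stop + pad + dz_fine, dz_fine)

    r_fine, dna_fine = _ideal_r(z_fine, spec)
    r_blur_fine = _blur(r_fine, dz_fine, spec.psf_axial_fwhm)

    cell_occ = ((z_fine > 0) & (z_fine < spec.thickness)).astype(float)
    substrate_occ = (z_fine <= 0).astype(float)
    w_cell = _blur(cell_occ, dz_fine, spec.psf_axial_fwhm)
    w_substrate = _blur(substrate_occ, dz_fine, spec.psf_axial_fwhm)

    r_ideal = np.interp(z, z_fine, r_fine)
    r_blurred = np.interp(z, z_fine, r_blur_fine)
    delta_na = np.interp(z, z_fine, dna_fine)
    wc = np.interp(z, z_fine, w_cell)
    ws = np.interp(z, z_fine, w_substrate)

    x = spec.config.grid()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    scans: list[tuple[float, Spectrum]] = []
    for i, zi in enumerate(z):
        params = [_water_band_params(r_blurred[i], spec.config)]
        extra = []
        for b in BAND_TABLE:
            if b.category == "lipid_protein":
                extra.append((wc[i] * spec.ch_area_scale * b.area,
                              b.center, b.width, b.shape_fraction))
            elif b.category == "substrate":
                extra.append((ws[i] * spec.pc_area_scale * b.area,
                              b.center, b.width, b.shape_fraction))
        params.append(np.array(extra))
        band_params = np.vstack(params)
        y = _synthesize(x, band_params, spec.config, rng, spec.noise_sd)
        labels = list(WATER_LABELS) + [b.label for b in BAND_TABLE
                                       if b.category != "water"]
        s = Spectrum(x, y, {
            "kind": "cell", "z": float(zi), "group": spec.group,
            # generating oracle: the exact areas this spectrum was built from
            "band_areas": {lbl: float(a) for lbl, (a, _, _, _)
                           in zip(labels, band_params)},
        })
        scans.append((float(zi), s))

    slope = spec.delta_na_slope if spec.group == "treated" else 0.0
    mean = spec.delta_na_mean if spec.group == "treated" else 0.0
    truth = GroundTruth(
        z=z, r_ideal=r_ideal, r_blurred=r_blurred, delta_na=delta_na,
        true_slope=slope, true_mean_delta_na=mean,
        true_thickness=spec.thickness, spec=spec,
    )
    return scans, truth


def make_cell_group(
    spec: CellScanSpec, n_cells: int = 5, seed: int | None = None
) -> tuple[list[list[tuple[float, Spectrum]]], GroundTruth]:
    """Generate ``n_cells`` independent scans of cells sharing one spec.

    Matches the experimental design of five independent cells per group.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_cells)
    cells = []
    truth = None
    for child in children:
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        scans, truth = make_cell_zscan(replace(spec, seed=cell_seed))
        cells.append(scans)
    assert truth is not None
    return cells, truth


def make_r_replicates(
    solute: str | SoluteSpec,
    r0: float = DEFAULT_R0,
    replicates: int = 20,
    r_sd: float = 0.008,
    seed: int | np.random.Generator | None = None,
    slope: float | None = None,
) -> dict[float, np.ndarray]:
    """Replicate r values drawn directly at the ratio level.

    Shortcut for statistical simulations (interaction-term type-I error,
    p-value uniformity) that would otherwise need tens of thousands of full
    spectrum fits: the spectrum-level pipeline yields unbiased r estimates
    with approximately Gaussian replicate noise, so the series is emulated
    as r = r0 + slope*c + N(0, r_sd).  ``r_sd`` defaults to the replicate
    scatter the spectrum route produces at 0.5% spectral noise.
    """
    if isinstance(solute, str):
        solute = DEFAULT_SOLUTES[solute]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    use_slope = solute.slope if slope is None else slope
    return {
        float(c): r0 + use_slope * c + rng.normal(0.0, r_sd, size=replicates)
        for c in solute.concentrations
    }
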