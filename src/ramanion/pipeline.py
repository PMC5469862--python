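"""End-to-end orchestration: spectra -> r(z) -> Delta[Na+] -> flux -> I_sc.

Two entry points are provided.  :func:`run_scan_analysis` works on
in-memory z-scans (lists of (z, Spectrum) per cell) and is what the
synthetic recovery experiments use; :func:`run_pipeline` is the file-based
variant driven by scan manifests, writing all intermediate tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import Calibration, calibrations_from_csv, fit_series
from .io import (ManifestEntry, PipelineConfig, ScanManifest, read_manifest,
                 read_spectrum, resolve_entry_path, write_manifest,
                 write_spectrum)
from .processing import r_from_spectrum
from .profile import (DeltaProfile, FluxResult, ZProfile, average_profiles,
                      delta_profile, estimate_thickness, fit_gradient,
                      mean_concentration_change, short_circuit_current,
                      sodium_flux)
from .spectrum import Spectrum
from .synthetic import CellScanSpec, make_calibration_series, make_cell_group

logger = logging.getLogger("ramanion")

__all__ = [
    "group_profile",
    "run_scan_analysis",
    "run_pipeline",
    "fit_calibration_from_series",
    "fit_nacl_calibration",
    "recovery_experiment",
    "additivity_experiment",
    "save_calibration_series",
    "save_zscan_group",
]


def _r_of(s: Spectrum, config: PipelineConfig) -> float:
    return r_from_spectrum(
        s,
        context=config.context,
        anchor_windows=config.baseline_anchors,
        normalize_target=config.normalize_target,
        center_window=config.center_window,
        width_bounds=config.width_bounds,
    ).r


def group_profile(
    cells: Sequence[Sequence[tuple[float, Spectrum]]],
    config: PipelineConfig | None = None,
) -> ZProfile:
    """Fit every spectrum of every cell and average the r(z) profiles."""
    config = config or PipelineConfig()
    per_cell = []
    for scans in cells:
        scans = sorted(scans, key=lambda zs: zs[0])
        z = np.array([zi for zi, _ in scans])
        r = np.array([_r_of(s, config) for _, s in scans])
        per_cell.append((z, r))
    return average_profiles(per_cell)


def run_scan_analysis(
    treated: ZProfile | Sequence[Sequence[tuple[float, Spectrum]]],
    control: ZProfile | Sequence[Sequence[tuple[float, Spectrum]]],
    cal_nacl: Calibration,
    config: PipelineConfig | None = None,
) -> dict:
    """Analyse a treated/control pair of cell groups.

    Accepts either ready-made :class:`ZProfile` objects or raw per-cell
    scans (which are then fitted spectrum by spectrum).  Returns a dict
    with the group profiles, estimated thickness, cytosolic difference
    profile, gradient fit and :class:`FluxResult`.
    """
    config = config or PipelineConfig()
    if not isinstance(treated, ZProfile):
        logger.info("fitting treated group (%d cells)", len(treated))
        treated = group_profile(treated, config)
    if not isinstance(control, ZProfile):
        logger.info("fitting control group (%d cells)", len(control))
        control = group_profile(control, config)

    step = float(np.median(np.diff(control.z)))
    plateau_starts = {
        "treated": estimate_thickness(treated, config.r_extracellular,
                                      config.plateau_tol),
        "control": estimate_thickness(control, config.r_extracellular,
                                      config.plateau_tol),
    }
    # The first in-plateau sample sits up to one grid step beyond the
    # apical membrane because the axial PSF smears the step; the membrane
    # is taken one step below the plateau onset (see docs/methods.md).
    thickness = max(min(plateau_starts.values()) - step, 0.0)
    logger.info("plateau onsets %s um -> thickness %.1f um",
                plateau_starts, thickness)

    dp = delta_profile(treated, control, thickness, cal_nacl,
                       alpha=config.alpha, equal_var=config.ttest_equal_var)
    if config.bh_correction:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, *_ = multipletests(dp.p_values, alpha=config.alpha,
                                          method="fdr_bh")
        dp = DeltaProfile(dp.z, dp.delta_r, dp.delta_na, p_adj, reject,
                          config.alpha)

    grad = fit_gradient(
        dp,
        z_min=config.gradient_margin_lower,
        z_max=thickness - config.gradient_margin_upper,
    )
    mean_change = mean_concentration_change(grad, thickness)
    j = sodium_flux(grad.slope, config.d_na)
    i_sc = short_circuit_current(j, config.faraday)
    flux = FluxResult(
        mean_delta_conc=mean_change,
        gradient_instrument=grad.slope,
        gradient_paper_convention=-grad.slope,
        d_na=config.d_na,
        flux=j,
        faraday=config.faraday,
        i_sc=i_sc,
        thickness=thickness,
        pearson_r=grad.pearson_r,
    )
    logger.info("gradient %.3g mM/um, mean change %.3g mM, "
                "flux %.3g mol/s/cm^2, I_sc %.3g uA/cm^2",
                grad.slope, mean_change, j, i_sc)
    return {
        "treated": treated,
        "control": control,
        "plateau_starts": plateau_starts,
        "thickness": thickness,
        "delta": dp,
        "gradient": grad,
        "flux": flux,
    }


def _load_group(manifest_path, group: str, config: PipelineConfig):
    manifest = read_manifest(manifest_path)
    cells: dict[int, list[tuple[float, Spectrum]]] = {}
    for e in manifest.entries:
        if e.group != group:
            continue
        s = read_spectrum(resolve_entry_path(manifest_path, e))
        s.metadata.update(z=e.z, group=e.group, cell=e.cell)
        cells.setdefault(e.cell, []).append((float(e.z), s))
    if not cells:
        raise ValueError(f"{manifest_path}: no entries with group {group!r}")
    return [cells[k] for k in sorted(cells)]


def run_pipeline(
    config: PipelineConfig,
    treated_manifest,
    control_manifest,
    calibration_csv,
    outdir,
) -> FluxResult:
    """File-based pipeline: manifests + calibration table -> results dir.

    Validates inputs up front (the calibration table must exist and
    contain NaCl before any spectrum is fitted), then runs the full chain
    and writes profiles.csv, delta_profile.csv and flux.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calibrations = calibrations_from_csv(calibration_csv)
    if "NaCl" not in calibrations:
        raise KeyError(f"{calibration_csv}: no NaCl calibration row")
    cal_nacl = calibrations["NaCl"]

    treated_cells = _load_group(treated_manifest, "treated", config)
    control_cells = _load_group(control_manifest, "control", config)
    result = run_scan_analysis(treated_cells, control_cells, cal_nacl, config)

    treated: ZProfile = result["treated"]
    control: ZProfile = result["control"]
    pd.DataFrame(
        {
            "z_um": treated.z,
            "r_mean_treated": treated.r_mean,
            "r_sd_treated": treated.r_sd,
            "r_mean_control": control.r_mean,
            "r_sd_control": control.r_sd,
            "n_treated": treated.n_cells,
            "n_control": control.n_cells,
        }
    ).to_csv(outdir / "profiles.csv", index=False)

    dp: DeltaProfile = result["delta"]
    pd.DataFrame(
        {
            "z_um": dp.z,
            "delta_r": dp.delta_r,
            "delta_na_mM": dp.delta_na,
            "p_value": dp.p_values,
            "significant": dp.significant,
        }
    ).to_csv(outdir / "delta_profile.csv", index=False)

    flux: FluxResult = result["flux"]
    with open(outdir / "flux.json", "w") as fh:
        json.dump(asdict(flux), fh, indent=2)
    return flux


def fit_calibration_from_series(
    series: Mapping[float, Sequence[Spectrum]],
    solute: str = "",
    unit: str = "mM",
    anchor_windows=None,
) -> Calibration:
    """Fit every spectrum of a calibration series and regress r on c."""
    from .processing import DEFAULT_ANCHORS
    anchors = anchor_windows or DEFAULT_ANCHORS
    r_by_c = {
        c: [r_from_spectrum(s, context="solution", anchor_windows=anchors).r
            for s in specs]
        for c, specs in series.items()
    }
    return fit_series(r_by_c, solute=solute, unit=unit)


def fit_nacl_calibration(seed: int | None = None,
                         replicates: int = 20) -> Calibration:
    """Generate a noisy NaCl series and fit its calibration line."""
    series = make_calibration_series("NaCl", replicates=replicates, seed=seed)
    return fit_calibration_from_series(series, solute="NaCl")


def recovery_experiment(
    seed: int | None = None,
    n_cells: int = 5,
    cal_nacl: Calibration | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """One full synthetic replication of the cell experiment.

    Generates treated and control groups of ``n_cells`` cells under the
    default scan conditions (t = 15 um, 0-30 um scan at 1 um steps, 1.14 um
    axial PSF, calibrated noise), runs the complete analysis and returns
    recovered quantities alongside the generating truth.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    if cal_nacl is None:
        cal_nacl = fit_nacl_calibration(seed=seeds[2])
    treated, truth = make_cell_group(CellScanSpec(group="treated"), n_cells,
                                     seed=seeds[0])
    control, _ = make_cell_group(CellScanSpec(group="control"), n_cells,
                                 seed=seeds[1])
    out = run_scan_analysis(treated, control, cal_nacl, config)
    flux: FluxResult = out["flux"]
    return {
        "thickness": flux.thickness,
        "gradient": out["gradient"].slope,
        "pearson": out["gradient"].pearson_r,
        "mean_delta_na": flux.mean_delta_conc,
        "flux": flux.flux,
        "i_sc": flux.i_sc,
        "true_thickness": truth.true_thickness,
        "true_gradient": truth.true_slope,
        "true_mean_delta_na": truth.true_mean_delta_na,
        "result": out,
    }


def additivity_experiment(seed: int | None = None,
                          replicates: int = 20) -> dict:
    """The buffer-additivity check in the generated world.

    Calibrates every solute of the isotonic buffer from synthetic series,
    predicts the mixture ratio additively, and compares with the ratio
    fitted from simulated buffer spectra (whose generating r follows the
    same additive model the generator uses throughout).
    """
    from .calibration import predict_mixture_r
    from .synthetic import ISOTONIC_BUFFER, buffer_r_true, make_water_spectrum

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ISOTONIC_BUFFER) + 1)
    calibrations = {}
    for (name, _), child in zip(ISOTONIC_BUFFER.items(), children):
        series = make_calibration_series(
            name, replicates=replicates,
            seed=int(child.generate_state(1)[0] % (2**31)))
        calibrations[name] = fit_calibration_from_series(series, solute=name)
    predicted = predict_mixture_r(calibrations, ISOTONIC_BUFFER)

    rng = np.random.default_rng(children[-1])
    r_true = buffer_r_true()
    measured = [
        r_from_spectrum(make_water_spectrum(r_true, seed=rng)).r
        for _ in range(replicates)
    ]
    return {
        "predicted": predicted,
        "measured_mean": float(np.mean(measured)),
        "measured_sd": float(np.std(measured, ddof=1)),
        "generating": r_true,
        "calibrations": calibrations,
    }


def save_calibration_series(
    solute: str, outdir, seed: int | None = None, replicates: int = 20,
    noise_sd: float | None = None,
) -> Path:
    """Generate and write a synthetic calibration series + manifest."""
    from .synthetic import DEFAULT_CONFIG
    from dataclasses import replace as dc_replace
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = DEFAULT_CONFIG if noise_sd is None else dc_replace(
        DEFAULT_CONFIG, noise_sd=noise_sd)
    series = make_calibration_series(solute, replicates=replicates,
                                     config=config, seed=seed)
    entries = []
    for c, specs in series.items():
        for rep, s in enumerate(specs):
            fname = f"{solute}_c{c:g}_rep{rep:02d}.csv"
            write_spectrum(s, outdir / fname)
            entries.append(ManifestEntry(file=fname, group="solution",
                                         solute=solute, concentration=c,
                                         replicate=rep))
    manifest_path = outdir / "manifest.yaml"
    write_manifest(ScanManifest(entries, {"seed": seed, "solute": solute}),
                   manifest_path)
    return manifest_path


def save_zscan_group(
    group: str, outdir, seed: int | None = None, n_cells: int = 5,
    spec: CellScanSpec | None = None,
) -> Path:
    """Generate and write a synthetic z-scan group + manifest."""
    from dataclasses import replace as dc_replace
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or CellScanSpec()
    spec = dc_replace(spec, group=group)
    cells, truth = make_cell_group(spec, n_cells=n_cells, seed=seed)
    entries = []
    for ci, scans in enumerate(cells):
        for z, s in scans:
            fname = f"{group}_cell{ci}_z{z:04.1f}.csv"
            write_spectrum(s, outdir / fname)
            entries.append(ManifestEntry(file=fname, group=group, z=z, cell=ci))
    manifest_path = outdir / "manifest.yaml"
    write_manifest(
        ScanManifest(entries, {
            "seed": seed, "group": group,
            "true_thickness_um": truth.true_thickness,
            "true_gradient_mM_per_um": truth.true_slope,
            "true_mean_delta_na_mM": truth.true_mean_delta_na,
        }),
        manifest_path,
    )
    return manifest_path
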