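"""Linear calibration of the DA/DDAA ratio against solute concentration.

Each solute series is summarised by an ordinary least-squares line
r = r0 + s*c fitted to all replicate measurements.  Slopes of two solutes
are compared through the interaction term of the pooled model
r ~ c + group + c:group (the classical ANCOVA slope test).  Mixture ratios
are predicted additively — shared intercept plus the sum of per-solute
slope*concentration contributions — and measured Delta r values are
inverted to concentration changes through the relevant slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Calibration",
    "SlopeComparison",
    "fit_series",
    "compare_slopes",
    "predict_mixture_r",
    "delta_r_to_concentration",
    "anion_axis",
    "calibrations_to_csv",
    "calibrations_from_csv",
]


@dataclass(frozen=True)
class Calibration:
    """One solute's fitted line r = intercept + slope * concentration."""

    solute: str
    slope: float              # Delta r per mM (per mg/mL for protein)
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_points: int             # replicate measurements used
    n_concentrations: int
    unit: str = "mM"

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA interaction-term comparison of two calibration slopes."""

    pair: tuple[str, str]
    delta_slope: float
    delta_slope_se: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _as_arrays(series: Mapping[float, Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    cs, rs = [], []
    for c, reps in series.items():
        reps = np.asarray(list(reps), dtype=float)
        if reps.size == 0:
            raise ValueError(f"no replicates at concentration {c}")
        cs.append(np.full(reps.size, float(c)))
        rs.append(reps)
    if not cs:
        raise ValueError("empty series")
    return np.concatenate(cs), np.concatenate(rs)


def fit_series(
    series: Mapping[float, Sequence[float]],
    solute: str = "",
    unit: str = "mM",
) -> Calibration:
    """OLS fit of all replicate r values on concentration.

    The regression uses every replicate (not per-concentration means), so
    the slope standard error reflects the full n = concentrations x
    replicates design.
    """
    c, r = _as_arrays(series)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations to fit a line")
    X = sm.add_constant(c)
    fit = sm.OLS(r, X).fit()
    return Calibration(
        solute=solute,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        r_squared=float(fit.rsquared),
        n_points=int(c.size),
        n_concentrations=int(np.unique(c).size),
        unit=unit,
    )


def compare_slopes(
    a: Mapping[float, Sequence[float]],
    b: Mapping[float, Sequence[float]],
    labels: tuple[str, str] = ("a", "b"),
) -> SlopeComparison:
    """Test whether two series have different slopes.

    Fits the pooled model r ~ c + group + c:group and returns the
    concentration-by-group interaction coefficient with its two-sided
    p-value — the same test as validating a slope difference through the
    interaction term in a linear regression package.
    """
    ca, ra = _as_arrays(a)
    cb, rb = _as_arrays(b)
    if np.unique(ca).size < 2 or np.unique(cb).size < 2:
        raise ValueError("each series needs >= 2 distinct concentrations")
    c = np.concatenate([ca, cb])
    r = np.concatenate([ra, rb])
    g = np.concatenate([np.zeros(ca.size), np.ones(cb.size)])
    X = np.column_stack([np.ones(c.size), c, g, c * g])
    fit = sm.OLS(r, X).fit()
    return SlopeComparison(
        pair=labels,
        delta_slope=float(fit.params[3]),
        delta_slope_se=float(fit.bse[3]),
        p_value=float(min(max(fit.pvalues[3], 0.0), 1.0)),
    )


def predict_mixture_r(
    calibrations: Mapping[str, Calibration],
    composition: Mapping[str, float],
) -> float:
    """Additive mixture prediction r = mean intercept + sum(slope_i * c_i).

    Naively summing the per-component r values would count the pure-water
    contribution once per solute, so the additivity rule used here shares
    a single intercept (the mean across the calibrations involved) and
    sums only the concentration-driven contributions.
    """
    for name, conc in composition.items():
        if name not in calibrations:
            raise KeyError(f"no calibration for buffer solute {name!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
    used = list(composition) if composition else list(calibrations)
    if not used:
        raise ValueError("no calibrations supplied")
    r0_bar = float(np.mean([calibrations[name].intercept for name in used]))
    return r0_bar + sum(
        calibrations[name].slope * conc for name, conc in composition.items()
    )


def delta_r_to_concentration(delta_r: float, cal: Calibration) -> float:
    """Invert a ratio change to a concentration change (mM).

    The intercept cancels in differences, so Delta c = Delta r / slope.
    """
    if cal.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    return float(delta_r) / cal.slope


def anion_axis(
    series: Mapping[float, Sequence[float]], anions_per_formula: int
) -> dict[float, Sequence[float]]:
    """Re-express a series with concentration counted per Cl- rather than
    per formula unit (e.g. x2 for MgCl2/CaCl2), for slope comparisons at
    equal anion concentration."""
    return {float(c) * anions_per_formula: reps for c, reps in series.items()}


def calibrations_to_csv(calibrations: Mapping[str, Calibration], path) -> None:
    rows = [
        {
            "solute": cal.solute or name,
            "slope": cal.slope,
            "intercept": cal.intercept,
            "slope_se": cal.slope_se,
            "intercept_se": cal.intercept_se,
            "r_squared": cal.r_squared,
            "n_points": cal.n_points,
            "n_concentrations": cal.n_concentrations,
            "unit": cal.unit,
        }
        for name, cal in calibrations.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def calibrations_from_csv(path) -> dict[str, Calibration]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration table not found: {path}")
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.solute] = Calibration(
            solute=row.solute,
            slope=float(row.slope),
            intercept=float(row.intercept),
            slope_se=float(row.slope_se),
            intercept_se=float(row.intercept_se),
            r_squared=float(row.r_squared),
            n_points=int(row.n_points),
            n_concentrations=int(row.n_concentrations),
            unit=str(row.unit),
        )
    return out
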