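"""Plain-text readers/writers, scan manifests and pipeline configuration.

Spectra travel as two-column text/CSV files (wavenumber cm^-1, intensity);
datasets are described by YAML manifests listing, per file, the depth z,
group label, solute, concentration and replicate id, plus global metadata
such as the generating seed.  Everything round-trips losslessly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .spectrum import Spectrum

__all__ = [
    "ManifestEntry",
    "ScanManifest",
    "PipelineConfig",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]

GROUP_VOCABULARY = {"control", "treated", "solution", "buffer"}

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_spectrum(path, min_points: int = 50) -> Spectrum:
    """Read a two-column text/CSV spectrum (optional single header line).

    Values may be separated by commas, whitespace or tabs.  Wavenumbers
    are re-sorted ascending with a warning if the file is not already
    sorted; duplicate wavenumbers and non-numeric rows are errors that
    name the offending line.
    """
    path = Path(path)
    wn, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in re.split(r"[,\s;]+", line) if t]
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            if not (_FLOAT_RE.match(tokens[0]) and _FLOAT_RE.match(tokens[1])):
                if lineno == 1 and not wn:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}")
            wn.append(float(tokens[0]))
            inten.append(float(tokens[1]))
    if len(wn) < min_points:
        raise ValueError(
            f"{path}: only {len(wn)} data points; need at least {min_points}"
        )
    w = np.asarray(wn)
    y = np.asarray(inten)
    if np.unique(w).size != w.size:
        raise ValueError(f"{path}: duplicate wavenumbers present")
    if not np.all(np.diff(w) > 0):
        warnings.warn(f"{path}: wavenumbers not ascending; re-sorting", UserWarning)
        order = np.argsort(w)
        w, y = w[order], y[order]
    return Spectrum(w, y, {"source": str(path)})


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV with a header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([s.wavenumbers, s.intensities])
    np.savetxt(path, data, fmt="%.10g", delimiter=",",
               header="wavenumber_cm-1,intensity", comments="")


@dataclass(frozen=True)
class ManifestEntry:
    """One spectrum file and its acquisition context."""

    file: str
    group: str
    z: float | None = None
    solute: str | None = None
    concentration: float | None = None
    replicate: int = 0
    cell: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_VOCABULARY:
            raise ValueError(
                f"group {self.group!r} not in {sorted(GROUP_VOCABULARY)}"
            )
        if self.z is not None and self.z < 0:
            raise ValueError(f"negative z position {self.z}")


@dataclass
class ScanManifest:
    """A list of spectrum files plus global dataset metadata."""

    entries: list[ManifestEntry]
    metadata: dict[str, Any] = field(default_factory=dict)

    def files(self) -> list[str]:
        return [e.file for e in self.entries]


def write_manifest(manifest: ScanManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "metadata": manifest.metadata,
        "entries": [
            {k: v for k, v in asdict(e).items() if v is not None}
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path, check_files: bool = True) -> ScanManifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with an 'entries' list")
    entries = [ManifestEntry(**e) for e in doc["entries"]]
    if check_files:
        base = path.parent
        for e in entries:
            f = Path(e.file)
            if not f.is_absolute():
                f = base / f
            if not f.exists():
                raise FileNotFoundError(f"{path}: listed spectrum missing: {e.file}")
    return ScanManifest(entries, doc.get("metadata") or {})


def resolve_entry_path(manifest_path, entry: ManifestEntry) -> Path:
    """Entry paths are interpreted relative to the manifest's directory."""
    f = Path(entry.file)
    return f if f.is_absolute() else Path(manifest_path).parent / f


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis, serialisable to YAML.

    Defaults encode the measurement conventions: 2400-4200 cm^-1 fit
    window, baseline anchors in the band-free tails, spectrum integral
    normalised to 100, 1% plateau tolerance for the thickness estimate,
    Student's unpaired t-test per depth, D_Na = 1.33e-8 cm^2/s and
    F = 96485.332 C/mol.
    """

    fit_window: tuple[float, float] = (2400.0, 4200.0)
    baseline_anchors: tuple[tuple[float, float], ...] = (
        (2400.0, 2500.0),
        (4100.0, 4200.0),
    )
    normalize_target: float = 100.0
    context: str = "cell"
    center_window: float = 30.0
    width_bounds: tuple[float, float] = (20.0, 400.0)
    plateau_tol: float = 0.01
    r_extracellular: float = 1.363
    ttest_equal_var: bool = True
    alpha: float = 0.05
    bh_correction: bool = False
    gradient_margin_lower: float = 1.0   # um excluded above the support
    gradient_margin_upper: float = 1.0   # um excluded below the apical membrane
    d_na: float = 1.33e-8
    faraday: float = 96485.332
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("normalize_target", "plateau_tol", "d_na", "faraday",
                     "r_extracellular"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["fit_window"] = list(self.fit_window)
        doc["baseline_anchors"] = [list(w) for w in self.baseline_anchors]
        doc["width_bounds"] = list(self.width_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["fit_window"] = tuple(doc["fit_window"])
        doc["baseline_anchors"] = tuple(tuple(w) for w in doc["baseline_anchors"])
        doc["width_bounds"] = tuple(doc["width_bounds"])
        return cls(**doc)
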