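"""Plain-text file formats: spectrum CSV, series manifest JSON, reports.

Spectrum files are two-column CSV (``field_G,intensity``, 6 significant
digits) with ``#`` comment lines carrying metadata.  A titration series is
described by a JSON manifest ``{guest_total_mM, points: [{host_total_mM,
file}]}``; user-facing concentrations are mM, converted to mol/L on load.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .globalfit import TitrationPoint, TitrationSeries
from .lineshape import Spectrum

__all__ = [
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "ManifestModel",
    "read_manifest",
    "write_series",
    "write_report",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files, with the offending line number."""


def write_spectrum(spectrum: Spectrum, path: Union[str, Path]) -> None:
    """Write a spectrum as two-column CSV; metadata becomes '#' comments."""
    lines = []
    for key, value in spectrum.meta.items():
        if isinstance(value, (str, int, float)):
            lines.append(f"# {key}: {value}")
    lines.append("field_G,intensity")
    # field needs ~10 digits: at X-band (3500 G) six significant digits
    # would quantize the axis to 0.01 G and break sub-milligauss round-trips
    for b, i in zip(spectrum.field, spectrum.intensity):
        lines.append(f"{b:.10g},{i:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: Union[str, Path]) -> Spectrum:
    """Read a spectrum CSV; '#' comment lines are parsed back as metadata."""
    path = Path(path)
    meta: dict = {}
    fields: list[float] = []
    intensities: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if line.replace(" ", "") != "field_G,intensity":
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected header 'field_G,intensity', "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected 2 comma-separated values, got {line!r}"
            )
        try:
            fields.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from None
    if not header_seen:
        raise SpectrumFormatError(f"{path}: missing 'field_G,intensity' header")
    if not fields:
        raise SpectrumFormatError(f"{path}: header present but no data rows")
    field = np.array(fields)
    if not np.all(np.diff(field) > 0):
        raise SpectrumFormatError(
            f"{path}: field axis is not strictly increasing"
        )
    return Spectrum(field, np.array(intensities), meta)


class ManifestPoint(BaseModel):
    model_config = ConfigDict(extra="forbid")
    host_total_mM: float = Field(ge=0)
    file: str


class ManifestModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    guest_total_mM: float = Field(gt=0)
    points: list[ManifestPoint] = Field(min_length=1)


def read_manifest(path: Union[str, Path]) -> TitrationSeries:
    """Load a titration series from a manifest and its spectrum files.

    Spectra are resampled to the first spectrum's grid; duplicate host
    totals are kept with a warning; a missing spectrum file raises an
    error naming it.
    """
    path = Path(path)
    manifest = ManifestModel.model_validate_json(path.read_text())
    hosts = [p.host_total_mM for p in manifest.points]
    if len(set(hosts)) < len(hosts):
        warnings.warn("manifest contains duplicate host totals; keeping all",
                      stacklevel=2)
    points = []
    for p in manifest.points:
        spec_path = (path.parent / p.file) if not Path(p.file).is_absolute() else Path(p.file)
        if not spec_path.exists():
            raise FileNotFoundError(f"spectrum file not found: {spec_path}")
        spectrum = read_spectrum(spec_path)
        points.append(TitrationPoint(host_total=p.host_total_mM * 1e-3, spectrum=spectrum))
    series = TitrationSeries(
        guest_total=manifest.guest_total_mM * 1e-3,
        points=points,
        meta={"manifest": str(path)},
    )
    return series


def write_series(series: TitrationSeries, outdir: Union[str, Path],
                 prefix: str = "spectrum") -> Path:
    """Write all spectra plus a manifest JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, point in enumerate(series.points):
        fname = f"{prefix}_{i:03d}.csv"
        write_spectrum(point.spectrum, outdir / fname)
        entries.append({"host_total_mM": point.host_total * 1e3, "file": fname})
    manifest = {"guest_total_mM": series.guest_total * 1e3, "points": entries}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def write_report(path: Union[str, Path], payload: dict) -> None:
    """Write a self-contained JSON report (config, seed, version, results)."""
    from . import __version__

    doc = {"eprbind_version": __version__, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    return str(obj)
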