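"""File I/O, configuration loading, and run reporting.

Conventions: pixel indices are 0-based with x right and y down, matching
image-array order; CSV output is comma-separated UTF-8 with a mandatory
header row and "." decimal separator.  Readers never silently coerce —
every repair (m/z sorting, dropped pixels) is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .hyperspectral import HyperspectralImage, LcoPipelineConfig, LcoResult
from .msi import MSIDataset, MsiQuantConfig

log = logging.getLogger(__name__)

__all__ = [
    "read_hyperspectral",
    "write_hyperspectral",
    "read_msi",
    "write_msi_imzml",
    "write_report",
    "RunConfig",
    "load_run_config",
]


# ---------------------------------------------------------------------------
# hyperspectral stacks: multi-page TIFF + wavelength sidecar JSON
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".wavelengths.json")


def write_hyperspectral(image: HyperspectralImage, path: str | Path) -> Path:
    """Write a channels-as-pages TIFF stack plus a wavelength sidecar JSON."""
    path = Path(path)
    pages = np.moveaxis(image.cube, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "wavelengths_nm": [float(w) for w in image.wavelengths],
        "pixel_size_nm": image.pixel_size_nm,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_hyperspectral(
    path: str | Path, wavelengths: np.ndarray | str | Path | None = None
) -> HyperspectralImage:
    """Read a multi-page TIFF stack with its wavelength axis.

    ``wavelengths`` may be an explicit array or a sidecar JSON path; by
    default the ``<stem>.wavelengths.json`` sidecar next to the stack is
    used.  A channel/wavelength count mismatch is an error; a non-32-channel
    stack loads with a warning.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    cube = np.moveaxis(pages, 0, 2).astype(float)
    pixel_size = None
    if wavelengths is None:
        wavelengths = _sidecar_path(path)
    if isinstance(wavelengths, (str, Path)):
        sidecar = json.loads(Path(wavelengths).read_text())
        pixel_size = sidecar.get("pixel_size_nm")
        wavelengths = np.asarray(sidecar["wavelengths_nm"], dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != cube.shape[2]:
        raise ValueError(
            f"{cube.shape[2]} channel page(s) but {wavelengths.size} wavelength(s)"
        )
    return HyperspectralImage(cube, wavelengths, pixel_size_nm=pixel_size)


# ---------------------------------------------------------------------------
# MSI datasets: imzML (processed mode)
# ---------------------------------------------------------------------------


def write_msi_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write per-pixel centroid spectra as processed-mode imzML (+ .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path), mode="processed") as writer:
        for (x, y), m, inten in zip(dataset.coords, dataset.mzs, dataset.intensities):
            # imzML coordinates are 1-based
            writer.addSpectrum(m, inten, (int(x) + 1, int(y) + 1))
    return path


def read_msi(path: str | Path) -> MSIDataset:
    """Read an imzML dataset into per-pixel centroid spectra.

    m/z axes are sorted ascending on read if needed (logged); duplicate
    coordinates or an empty pixel list are errors.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords, mzs, intens = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        m, inten = parser.getspectrum(i)
        coords.append((int(x) - 1, int(y) - 1))
        mzs.append(np.asarray(m, dtype=float))
        intens.append(np.asarray(inten, dtype=float))
    if not coords:
        raise ValueError(f"{path}: empty pixel list")
    return MSIDataset(np.asarray(coords), mzs, intens)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def _dataclass_from_dict(cls, data: dict[str, Any]):
    """Build a dataclass, rejecting unknown keys loudly."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass
class RunConfig:
    """Umbrella configuration: sub-configs, global seed, output, verbosity."""

    lco: LcoPipelineConfig = dataclasses.field(default_factory=LcoPipelineConfig)
    msi: MsiQuantConfig = dataclasses.field(default_factory=MsiQuantConfig)
    seed: int = 0
    outdir: str = "vesselmap_out"
    verbose: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a mapping")
    known = {"lco", "msi", "seed", "outdir", "verbose"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown RunConfig key(s): {sorted(unknown)}")
    lco = _dataclass_from_dict(LcoPipelineConfig, raw.get("lco", {}) or {})
    if "ratio_wavelengths" in (raw.get("lco") or {}):
        lco.ratio_wavelengths = tuple(lco.ratio_wavelengths)  # YAML lists -> tuple
    msi = _dataclass_from_dict(MsiQuantConfig, raw.get("msi", {}) or {})
    return RunConfig(
        lco=lco,
        msi=msi,
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "vesselmap_out")),
        verbose=bool(raw.get("verbose", False)),
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def write_report(results: dict[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Write CSV tables, arrays and a JSON run manifest to ``outdir``.

    ``results`` maps names to pandas DataFrames (written as CSV), numpy
    arrays (written as TIFF for 2D/3D, CSV for 1D) or JSON-serialisable
    scalars/dicts (collected into the manifest).  Two runs with the same
    manifest produce identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest: dict[str, Any] = {"tables": [], "images": []}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=False)
            manifest["tables"].append(p.name)
            written[name] = p
        elif isinstance(obj, np.ndarray) and obj.ndim in (2, 3):
            p = outdir / f"{name}.tiff"
            tifffile.imwrite(p, obj.astype(np.float32))
            manifest["images"].append(p.name)
            written[name] = p
        elif isinstance(obj, np.ndarray):
            p = outdir / f"{name}.csv"
            pd.DataFrame({name: obj}).to_csv(p, index=False)
            manifest["tables"].append(p.name)
            written[name] = p
        else:
            manifest[name] = obj
    import vesselmap

    manifest["version"] = vesselmap.__version__
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1, default=str))
    written["manifest"] = p
    return written


def lco_result_tables(result: LcoResult, wavelengths: np.ndarray) -> dict[str, pd.DataFrame]:
    """Per-ROI summary and spectra tables for a finished LCO run."""
    rows = [
        {
            "label": s.label,
            "pixel_count": s.pixel_count,
            "centroid_y": s.centroid[0],
            "centroid_x": s.centroid[1],
            "ratio_500_580": s.ratio_500_580,
        }
        for s in result.summaries
    ]
    summary = pd.DataFrame(rows)
    spectra = pd.DataFrame(
        [r.mean_spectrum for r in result.rois],
        columns=[f"{w:.1f}nm" for w in wavelengths],
    )
    if not spectra.empty:
        spectra.insert(0, "label", [r.label for r in result.rois])
    return {"roi_summary": summary, "roi_spectra": spectra}
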