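"""Readers, writers, and the end-to-end pipeline runner.

Volumes come in as multi-page TIFF stacks or directories of numbered 2D
TIFF slices (8- or 16-bit grayscale); results go out as tidy CSV tables,
per-fraction trend CSVs, and a JSON run manifest listing every output file
with a checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ontogeny import run_cohort_analysis
from .section import CrossSectionImage, section_geometry
from .volume import (
    AlignedBone,
    VoxelVolume,
    binarize_volume,
    extract_section,
    standardize,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "specimen_id", "fraction",
    "TA_mm2", "CA_mm2", "MA_mm2", "CPA_mm2",
    "Ix_mm4", "Iy_mm4", "Ixy_mm4", "Imax_mm4", "Imin_mm4", "theta_deg",
    "imax_imin_ratio", "ix_iy_ratio", "medullary_index", "porosity_index",
    "length_mm", "threshold",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    stacks: dict  # specimen_id -> path to TIFF stack or slice directory
    voxel_size_mm: dict | float
    output_dir: Path
    metadata_csv: Path | None = None
    fractions: tuple = (0.35, 0.5, 0.65)
    threshold: str | float = "auto"
    sides: dict = field(default_factory=dict)  # specimen_id -> "R"/"L"
    distal: dict = field(default_factory=dict)  # specimen_id -> "auto"/"low"/"high"
    crop: dict = field(default_factory=dict)  # specimen_id -> (z0, z1) slice range
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for f in self.fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"fraction {f} outside (0, 1)")


# ---------------------------------------------------------------------------
# readers / writers


def read_stack(path, voxel_size_mm: float, provenance: str = "") -> VoxelVolume:
    """Read a multi-page TIFF or a directory of numbered 2D TIFF slices."""
    path = Path(path)
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        planes = [tifffile.imread(p) for p in slices]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(planes)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected grayscale slices, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: expected 8- or 16-bit grayscale, got {data.dtype}")
    return VoxelVolume(data, voxel_size_mm, provenance=provenance or path.name)


def write_volume(volume: VoxelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(volume.intensities))
    return path


def read_section_tiff(path, pixel_size_mm: float) -> CrossSectionImage:
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale 2D image")
    return CrossSectionImage(data, pixel_size_mm, provenance=Path(path).name)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write each named table as CSV; returns {relative name: sha256}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        checksums[path.name] = _sha256(path)
    return checksums


# ---------------------------------------------------------------------------
# pipeline


def analyse_volume(
    volume: VoxelVolume,
    fractions=(0.35, 0.5, 0.65),
    threshold="auto",
    side: str = "R",
    distal: str = "auto",
    crop: tuple | None = None,
    specimen_id: str = "",
) -> tuple[AlignedBone, list[dict]]:
    """Binarize -> align -> orient -> slice -> per-section geometry."""
    data = np.asarray(volume.intensities)
    if crop is not None:
        data = data[slice(*crop)]
        volume = VoxelVolume(data, volume.voxel_size_mm, volume.provenance)
    binary = binarize_volume(volume, threshold)
    background = float(np.min(data))
    oriented = standardize(
        binary, volume.voxel_size_mm, gray=data, distal=distal, side=side,
        background=background, provenance=specimen_id or volume.provenance,
    )
    rows = []
    for frac in fractions:
        sec = extract_section(oriented, frac)
        geom = section_geometry(sec, threshold=threshold)
        row = {"specimen_id": specimen_id or volume.provenance, "fraction": frac}
        row.update(geom.as_dict())
        row["length_mm"] = oriented.length_mm
        row["threshold"] = geom.threshold
        rows.append(row)
    return oriented, rows


def run_pipeline(config: RunConfig) -> Path:
    """Run the full per-specimen pipeline and, when metadata is present,
    the cohort analysis; returns the path to the JSON run manifest.

    Per-specimen failures are logged and recorded in the manifest; the
    manifest's ``failed`` list is non-empty in that case and the caller is
    expected to exit non-zero.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, failed, warnings = [], [], []
    for sid, stack in config.stacks.items():
        try:
            vx = (
                config.voxel_size_mm[sid]
                if isinstance(config.voxel_size_mm, dict)
                else config.voxel_size_mm
            )
            volume = read_stack(stack, vx, provenance=sid)
            _, specimen_rows = analyse_volume(
                volume,
                fractions=config.fractions,
                threshold=config.threshold,
                side=config.sides.get(sid, "R"),
                distal=config.distal.get(sid, "auto"),
                crop=config.crop.get(sid),
                specimen_id=sid,
            )
            rows.extend(specimen_rows)
        except Exception as exc:  # noqa: BLE001 — per-specimen isolation
            logger.error("[%s] failed: %s", sid, exc)
            failed.append({"specimen_id": sid, "error": str(exc)})

    tables: dict[str, pd.DataFrame] = {}
    if rows:
        results = pd.DataFrame(rows)[RESULT_COLUMNS]
        tables["sections"] = results
        if config.metadata_csv is not None:
            metadata = pd.read_csv(config.metadata_csv)
            try:
                cohort = run_cohort_analysis(metadata, results, fractions=config.fractions)
                tables["cohort"] = cohort.table
                for (frac, param), fit in cohort.trends.items():
                    tables[f"trend_{param}_{int(round(frac * 100))}"] = pd.DataFrame(
                        {"age_years": fit.grid, "fitted": fit.fitted,
                         "ci_half_width": fit.ci_half_width}
                    )
            except ValueError as exc:
                warnings.append(str(exc))
                logger.warning("cohort analysis skipped: %s", exc)

    checksums = write_results(tables, out_dir)
    manifest = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "stacks"
        },
        "stacks": {k: str(v) for k, v in config.stacks.items()},
        "seed": config.seed,
        "outputs": checksums,
        "failed": failed,
        "warnings": warnings,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
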