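"""Readers, writers, run configuration and the quantification pipeline.

Formats
-------
Contours travel as JSON::

    {"rv_insertion_angle_rad": 0.0,
     "slices": [{"z_index": 0, "slice_span_mm": 10.0,
                 "pixel_spacing_mm": [1.0, 1.0], "grid_shape": [64, 64],
                 "endo": [[x, y], ...], "epi": [[x, y], ...]}, ...]}

or as a flat CSV dialect with columns ``slice, boundary, vertex_index, x_mm,
y_mm`` (grid metadata supplied separately).  Masks are NIfTI volumes
(rows x cols x slices), multi-page TIFF, or a directory of plain-text
matrices (``mask_000.txt`` ...); nonzero = scar.

Output CSV columns are stable:
``segments.csv``: patient_id, segment_id, stab, stlb, wit, smst, has_scar.
``summary.csv``: patient_id, percent_scar, scar_mass_g, lv_mass_g, then per
method the four quartile counts and total, then cap_has_scar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import InputError
from .geometry import ContourStack, MyocardiumMask, SliceGeometry
from .metrics import (DEFAULT_N_CHORDS, DEFAULT_N_SAMPLES, METHODS,
                      PatientScarSummary, ScarRaster, summarize_patient)

log = logging.getLogger("scarq")


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def stack_to_dict(stack: ContourStack) -> dict:
    return {
        "rv_insertion_angle_rad": stack.rv_insertion_angle,
        "slices": [{
            "z_index": s.z_index,
            "slice_span_mm": s.slice_span,
            "pixel_spacing_mm": list(s.pixel_spacing),
            "grid_shape": list(s.grid_shape),
            "endo": s.endo.tolist(),
            "epi": s.epi.tolist(),
        } for s in stack.slices],
    }


def write_contours_json(stack: ContourStack, path) -> None:
    Path(path).write_text(json.dumps(stack_to_dict(stack)))


def read_contours_json(path) -> ContourStack:
    text = Path(path).read_text()
    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise InputError(f"{path}: malformed JSON at byte offset {e.pos}: {e.msg}") from e
    try:
        slices = [
            SliceGeometry(
                z_index=int(s["z_index"]),
                endo=np.asarray(s["endo"], dtype=float),
                epi=np.asarray(s["epi"], dtype=float),
                pixel_spacing=tuple(float(v) for v in s["pixel_spacing_mm"]),
                slice_span=float(s["slice_span_mm"]),
                grid_shape=tuple(int(v) for v in s["grid_shape"]),
            )
            for s in d["slices"]
        ]
        return ContourStack(slices, rv_insertion_angle=float(d["rv_insertion_angle_rad"]))
    except KeyError as e:
        raise InputError(f"{path}: missing contour field {e}") from e


def write_contours_csv(stack: ContourStack, path) -> None:
    rows = []
    for s in stack.slices:
        for boundary, ring in (("endo", s.endo), ("epi", s.epi)):
            for i, (x, y) in enumerate(ring):
                rows.append((s.z_index, boundary, i, x, y))
    pd.DataFrame(rows, columns=["slice", "boundary", "vertex_index", "x_mm", "y_mm"]) \
        .to_csv(path, index=False)


def read_contours_csv(path, pixel_spacing, slice_span, grid_shape,
                      rv_insertion_angle: float = 0.0) -> ContourStack:
    """Read the flat CSV contour dialect; grid metadata is supplied by the caller."""
    df = pd.read_csv(path)
    required = {"slice", "boundary", "vertex_index", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: contour CSV needs columns {sorted(required)}")
    slices = []
    for z, g in df.sort_values(["slice", "boundary", "vertex_index"]).groupby("slice"):
        rings = {}
        for boundary, gg in g.groupby("boundary"):
            rings[boundary] = gg[["x_mm", "y_mm"]].to_numpy()
        if "endo" not in rings or "epi" not in rings:
            raise InputError(f"{path}: slice {z} lacks an endo or epi contour")
        slices.append(SliceGeometry(int(z), rings["endo"], rings["epi"],
                                    tuple(pixel_spacing), float(slice_span),
                                    tuple(grid_shape)))
    return ContourStack(slices, rv_insertion_angle=rv_insertion_angle)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(path, grids: list[np.ndarray]) -> None:
    """Write per-slice grids as NIfTI (.nii/.nii.gz), TIFF (.tif) or text directory."""
    path = Path(path)
    vol = np.stack([np.asarray(g) for g in grids], axis=-1)
    if path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.moveaxis(vol, -1, 0).astype(np.float32))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, g in enumerate(grids):
            np.savetxt(path / f"mask_{i:03d}.txt", np.asarray(g, dtype=float), fmt="%.6g")


def read_mask(path) -> list[np.ndarray]:
    """Read per-slice grids from NIfTI, multi-page TIFF or a text directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    if path.is_dir():
        files = sorted(path.glob("mask_*.txt"))
        if not files:
            raise InputError(f"{path}: no mask_*.txt files found")
        return [np.atleast_2d(np.loadtxt(f)) for f in files]
    if path.suffix in (".nii", ".gz"):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            vol = vol[..., None]
        return [vol[..., i] for i in range(vol.shape[-1])]
    if path.suffix in (".tif", ".tiff"):
        vol = tifffile.imread(str(path))
        if vol.ndim == 2:
            vol = vol[None, ...]
        return [vol[i] for i in range(vol.shape[0])]
    raise InputError(f"{path}: unsupported mask format {path.suffix!r}")


def load_case(contours_path, mask_path, intensity_path=None,
              remote_intensity: float | None = None,
              core_intensity: float | None = None) -> tuple[ContourStack, ScarRaster]:
    """Load and co-register a contour stack and scar raster (clipping with a log)."""
    contours_path = Path(contours_path)
    if not contours_path.exists():
        raise FileNotFoundError(f"contours not found: {contours_path}")
    stack = read_contours_json(contours_path)
    grids = read_mask(mask_path)
    if len(grids) != len(stack):
        raise InputError(
            f"{mask_path}: {len(grids)} mask slices but {len(stack)} contour slices")
    for s, g in zip(stack.slices, grids):
        if tuple(g.shape) != tuple(s.grid_shape):
            raise InputError(
                f"slice {s.z_index}: mask shape {g.shape} != grid_shape {s.grid_shape}")
    myo = MyocardiumMask.from_stack(stack)
    kw = {}
    if intensity_path is not None:
        inten = read_mask(intensity_path)
        kw = {"intensity": inten, "remote_intensity": remote_intensity,
              "core_intensity": core_intensity}
    raster = ScarRaster.from_masks([g > 0 for g in grids], myo=myo, **kw)
    if raster.clipped_pixels:
        log.warning("%d scar pixels outside the myocardium were clipped",
                    raster.clipped_pixels)
    return stack, raster


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of one quantification run."""

    contours: str
    mask: str
    out_dir: str
    patient_id: str = "case"
    intensity: str | None = None
    remote_intensity: float | None = None
    core_intensity: float | None = None
    n_chords: int = DEFAULT_N_CHORDS
    n_samples: int = DEFAULT_N_SAMPLES
    min_scar_area_mm2: float = 0.0
    weighted_stlb: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.n_chords < 8 or self.n_samples < 1:
            raise InputError("n_chords must be >= 8 and n_samples >= 1")
        if self.min_scar_area_mm2 < 0:
            raise InputError("min_scar_area_mm2 must be nonnegative")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def summary_row(summary: PatientScarSummary, patient_id: str) -> dict:
    row = {
        "patient_id": patient_id,
        "percent_scar": summary.percent_scar,
        "scar_mass_g": summary.scar_mass,
        "lv_mass_g": summary.lv_mass,
    }
    for m in METHODS:
        p = summary.profiles[m]
        for i, b in enumerate(p.bins, start=1):
            row[f"{m}_q{i}"] = b
        row[f"{m}_total"] = p.total
    row["cap_has_scar"] = summary.cap_has_scar
    return row


def run_quantify(config: RunConfig) -> PatientScarSummary:
    """Run the full pipeline and write segments.csv, summary.csv/json, provenance.json.

    Partial outputs are removed if any stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stack, scar = load_case(config.contours, config.mask,
                                intensity_path=config.intensity,
                                remote_intensity=config.remote_intensity,
                                core_intensity=config.core_intensity)
        summary = summarize_patient(stack, scar, n_chords=config.n_chords,
                                    n_samples=config.n_samples,
                                    min_scar_area_mm2=config.min_scar_area_mm2,
                                    weighted_stlb=config.weighted_stlb)
        seg_path = out / "segments.csv"
        summary.segment_table(config.patient_id).to_csv(
            seg_path, index=False, float_format="%.6f")
        written.append(seg_path)

        sum_csv = out / "summary.csv"
        pd.DataFrame([summary_row(summary, config.patient_id)]).to_csv(
            sum_csv, index=False, float_format="%.6f")
        written.append(sum_csv)

        sum_json = out / "summary.json"
        sum_json.write_text(json.dumps(summary.to_dict(), indent=2))
        written.append(sum_json)

        prov = out / "provenance.json"
        prov.write_text(json.dumps({
            "config": config.to_dict(),
            "config_sha256": config.sha256(),
            "scarq_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
        }, indent=2))
        written.append(prov)
        return summary
    except Exception:
        for p in written:
            try:
                os.unlink(p)
            except OSError:
                pass
        raise
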