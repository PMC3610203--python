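"""Scar burden and per-segment transmurality metrics.

Global burden
-------------
``percent_scar`` is the hyperenhanced (scar) volume as a percentage of total
LV myocardial volume, volume-weighted across slices; ``scar_mass`` multiplies
it by LV mass.

Per-segment transmurality
-------------------------
Four estimators are computed per AHA segment (1-16):

STAB
    "scar transmurality, area based": scar area / myocardial area in the
    segment, pooled over the segment's slices.
STLB
    "scar transmurality, line based": radial chords are cast from the
    endocardial centroid; the segment value is the thickness-weighted mean
    radial scar extent, sum(scar length) / sum(wall length) over its chords.
WIT
    "weighted infarct transmurality": scar mass fraction of the segment with
    per-pixel weights from a linear intensity ramp between remote and core
    calibration intensities (partial-volume accounting); with no intensity
    channel the weights are 1 and WIT is the plain segment scar-mass fraction.
SMST
    "spatial maximal scar transmurality": the maximum chord transmurality in
    the sector.  Because a maximum amplifies raster quantization noise, SMST
    is read from a regularized angular transmurality profile (edge-preserving
    iterated bilateral filter plus a reprojection correction that cancels the
    predictable pixelation moire); it is clamped from below by STLB, since a
    maximum can never be smaller than a weighted mean.

Chord sampling uses area-consistent bilinear interpolation of the binary
masks (each mask value extended outside the myocardium by nearest myocardial
pixel), which keeps the chord estimates unbiased at the endo/epi raster edges.

Quartile binning follows the clinical convention: bins 1-24 / 25-49 / 50-74 /
>= 75 percent, with >= 75 % defined as transmural; values in (0, 1) round into
the first bin so that bin counts always sum to the number of scarred segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry as geo
from .errors import CalibrationError, GeometryError
from .geometry import AHAModel, ContourStack, MyocardiumMask, SliceGeometry

METHODS = ("stab", "stlb", "wit", "smst")

#: default number of chords per angular sector
DEFAULT_N_CHORDS = 60
#: default number of samples along each chord
DEFAULT_N_SAMPLES = 200

# --- angular profile regularization (SMST channel) ---
#: Gaussian angular window of the bilateral filter (degrees)
PROFILE_SIGMA_PHI_DEG = 20.0
#: range gate of the bilateral filter (percentage points)
PROFILE_SIGMA_R_PCT = 5.0
#: fixed-point iterations of the bilateral filter
PROFILE_ITERATIONS = 6
#: depth grid of the reprojection (moire-cancellation) correction
REPROJECTION_DEPTHS = np.linspace(0.1, 1.0, 10)
#: plateau gate: local profile range (pp) below which the correction applies
REPROJECTION_FLAT_TOL_PCT = 6.0
#: half-width (degrees) of the plateau-gate window
REPROJECTION_FLAT_HALF_DEG = 10.0


# ---------------------------------------------------------------------------
# scar raster container
# ---------------------------------------------------------------------------

@dataclass
class ScarRaster:
    """Per-slice binary scar grids, optionally with a signal-intensity channel."""

    masks: list[np.ndarray]
    intensity: list[np.ndarray] | None = None
    remote_intensity: float | None = None
    core_intensity: float | None = None
    clipped_pixels: int = 0

    def __post_init__(self):
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        if self.intensity is not None:
            self.intensity = [np.asarray(g, dtype=float) for g in self.intensity]
            if len(self.intensity) != len(self.masks) or any(
                g.shape != m.shape for g, m in zip(self.intensity, self.masks)
            ):
                raise ValueError("intensity grids must match scar mask shapes")
            if self.remote_intensity is not None and self.core_intensity is not None:
                if self.core_intensity <= self.remote_intensity:
                    raise CalibrationError(
                        "core_intensity must exceed remote_intensity "
                        f"({self.core_intensity} <= {self.remote_intensity})"
                    )

    @classmethod
    def from_masks(cls, masks, myo: MyocardiumMask | None = None, **kw) -> "ScarRaster":
        """Build a raster, clipping scar pixels outside the myocardium (with a warning)."""
        masks = [np.asarray(m, dtype=bool) for m in masks]
        clipped = 0
        if myo is not None:
            out = []
            for m, w in zip(masks, myo.masks):
                if m.shape != w.shape:
                    raise ValueError("scar mask shape does not match myocardium mask")
                clipped += int((m & ~w).sum())
                out.append(m & w)
            masks = out
            if clipped:
                warnings.warn(f"{clipped} scar pixels outside the myocardium were clipped")
        return cls(masks, clipped_pixels=clipped, **kw)

    def has_intensity(self) -> bool:
        return self.intensity is not None

    def weights(self, i: int) -> np.ndarray:
        """Per-pixel partial-volume weights for slice ``i`` (1.0 for binary input)."""
        m = self.masks[i]
        if self.intensity is None:
            return np.ones_like(m, dtype=float)
        if self.remote_intensity is None or self.core_intensity is None:
            raise CalibrationError("intensity channel present but remote/core not calibrated")
        span = self.core_intensity - self.remote_intensity
        if span <= 0:
            raise CalibrationError("core_intensity must exceed remote_intensity")
        w = (self.intensity[i] - self.remote_intensity) / span
        return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# chord casting
# ---------------------------------------------------------------------------

def _ray_ring_radii(origin: np.ndarray, angles: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Largest positive distance from ``origin`` to the ring along each angle (nan if none)."""
    P = np.vstack([ring, ring[:1]])
    A, B = P[:-1], P[1:]
    E = B - A                                   # (m, 2) edges
    U = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (n, 2)
    W = A - origin                              # (m, 2)
    denom = U[:, 0:1] * E[:, 1] - U[:, 1:2] * E[:, 0]       # (n, m) cross(u, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (W[:, 0] * E[:, 1] - W[:, 1] * E[:, 0]) / denom             # (n, m)
        s = (W[:, 0] * U[:, 1:2] - W[:, 1] * U[:, 0:1]) / denom
    ok = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s < 1.0) & (t > 1e-9)
    t = np.where(ok, t, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows
        return np.nanmax(t, axis=1)


def _extended_field(values: np.ndarray, myo: np.ndarray) -> np.ndarray:
    """Extend per-pixel values outside the myocardium by nearest myocardial pixel."""
    if myo.all():
        return np.asarray(values, dtype=float)
    _, (ri, ci) = ndimage.distance_transform_edt(~myo, return_indices=True)
    return np.asarray(values, dtype=float)[ri, ci]


def _chords_at_angles(sl: SliceGeometry, field: np.ndarray, angles: np.ndarray,
                      n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Wall lengths and mean field value along each chord (nan for dropped chords)."""
    origin = sl.centroid
    r_in = _ray_ring_radii(origin, angles, sl.endo)
    r_out = _ray_ring_radii(origin, angles, sl.epi)
    wall = r_out - r_in
    valid = np.isfinite(r_in) & np.isfinite(r_out) & (wall > 1e-9)
    n_bad = int((~valid).sum())
    if n_bad == len(angles):
        raise GeometryError(f"slice {sl.z_index}: all chords dropped")
    if n_bad:
        warnings.warn(f"slice {sl.z_index}: {n_bad} chords dropped (no endo/epi crossing)")
    t = (np.arange(n_samples) + 0.5) / n_samples
    rr = np.where(valid, r_in, 0.0)[:, None] + t[None, :] * np.where(valid, wall, 0.0)[:, None]
    X = origin[0] + np.cos(angles)[:, None] * rr
    Y = origin[1] + np.sin(angles)[:, None] * rr
    dx, dy = sl.pixel_spacing
    coords = np.vstack([(Y / dy - 0.5).ravel(), (X / dx - 0.5).ravel()])
    v = ndimage.map_coordinates(field, coords, order=1, mode="nearest")
    frac = v.reshape(len(angles), n_samples).mean(axis=1)
    wall = np.where(valid, wall, np.nan)
    frac = np.where(valid, frac, np.nan)
    return wall, frac


def cast_chords(sl: SliceGeometry, myo_mask: np.ndarray, scar_mask: np.ndarray,
                sector: tuple[float, float], n_chords: int = DEFAULT_N_CHORDS,
                n_samples: int = DEFAULT_N_SAMPLES) -> tuple[np.ndarray, np.ndarray]:
    """Raw chords for one angular sector.

    Rays start at the endocardial centroid, at uniform midpoint angles within
    ``sector = (start, end)`` radians.  Returns ``(wall_lengths, scar_lengths)``
    in mm; chords that fail to cross both contours are nan.
    """
    if n_chords < 8:
        raise ValueError("need at least 8 chords per sector")
    start, end = sector
    angles = start + (np.arange(n_chords) + 0.5) / n_chords * (end - start)
    field = _extended_field(scar_mask & myo_mask, myo_mask)
    wall, frac = _chords_at_angles(sl, field, angles, n_samples)
    return wall, wall * frac


# ---------------------------------------------------------------------------
# angular profile regularization
# ---------------------------------------------------------------------------

def _iterated_bilateral(f_pct: np.ndarray, spacing_deg: float,
                        sigma_phi_deg: float = PROFILE_SIGMA_PHI_DEG,
                        sigma_r_pct: float = PROFILE_SIGMA_R_PCT,
                        iterations: int = PROFILE_ITERATIONS) -> np.ndarray:
    """Edge-preserving smoothing of a periodic angular profile (percent units)."""
    n = len(f_pct)
    half = int(np.ceil(3.0 * sigma_phi_deg / spacing_deg))
    off = np.arange(-half, half + 1)
    gs = np.exp(-0.5 * (off * spacing_deg / sigma_phi_deg) ** 2)
    idx = (np.arange(n)[:, None] + off[None, :]) % n
    vals = f_pct[idx]
    fs = f_pct.copy()
    for _ in range(iterations):
        gr = np.exp(-0.5 * ((vals - fs[:, None]) / sigma_r_pct) ** 2)
        w = gs[None, :] * gr
        fs = (w * vals).sum(axis=1) / w.sum(axis=1)
    return fs


def _rolling_range(x: np.ndarray, half: int) -> np.ndarray:
    idx = (np.arange(len(x))[:, None] + np.arange(-half, half + 1)[None, :]) % len(x)
    v = x[idx]
    return v.max(axis=1) - v.min(axis=1)


class _SliceChordEngine:
    """Chord profile of one slice: raw and regularized transmurality vs angle."""

    def __init__(self, sl: SliceGeometry, myo_mask: np.ndarray, scar_mask: np.ndarray,
                 level: str, rv: float, n_chords: int, n_samples: int):
        if n_chords < 8:
            raise ValueError("need at least 8 chords per sector")
        self.sl = sl
        nsec = geo.SECTOR_COUNT[level]
        self.n_phi = nsec * n_chords
        self.spacing_deg = 360.0 / self.n_phi
        self.angles = rv + (np.arange(self.n_phi) + 0.5) * 2.0 * math.pi / self.n_phi
        self.myo = myo_mask
        scar = scar_mask & myo_mask
        field = _extended_field(scar, myo_mask)
        self.wall, frac = _chords_at_angles(sl, field, self.angles, n_samples)
        self.f_raw = 100.0 * frac                     # percent, nan where dropped
        self.f_reg = self._regularize(n_samples)

    def _regularize(self, n_samples: int) -> np.ndarray:
        f = np.where(np.isfinite(self.f_raw), self.f_raw, 0.0)
        fs1 = _iterated_bilateral(f, self.spacing_deg)
        bias = self._reprojection_bias(fs1, n_samples)
        fs2 = _iterated_bilateral(f - bias, self.spacing_deg)
        return fs2

    def _reprojection_bias(self, fs1: np.ndarray, n_samples: int) -> np.ndarray:
        """Predicted pixelation moire at the locally estimated depth (plateau-gated)."""
        sl = self.sl
        origin = sl.centroid
        r_in = _ray_ring_radii(origin, self.angles, sl.endo)
        r_out = _ray_ring_radii(origin, self.angles, sl.epi)
        valid = np.isfinite(r_in) & np.isfinite(r_out)
        if not valid.all():
            fill_in = np.nanmedian(r_in) if np.isfinite(r_in).any() else 0.0
            fill_out = np.nanmedian(r_out) if np.isfinite(r_out).any() else 1.0
            r_in = np.where(valid, r_in, fill_in)
            r_out = np.where(valid, r_out, fill_out)
        X, Y = sl.pixel_centers()
        a_pix = np.mod(np.arctan2(Y - origin[1], X - origin[0]) - self.angles[0], 2.0 * math.pi)
        r_pix = np.hypot(X - origin[0], Y - origin[1])
        rel = np.mod(self.angles - self.angles[0], 2.0 * math.pi)
        order = np.argsort(rel)
        ri_p = np.interp(a_pix.ravel(), rel[order], r_in[order], period=2.0 * math.pi)
        ro_p = np.interp(a_pix.ravel(), rel[order], r_out[order], period=2.0 * math.pi)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_pix = (r_pix.ravel() - ri_p) / np.maximum(ro_p - ri_p, 1e-9)
        t_pix = t_pix.reshape(r_pix.shape)

        depths = REPROJECTION_DEPTHS
        table = np.empty((len(depths), self.n_phi))
        for k, d in enumerate(depths):
            ring = self.myo & (t_pix <= d)
            field = _extended_field(ring, self.myo)
            _, frac = _chords_at_angles(sl, field, self.angles, n_samples)
            table[k] = 100.0 * np.where(np.isfinite(frac), frac, d) - 100.0 * d

        dhat = np.clip(fs1 / 100.0, depths[0], depths[-1])
        idx = np.clip(np.searchsorted(depths, dhat) - 1, 0, len(depths) - 2)
        w = (dhat - depths[idx]) / (depths[idx + 1] - depths[idx])
        ar = np.arange(self.n_phi)
        bias = (1.0 - w) * table[idx, ar] + w * table[idx + 1, ar]
        half = max(1, int(round(REPROJECTION_FLAT_HALF_DEG / self.spacing_deg)))
        flat = _rolling_range(fs1, half) < REPROJECTION_FLAT_TOL_PCT
        return np.where(flat & (fs1 > 1.0), bias, 0.0)


# ---------------------------------------------------------------------------
# the four estimators
# ---------------------------------------------------------------------------

def _clamp_pct(v: float) -> float:
    # guard against float round-off just outside [0, 100]
    return min(max(v, 0.0), 100.0)


def stab(scar_area_mm2: float, myo_area_mm2: float) -> float | None:
    """Area-based transmurality (percent); None for an empty segment."""
    if myo_area_mm2 <= 0:
        return None
    return _clamp_pct(100.0 * scar_area_mm2 / myo_area_mm2)


def stlb(wall_lengths: np.ndarray, scar_lengths: np.ndarray, weighted: bool = True) -> float | None:
    """Line-based transmurality: thickness-weighted mean radial scar extent (percent)."""
    wall = np.asarray(wall_lengths, dtype=float)
    scar = np.asarray(scar_lengths, dtype=float)
    ok = np.isfinite(wall) & np.isfinite(scar) & (wall > 0)
    if not ok.any():
        return None
    if weighted:
        return _clamp_pct(100.0 * scar[ok].sum() / wall[ok].sum())
    return _clamp_pct(100.0 * float(np.mean(scar[ok] / wall[ok])))


def wit(scar_weighted_mass: float, segment_mass: float) -> float | None:
    """Intensity-weighted scar mass fraction of the segment (percent)."""
    if segment_mass <= 0:
        return None
    return _clamp_pct(100.0 * scar_weighted_mass / segment_mass)


def smst(regularized_fractions_pct: np.ndarray, floor: float | None = None) -> float | None:
    """Spatial maximal transmurality: max of the regularized chord profile (percent)."""
    f = np.asarray(regularized_fractions_pct, dtype=float)
    f = f[np.isfinite(f)]
    if f.size == 0:
        return None
    value = float(np.clip(f.max(), 0.0, 100.0))
    if floor is not None:
        value = max(value, min(floor, 100.0))
    return value


# ---------------------------------------------------------------------------
# per-segment assembly
# ---------------------------------------------------------------------------

@dataclass
class SegmentTransmurality:
    """Per-segment values of the four estimators, in percent (None = missing)."""

    segment_id: int
    stab: float | None
    stlb: float | None
    wit: float | None
    smst: float | None
    has_scar: bool

    def value(self, method: str) -> float | None:
        return getattr(self, method)


@dataclass
class QuartileProfile:
    """Counts of scarred segments per transmurality quartile for one method."""

    method: str
    bins: tuple[int, int, int, int]   # [1,25), [25,50), [50,75), [75,100]
    total: int                        # segments with any scar (value > 0)

    @property
    def n_transmural(self) -> int:
        return self.bins[3]


def quartile_profile(values, method: str = "") -> QuartileProfile:
    """Bin per-segment transmuralities into the 1-24/25-49/50-74/>=75 quartiles.

    Zero is excluded from every bin; values in (0, 1) count into the first bin,
    so the bins always sum to the number of segments with any scar.  75 falls
    in the transmural bin (>= 75 % is transmural by definition).
    """
    vals = np.array([v for v in values if v is not None], dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("transmurality values must lie in [0, 100]")
    pos = vals[vals > 0]
    b1 = int(((pos > 0) & (pos < 25)).sum())
    b2 = int(((pos >= 25) & (pos < 50)).sum())
    b3 = int(((pos >= 50) & (pos < 75)).sum())
    b4 = int((pos >= 75).sum())
    return QuartileProfile(method, (b1, b2, b3, b4), int((vals > 0).sum()))


def _slice_sector_stats(sl: SliceGeometry, level: str, rv: float,
                        myo_mask: np.ndarray, scar: ScarRaster, slice_pos: int,
                        n_chords: int, n_samples: int) -> dict:
    """All per-sector accumulators contributed by one slice."""
    scar_mask = scar.masks[slice_pos] & myo_mask
    labels = geo.segment_label_map(sl, level, rv, myo=myo_mask)
    weights = scar.weights(slice_pos)
    engine = _SliceChordEngine(sl, myo_mask, scar_mask, level, rv, n_chords, n_samples)

    out = {}
    px_area = sl.pixel_area_mm2
    vox_mass = sl.voxel_volume_mm3 * geo.MYOCARDIAL_DENSITY_G_PER_CM3 / 1000.0
    nsec = geo.SECTOR_COUNT[level]
    for k in range(nsec):
        seg = geo.SEGMENT_BASE[level] + k
        in_seg = labels == seg
        sel = slice(k * n_chords, (k + 1) * n_chords)
        out[seg] = {
            "myo_area": float(in_seg.sum()) * px_area,
            "scar_area": float((in_seg & scar_mask).sum()) * px_area,
            "seg_mass": float(in_seg.sum()) * vox_mass,
            "scar_wmass": float(weights[in_seg & scar_mask].sum()) * vox_mass,
            "wall": engine.wall[sel],
            "scar_len": engine.wall[sel] * engine.f_raw[sel] / 100.0,
            "f_reg": engine.f_reg[sel],
        }
    return out


def segment_transmuralities(stack: ContourStack, scar: ScarRaster,
                            aha: AHAModel | None = None,
                            myo: MyocardiumMask | None = None,
                            n_chords: int = DEFAULT_N_CHORDS,
                            n_samples: int = DEFAULT_N_SAMPLES,
                            min_scar_area_mm2: float = 0.0,
                            weighted_stlb: bool = True) -> list[SegmentTransmurality]:
    """Compute STAB/STLB/WIT/SMST for the 16 sectoral AHA segments.

    Chords and pixel counts are pooled over the slices of each segment's level.
    Identical slices (same geometry and masks) are computed once and reused.
    """
    if aha is None:
        aha = AHAModel.from_stack(stack)
    if myo is None:
        myo = MyocardiumMask.from_stack(stack)
    rv = aha.rv_insertion_angle

    acc: dict[int, dict] = {}
    cache: dict[bytes, dict] = {}
    for pos, sl in enumerate(stack.slices):
        level = aha.level_of_slice[sl.z_index]
        key = b"|".join([
            sl.endo.tobytes(), sl.epi.tobytes(),
            np.asarray(sl.pixel_spacing).tobytes(), np.float64(sl.slice_span).tobytes(),
            level.encode(), scar.masks[pos].tobytes(),
            scar.intensity[pos].tobytes() if scar.intensity is not None else b"",
            np.int64(n_chords).tobytes(), np.int64(n_samples).tobytes(),
        ])
        if key not in cache:
            cache[key] = _slice_sector_stats(sl, level, rv, myo.masks[pos], scar, pos,
                                             n_chords, n_samples)
        for seg, s in cache[key].items():
            a = acc.setdefault(seg, {
                "myo_area": 0.0, "scar_area": 0.0, "seg_mass": 0.0, "scar_wmass": 0.0,
                "wall": [], "scar_len": [], "f_reg": [],
            })
            for f in ("myo_area", "scar_area", "seg_mass", "scar_wmass"):
                a[f] += s[f]
            for f in ("wall", "scar_len", "f_reg"):
                a[f].append(s[f])

    results = []
    for seg in geo.SECTORAL_SEGMENTS:
        if seg not in acc or acc[seg]["myo_area"] <= 0:
            results.append(SegmentTransmurality(seg, None, None, None, None, False))
            continue
        a = acc[seg]
        wall = np.concatenate(a["wall"])
        scar_len = np.concatenate(a["scar_len"])
        f_reg = np.concatenate(a["f_reg"])
        v_stab = stab(a["scar_area"], a["myo_area"])
        v_stlb = stlb(wall, scar_len, weighted=weighted_stlb)
        v_wit = wit(a["scar_wmass"], a["seg_mass"])
        if min_scar_area_mm2 > 0:
            has = a["scar_area"] >= min_scar_area_mm2
        else:
            has = a["scar_area"] > 0
        v_smst = smst(f_reg, floor=v_stlb) if has else (0.0 if v_stlb is not None else None)
        if not has:
            # no scar pixels: the chord channel is identically zero up to noise
            v_stab = 0.0 if v_stab is not None else None
            v_stlb = 0.0 if v_stlb is not None else None
            v_wit = 0.0 if v_wit is not None else None
        results.append(SegmentTransmurality(seg, v_stab, v_stlb, v_wit, v_smst, bool(has)))
    return results


# ---------------------------------------------------------------------------
# global burden and the patient summary
# ---------------------------------------------------------------------------

def percent_scar(stack: ContourStack, scar: ScarRaster,
                 myo: MyocardiumMask | None = None) -> float:
    """Scar volume as a percentage of LV myocardial volume (volume-weighted)."""
    if myo is None:
        myo = MyocardiumMask.from_stack(stack)
    myo_vol = 0.0
    scar_vol = 0.0
    for sl, m, s in zip(stack.slices, myo.masks, scar.masks):
        v = sl.voxel_volume_mm3
        myo_vol += int(m.sum()) * v
        scar_vol += int((s & m).sum()) * v
    if myo_vol <= 0:
        raise GeometryError("empty myocardium: percent scar undefined")
    return 100.0 * scar_vol / myo_vol


def scar_mass(percent: float, lv_mass_g: float) -> float:
    """Scar mass in grams: percent scar times LV mass."""
    if percent < 0 or lv_mass_g < 0:
        raise ValueError("percent scar and LV mass must be nonnegative")
    return percent / 100.0 * lv_mass_g


@dataclass
class PatientScarSummary:
    """Global burden, quartile profiles and per-segment values for one study."""

    percent_scar: float
    scar_mass: float
    lv_mass: float
    segments: list[SegmentTransmurality]
    profiles: dict[str, QuartileProfile]
    cap_has_scar: bool

    @property
    def n_transmural(self) -> dict[str, int]:
        return {m: p.n_transmural for m, p in self.profiles.items()}

    def segment_table(self, patient_id: str = "") -> pd.DataFrame:
        rows = [{
            "patient_id": patient_id,
            "segment_id": s.segment_id,
            "stab": s.stab, "stlb": s.stlb, "wit": s.wit, "smst": s.smst,
            "has_scar": s.has_scar,
        } for s in self.segments]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "percent_scar": self.percent_scar,
            "scar_mass_g": self.scar_mass,
            "lv_mass_g": self.lv_mass,
            "cap_has_scar": self.cap_has_scar,
            "quartiles": {
                m: {"bins": list(p.bins), "total": p.total, "n_transmural": p.n_transmural}
                for m, p in self.profiles.items()
            },
            "segments": [{
                "segment_id": s.segment_id, "stab": s.stab, "stlb": s.stlb,
                "wit": s.wit, "smst": s.smst, "has_scar": s.has_scar,
            } for s in self.segments],
        }


def summarize_patient(stack: ContourStack, scar: ScarRaster,
                      aha: AHAModel | None = None,
                      n_chords: int = DEFAULT_N_CHORDS,
                      n_samples: int = DEFAULT_N_SAMPLES,
                      min_scar_area_mm2: float = 0.0,
                      weighted_stlb: bool = True) -> PatientScarSummary:
    """Full scar quantification of one study: burden, transmuralities, quartiles."""
    if aha is None:
        aha = AHAModel.from_stack(stack)
    myo = MyocardiumMask.from_stack(stack)
    pct = percent_scar(stack, scar, myo=myo)
    lvm = geo.lv_mass(stack, myo=myo)
    segs = segment_transmuralities(stack, scar, aha=aha, myo=myo, n_chords=n_chords,
                                   n_samples=n_samples,
                                   min_scar_area_mm2=min_scar_area_mm2,
                                   weighted_stlb=weighted_stlb)
    profiles = {
        m: quartile_profile((s.value(m) for s in segs), method=m) for m in METHODS
    }
    apical_pos = [i for i, s in enumerate(stack.slices) if s.z_index == aha.apical_z][0]
    cap = bool((scar.masks[apical_pos] & myo.masks[apical_pos]).any())
    return PatientScarSummary(pct, scar_mass(pct, lvm), lvm, segs, profiles, cap)
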