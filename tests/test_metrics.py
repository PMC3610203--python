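"""Scar burden, the four transmurality estimators and quartile binning."""

import math

import numpy as np
import pytest

import scarq
from scarq.errors import CalibrationError, GeometryError
from scarq.geometry import MyocardiumMask
from scarq.metrics import (ScarRaster, cast_chords, percent_scar,
                           quartile_profile, scar_mass, segment_transmuralities,
                           summarize_patient)


def seg_by_id(summary_or_list, seg_id):
    segs = getattr(summary_or_list, "segments", summary_or_list)
    return next(s for s in segs if s.segment_id == seg_id)


# ---------------------------------------------------------------------------
# global burden
# ---------------------------------------------------------------------------

def test_percent_scar_empty_and_full(annulus_stack):
    myo = MyocardiumMask.from_stack(annulus_stack)
    empty = ScarRaster([np.zeros_like(m) for m in myo.masks])
    assert percent_scar(annulus_stack, empty, myo=myo) == 0.0
    full = ScarRaster([m.copy() for m in myo.masks])
    assert percent_scar(annulus_stack, full, myo=myo) == 100.0


def test_percent_scar_quarter_wedge_closed_form(annulus_stack):
    # 90-degree span, depth 0.5: 100 * (90/360) * (25^2-20^2)/(30^2-20^2) = 11.25 %
    scar, truth = scarq.apply_wedge(
        annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 2, 0.5))
    assert truth.percent_scar == pytest.approx(11.25, abs=1e-9)
    measured = percent_scar(annulus_stack, scar)
    assert measured == pytest.approx(11.25, rel=0.02)


@pytest.mark.parametrize("pct, lvm, expected", [
    (10.0, 200.0, 20.0),
    (0.0, 123.0, 0.0),
    (15.1, 205.0, 30.955),
])
def test_scar_mass_definition(pct, lvm, expected):
    assert scar_mass(pct, lvm) == pytest.approx(expected, rel=1e-12)


def test_scar_mass_rejects_negative_inputs():
    with pytest.raises(ValueError):
        scar_mass(-1.0, 100.0)


def test_scar_mass_conservation_is_exact(wedge_case):
    _, _, _, summary = wedge_case
    assert summary.scar_mass == pytest.approx(
        summary.percent_scar / 100.0 * summary.lv_mass, rel=1e-9)


# ---------------------------------------------------------------------------
# STAB
# ---------------------------------------------------------------------------

def test_stab_full_sector_wedge(wedge_case):
    # depth 0.5 over one whole basal sector: 100*(25^2-20^2)/(30^2-20^2) = 45 %
    _, _, _, summary = wedge_case
    assert seg_by_id(summary, 1).stab == pytest.approx(45.0, abs=1.0)


def test_stab_is_exactly_100_when_scar_fills_segment(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 3, 1.0))
    segs = segment_transmuralities(annulus_stack, scar)
    assert seg_by_id(segs, 1).stab == pytest.approx(100.0, abs=1e-12)


def test_stab_halves_with_half_sector_coverage(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 6, 0.5))
    segs = segment_transmuralities(annulus_stack, scar)
    assert seg_by_id(segs, 1).stab == pytest.approx(22.5, abs=1.0)


# ---------------------------------------------------------------------------
# chords, STLB, SMST
# ---------------------------------------------------------------------------

def test_cast_chords_scar_free_and_full_wall(annulus_stack):
    sl = annulus_stack.slices[0]
    myo = scarq.rasterize_myocardium(sl)
    none = np.zeros_like(myo)
    wall, scar_len = cast_chords(sl, myo, none, sector=(0.0, math.pi / 3))
    assert np.allclose(scar_len, 0.0)
    assert np.allclose(wall, 10.0, atol=0.2)
    wall, scar_len = cast_chords(sl, myo, myo, sector=(0.0, math.pi / 3))
    assert np.allclose(scar_len, wall)


def test_chord_through_wedge_measures_half_the_wall(wedge_case):
    stack, scar, _, _ = wedge_case
    sl = stack.slices[0]
    myo = scarq.rasterize_myocardium(sl)
    # interior chords of the wedge (away from its angular edges)
    wall, scar_len = cast_chords(sl, myo, scar.masks[0],
                                 sector=(math.radians(10), math.radians(50)))
    assert np.nanmean(scar_len) == pytest.approx(5.0, abs=0.2)


def test_stlb_and_smst_on_aligned_wedge(wedge_case):
    _, _, _, summary = wedge_case
    s1 = seg_by_id(summary, 1)
    assert s1.stlb == pytest.approx(50.0, abs=1.0)
    assert s1.smst == pytest.approx(50.0, abs=1.0)


def test_stlb_halves_when_wedge_covers_half_sector(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 6, 0.5))
    segs = segment_transmuralities(annulus_stack, scar)
    s1 = seg_by_id(segs, 1)
    assert s1.stlb == pytest.approx(25.0, abs=1.0)
    assert s1.smst == pytest.approx(50.0, abs=1.0)   # max keeps the spatial signal


def test_smst_detects_concentrated_lesion(annulus_stack):
    # 6-degree wedge (10 % of the sector), depth 0.5: STLB ~ 5, SMST ~ 50
    scar, _ = scarq.apply_wedge(
        annulus_stack, scarq.WedgeScarSpec(math.radians(27), math.radians(6), 0.5))
    s1 = seg_by_id(segment_transmuralities(annulus_stack, scar), 1)
    assert s1.stlb == pytest.approx(5.0, abs=1.0)
    assert s1.smst == pytest.approx(50.0, abs=1.0)


def test_smst_flags_transmural_needle_as_transmural(annulus_stack):
    """A 6-degree transmural needle is only ~2.6 pixels wide at 1 mm spacing,
    so its regularized peak reads slightly below the ideal 100; it must still
    land far above the 75 % transmural threshold while STLB stays near 10."""
    scar, _ = scarq.apply_wedge(
        annulus_stack, scarq.WedgeScarSpec(math.radians(27), math.radians(6), 1.0))
    s1 = seg_by_id(segment_transmuralities(annulus_stack, scar), 1)
    assert s1.smst > 90.0
    assert s1.stlb == pytest.approx(10.0, abs=1.0)


def test_smst_never_below_stlb(wedge_case):
    _, _, _, summary = wedge_case
    for s in summary.segments:
        if s.smst is not None and s.stlb is not None:
            assert s.smst >= s.stlb - 1e-9


def test_metrics_increase_with_wedge_depth():
    stack = scarq.make_annulus_stack(3, 20.0, 30.0, 1.0, 10.0)
    prev = None
    for depth in (0.3, 0.5, 0.7, 0.9):
        scar, _ = scarq.apply_wedge(stack, scarq.WedgeScarSpec(0.0, math.pi / 3, depth))
        s1 = seg_by_id(segment_transmuralities(stack, scar), 1)
        cur = (s1.stab, s1.stlb, s1.wit, s1.smst)
        if prev is not None:
            assert all(c > p for c, p in zip(cur, prev))
        prev = cur


def test_chord_count_convergence(wedge_case):
    stack, scar, _, summary = wedge_case
    s120 = summarize_patient(stack, scar, n_chords=120)
    for m in ("stlb", "smst"):
        d = abs(seg_by_id(summary, 1).value(m) - seg_by_id(s120, 1).value(m))
        assert d < 0.5


# ---------------------------------------------------------------------------
# WIT
# ---------------------------------------------------------------------------

def test_wit_equals_stab_for_binary_uniform_input(wedge_case):
    _, _, _, summary = wedge_case
    for s in summary.segments:
        if s.wit is not None:
            assert s.wit == pytest.approx(s.stab, rel=1e-9, abs=1e-9)


def test_wit_is_half_stab_at_uniform_half_weight(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, math.pi / 3, 0.5))
    intensity = [np.where(m, 60.0, 20.0) for m in scar.masks]  # w = 0.5 everywhere
    raster = ScarRaster(scar.masks, intensity=intensity,
                        remote_intensity=20.0, core_intensity=100.0)
    segs = segment_transmuralities(annulus_stack, raster)
    s1 = seg_by_id(segs, 1)
    assert s1.wit == pytest.approx(s1.stab / 2.0, rel=1e-9)


def test_wit_below_stab_with_partial_volume_ramp(annulus_stack):
    ramp = scarq.IntensityRamp(core=100.0, remote=20.0, edge_width_mm=4.0, noise_sd=0.0)
    scar, _ = scarq.apply_wedge(
        annulus_stack,
        scarq.WedgeScarSpec(0.0, math.pi / 3, 0.5, intensity_model=ramp))
    s1 = seg_by_id(segment_transmuralities(annulus_stack, scar), 1)
    assert s1.wit < s1.stab


def test_wit_calibration_error_when_core_not_above_remote(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, 1.0, 0.5))
    with pytest.raises(CalibrationError):
        ScarRaster(scar.masks, intensity=[m.astype(float) for m in scar.masks],
                   remote_intensity=50.0, core_intensity=50.0)


# ---------------------------------------------------------------------------
# quartiles and the patient summary
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values, bins, total", [
    ([0, 10, 30, 80], (1, 1, 0, 1), 3),
    ([0, 0, 0], (0, 0, 0, 0), 0),
    ([75.0], (0, 0, 0, 1), 1),          # >= 75 is transmural by definition
    ([74.999], (0, 0, 1, 0), 1),
    ([0.5], (1, 0, 0, 0), 1),           # (0,1) rounds into the first bin
    ([25.0, 50.0, 24.999], (1, 1, 1, 0), 3),
])
def test_quartile_binning(values, bins, total):
    p = quartile_profile(values)
    assert p.bins == bins
    assert p.total == total
    assert sum(p.bins) == p.total


def test_summary_scar_free_patient(annulus_stack):
    empty = ScarRaster([np.zeros(s.grid_shape, dtype=bool) for s in annulus_stack.slices])
    s = summarize_patient(annulus_stack, empty)
    assert s.percent_scar == 0.0 and s.scar_mass == 0.0
    assert all(p.total == 0 for p in s.profiles.values())
    assert not s.cap_has_scar


def test_summary_full_thickness_full_circumference(annulus_stack):
    scar, _ = scarq.apply_wedge(annulus_stack, scarq.WedgeScarSpec(0.0, 2 * math.pi, 1.0))
    s = summarize_patient(annulus_stack, scar)
    assert s.percent_scar == pytest.approx(100.0, abs=1e-9)
    for p in s.profiles.values():
        assert p.total == 16 and p.bins == (0, 0, 0, 16)
    assert s.cap_has_scar


def test_summary_matches_phantom_truth(wedge_case):
    _, _, truth, summary = wedge_case
    assert summary.percent_scar == pytest.approx(truth.percent_scar, abs=2.0)
    assert summary.lv_mass == pytest.approx(truth.lv_mass, rel=0.02)
    for s in summary.segments:
        for m in ("stab", "stlb", "wit", "smst"):
            assert s.value(m) == pytest.approx(truth.value(s.segment_id, m), abs=2.0)


def test_empty_myocardium_is_an_error(annulus_stack):
    empty = ScarRaster([np.zeros(s.grid_shape, dtype=bool) for s in annulus_stack.slices])
    bad = MyocardiumMask([np.zeros(s.grid_shape, dtype=bool) for s in annulus_stack.slices])
    with pytest.raises(GeometryError):
        percent_scar(annulus_stack, empty, myo=bad)
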