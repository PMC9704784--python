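"""Frequency-offset estimation, slab fitting and gradient selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zshim import (AcquisitionParams, FieldMap, PhaseSeries, ZShimGrid,
                   fit_all_slices, fit_slicewise_basis,
                   frequency_from_multiecho, frequency_from_two_echoes,
                   histogram_gradient, select_zshim_fm, smooth_fieldmap,
                   unwrap_echo_train)
from zshim.fieldmap import HZ_PER_MM_PER_MT_M, SliceFit, wrap_phase


def _phase_series(dnu, echo_times_ms, phi0=0.0):
    tes = np.asarray(echo_times_ms, dtype=float)
    phases = wrap_phase(2 * np.pi * dnu[..., None] * tes / 1000.0 + phi0)
    return PhaseSeries(phases=phases, echo_times=tes)


# ---------------------------------------------------------------------------
# Two-echo and multi-echo frequency estimation
# ---------------------------------------------------------------------------

def test_two_echo_quarter_cycle():
    phases = np.zeros((1, 1, 1, 2))
    phases[..., 1] = np.pi / 2
    series = PhaseSeries(phases=phases, echo_times=[4.0, 6.46])
    fm = frequency_from_two_echoes(series)
    assert fm.dnu[0, 0, 0] == pytest.approx(0.25 / 0.00246, rel=1e-9)


def test_two_echo_equal_phases_give_zero():
    series = PhaseSeries(phases=np.full((2, 2, 2, 2), 1.2),
                         echo_times=[4.0, 6.46])
    assert np.all(frequency_from_two_echoes(series).dnu == 0.0)


def test_two_echo_round_trip_within_alias_limit():
    rng = np.random.default_rng(0)
    dnu = rng.uniform(-200.0, 200.0, size=(5, 5, 4))  # < 1/(2*2.46ms) = 203 Hz
    series = _phase_series(dnu, [4.0, 6.46], phi0=0.7)
    fm = frequency_from_two_echoes(series)
    assert np.allclose(fm.dnu, dnu, atol=1e-9)


def test_two_echo_requires_exactly_two():
    series = _phase_series(np.zeros((2, 2, 2)), [4.0, 5.3, 6.6])
    with pytest.raises(ValueError):
        frequency_from_two_echoes(series)


@pytest.mark.parametrize("slope", [2.0, 0.5, -2.5])
def test_unwrap_recovers_linear_ramps(slope):
    """Wrap-then-unwrap round trip for ramps steeper and shallower than pi."""
    n_echo = 12
    true = slope * np.arange(n_echo)[None, None, None, :] * np.ones((2, 2, 2, 1))
    series = PhaseSeries(phases=wrap_phase(true),
                         echo_times=4.0 + 1.3 * np.arange(n_echo))
    unwrapped = unwrap_echo_train(series)
    # first echo unchanged; recovered up to the first echo's wrap multiple
    assert np.array_equal(unwrapped[..., 0], series.phases[..., 0])
    assert np.allclose(np.diff(unwrapped, axis=3), slope, atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(slope=st.floats(min_value=-3.1, max_value=3.1, allow_nan=False))
def test_unwrap_successive_differences_bounded(slope):
    true = slope * np.arange(8)[None, None, None, :] * np.ones((1, 1, 1, 1))
    series = PhaseSeries(phases=wrap_phase(true),
                         echo_times=1.0 + np.arange(8))
    diffs = np.diff(unwrap_echo_train(series), axis=3)
    assert np.all(diffs > -np.pi - 1e-12) and np.all(diffs <= np.pi + 1e-12)


def test_multiecho_noiseless_recovery():
    dnu = np.full((3, 3, 2), 100.0)
    series = _phase_series(dnu, 4.0 + 1.3 * np.arange(12), phi0=0.3)
    fm = frequency_from_multiecho(series)
    assert np.allclose(fm.dnu, 100.0, atol=1e-9)


def test_multiecho_zero_field():
    series = _phase_series(np.zeros((2, 2, 2)), 4.0 + 1.3 * np.arange(12))
    assert np.allclose(frequency_from_multiecho(series).dnu, 0.0, atol=1e-12)


def test_multiecho_equals_two_point_slope_when_wrap_free():
    rng = np.random.default_rng(1)
    dnu = rng.uniform(-8.0, 8.0, size=(4, 4, 3))  # |phase| < pi at every TE
    tes = 4.0 + 1.3 * np.arange(12)
    series = _phase_series(dnu, tes)
    fm = frequency_from_multiecho(series)
    two_point = (series.phases[..., -1] - series.phases[..., 0]) / (
        2 * np.pi * (tes[-1] - tes[0]) / 1000.0)
    assert np.allclose(fm.dnu, two_point, atol=1e-9)


def test_multiecho_beats_two_echo_under_phase_noise():
    """Monte-Carlo: the 12-echo OLS slope has lower variance than the
    two-echo difference over a matched TE span."""
    rng = np.random.default_rng(2026)
    tes = 4.0 + 1.3 * np.arange(12)
    n_rep = 300
    multi, two = [], []
    for _ in range(n_rep):
        noise = rng.normal(0.0, 0.05, size=(1, 1, 1, 12))
        phases = 2 * np.pi * 50.0 * tes / 1000.0 + noise
        series = PhaseSeries(phases=wrap_phase(phases), echo_times=tes)
        multi.append(frequency_from_multiecho(series).dnu[0, 0, 0])
        pair = PhaseSeries(phases=series.phases[..., [0, -1]],
                           echo_times=tes[[0, -1]])
        two.append(frequency_from_two_echoes(pair).dnu[0, 0, 0])
    assert np.std(multi) < np.std(two)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def test_smoothing_preserves_constant_fields():
    fm = FieldMap(dnu=np.full((8, 8, 10), 42.0), voxel_size=(1.0, 1.0, 1.0))
    assert np.allclose(smooth_fieldmap(fm, 1.0).dnu, 42.0, atol=1e-10)


def test_smoothing_leaves_linear_field_unchanged_in_interior():
    z = np.arange(30, dtype=float)
    dnu = np.broadcast_to(3.0 * z, (10, 10, 30)).copy()
    fm = FieldMap(dnu=dnu, voxel_size=(1.0, 1.0, 1.0))
    sm = smooth_fieldmap(fm, 1.0).dnu
    interior = (slice(5, -5),) * 3
    assert np.allclose(sm[interior], dnu[interior], atol=1e-8)


def test_smoothing_conserves_impulse_mass():
    dnu = np.zeros((15, 15, 15))
    dnu[7, 7, 7] = 1.0
    sm = smooth_fieldmap(FieldMap(dnu=dnu, voxel_size=(1.0, 1.0, 1.0)),
                         1.0).dnu
    assert sm.sum() == pytest.approx(1.0, abs=1e-6)
    assert sm[7, 7, 7] < 1.0


# ---------------------------------------------------------------------------
# Slice-wise basis fitting
# ---------------------------------------------------------------------------

def _linear_fieldmap(a, b, c, d, shape=(12, 12, 17), z0=-3.0):
    """dnu = a*x + b*y + c*z + d on a 1 mm grid (slopes in Hz/mm)."""
    x = np.arange(shape[0], dtype=float)
    y = np.arange(shape[1], dtype=float)
    z = z0 + np.arange(shape[2], dtype=float)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return FieldMap(dnu=a * X + b * Y + c * Z + d,
                    voxel_size=(1.0, 1.0, 1.0), z0=z0)


def _single_slice_params():
    return AcquisitionParams(te=40.0, slice_thickness=5.0, n_slices=1)


def test_fit_recovers_exact_linear_field():
    fm = _linear_fieldmap(1.7, -0.4, 3.3, 11.0)
    rng = np.random.default_rng(0)
    mask = rng.uniform(size=fm.dnu.shape) < 0.4
    fit = fit_slicewise_basis(fm, mask, 0, _single_slice_params())
    assert fit.valid
    assert fit.gz == pytest.approx(3.3 / HZ_PER_MM_PER_MT_M, rel=1e-10)
    assert fit.gx == pytest.approx(1.7 / HZ_PER_MM_PER_MT_M, rel=1e-10)
    assert fit.gy == pytest.approx(-0.4 / HZ_PER_MM_PER_MT_M, rel=1e-10)
    assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)


def test_fit_constant_field_gives_zero_slopes():
    fm = _linear_fieldmap(0.0, 0.0, 0.0, 25.0)
    mask = np.ones(fm.dnu.shape, dtype=bool)
    fit = fit_slicewise_basis(fm, mask, 0, _single_slice_params())
    assert (fit.gx, fit.gy, fit.gz) == pytest.approx((0.0, 0.0, 0.0),
                                                     abs=1e-12)
    assert fit.offset_hz == pytest.approx(25.0)


def test_fit_unit_bridge():
    """A 42.577 Hz/mm through-slice slope is exactly a 1 mT/m gradient."""
    fm = _linear_fieldmap(0.0, 0.0, HZ_PER_MM_PER_MT_M, 0.0)
    mask = np.ones(fm.dnu.shape, dtype=bool)
    fit = fit_slicewise_basis(fm, mask, 0, _single_slice_params())
    assert fit.gz == pytest.approx(1.0, rel=1e-12)


def test_fit_matches_normal_equations_oracle():
    """OLS fit equals a brute-force normal-equations solve on random slabs."""
    rng = np.random.default_rng(9)
    params = _single_slice_params()
    for _ in range(50):
        fm = FieldMap(dnu=rng.normal(0.0, 20.0, size=(8, 8, 11)),
                      voxel_size=(1.0, 1.0, 1.0), z0=-2.0)
        mask = rng.uniform(size=fm.dnu.shape) < 0.5
        if mask.sum() < 8:
            continue
        fit = fit_slicewise_basis(fm, mask, 0, params)
        ix, iy, iz = np.nonzero(mask & (np.abs(fm.z_coords - 2.5)
                                        <= 4.5 + 1e-9)[None, None, :])
        coords = np.column_stack([ix * 1.0, iy * 1.0, fm.z_coords[iz]])
        coords -= coords.mean(axis=0)
        A = np.column_stack([coords, np.ones(len(ix))])
        beta = np.linalg.solve(A.T @ A, A.T @ fm.dnu[mask & (
            np.abs(fm.z_coords - 2.5) <= 4.5 + 1e-9)[None, None, :]])
        assert fit.gz == pytest.approx(beta[2] / HZ_PER_MM_PER_MT_M, rel=1e-8)
        assert fit.offset_hz == pytest.approx(beta[3], rel=1e-8)


def test_fit_flags_underdetermined_slab():
    fm = _linear_fieldmap(1.0, 1.0, 1.0, 0.0)
    mask = np.zeros(fm.dnu.shape, dtype=bool)
    mask[3, 3, 8] = True  # one voxel only
    fit = fit_slicewise_basis(fm, mask, 0, _single_slice_params())
    assert not fit.valid


def test_fit_flags_rank_deficient_design():
    fm = _linear_fieldmap(1.0, 0.0, 2.0, 0.0)
    mask = np.zeros(fm.dnu.shape, dtype=bool)
    mask[4, 4, 6:10] = True  # a single column: x and y do not vary
    fit = fit_slicewise_basis(fm, mask, 0, _single_slice_params())
    assert not fit.valid


def test_select_fm_zero_gradient_everywhere(grid21, params):
    fits = [SliceFit(s, 0.0, 0.0, 0.0, 5.0, 100, 0.1)
            for s in range(params.n_slices)]
    sel = select_zshim_fm(fits, grid21, params)
    assert np.all(sel.indices == 11)
    assert sel.method == "fm_fit"


def test_select_fm_clamps_out_of_range_gradient(grid21, params):
    fits = [SliceFit(0, 0.0, 0.0, 0.30, 0.0, 100, 0.1)]
    p1 = AcquisitionParams(n_slices=1)
    sel = select_zshim_fm(fits, grid21, p1)
    assert sel.indices[0] == 1
    assert any("clamped" in w for w in sel.warnings)


def test_select_fm_failed_slice_falls_back_to_neutral(grid21):
    fits = [SliceFit.failed(0), SliceFit(1, 0.0, 0.0, 0.042, 0.0, 50, 0.1)]
    p2 = AcquisitionParams(n_slices=2)
    sel = select_zshim_fm(fits, grid21, p2)
    assert sel.indices[0] == 11
    assert sel.indices[1] == 9
    assert any("fallback" in w or "falling back" in w for w in sel.warnings)


# ---------------------------------------------------------------------------
# Histogram gradient estimator
# ---------------------------------------------------------------------------

def _column_slope_fieldmap(slopes_hz_per_mm, nz=9, z0=-1.5):
    """Each in-plane column gets its own exact through-slice slope."""
    slopes = np.asarray(slopes_hz_per_mm)
    z = z0 + np.arange(nz, dtype=float)
    dnu = slopes[:, :, None] * z[None, None, :]
    return FieldMap(dnu=dnu, voxel_size=(1.0, 1.0, 1.0), z0=z0)


def test_histogram_exact_on_linear_field():
    g_true = 0.08  # mT/m
    fm = _column_slope_fieldmap(np.full((6, 6), g_true * HZ_PER_MM_PER_MT_M))
    mask = np.ones(fm.dnu.shape, dtype=bool)
    est = histogram_gradient(fm, mask, 0, _single_slice_params())
    assert est == pytest.approx(g_true, rel=1e-12)


def test_histogram_zero_on_constant_field():
    fm = FieldMap(dnu=np.full((6, 6, 9), 13.0), voxel_size=(1.0, 1.0, 1.0),
                  z0=-1.5)
    mask = np.ones(fm.dnu.shape, dtype=bool)
    assert histogram_gradient(fm, mask, 0, _single_slice_params()) == 0.0


def test_histogram_resists_outlier_contamination():
    """90% of columns at 0.05 mT/m, 10% at 0.20: the histogram estimate
    stays within one bin width of the bulk value while the plain mean is
    dragged to ~0.065."""
    rng = np.random.default_rng(4)
    slopes_mt = np.where(rng.uniform(size=(10, 10)) < 0.10, 0.20, 0.05)
    # force the intended 10% contamination exactly
    flat = slopes_mt.ravel()
    flat[:] = 0.05
    flat[rng.choice(flat.size, size=10, replace=False)] = 0.20
    fm = _column_slope_fieldmap(slopes_mt * HZ_PER_MM_PER_MT_M)
    mask = np.ones(fm.dnu.shape, dtype=bool)
    params = _single_slice_params()
    est = histogram_gradient(fm, mask, 0, params, n_bins=21)
    bin_width = (0.20 - 0.05) / 21
    assert abs(est - 0.05) <= bin_width
    plain_mean = slopes_mt.mean()
    assert plain_mean == pytest.approx(0.065, abs=1e-12)
    assert abs(est - 0.05) < abs(plain_mean - 0.05)


def test_histogram_error_never_exceeds_ls_error_on_mixture_family():
    """On the contaminated-mixture family the mode-centered estimate is at
    least as close to the bulk gradient as the least-squares fit, for every
    seed."""
    params = _single_slice_params()
    for seed in range(10):
        rng = np.random.default_rng(seed)
        slopes_mt = np.full((10, 10), 0.05)
        slopes_mt.ravel()[rng.choice(100, size=10, replace=False)] = 0.20
        fm = _column_slope_fieldmap(slopes_mt * HZ_PER_MM_PER_MT_M)
        mask = np.ones(fm.dnu.shape, dtype=bool)
        est = histogram_gradient(fm, mask, 0, params)
        fit = fit_slicewise_basis(fm, mask, 0, params)
        assert abs(est - 0.05) <= abs(fit.gz - 0.05) + 1e-12


def test_histogram_flags_insufficient_voxels():
    fm = _column_slope_fieldmap(np.full((4, 4), 1.0))
    mask = np.zeros(fm.dnu.shape, dtype=bool)
    mask[0, 0, 4] = True
    assert histogram_gradient(fm, mask, 0, _single_slice_params()) is None


# ---------------------------------------------------------------------------
# End-to-end field-map pipeline on the synthetic phantom
# ---------------------------------------------------------------------------

def test_table_mode_field_fit_recovery(grid21, params, phantom_spec,
                                       ongrid_scenario, fm_grid):
    from zshim import make_field, sim

    shape, voxel, z0 = fm_grid
    fm = make_field(ongrid_scenario["field"], shape, voxel, z0, params)
    mask = sim.cylinder_mask(shape, voxel, phantom_spec.cord_center,
                             phantom_spec.cord_radius)
    fits = fit_all_slices(fm, mask, params)
    sel = select_zshim_fm(fits, grid21, params)
    assert all(f.valid for f in fits)
    assert np.array_equal(sel.indices, ongrid_scenario["indices"])
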