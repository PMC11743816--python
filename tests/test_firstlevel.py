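"""First-level GLM building blocks against closed-form and hand oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facehouse.core import VolumeSeries
from facehouse.firstlevel import (
    CONTRASTS,
    ContrastSpec,
    DesignMatrix,
    SignalMask,
    build_design_matrix,
    compute_contrast,
    compute_signal_mask,
    fit_glm,
    framewise_displacement,
    smooth_volume,
)
from facehouse.hrf import condition_regressor, sampled_hrf


def _series(data, realignment=None):
    data = np.asarray(data, dtype=float)
    if realignment is None:
        realignment = np.zeros((data.shape[3], 6))
    return VolumeSeries(
        data=data, voxel_size=(2.5, 2.5, 2.5), affine=np.eye(4), realignment=realignment
    )


# ---------------------------------------------------------------- mask


def test_uniform_series_fully_included():
    s = _series(np.full((6, 6, 4, 10), 50.0))
    m = compute_signal_mask(s, 0.8)
    assert m.include.all()
    assert not m.has_holes


def test_interior_low_signal_blob_is_hole():
    data = np.full((8, 8, 6, 5), 100.0)
    data[3:5, 3:5, 2:4, :] = 50.0  # 50% of global mean, interior
    m = compute_signal_mask(_series(data), 0.8)
    assert not m.include[3, 3, 2]
    assert m.has_holes


def test_border_touching_exclusion_is_not_hole():
    data = np.full((8, 8, 6, 5), 100.0)
    data[0:2, 0:2, :, :] = 10.0  # corner slab touching the border
    m = compute_signal_mask(_series(data), 0.8)
    assert not m.include[0, 0, 0]
    assert not m.has_holes


def test_mask_fraction_precondition():
    s = _series(np.full((4, 4, 4, 3), 1.0))
    with pytest.raises(ValueError):
        compute_signal_mask(s, 0.0)
    with pytest.raises(ValueError):
        compute_signal_mask(_series(np.zeros((4, 4, 4, 3))), 0.8)


@given(st.integers(0, 2**31 - 1))
def test_mask_monotone_in_fraction(seed):
    rng = np.random.default_rng(seed)
    data = rng.gamma(2.0, 50.0, (6, 6, 4, 5))
    s = _series(data)
    lo = compute_signal_mask(s, 0.5).include
    hi = compute_signal_mask(s, 0.9).include
    assert (hi <= lo).all()  # raising the fraction never adds voxels


# ------------------------------------------------------- design matrix


def test_no_events_no_motion_gives_dct_plus_intercept():
    X = build_design_matrix(None, None, 1.0, 389, 128.0)
    assert X.names == [f"dct_{k}" for k in range(1, 7)] + ["intercept"]


def test_dct_column_count_formula():
    X = build_design_matrix(None, None, 1.0, 389, 128.0)
    n_dct = sum(n.startswith("dct_") for n in X.names)
    assert n_dct == int(np.floor(2 * 389 * 1.0 / 128.0))


def test_single_sequence_regressor_integral():
    """The time-integral of an 18 s sequence column equals 18 x the HRF
    integral (quadrature on the oversampled grid)."""
    tr, n = 1.0, 200
    reg = condition_regressor([(20.0, 18.0)], tr, n)
    dt = tr / 20
    hrf = sampled_hrf(dt)
    assert hrf.sum() * dt == pytest.approx(1.0, abs=1e-9)
    assert reg.sum() * tr == pytest.approx(18.0, rel=1e-3)


def test_design_matrix_full_rank_and_shape(default_design):
    realign = np.random.default_rng(0).normal(0, 0.05, (389, 6))
    X = build_design_matrix(default_design, realign, 1.0, 389)
    assert X.values.shape == (389, 4 + 6 + 6 + 1)
    assert np.linalg.matrix_rank(X.values) == X.values.shape[1]


def test_duplicated_column_rank_error(default_design):
    realign = np.ones((389, 6))  # constant columns collide with intercept
    with pytest.raises(ValueError, match="rank"):
        build_design_matrix(default_design, realign, 1.0, 389)


# ----------------------------------------------------------------- GLM


def test_glm_matches_normal_equations_oracle():
    """3-voxel fixture vs the closed-form normal-equations solution."""
    rng = np.random.default_rng(7)
    T = 40
    X = np.column_stack([rng.normal(size=T), np.ones(T)])
    dm = DesignMatrix(values=X, names=["a", "intercept"])
    Y = rng.normal(size=(3, 1, 1, T))
    s = _series(Y)
    mask = SignalMask(
        include=np.ones((3, 1, 1), bool), global_fraction=0.8, has_holes=False
    )
    glm = fit_glm(s, dm, mask)
    for v in range(3):
        beta = np.linalg.solve(X.T @ X, X.T @ Y[v, 0, 0])
        assert glm.betas["a"][v, 0, 0] == pytest.approx(beta[0], abs=1e-8)
        resid = Y[v, 0, 0] - X @ beta
        assert glm.sigma2[v, 0, 0] == pytest.approx(
            resid @ resid / (T - 2), abs=1e-8
        )


def test_glm_too_few_frames_rejected():
    X = DesignMatrix(values=np.ones((2, 3)), names=["a", "b", "c"])
    s = _series(np.ones((2, 2, 2, 2)))
    m = compute_signal_mask(s, 0.5)
    with pytest.raises(ValueError, match="fewer frames"):
        fit_glm(s, X, m)


def test_frame_permutation_breaks_recovery(default_design):
    """Shuffling frames against a fixed design destroys the planted
    amplitude (sanity anti-test for the forward model)."""
    from facehouse.bold import Blob, ScanConfig, simulate_bold

    scan = ScanConfig(
        grid_dims=(8, 8, 6),
        n_volumes=340,
        noise_sd=0.0,
        drift_amplitude=0.0,
        blobs=[Blob((4, 4, 3), 2.0, {"happy": 1.0})],
        seed=1,
    )
    series, truth = simulate_bold(default_design, scan)
    perm = np.random.default_rng(0).permutation(340)
    shuffled = _series(series.data[..., perm])
    mask = compute_signal_mask(shuffled)
    X = build_design_matrix(default_design, None, 1.0, 340)
    glm = fit_glm(shuffled, X, mask)
    blob = truth.amplitude_maps["happy"] > 0
    assert np.nanmax(np.abs(glm.betas["happy"][blob] - 1.0)) > 0.5


# ------------------------------------------------------------ contrast


def test_contrast_identity_and_linearity(default_design):
    from facehouse.bold import ScanConfig, simulate_bold

    scan = ScanConfig(grid_dims=(6, 6, 4), n_volumes=340, seed=3)
    series, _ = simulate_bold(default_design, scan)
    mask = compute_signal_mask(series)
    X = build_design_matrix(default_design, None, 1.0, 340)
    glm = fit_glm(series, X, mask)
    single = compute_contrast(glm, ContrastSpec("happy", {"happy": 1.0})).values
    assert np.allclose(single[mask.include], glm.betas["happy"][mask.include])
    c1 = CONTRASTS["happy>neutral"]
    c2 = CONTRASTS["fearful>neutral"]
    combo = ContrastSpec(
        "combo", {"happy": 2.0, "neutral": -2.0 + 3.0 * -1.0, "fearful": 3.0}
    )
    expected = 2.0 * compute_contrast(glm, c1).values + 3.0 * compute_contrast(glm, c2).values
    got = compute_contrast(glm, combo).values
    assert np.allclose(got[mask.include], expected[mask.include], atol=1e-10)


def test_unknown_regressor_rejected(default_design):
    from facehouse.bold import ScanConfig, simulate_bold

    scan = ScanConfig(grid_dims=(4, 4, 4), n_volumes=340, seed=3)
    series, _ = simulate_bold(default_design, scan)
    mask = compute_signal_mask(series)
    X = build_design_matrix(default_design, None, 1.0, 340)
    glm = fit_glm(series, X, mask)
    with pytest.raises(ValueError, match="unknown regressor"):
        compute_contrast(glm, ContrastSpec("bad", {"sadness": 1.0}))


# ----------------------------------------------------------- smoothing


def test_smooth_fwhm_zero_is_identity(rng):
    img = rng.normal(size=(8, 8, 8))
    assert smooth_volume(img, 0.0, (2.5, 2.5, 2.5)) is img


def test_smooth_delta_matches_analytic_gaussian():
    img = np.zeros((15, 15, 15))
    img[7, 7, 7] = 1.0
    fwhm, vox = 6.0, 2.0
    out = smooth_volume(img, fwhm, (vox, vox, vox))
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
    g = np.arange(15) - 7.0
    k1 = np.exp(-(g**2) / (2 * sigma**2))
    k1 /= k1.sum()
    expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    assert np.max(np.abs(out - expected)) < 1e-6


def test_smooth_preserves_mass_interior(rng):
    img = np.zeros((20, 20, 20))
    img[8:12, 8:12, 8:12] = rng.normal(size=(4, 4, 4))
    out = smooth_volume(img, 4.0, (2.5, 2.5, 2.5))
    assert out.sum() == pytest.approx(img.sum(), abs=1e-6)


def test_smooth_constant_interior_preserved():
    img = np.ones((20, 20, 20))
    out = smooth_volume(img, 8.0, (2.5, 2.5, 2.5))
    assert np.allclose(out[8:12, 8:12, 8:12], 1.0, atol=1e-6)


# ------------------------------------------------- framewise displacement


def test_fd_zero_motion():
    m = framewise_displacement(np.zeros((50, 6)))
    assert np.all(m.fd == 0)
    assert m.low_motion


def test_fd_single_translation_step():
    r = np.zeros((10, 6))
    r[5:, 0] = 1.0  # 1 mm x-translation between frames 4 and 5
    m = framewise_displacement(r)
    assert m.fd[5] == pytest.approx(1.0)
    assert m.fd[4] == 0.0


def test_fd_rotation_radius_scaling():
    r = np.zeros((3, 6))
    r[1:, 3] = 0.01  # 0.01 rad about x
    m = framewise_displacement(r, radius_mm=50.0)
    assert m.fd[1] == pytest.approx(0.5)


def test_fd_35_percent_high_is_not_low_motion():
    n = 100
    r = np.zeros((n, 6))
    # 35 alternating jumps of 0.5 mm -> 35% of frames exceed 0.3 mm
    for i, f in enumerate(range(2, 72, 2)):
        r[f:, 0] += 0.5 * (-1) ** i
    m = framewise_displacement(r)
    assert m.frac_high == pytest.approx(0.35)
    assert not m.low_motion


@given(st.floats(-10, 10), st.integers(0, 2**31 - 1))
def test_fd_invariant_to_constant_offset(offset, seed):
    rng = np.random.default_rng(seed)
    r = rng.normal(0, 0.1, (20, 6))
    a = framewise_displacement(r).fd
    b = framewise_displacement(r + offset).fd
    assert np.allclose(a, b, atol=1e-12)


def test_fd_wrong_columns_rejected():
    with pytest.raises(ValueError):
        framewise_displacement(np.zeros((10, 5)))
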