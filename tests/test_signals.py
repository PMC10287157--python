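"""Feature extraction: binning, artifact removal, filtering, peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fingerctx as fc
from fingerctx.session import BinnedFeatures, ContinuousStreams
from fingerctx.signals import PeakMovement


def _streams(sbp, counts=None):
    sbp = np.asarray(sbp, dtype=float)
    if counts is None:
        counts = np.full(sbp.shape, 2, dtype=np.int8)
    return ContinuousStreams(
        sbp_1ms=sbp, raw_sample_count_1ms=counts,
        crossing_times=[np.array([], dtype=int)] * sbp.shape[1],
        finger_position=np.full((sbp.shape[0], 2), 50.0))


# ---------------------------------------------------------------------------
# SBP / TCFR binning
# ---------------------------------------------------------------------------

def test_bin_sbp_constant_amplitude_identity():
    """Constant rectified amplitude a on every sample gives bins == a."""
    s = _streams(np.full((320, 3), 2 * 1.7))   # per-ms sum of two samples of 1.7
    out = fc.bin_sbp(s, 32)
    np.testing.assert_allclose(out.values, 1.7)
    assert out.n_bins == 10


def test_bin_sbp_matches_loop_oracle():
    rng = np.random.default_rng(5)
    sbp = rng.random((397, 4))
    counts = rng.integers(0, 3, size=(397, 4)).astype(np.int8)
    s = _streams(sbp, counts)
    out = fc.bin_sbp(s, 20)
    for b in range(out.n_bins):
        for ch in range(4):
            num = sbp[b * 20:(b + 1) * 20, ch].sum()
            den = counts[b * 20:(b + 1) * 20, ch].sum()
            expect = num / den if den else 0.0
            assert abs(out.values[b, ch] - expect) < 1e-12
    # trailing partial bin dropped, never padded
    assert out.n_bins == 397 // 20


def test_bin_sbp_bin_starts_on_grid():
    s = _streams(np.ones((200, 2)))
    out = fc.bin_sbp(s, 50)
    np.testing.assert_array_equal(out.bin_start_times_ms, [0, 50, 100, 150])


def test_bin_tcfr_rate_arithmetic():
    """3 events in one 20 ms bin = 150 Hz; empty channel stays zero."""
    out = fc.bin_tcfr([[3, 7, 12], []], 20, n_ms=40)
    assert out.values[0, 0] == pytest.approx(150.0)
    assert out.values[1, 0] == 0.0
    np.testing.assert_array_equal(out.values[:, 1], 0.0)


def test_bin_tcfr_poisson_rate_recovery():
    """Poisson events at 30 Hz over 100 s recover the rate within 3 SE."""
    rng = np.random.default_rng(11)
    n_ms = 100_000
    events = np.flatnonzero(rng.random(n_ms) < 30.0 / 1000)
    out = fc.bin_tcfr([events], 50, n_ms=n_ms)
    se = np.sqrt(30.0 / 100.0)
    assert abs(out.values.mean() - 30.0) < 3 * se


# ---------------------------------------------------------------------------
# Artifact removal
# ---------------------------------------------------------------------------

def test_remove_artifacts_threshold_boundary():
    """19 coincident channels keep their events; 20 clear the millisecond."""
    t = 55
    below = [[t] for _ in range(19)] + [[] for _ in range(5)]
    out = fc.remove_artifacts(below)
    assert all(len(c) == 1 for c in out[:19])
    at = [[t] for _ in range(20)] + [[] for _ in range(4)]
    out = fc.remove_artifacts(at)
    assert all(len(c) == 0 for c in out[:20])


def test_remove_artifacts_planted_recovery_and_idempotence():
    rng = np.random.default_rng(3)
    n_ch, n_ms = 30, 5_000
    crossings = [np.flatnonzero(rng.random(n_ms) < 0.01) for _ in range(n_ch)]
    artifact_ticks = [123, 1234, 4321]
    planted = [np.union1d(c, artifact_ticks) for c in crossings]
    cleaned = fc.remove_artifacts(planted)
    for c in cleaned:
        assert not np.isin(artifact_ticks, c).any()
    # only artifact ticks removed (background coincidences are improbable)
    total_removed = sum(len(p) - len(c) for p, c in zip(planted, cleaned))
    assert total_removed == n_ch * len(artifact_ticks)
    twice = fc.remove_artifacts(cleaned)
    for a, b in zip(cleaned, twice):
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# EMG envelope
# ---------------------------------------------------------------------------

def test_emg_envelope_passband_sinusoid_mean_abs():
    """A 300 Hz tone of amplitude A has envelope 2A/pi after the transient."""
    t = np.arange(100_000) / 10_000.0
    A = 3.0
    emg = (A * np.sin(2 * np.pi * 300 * t))[:, None]
    out = fc.emg_envelope(emg, 50)
    settled = out.values[out.n_bins // 2:, 0]
    assert np.abs(settled.mean() - 2 * A / np.pi) / (2 * A / np.pi) < 0.05


def test_emg_envelope_stopband_attenuation():
    """A 10 Hz tone is attenuated more than 20x relative to passband."""
    t = np.arange(100_000) / 10_000.0
    pass_out = fc.emg_envelope(np.sin(2 * np.pi * 300 * t)[:, None], 50)
    stop_out = fc.emg_envelope(np.sin(2 * np.pi * 10 * t)[:, None], 50)
    p = pass_out.values[pass_out.n_bins // 2:, 0].mean()
    s = stop_out.values[stop_out.n_bins // 2:, 0].mean()
    assert p / s > 20


def test_emg_envelope_zero_input_and_short_input():
    out = fc.emg_envelope(np.zeros((20_000, 2)), 20)
    np.testing.assert_allclose(out.values, 0.0)
    with pytest.raises(ValueError, match="warm-up"):
        fc.emg_envelope(np.zeros((10, 2)), 20)


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def _binned(values, bin_ms=20):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    return BinnedFeatures(values, bin_ms, np.arange(values.shape[0]) * bin_ms,
                          np.ones(values.shape[1], bool), "sbp")


def test_gaussian_smooth_impulse_is_unit_kernel():
    x = np.zeros(101)
    x[50] = 1.0
    out = fc.gaussian_smooth(_binned(x), 100.0)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
    assert out.values[50, 0] == out.values.max()


def test_gaussian_smooth_preserves_constants():
    out = fc.gaussian_smooth(_binned(np.full(60, 3.3)), 100.0)
    np.testing.assert_allclose(out.values, 3.3, atol=1e-12)


def test_gaussian_smooth_white_noise_variance_reduction():
    """Smoothing shrinks white-noise variance by the kernel sum-of-squares."""
    sigma_bins = 100.0 / 20.0
    half = int(np.ceil(3 * sigma_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_bins) ** 2)
    k /= k.sum()
    factor = (k ** 2).sum()
    rng = np.random.default_rng(8)
    x = rng.standard_normal(40_000)
    out = fc.gaussian_smooth(_binned(x), 100.0)
    interior = out.values[half:-half, 0]
    assert abs(interior.var() / factor - 1) < 0.1


# ---------------------------------------------------------------------------
# Kinematic conditioning
# ---------------------------------------------------------------------------

def test_savgol_velocity_exact_on_polynomials():
    t_ms = np.arange(2000)
    ramp = 0.02 * t_ms                      # slope 20 %/s
    pos, vel = fc.savgol_velocity(np.column_stack([ramp, ramp]))
    np.testing.assert_allclose(vel[3:-3], 20.0, rtol=1e-9)
    quad = 1e-5 * t_ms ** 2                 # derivative 2e-5 * t (%/ms)
    _, velq = fc.savgol_velocity(np.column_stack([quad, quad]))
    expect = 2e-5 * t_ms[::20] * 1000.0
    np.testing.assert_allclose(velq[3:-3, 0], expect[3:-3], rtol=1e-6)


def test_savgol_minimum_jerk_peak_speed_closed_form():
    """Peak speed of a minimum-jerk reach is within 2% of 15A/(8T)."""
    from fingerctx.synth import min_jerk
    A, T = 40.0, 500
    trace = np.concatenate([np.zeros(300), min_jerk(A, T), np.full(300, A)])
    pos, vel = fc.savgol_velocity(np.column_stack([trace, trace]))
    peak = np.abs(vel[:, 0]).max()
    expect = 15 * A / (8 * (T / 1000.0))
    assert abs(peak - expect) / expect < 0.02


def test_find_peak_movement_largest_peak_rule():
    bins = np.zeros(100)
    bins[20:25] = [1, 3, 5, 3, 1]
    bins[60:65] = [2, 6, 9, 6, 2]           # later but larger peak wins
    pk = fc.find_peak_movement(np.column_stack([bins, np.zeros(100)]))
    assert pk.peak_bin_index == 62
    assert not pk.degenerate


def test_find_peak_movement_monotone_trace_flagged():
    ramp = np.linspace(0, 10, 50)
    pk = fc.find_peak_movement(np.column_stack([ramp, ramp]))
    assert pk.degenerate
    assert pk.peak_bin_index == 49


def test_peri_movement_average_window_and_oracle():
    rng = np.random.default_rng(2)
    vals = rng.random((60, 5))
    b = _binned(vals)
    out = fc.peri_movement_average(b, peak_bin=30)
    np.testing.assert_allclose(out, vals[20:41].mean(axis=0), atol=1e-14)
    # 21 bins of 20 ms = the 420 ms peri-movement window
    assert (10 + 1 + 10) * b.bin_width_ms == 420
    with pytest.raises(IndexError):
        fc.peri_movement_average(b, peak_bin=5)


def test_compare_groups_basics():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(200)
    stat, p, ci = fc.compare_groups(a, a, kind="two_sample_t")
    assert stat == pytest.approx(0.0, abs=1e-12)
    _, p_ks, _ = fc.compare_groups(a, a, kind="ks_two_sample")
    assert p_ks == pytest.approx(1.0)
    _, p_sep, _ = fc.compare_groups(a + 10.0, a, kind="two_sample_t")
    assert p_sep < 1e-10
    with pytest.raises(ValueError, match="degenerate"):
        fc.compare_groups(np.ones(5), np.ones(5), kind="two_sample_t")


def test_compare_groups_ci_coverage():
    """99% CI of a planted shift covers it at roughly the nominal rate."""
    rng = np.random.default_rng(42)
    delta, covered, reps = 0.3, 0, 300
    for _ in range(reps):
        a = rng.standard_normal(300) + delta
        b = rng.standard_normal(300)
        _, _, ci = fc.compare_groups(a, b, kind="two_sample_t", ci_level=0.99)
        covered += ci[0] <= delta <= ci[1]
    assert covered / reps > 0.97


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_binning_commutes_with_additive_constants(seed):
    """gaussian_smooth and savgol shift by c when the input shifts by c."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(80)
    c = float(rng.uniform(-5, 5))
    s0 = fc.gaussian_smooth(_binned(x), 100.0).values
    s1 = fc.gaussian_smooth(_binned(x + c), 100.0).values
    np.testing.assert_allclose(s1, s0 + c, atol=1e-9)
    p = np.cumsum(rng.standard_normal(1000)) * 0.01 + 50
    v0 = fc.savgol_velocity(np.column_stack([p, p]))[1]
    v1 = fc.savgol_velocity(np.column_stack([p + c, p + c]))[1]
    np.testing.assert_allclose(v0, v1, atol=1e-9)
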