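"""Feature extraction and behavioral-signal conditioning.

Spiking-band power (SBP) arrives as per-millisecond rectified sums of the
300-1000 Hz band together with the count of 2 kHz samples behind each sum;
binning divides the summed amplitude by the summed sample count so the bin
value is a mean rectified amplitude. Threshold-crossing firing rate (TCFR)
is events per bin divided by bin width. EMG is band-passed 100-500 Hz and
rectified-averaged per bin. Kinematic conditioning (Savitzky-Golay
smoothing and differentiation, peak-speed detection, peri-movement
averaging) runs on a 20 ms grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .session import BinnedFeatures, ContinuousStreams

logger = logging.getLogger("fingerctx")

VALID_BIN_WIDTHS = (20, 32, 50)


@dataclass
class PeakMovement:
    """Location and size of the largest speed peak after trial start."""

    peak_time_ms: int
    peak_bin_index: int          # index on the 20 ms grid
    peak_speed: float            # %/s, Euclidean norm over active groups
    degenerate: bool = False     # True when no local peak existed


# ---------------------------------------------------------------------------
# Neural feature binning
# ---------------------------------------------------------------------------

def bin_sbp(streams: ContinuousStreams, bin_width_ms: int) -> BinnedFeatures:
    """Bin per-ms SBP sums into mean rectified amplitude per bin.

    Each bin value is the sum of the per-ms rectified sums divided by the
    total number of raw 2 kHz samples in the bin. A trailing partial bin
    is discarded; a bin with zero raw samples yields 0 with a warning.
    """
    _check_bin_width(bin_width_ms)
    n_ms, n_ch = streams.sbp_1ms.shape
    n_bins = n_ms // bin_width_ms
    if n_bins < 1:
        raise ValueError(f"stream of {n_ms} ms shorter than one {bin_width_ms} ms bin")
    t = n_bins * bin_width_ms
    sums = streams.sbp_1ms[:t].reshape(n_bins, bin_width_ms, n_ch).sum(axis=1)
    counts = streams.raw_sample_count_1ms[:t].reshape(n_bins, bin_width_ms, n_ch).sum(axis=1)
    empty = counts == 0
    if empty.any():
        logger.warning("bin_sbp: %d bins had zero raw samples; set to 0", int(empty.sum()))
    values = np.divide(sums, counts, out=np.zeros_like(sums, dtype=float), where=~empty)
    return BinnedFeatures(
        values=values,
        bin_width_ms=bin_width_ms,
        bin_start_times_ms=np.arange(n_bins) * bin_width_ms + streams.time_offset_ms,
        channel_mask=np.ones(n_ch, dtype=bool),
        feature_kind="sbp",
    )


def bin_tcfr(
    crossings: list,
    bin_width_ms: int,
    n_ms: int,
    time_offset_ms: int = 0,
) -> BinnedFeatures:
    """Threshold-crossing rate per bin in Hz (count / bin width)."""
    _check_bin_width(bin_width_ms)
    n_bins = n_ms // bin_width_ms
    if n_bins < 1:
        raise ValueError(f"stream of {n_ms} ms shorter than one {bin_width_ms} ms bin")
    edges = np.arange(n_bins + 1) * bin_width_ms
    values = np.empty((n_bins, len(crossings)))
    for ch, times in enumerate(crossings):
        counts, _ = np.histogram(np.asarray(times), bins=edges)
        values[:, ch] = counts / (bin_width_ms / 1000.0)
    return BinnedFeatures(
        values=values,
        bin_width_ms=bin_width_ms,
        bin_start_times_ms=edges[:-1] + time_offset_ms,
        channel_mask=np.ones(len(crossings), dtype=bool),
        feature_kind="tcfr",
    )


def remove_artifacts(crossings: list, coincidence_threshold: int = 20) -> list:
    """Drop every crossing in any millisecond where >= 20 channels fired.

    Simultaneous threshold crossings across that many electrodes are
    electrical artifacts, not spikes; the whole millisecond is cleared on
    all channels. Idempotent.
    """
    if not crossings:
        return []
    all_times = np.concatenate([np.asarray(t, dtype=np.int64) for t in crossings]) \
        if any(len(t) for t in crossings) else np.array([], dtype=np.int64)
    if all_times.size == 0:
        return [np.asarray(t, dtype=np.int64) for t in crossings]
    # count distinct channels per ms tick
    ticks = []
    for t in crossings:
        ticks.append(np.unique(np.asarray(t, dtype=np.int64)))
    counted = np.concatenate(ticks)
    uniq, counts = np.unique(counted, return_counts=True)
    bad = set(uniq[counts >= coincidence_threshold].tolist())
    cleaned = []
    for t in crossings:
        t = np.asarray(t, dtype=np.int64)
        if bad:
            t = t[~np.isin(t, list(bad))]
        cleaned.append(t)
    return cleaned


def emg_envelope(
    emg_10khz: np.ndarray,
    bin_width_ms: int,
    fs_hz: float = 10_000.0,
    zero_phase: bool = False,
) -> BinnedFeatures:
    """Muscle-activation envelope: 100-500 Hz band-pass then per-bin mean |x|.

    The second-order Butterworth band-pass is applied causally by default,
    as online acquisition hardware would; ``zero_phase=True`` switches to
    forward-backward filtering for offline parity studies.
    """
    _check_bin_width(bin_width_ms)
    emg = np.atleast_2d(np.asarray(emg_10khz, dtype=float))
    if emg.shape[0] == 1 and emg.size > emg.shape[1]:
        emg = emg.T
    samples_per_bin = int(round(bin_width_ms * fs_hz / 1000.0))
    if emg.shape[0] < max(3 * samples_per_bin, 64):
        raise ValueError("EMG stream shorter than filter warm-up")
    sos = sps.butter(2, [100.0, 500.0], btype="bandpass", fs=fs_hz, output="sos")
    filt = sps.sosfiltfilt(sos, emg, axis=0) if zero_phase else sps.sosfilt(sos, emg, axis=0)
    n_bins = emg.shape[0] // samples_per_bin
    t = n_bins * samples_per_bin
    mav = np.abs(filt[:t]).reshape(n_bins, samples_per_bin, emg.shape[1]).mean(axis=1)
    return BinnedFeatures(
        values=mav,
        bin_width_ms=bin_width_ms,
        bin_start_times_ms=np.arange(n_bins) * bin_width_ms,
        channel_mask=np.ones(emg.shape[1], dtype=bool),
        feature_kind="emg_envelope",
    )


def gaussian_smooth(
    binned: BinnedFeatures,
    kernel_ms: float = 100.0,
    kernel_is_fwhm: bool = False,
) -> BinnedFeatures:
    """Smooth binned features with a Gaussian kernel.

    ``kernel_ms`` is read as the kernel standard deviation (the common
    convention); set ``kernel_is_fwhm=True`` to read it as full width at
    half maximum instead. The kernel is truncated at +/-3 sigma, unit-sum,
    and renormalized at the edges so constants pass through unchanged.
    """
    sigma_ms = kernel_ms / 2.3548200450309493 if kernel_is_fwhm else kernel_ms
    sigma_bins = sigma_ms / binned.bin_width_ms
    half = max(1, int(np.ceil(3 * sigma_bins)))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kernel /= kernel.sum()
    values = np.asarray(binned.values, dtype=float)
    n = values.shape[0]
    # edge renormalization: divide by the convolution of the kernel with ones
    out = np.empty_like(values)
    norm = np.convolve(np.ones(n), kernel, mode="same")
    for ch in range(values.shape[1]):
        out[:, ch] = np.convolve(values[:, ch], kernel, mode="same") / norm
    return BinnedFeatures(
        values=out,
        bin_width_ms=binned.bin_width_ms,
        bin_start_times_ms=binned.bin_start_times_ms,
        channel_mask=binned.channel_mask,
        feature_kind=binned.feature_kind,
    )


# ---------------------------------------------------------------------------
# Kinematic conditioning
# ---------------------------------------------------------------------------

def savgol_velocity(
    finger_position_1khz: np.ndarray,
    window_points: int = 7,
    polyorder: int = 2,
    bin_width_ms: int = 20,
) -> tuple:
    """Downsample positions to the 20 ms grid, smooth, and differentiate.

    Positions are decimated to one sample per bin, smoothed with a
    second-order Savitzky-Golay filter (default window 7 points = 140 ms),
    and velocity (%/s) is obtained by central differences of the smoothed
    positions. Exact for polynomial trajectories up to the filter order.
    """
    pos = np.atleast_2d(np.asarray(finger_position_1khz, dtype=float))
    if pos.shape[0] == 1 and pos.size > pos.shape[1]:
        pos = pos.T
    down = pos[::bin_width_ms]
    if down.shape[0] < window_points:
        raise ValueError("trace shorter than the Savitzky-Golay window")
    smooth = sps.savgol_filter(down, window_points, polyorder, axis=0, mode="interp")
    dt_s = bin_width_ms / 1000.0
    vel = np.gradient(smooth, dt_s, axis=0)
    return smooth, vel


def find_peak_movement(
    velocity: np.ndarray,
    presentation_bin: int = 0,
    bin_width_ms: int = 20,
    active_groups=None,
) -> PeakMovement:
    """Largest local speed peak after trial start.

    Speed is the Euclidean norm of the active finger groups' velocities.
    Among local maxima at or after ``presentation_bin`` the largest wins,
    earliest on ties. A monotone trace with no interior peak returns the
    global maximum flagged as degenerate.
    """
    vel = np.atleast_2d(np.asarray(velocity, dtype=float))
    if vel.shape[0] == 1 and vel.size > vel.shape[1]:
        vel = vel.T
    if active_groups is not None:
        vel = vel[:, list(active_groups)]
    speed = np.linalg.norm(vel, axis=1)
    seg = speed[presentation_bin:]
    peaks, _ = sps.find_peaks(seg)
    if peaks.size:
        best = peaks[np.argmax(seg[peaks])]
        # earliest tie wins: argmax returns first occurrence among equal values
        degenerate = False
    else:
        best = int(np.argmax(seg))
        degenerate = True
    idx = int(best + presentation_bin)
    return PeakMovement(
        peak_time_ms=idx * bin_width_ms,
        peak_bin_index=idx,
        peak_speed=float(speed[idx]),
        degenerate=degenerate,
    )


def peri_movement_average(
    binned: BinnedFeatures,
    peak_bin: int,
    n_before: int = 10,
    n_after: int = 10,
) -> np.ndarray:
    """Mean per channel over the window around the peak-movement bin.

    The default 10+1+10 bins at 20 ms is the 420 ms peri-movement window;
    manifold analyses use 20 before / 37 after (400 ms / 740 ms).
    """
    lo = peak_bin - n_before
    hi = peak_bin + n_after + 1
    if lo < 0 or hi > binned.n_bins:
        raise IndexError(
            f"peri-movement window [{lo}, {hi}) outside slice of {binned.n_bins} bins"
        )
    return binned.values[lo:hi].mean(axis=0)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    values_a: np.ndarray,
    values_b=None,
    kind: str = "two_sample_t",
    ci_level: float = 0.99,
):
    """Run the named two-group (or one-sample KS) test.

    Returns ``(statistic, p_value, ci)`` where ``ci`` is the confidence
    interval of the mean difference for t-tests and ``None`` for KS tests.
    ``ks_one_sample`` tests ``values_a`` against the standard normal.
    """
    a = np.asarray(values_a, dtype=float)
    if kind == "ks_one_sample":
        res = spstats.kstest(a, "norm")
        return res.statistic, res.pvalue, None
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be nonempty")
    if kind == "ks_two_sample":
        res = spstats.ks_2samp(a, b)
        return res.statistic, res.pvalue, None
    if kind in ("two_sample_t", "paired_t"):
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("degenerate test: zero variance in both groups")
        if kind == "paired_t":
            if a.size != b.size:
                raise ValueError("paired test requires equal lengths")
            d = a - b
            res = spstats.ttest_1samp(d, 0.0)
            se = d.std(ddof=1) / np.sqrt(d.size)
            df = d.size - 1
            center = d.mean()
        else:
            res = spstats.ttest_ind(a, b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se = np.sqrt(va / a.size + vb / b.size)
            # pooled-variance dof, matching the equal-variance t statistic
            df = a.size + b.size - 2
            sp = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / df)
            se = sp * np.sqrt(1 / a.size + 1 / b.size)
            center = a.mean() - b.mean()
        tcrit = spstats.t.ppf(0.5 + ci_level / 2, df)
        ci = (center - tcrit * se, center + tcrit * se)
        return res.statistic, res.pvalue, ci
    raise ValueError(f"unknown test kind {kind!r}")


def _check_bin_width(bin_width_ms: int) -> None:
    if bin_width_ms not in VALID_BIN_WIDTHS:
        warnings.warn(
            f"bin width {bin_width_ms} ms is nonstandard (expected one of "
            f"{VALID_BIN_WIDTHS})", stacklevel=3,
        )
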