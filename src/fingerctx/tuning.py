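"""Per-channel tuning and context-modulation regression.

For each channel the standardized feature series x̂ (20 ms bins, z-scored
over the concatenated normal + off-context data) is related to finger
position and velocity at the channel's optimal lag by

    Y = B + [x̂, c·x̂] · W

where c indicates off-context samples. A channel is *tuned* if either
first-row coefficient (feature -> position or velocity) is significantly
nonzero, and *context modulated* if either second-row coefficient (the
context-dependent slope change) is. Significance uses per-coefficient
t-tests with Benjamini-Hochberg FDR at 0.1% pooled across all
coefficients in the session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .session import BinnedFeatures, SessionRecord, select_analysis_trials
from . import signals

logger = logging.getLogger("fingerctx")


@dataclass
class TuningDesign:
    """Design and fit for one channel's tuning regression."""

    x_hat: np.ndarray            # (T,), standardized feature at optimal lag
    c: np.ndarray                # (T,), 1 = off-context
    Y: np.ndarray                # (T, 2): position, velocity
    lag_bins: int = 0
    B: np.ndarray = None         # (2,) intercepts
    W: np.ndarray = None         # (2, 2): rows {feature, feature*context}
    t_stats: np.ndarray = None   # (2, 2)
    p_values: np.ndarray = None  # (2, 2)


@dataclass
class TuningResult:
    """Session-level tuning summary in the shape of a tuned/modulated table."""

    per_channel: pd.DataFrame    # channel, lag, coefficients, p-values, flags
    n_tuned: int
    n_context_modulated: int     # among tuned channels
    pct_modulated_among_tuned: float
    fdr_level: float
    feature_kind: str


def optimal_lag(
    channel_feature: np.ndarray,
    kinematics: np.ndarray,
    lag_range_bins: int = 10,
) -> int:
    """Lag maximizing the 2-norm of the OLS coefficients feature -> [pos, vel].

    Positive lag means the feature leads the kinematics. Ties prefer the
    smallest |lag|, negative first; a constant feature returns lag 0.
    """
    x = np.asarray(channel_feature, dtype=float)
    Y = np.asarray(kinematics, dtype=float)
    if np.std(x) == 0:
        logger.warning("optimal_lag: constant feature; returning lag 0")
        return 0
    lags = sorted(range(-lag_range_bins, lag_range_bins + 1),
                  key=lambda l: (abs(l), l))
    best_lag, best_norm = 0, -np.inf
    n = x.size
    for lag in lags:
        if lag >= 0:
            xs, ys = x[:n - lag] if lag else x, Y[lag:] if lag else Y
        else:
            xs, ys = x[-lag:], Y[:n + lag]
        xs = xs - xs.mean()
        denom = xs @ xs
        if denom == 0:
            continue
        coef = xs @ (ys - ys.mean(axis=0)) / denom
        norm = float(np.linalg.norm(coef))
        if norm > best_norm + 1e-15:
            best_norm, best_lag = norm, lag
    return best_lag


def context_tuning_regression(design: TuningDesign) -> TuningDesign:
    """Fit Y = B + [x̂, c·x̂]·W column-wise by least squares.

    t-statistics use residual standard errors with T - 3 degrees of
    freedom per output column. Requires both contexts to be present.
    """
    x, c, Y = design.x_hat, design.c, design.Y
    T = x.size
    if T <= 4:
        raise ValueError("need more than 4 samples")
    if c.min() == c.max():
        raise np.linalg.LinAlgError(
            "single-context data: the context column is degenerate")
    X = np.column_stack([np.ones(T), x, c * x])
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient tuning design")
    resid = Y - X @ coef
    dof = T - 3
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2 * spstats.t.sf(np.abs(t), dof)
    design.B = coef[0]
    design.W = coef[1:]
    design.t_stats = t[1:]
    design.p_values = p[1:]
    return design


def build_tuning_designs(
    session: SessionRecord,
    feature: str = "sbp",
    bin_width_ms: int = 20,
    smooth_kernel_ms: float = None,
    lag_range_bins: int = 10,
    finger_group: int = 0,
) -> list:
    """Assemble per-channel designs from a session.

    Uses analysis trials only, concatenates their 20 ms binned features
    and kinematics, standardizes each channel over the combined normal +
    off-context data, and finds each channel's optimal lag on the
    concatenated data. Features are left unsmoothed by default: the
    per-coefficient t-tests assume roughly white feature noise, which
    kernel smoothing would destroy.
    """
    trials = select_analysis_trials(session)
    if not trials:
        raise ValueError("no analysis trials in session")
    feats, kin, ctx = [], [], []
    for tr in trials:
        from .session import slice_trial
        sl = slice_trial(session.streams, tr)
        if feature == "sbp":
            binned = signals.bin_sbp(sl, bin_width_ms)
        else:
            binned = signals.bin_tcfr(
                signals.remove_artifacts(sl.crossing_times),
                bin_width_ms, sl.n_ms)
        if smooth_kernel_ms:
            binned = signals.gaussian_smooth(binned, smooth_kernel_ms)
        pos, vel = signals.savgol_velocity(sl.finger_position,
                                           bin_width_ms=bin_width_ms)
        n = min(binned.n_bins, pos.shape[0])
        feats.append(binned.values[:n])
        kin.append(np.column_stack([pos[:n, finger_group], vel[:n, finger_group]]))
        ctx.append(np.full(n, 0.0 if tr.context == "normal" else 1.0))
    F = np.concatenate(feats, axis=0)
    Y = np.concatenate(kin, axis=0)
    c = np.concatenate(ctx)
    designs = []
    for ch in range(F.shape[1]):
        x = F[:, ch]
        sd = x.std()
        x_hat = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        lag = optimal_lag(x_hat, Y, lag_range_bins)
        if lag >= 0:
            xs = x_hat[:x_hat.size - lag] if lag else x_hat
            ys = Y[lag:] if lag else Y
            cs = c[lag:] if lag else c
        else:
            xs, ys, cs = x_hat[-lag:], Y[:x_hat.size + lag], c[:x_hat.size + lag]
        designs.append(TuningDesign(x_hat=xs, c=cs, Y=ys, lag_bins=lag))
    return designs


def classify_channels(
    designs: list,
    fdr_level: float = 0.001,
    feature_kind: str = "sbp",
    pool: str = "session",
) -> TuningResult:
    """Fit all channels and apply BH FDR across the session's coefficients.

    ``pool="session"`` (default) pools all four coefficients of every
    channel into one BH family — the conservative reading; ``pool="row"``
    corrects tuning and context rows separately.
    """
    if not designs:
        return TuningResult(pd.DataFrame(), 0, 0, float("nan"),
                            fdr_level, feature_kind)
    fitted = [context_tuning_regression(d) for d in designs]
    pvals = np.array([d.p_values for d in fitted])   # (n_ch, 2, 2)
    n_ch = pvals.shape[0]
    if pool == "session":
        reject = multipletests(pvals.ravel(), alpha=fdr_level,
                               method="fdr_bh")[0].reshape(pvals.shape)
    else:
        reject = np.empty_like(pvals, dtype=bool)
        for row in range(2):
            reject[:, row, :] = multipletests(
                pvals[:, row, :].ravel(), alpha=fdr_level,
                method="fdr_bh")[0].reshape(n_ch, 2)
    tuned = reject[:, 0, :].any(axis=1)
    modulated = reject[:, 1, :].any(axis=1)
    rows = []
    for ch, d in enumerate(fitted):
        rows.append({
            "channel": ch,
            "lag_bins": d.lag_bins,
            "w_pos": d.W[0, 0], "w_vel": d.W[0, 1],
            "w_ctx_pos": d.W[1, 0], "w_ctx_vel": d.W[1, 1],
            "p_pos": d.p_values[0, 0], "p_vel": d.p_values[0, 1],
            "p_ctx_pos": d.p_values[1, 0], "p_ctx_vel": d.p_values[1, 1],
            "tuned": bool(tuned[ch]),
            "context_modulated": bool(modulated[ch]),
        })
    df = pd.DataFrame(rows)
    n_tuned = int(tuned.sum())
    n_mod = int((tuned & modulated).sum())
    pct = 100.0 * n_mod / n_tuned if n_tuned else float("nan")
    return TuningResult(
        per_channel=df,
        n_tuned=n_tuned,
        n_context_modulated=n_mod,
        pct_modulated_among_tuned=pct,
        fdr_level=fdr_level,
        feature_kind=feature_kind,
    )


def tuning_summary(session: SessionRecord, feature: str = "sbp",
                   fdr_level: float = 0.001, **kw) -> TuningResult:
    """End-to-end tuning analysis for one session."""
    designs = build_tuning_designs(session, feature=feature, **kw)
    return classify_channels(designs, fdr_level=fdr_level, feature_kind=feature)
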