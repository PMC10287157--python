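"""Offline decoding: lagged ridge regression and cross-context generalization.

Spiking-band power in 32 ms bins (channels masked to a mean
threshold-crossing rate above 1 Hz, each with 12 bins of history) is
regressed onto kinematics or muscle-activation envelopes. Models are
trained on normal-context trials with 10-fold cross-validation: each fold's
model is scored on its held-out normal bins and on all off-context bins,
quantifying how far a fixed decoder generalizes when the physical task
context changes. Accuracy is reported as the Pearson correlation and the
MSE normalized by the variance of the measured signal (nMSE), which equals
one minus the coefficient of determination — the fraction of unexplained
variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import BinnedFeatures, SessionRecord, select_analysis_trials, slice_trial
from . import signals

logger = logging.getLogger("fingerctx")


@dataclass
class RidgeDecoder:
    """Fitted lagged ridge regression (intercept unpenalized)."""

    weights: np.ndarray          # (n_features + 1, n_outputs), last row intercept
    ridge_lambda: float
    n_history_bins: int = 12
    bin_width_ms: int = 32
    output_kind: str = "kinematics"
    feature_mean: np.ndarray = None   # standardization, training stats
    feature_sd: np.ndarray = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.weights.shape[0]:
            X = X[:, :-1]      # drop the design's intercept column
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_sd
        return X @ self.weights[:-1] + self.weights[-1]


@dataclass
class PredictionMetrics:
    """Per-output Pearson r and normalized MSE on one test set."""

    pearson_r: np.ndarray
    nmse: np.ndarray
    n_samples: int


def channel_mask_by_tcfr(session: SessionRecord, min_rate_hz: float = 1.0) -> np.ndarray:
    """Channels whose session-average threshold-crossing rate exceeds 1 Hz."""
    dur_s = session.streams.n_ms / 1000.0
    rates = np.array([len(t) / dur_s for t in session.streams.crossing_times])
    return rates > min_rate_hz


def build_lagged_design(values: np.ndarray, n_history_bins: int) -> np.ndarray:
    """Concatenate each bin with its recent history for one contiguous trial.

    Row t holds bins t, t-1, ..., t-n_history per channel plus a trailing
    intercept column; the first ``n_history_bins`` rows are dropped so no
    row reaches before the trial start.
    """
    v = np.asarray(values, dtype=float)
    n_bins, n_ch = v.shape
    h = n_history_bins
    if n_bins <= h:
        raise ValueError("trial shorter than requested history")
    cols = [v[h - k: n_bins - k] for k in range(h + 1)]
    X = np.concatenate(cols, axis=1)
    return np.column_stack([X, np.ones(X.shape[0])])


def fit_ridge(X: np.ndarray, Y: np.ndarray, ridge_lambda: float = 0.0) -> RidgeDecoder:
    """Penalized least squares with an unpenalized intercept.

    ``X`` includes an intercept column (as produced by
    :func:`build_lagged_design`); the penalty applies to every other
    column. At lambda = 0 a singular system raises with advice to
    regularize.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    Xc = X[:, :-1]
    xm = Xc.mean(axis=0)
    ym = Y.mean(axis=0)
    Xd, Yd = Xc - xm, Y - ym
    A = Xd.T @ Xd + ridge_lambda * np.eye(Xd.shape[1])
    try:
        W = np.linalg.solve(A, Xd.T @ Yd)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular normal equations; use ridge_lambda > 0") from e
    if ridge_lambda == 0.0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "ill-conditioned system at lambda=0; use ridge_lambda > 0")
    intercept = ym - xm @ W
    weights = np.vstack([W, intercept])
    return RidgeDecoder(weights=weights, ridge_lambda=float(ridge_lambda))


def gcv_lambda(X: np.ndarray, Y: np.ndarray, grid=None) -> float:
    """Generalized cross-validation choice of the ridge penalty."""
    X = np.asarray(X, dtype=float)[:, :-1]
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Xd = X - X.mean(axis=0)
    Yd = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xd, full_matrices=False)
    UtY = U.T @ Yd
    n = Xd.shape[0]
    if grid is None:
        s2max = s.max() ** 2 if s.size else 1.0
        grid = s2max * np.logspace(-10, 0, 21)
    best_lam, best_gcv = grid[0], np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        df = shrink.sum()
        resid = ((1 - shrink)[:, None] * UtY)
        rss = float((resid**2).sum()) + float((Yd**2).sum()) - float((UtY**2).sum())
        g = n * rss / (n - df) ** 2
        if g < best_gcv:
            best_gcv, best_lam = g, lam
    return float(best_lam)


def prediction_metrics(predicted: np.ndarray, measured: np.ndarray) -> PredictionMetrics:
    """Pearson r and nMSE per output column.

    nMSE divides the mean squared error by the population variance of the
    measured data on the same test set, so the constant-mean predictor
    scores exactly 1 and nMSE = 1 - R^2.
    """
    P = np.asarray(predicted, dtype=float)
    M = np.asarray(measured, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if M.ndim == 1:
        M = M[:, None]
    if P.shape != M.shape or P.shape[0] < 2:
        raise ValueError("predicted/measured must be equal-length with >= 2 rows")
    var = M.var(axis=0)
    if np.any(var == 0):
        raise ValueError("measured variance is zero; nMSE undefined")
    mse = ((P - M) ** 2).mean(axis=0)
    r = np.array([
        np.corrcoef(P[:, j], M[:, j])[0, 1] if P[:, j].std() > 0 else 0.0
        for j in range(P.shape[1])
    ])
    return PredictionMetrics(pearson_r=r, nmse=mse / var, n_samples=P.shape[0])


# ---------------------------------------------------------------------------
# Session feature/target assembly
# ---------------------------------------------------------------------------

def _trial_targets(session: SessionRecord, trial, bin_width_ms: int,
                   target: str, smooth_kernel_ms: float = 100.0) -> np.ndarray:
    sl = slice_trial(session.streams, trial)
    n_bins = sl.n_ms // bin_width_ms
    if target == "kinematics":
        t = n_bins * bin_width_ms
        pos = sl.finger_position[:t].reshape(n_bins, bin_width_ms, 2).mean(axis=1)
        vel = np.gradient(pos, bin_width_ms / 1000.0, axis=0)
        return np.column_stack([pos, vel])
    if target == "emg":
        if sl.emg_10khz is not None:
            env = signals.emg_envelope(sl.emg_10khz, bin_width_ms).values
        elif sl.emg_envelope_1khz is not None:
            t = n_bins * bin_width_ms
            env = sl.emg_envelope_1khz[:t].reshape(n_bins, bin_width_ms, 8).mean(axis=1)
        else:
            raise ValueError("session carries no EMG")
        binned = BinnedFeatures(env, bin_width_ms, np.arange(env.shape[0]),
                                np.ones(env.shape[1], bool), "emg_envelope")
        return signals.gaussian_smooth(binned, smooth_kernel_ms).values
    raise ValueError(f"unknown target {target!r}")


def session_design(
    session: SessionRecord,
    target: str = "kinematics",
    bin_width_ms: int = 32,
    n_history_bins: int = 12,
):
    """Per-trial lagged designs and targets, grouped by context.

    Returns ``(designs, targets, contexts, trials)`` aligned lists; trials
    shorter than the history are skipped with a warning.
    """
    mask = channel_mask_by_tcfr(session)
    if not mask.any():
        raise ValueError("no channels pass the 1 Hz TCFR mask")
    trials = select_analysis_trials(session)
    designs, targets, contexts, kept = [], [], [], []
    for tr in trials:
        sl = slice_trial(session.streams, tr)
        feats = signals.bin_sbp(sl, bin_width_ms).values[:, mask]
        if feats.shape[0] <= n_history_bins:
            logger.warning("trial %d shorter than history; skipped", tr.trial_index)
            continue
        X = build_lagged_design(feats, n_history_bins)
        Y = _trial_targets(session, tr, bin_width_ms, target)[n_history_bins:]
        n = min(X.shape[0], Y.shape[0])
        designs.append(X[:n])
        targets.append(Y[:n])
        contexts.append(tr.context)
        kept.append(tr)
    return designs, targets, contexts, kept


def _fold_partition(sizes, n_folds: int):
    """Split trial indices into contiguous folds with near-equal bin counts."""
    total = sum(sizes)
    bounds = [round(k * total / n_folds) for k in range(n_folds + 1)]
    folds, cum, f = [[] for _ in range(n_folds)], 0, 0
    for i, s in enumerate(sizes):
        mid = cum + s / 2
        while f < n_folds - 1 and mid >= bounds[f + 1]:
            f += 1
        folds[f].append(i)
        cum += s
    return [fi for fi in folds if fi]


@dataclass
class GeneralizationResult:
    """Per-fold metrics for held-out normal and each off-context test set."""

    per_fold: pd.DataFrame       # fold, test_set, output, r, nmse
    summary: pd.DataFrame        # test_set, output, mean/sd of r and nmse, pct change
    ridge_lambda: float
    output_names: list


def crossval_generalization(
    session: SessionRecord,
    test_contexts=None,
    target: str = "kinematics",
    ridge_lambda="gcv",
    folds: int = 10,
    n_history_bins: int = 12,
    bin_width_ms: int = 32,
) -> GeneralizationResult:
    """Train on normal trials, test within and across context.

    Normal-context bins are split into ``folds`` contiguous trial blocks
    of near-equal bin counts; each fold's model is evaluated on the
    held-out normal bins and on all bins of every off-context test set.
    The summary includes the percent change of each metric relative to
    held-out normal performance.
    """
    designs, targets, contexts, _ = session_design(
        session, target=target, bin_width_ms=bin_width_ms,
        n_history_bins=n_history_bins)
    normal_idx = [i for i, c in enumerate(contexts) if c == "normal"]
    if len(normal_idx) < folds:
        raise ValueError(f"need >= {folds} normal trials, have {len(normal_idx)}")
    if test_contexts is None:
        test_contexts = sorted({c for c in contexts if c != "normal"})
    off_sets = {}
    for ctx in test_contexts:
        idx = [i for i, c in enumerate(contexts) if c == ctx]
        if not idx:
            logger.warning("context %s absent from session", ctx)
            continue
        off_sets[ctx] = (np.concatenate([designs[i] for i in idx]),
                         np.concatenate([targets[i] for i in idx]))
    sizes = [designs[i].shape[0] for i in normal_idx]
    fold_trials = _fold_partition(sizes, folds)

    out_names = (["pos_index", "pos_mrs", "vel_index", "vel_mrs"]
                 if target == "kinematics" else [f"emg{m}" for m in range(8)])
    rows = []
    for f, held in enumerate(fold_trials):
        train_ids = [normal_idx[i] for fi in fold_trials if fi is not held for i in fi]
        test_ids = [normal_idx[i] for i in held]
        Xtr = np.concatenate([designs[i] for i in train_ids])
        Ytr = np.concatenate([targets[i] for i in train_ids])
        mu = Xtr[:, :-1].mean(axis=0)
        sd = Xtr[:, :-1].std(axis=0)
        sd[sd == 0] = 1.0

        def stdize(X):
            Z = X.copy()
            Z[:, :-1] = (Z[:, :-1] - mu) / sd
            return Z

        Xtr = stdize(Xtr)
        lam = gcv_lambda(Xtr, Ytr) if ridge_lambda == "gcv" else float(ridge_lambda)
        model = fit_ridge(Xtr, Ytr, lam)
        eval_sets = {"normal_heldout": (
            np.concatenate([designs[i] for i in test_ids]),
            np.concatenate([targets[i] for i in test_ids]))}
        eval_sets.update(off_sets)
        for name, (Xte, Yte) in eval_sets.items():
            m = prediction_metrics(model.predict(stdize(Xte)), Yte)
            for j, out in enumerate(out_names):
                rows.append({"fold": f, "test_set": name, "output": out,
                             "r": m.pearson_r[j], "nmse": m.nmse[j],
                             "lambda": lam})
    per_fold = pd.DataFrame(rows)
    base = per_fold[per_fold.test_set == "normal_heldout"].groupby("output")[
        ["r", "nmse"]].mean()
    summ = per_fold.groupby(["test_set", "output"]).agg(
        r_mean=("r", "mean"), r_sd=("r", "std"),
        nmse_mean=("nmse", "mean"), nmse_sd=("nmse", "std")).reset_index()
    summ["nmse_pct_change"] = [
        100.0 * (row.nmse_mean - base.loc[row.output, "nmse"]) /
        base.loc[row.output, "nmse"] for row in summ.itertuples()]
    summ["r_pct_change"] = [
        100.0 * (row.r_mean - base.loc[row.output, "r"]) /
        abs(base.loc[row.output, "r"]) for row in summ.itertuples()]
    lam_used = per_fold["lambda"].iloc[0] if len(per_fold) else float("nan")
    return GeneralizationResult(per_fold=per_fold, summary=summ,
                                ridge_lambda=lam_used, output_names=out_names)


def offcontext_amplitude_ratio(
    session: SessionRecord,
    context: str = "spring",
    muscle_channels=range(0, 4),
    ridge_lambda="gcv",
    n_history_bins: int = 12,
) -> float:
    """Predicted/measured peri-movement EMG amplitude on off-context trials.

    A decoder trained on all normal trials predicts the off-context
    muscle envelopes. Amplitudes are baseline-subtracted (median of each
    trace) means over the top-decile bins of the measured envelope, so
    the ratio estimates how strongly the normal-context model
    under-predicts the raised off-context activation — the reciprocal of
    the planted context gain when the model generalizes the kinematic
    component faithfully.
    """
    designs, targets, contexts, _ = session_design(
        session, target="emg", n_history_bins=n_history_bins)
    tr_idx = [i for i, c in enumerate(contexts) if c == "normal"]
    te_idx = [i for i, c in enumerate(contexts) if c == context]
    if not tr_idx or not te_idx:
        raise ValueError("need both normal and off-context trials")
    Xtr = np.concatenate([designs[i] for i in tr_idx])
    Ytr = np.concatenate([targets[i] for i in tr_idx])
    mu = Xtr[:, :-1].mean(axis=0)
    sd = Xtr[:, :-1].std(axis=0)
    sd[sd == 0] = 1.0

    def stdize(X):
        Z = X.copy()
        Z[:, :-1] = (Z[:, :-1] - mu) / sd
        return Z

    Xtr = stdize(Xtr)
    lam = gcv_lambda(Xtr, Ytr) if ridge_lambda == "gcv" else float(ridge_lambda)
    model = fit_ridge(Xtr, Ytr, lam)
    Xte = np.concatenate([designs[i] for i in te_idx])
    Yte = np.concatenate([targets[i] for i in te_idx])
    pred = model.predict(stdize(Xte))
    cols = list(muscle_channels)
    meas = Yte[:, cols].mean(axis=1)
    est = pred[:, cols].mean(axis=1)
    k = max(1, meas.size // 10)
    top = np.argsort(meas)[-k:]
    meas_amp = meas[top].mean() - np.median(meas)
    pred_amp = est[top].mean() - np.median(est)
    return float(pred_amp / meas_amp)
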