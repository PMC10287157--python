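"""Online neural activity patterns and pushing magnitudes.

A linear readout from 50 ms binned neural features (current bin plus five
history bins per channel) to finger velocities is trained on normal-context
offline trials. Applied to online trials, the prediction at the moment of
peak decoded velocity toward the target is that trial's *neural activity
pattern*; its projection onto the unit target direction is the trial's
*pushing magnitude*. Pushing magnitudes are compared between normal and
off-context trials per movement group (flexion, extension, split) with
two-sample t-tests under 5% Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .offline import build_lagged_design, fit_ridge, channel_mask_by_tcfr
from .session import SessionRecord, select_analysis_trials, slice_trial
from . import signals

logger = logging.getLogger("fingerctx")

PATTERN_BIN_MS = 50
N_HISTORY = 5


@dataclass
class PatternReadout:
    """Linear velocity readout from lagged 50 ms neural features."""

    weights: np.ndarray          # (channels*6 + 1, 2)
    channel_mask: np.ndarray
    bin_width_ms: int = PATTERN_BIN_MS

    def predict(self, lagged_design: np.ndarray) -> np.ndarray:
        return lagged_design @ self.weights


@dataclass
class NeuralActivityPattern:
    trial_index: int
    readout_velocity: np.ndarray   # (2,), %/s
    target_direction: np.ndarray   # unit 2-vector
    context: str
    pushing_magnitude: float
    movement_group: str            # flexion | extension | split


def fit_pattern_readout(
    session: SessionRecord,
    ridge_lambda: float = 1e-3,
) -> PatternReadout:
    """Least-squares velocity readout from normal offline trials."""
    mask = channel_mask_by_tcfr(session)
    trials = [t for t in select_analysis_trials(session)
              if t.context == "normal" and t.mode == "manipulandum"]
    if not trials:
        raise ValueError("no normal offline trials to train the readout")
    Xs, Ys = [], []
    for tr in trials:
        sl = slice_trial(session.streams, tr)
        feats = signals.bin_sbp(sl, PATTERN_BIN_MS).values[:, mask]
        if feats.shape[0] <= N_HISTORY:
            continue
        n_bins = feats.shape[0]
        t = n_bins * PATTERN_BIN_MS
        pos = sl.finger_position[:t].reshape(n_bins, PATTERN_BIN_MS, 2).mean(axis=1)
        vel = np.gradient(pos, PATTERN_BIN_MS / 1000.0, axis=0)
        X = build_lagged_design(feats, N_HISTORY)
        Xs.append(X)
        Ys.append(vel[N_HISTORY:])
    model = fit_ridge(np.concatenate(Xs), np.concatenate(Ys), ridge_lambda)
    return PatternReadout(weights=model.weights, channel_mask=mask)


def movement_group(target_direction: np.ndarray) -> str:
    """Flexion, extension, or split, from the signed target direction."""
    di, dm = target_direction
    if di >= 0 and dm >= 0:
        return "flexion"
    if di <= 0 and dm <= 0:
        return "extension"
    return "split"


def extract_patterns(
    online_trials: list,
    readout: PatternReadout,
    start_positions=None,
) -> list:
    """Readout predictions at the bin of peak decoded velocity toward target.

    ``online_trials`` are closed-loop results carrying per-step features
    and decoded velocities on the 32 ms loop grid; features are rebinned
    to the readout's 50 ms grid by interval-weighted averaging. The
    selected bin maximizes the decoded velocity's projection onto the
    unit target direction (earliest on ties).
    """
    patterns = []
    for tr in online_trials:
        if tr.features is None or tr.features.shape[0] <= N_HISTORY + 2:
            logger.warning("trial %d has no usable movement bins; skipped",
                           tr.trial_index)
            continue
        start = tr.trajectory[0]
        direction = np.asarray(tr.target_center, float) - np.asarray(start, float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            logger.warning("trial %d has zero target offset; skipped",
                           tr.trial_index)
            continue
        direction = direction / norm
        feats50 = _rebin_mean(tr.features[:, readout.channel_mask], 32,
                              PATTERN_BIN_MS)
        vel50 = _rebin_mean(tr.decoded_velocity[1:], 32, PATTERN_BIN_MS)
        n = min(feats50.shape[0], vel50.shape[0])
        if n <= N_HISTORY:
            continue
        X = build_lagged_design(feats50[:n], N_HISTORY)
        preds = readout.predict(X)
        proj = vel50[N_HISTORY:n] @ direction
        k = int(np.argmax(proj))
        pat = preds[k]
        patterns.append(NeuralActivityPattern(
            trial_index=tr.trial_index,
            readout_velocity=pat,
            target_direction=direction,
            context=tr.context,
            pushing_magnitude=pushing_magnitude(pat, direction),
            movement_group=movement_group(direction),
        ))
    return patterns


def _rebin_mean(values: np.ndarray, src_ms: int, dst_ms: int) -> np.ndarray:
    """Average a src-ms-grid signal onto a dst-ms grid (interval overlap)."""
    v = np.asarray(values, dtype=float)
    total_ms = v.shape[0] * src_ms
    n_out = total_ms // dst_ms
    fine = np.repeat(v, src_ms, axis=0)[: n_out * dst_ms]
    return fine.reshape(n_out, dst_ms, v.shape[1]).mean(axis=1)


def pushing_magnitude(pattern: np.ndarray, target_direction: np.ndarray) -> float:
    """Scalar projection of the pattern velocity onto the unit target direction."""
    d = np.asarray(target_direction, dtype=float)
    n = np.linalg.norm(d)
    if not np.isclose(n, 1.0):
        d = d / n
    return float(np.dot(np.asarray(pattern, dtype=float), d))


def compare_pattern_groups(
    patterns: list,
    fdr_level: float = 0.05,
    min_per_side: int = 2,
) -> pd.DataFrame:
    """Normal vs off-context pushing magnitudes per movement group.

    Two-sample t-tests per group with Benjamini-Hochberg FDR at 5% across
    the session's groups; groups missing a side or with fewer than
    ``min_per_side`` trials per side are skipped with a warning.
    """
    df = pd.DataFrame({
        "group": [p.movement_group for p in patterns],
        "context": [p.context for p in patterns],
        "push": [p.pushing_magnitude for p in patterns],
    })
    rows = []
    for g, grp in df.groupby("group"):
        a = grp.loc[grp.context == "normal", "push"].to_numpy()
        b = grp.loc[grp.context != "normal", "push"].to_numpy()
        if len(a) < min_per_side or len(b) < min_per_side:
            logger.warning("group %s lacks trials on one side; skipped", g)
            continue
        t, p = spstats.ttest_ind(a, b)
        rows.append({"group": g, "n_normal": len(a), "n_off": len(b),
                     "delta": b.mean() - a.mean(), "t": t, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = multipletests(out["p"], alpha=fdr_level,
                                           method="fdr_bh")[0]
    return out
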