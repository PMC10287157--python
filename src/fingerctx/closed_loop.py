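"""Closed-loop BMI simulation: Kalman decoding, ReFIT retraining, metrics.

The online decoder is a linear-Gaussian position/velocity Kalman filter
over the state [pos_index, pos_mrs, vel_index, vel_mrs, 1] with a 32 ms
update. Position rows of the transition matrix implement physical
integration; displayed finger position is the integral of the posterior
velocity, clamped to [0, 100]. ReFIT retraining rotates decoded velocities
toward the instantaneous target direction (preserving magnitude), zeroes
them inside the target, and refits the observation model against these
intention states.

A configurable intention model stands in for the monkey: it emits a
velocity command toward the target (with optional re-aim offset and
noise), a linear encoder turns the command into channel features —
optionally with a context gain mismatching the decoder's training
condition — and the filter closes the loop. Online performance is scored
with acquisition time, time to target, orbiting time, and path
efficiency; adaptation is scored by within-block z-scored acquisition
times averaged over the first trials of each block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .synth import LinearEncoder

logger = logging.getLogger("fingerctx")

DT_S = 0.032
BIN_MS = 32


@dataclass
class KalmanDecoder:
    """Position/velocity Kalman filter with an appended constant-1 state."""

    A: np.ndarray                # (5, 5) state transition
    W: np.ndarray                # (5, 5) process noise covariance
    C: np.ndarray                # (n_ch, 5) observation matrix
    Q: np.ndarray                # (n_ch, n_ch) observation noise covariance
    bin_width_ms: int = BIN_MS


@dataclass
class KalmanState:
    x: np.ndarray                # (5,)
    P: np.ndarray                # (5, 5)

    @classmethod
    def initial(cls, pos=(50.0, 50.0)) -> "KalmanState":
        x = np.array([pos[0], pos[1], 0.0, 0.0, 1.0])
        return cls(x=x, P=np.diag([0.0, 0.0, 10.0, 10.0, 0.0]))


@dataclass
class IntentionModel:
    """Behavioral stand-in: proportional velocity command toward the target."""

    gain: float = 0.9            # fraction of the remaining gap each plan closes
    noise_sd: float = 10.0       # %/s
    reaim_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    reaction_time_ms: int = 96
    max_speed: float = 200.0     # %/s
    deadband_fraction: float = 1.0   # relax while inside the target
    replan_interval_ms: int = 192    # intermittent control: commands are
                                     # re-planned at this cadence, ballistic
                                     # in between (uncorrected overshoot)
    feedback_delay_ms: int = 128     # visual feedback latency: plans and the
                                     # relax decision use this-old positions
    _plan: np.ndarray = None
    _plan_t: int = -10**9

    def reset(self) -> None:
        """Clear the current motor plan (call at trial start)."""
        self._plan = np.zeros(2)
        self._plan_t = -10**9

    def command(self, pos, target, t_ms, rng, half_width: float = 7.5) -> np.ndarray:
        if t_ms < self.reaction_time_ms:
            return np.zeros(2)
        # forward model: the seen position is feedback_delay_ms old, so
        # predict the current position assuming the running plan executed
        # as intended; a context mismatch violates this prediction
        pred = np.asarray(pos, dtype=float) +             self._plan * (self.feedback_delay_ms / 1000.0)
        err = np.asarray(target) - pred
        inside = np.all(np.abs(err) <= self.deadband_fraction * half_width)
        if inside or t_ms - self._plan_t >= self.replan_interval_ms:
            if inside:
                # on target: stop pushing (no active error correction)
                v = np.zeros(2)
            else:
                # plan to close (gain x) the gap within one replan interval
                v = self.gain * err / (self.replan_interval_ms / 1000.0)
                speed = np.linalg.norm(v)
                if speed > self.max_speed:
                    v *= self.max_speed / speed
            self._plan = v
            self._plan_t = t_ms
        return self._plan + self.reaim_offset + self.noise_sd * rng.standard_normal(2)


@dataclass
class OnlineTrialResult:
    """One closed-loop trial with its trajectory and performance metrics."""

    trial_index: int
    context: str
    target_center: np.ndarray
    target_width: float
    success: bool
    acquisition_time_ms: float
    time_to_target_ms: float
    orbiting_time_ms: float
    path_efficiency: float
    trajectory: np.ndarray            # (n_steps, 2) positions at 32 ms
    decoded_velocity: np.ndarray      # (n_steps, 2)
    features: Optional[np.ndarray] = None  # (n_steps, n_ch)


# ---------------------------------------------------------------------------
# Fitting and the filter recursion
# ---------------------------------------------------------------------------

def _states(kinematics: np.ndarray) -> np.ndarray:
    kin = np.asarray(kinematics, dtype=float)
    return np.column_stack([kin, np.ones(kin.shape[0])])


def fit_kalman(binned_features: np.ndarray, kinematics: np.ndarray) -> KalmanDecoder:
    """Fit the filter from trial-concatenated training data.

    ``kinematics`` is (T, 4): positions then velocities on the 32 ms grid.
    Velocity transition rows are least squares; position rows are fixed to
    physical integration; the constant row is pinned. The observation
    matrix regresses features on the full state.
    """
    F = np.asarray(binned_features, dtype=float)
    X = _states(kinematics)
    T = X.shape[0]
    if T - 1 < X.shape[1]:
        raise np.linalg.LinAlgError("fewer samples than state dimension")
    X0, X1 = X[:-1], X[1:]
    vel_rows, *_ = np.linalg.lstsq(X0, X1[:, 2:4], rcond=None)
    A = np.zeros((5, 5))
    A[0, 0] = A[1, 1] = 1.0
    A[0, 2] = A[1, 3] = DT_S
    A[2:4, :] = vel_rows.T
    A[4, 4] = 1.0
    W = np.zeros((5, 5))
    vres = X1[:, 2:4] - X0 @ vel_rows
    W[2:4, 2:4] = vres.T @ vres / max(T - 1, 1)
    Ct, *_ = np.linalg.lstsq(X, F, rcond=None)
    C = Ct.T
    fres = F - X @ Ct
    Q = fres.T @ fres / T
    Q += 1e-8 * np.trace(Q) / Q.shape[0] * np.eye(Q.shape[0])
    return KalmanDecoder(A=A, W=W, C=C, Q=Q)


def kalman_step(decoder: KalmanDecoder, state: KalmanState,
                features: np.ndarray) -> KalmanState:
    """One predict/update step; displayed position integrates velocity.

    Non-finite features reject the step and hold the state. The output
    position is previous position + posterior velocity * 32 ms, clamped
    to [0, 100], and is written back into the state (position feedback).
    """
    y = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(y)):
        logger.warning("kalman_step: non-finite features; state held")
        return state
    A, W, C, Q = decoder.A, decoder.W, decoder.C, decoder.Q
    prev_pos = state.x[0:2].copy()
    x_pred = A @ state.x
    P_pred = A @ state.P @ A.T + W
    S = C @ P_pred @ C.T + Q
    K = np.linalg.solve(S, C @ P_pred).T
    x_post = x_pred + K @ (y - C @ x_pred)
    P_post = (np.eye(5) - K @ C) @ P_pred
    pos = np.clip(prev_pos + x_post[2:4] * DT_S, 0.0, 100.0)
    x_post[0:2] = pos
    x_post[4] = 1.0
    P_post[4, :] = 0.0
    P_post[:, 4] = 0.0
    return KalmanState(x=x_post, P=P_post)


def rotate_toward(velocity: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotate a velocity onto a target direction, preserving magnitude."""
    speed = np.linalg.norm(velocity)
    norm = np.linalg.norm(direction)
    if norm == 0:
        return np.zeros_like(velocity)
    return speed * np.asarray(direction) / norm


def refit_retrain(decoder: KalmanDecoder, online_trials: list) -> KalmanDecoder:
    """ReFIT: rotate decoded velocities toward the target, refit C and Q.

    Intention velocity keeps the decoded magnitude but points from the
    current position to the target center in the 2-D finger space, and is
    zero whenever all fingers are inside the target. The transition model
    is untouched.
    """
    feats, states = [], []
    for tr in online_trials:
        if tr.target_center is None:
            logger.warning("trial %d missing target; skipped", tr.trial_index)
            continue
        if tr.features is None:
            continue
        target = np.asarray(tr.target_center, dtype=float)
        half = tr.target_width / 2.0
        # features[i] were observed at position trajectory[i]; the decoded
        # velocity they produced is decoded_velocity[i + 1]
        for pos, vel, f in zip(tr.trajectory[:-1], tr.decoded_velocity[1:],
                               tr.features):
            inside = np.all(np.abs(pos - target) <= half)
            v_int = np.zeros(2) if inside else rotate_toward(vel, target - pos)
            states.append([pos[0], pos[1], v_int[0], v_int[1], 1.0])
            feats.append(f)
    if not feats:
        raise ValueError("no usable online trials for ReFIT")
    X = np.asarray(states)
    F = np.asarray(feats)
    Ct, *_ = np.linalg.lstsq(X, F, rcond=None)
    fres = F - X @ Ct
    Q = fres.T @ fres / X.shape[0]
    Q += 1e-8 * np.trace(Q) / Q.shape[0] * np.eye(Q.shape[0])
    return KalmanDecoder(A=decoder.A.copy(), W=decoder.W.copy(), C=Ct.T, Q=Q)


# ---------------------------------------------------------------------------
# Closed-loop simulation
# ---------------------------------------------------------------------------

def online_metrics(trajectory: np.ndarray, target_center, target_width: float,
                   hold_time_ms: int, end_time_ms: float,
                   start_pos=None) -> dict:
    """Performance measures for one online trial trajectory (32 ms grid).

    Acquisition time runs from presentation to trial end minus the hold;
    time to target is the first moment all fingers sit inside the target;
    orbiting is their difference (0 if the fingers never left); path
    efficiency is straight-line distance over traveled path length.
    """
    traj = np.asarray(trajectory, dtype=float)
    target = np.asarray(target_center, dtype=float)
    half = target_width / 2.0
    if start_pos is None:
        start_pos = traj[0]
    inside = np.all(np.abs(traj - target) <= half, axis=1)
    success = hold_time_ms > 0
    if inside.any():
        first_in = int(np.argmax(inside))
        t2t = first_in * BIN_MS
        if success:
            # start of the terminal continuous inside-run = final entry
            outside = np.flatnonzero(~inside)
            final_entry = int(outside[-1]) + 1 if outside.size else 0
            acquisition = final_entry * BIN_MS
        else:
            acquisition = float(end_time_ms)
        orbiting = acquisition - t2t
    else:
        t2t = float("nan")
        acquisition = float(end_time_ms)
        orbiting = float("nan")
    path_len = float(np.sum(np.linalg.norm(np.diff(traj, axis=0), axis=1)))
    straight = float(np.linalg.norm(target - np.asarray(start_pos)))
    eff = straight / path_len if path_len > 0 else float("nan")
    return {"acquisition_time_ms": acquisition, "time_to_target_ms": t2t,
            "orbiting_time_ms": orbiting, "path_efficiency": eff}


def simulate_closed_loop(
    encoder: LinearEncoder,
    intention: IntentionModel,
    decoder: KalmanDecoder,
    n_trials: int = 100,
    context_schedule=None,
    context_gains: dict = None,
    hold_time_ms: int = 500,
    timeout_ms: int = 10_000,
    target_width: float = 15.0,
    task: str = "center_out_1dof_random",
    seed: int = 0,
    record_features: bool = True,
) -> list:
    """Run closed-loop trials and return per-trial results.

    ``context_schedule`` is a list of ``(context, n_trials)`` pairs (the
    ``n_trials`` argument is ignored when given); ``context_gains`` maps
    context name to the encoder gain mismatch (1.0 = matched). Targets
    follow center-out-and-back; a trial succeeds on ``hold_time_ms`` of
    continuous target occupancy and fails at ``timeout_ms``.
    """
    from .synth import _target_sequence

    rng = np.random.default_rng(seed)
    if context_schedule is None:
        context_schedule = [("normal", n_trials)]
    if context_gains is None:
        context_gains = {}
    results = []
    pos = np.array([50.0, 50.0])
    trial_idx = 0
    for ctx, n in context_schedule:
        gain = context_gains.get(ctx, 1.0)
        targets = _target_sequence(task, n, rng)
        for tci, tcm, dof in targets:
            target = np.array([tci, tcm])
            intention.reset()
            state = KalmanState.initial(pos)
            delay_steps = max(0, int(round(intention.feedback_delay_ms / BIN_MS)))
            traj, vels, feats = [pos.copy()], [np.zeros(2)], []
            held_ms = 0
            t_ms = 0
            success = False
            half = target_width / 2.0
            while t_ms < timeout_ms:
                seen = traj[-(delay_steps + 1)] if len(traj) > delay_steps else traj[0]
                v_cmd = intention.command(seen, target, t_ms, rng, half)
                y = encoder.encode(pos, v_cmd, rng, context_gain=gain)
                state = kalman_step(decoder, state, y)
                pos = state.x[0:2].copy()
                traj.append(pos.copy())
                vels.append(state.x[2:4].copy())
                if record_features:
                    feats.append(y)
                t_ms += BIN_MS
                if np.all(np.abs(pos - target) <= half):
                    held_ms += BIN_MS
                    if held_ms >= hold_time_ms:
                        success = True
                        break
                else:
                    held_ms = 0
            end_ms = t_ms
            m = online_metrics(np.asarray(traj), target, target_width,
                               hold_time_ms if success else 0, end_ms,
                               start_pos=traj[0])
            results.append(OnlineTrialResult(
                trial_index=trial_idx,
                context=ctx,
                target_center=target,
                target_width=target_width,
                success=success,
                trajectory=np.asarray(traj),
                decoded_velocity=np.asarray(vels),
                features=np.asarray(feats) if record_features else None,
                **m,
            ))
            trial_idx += 1
    return results


# ---------------------------------------------------------------------------
# Adaptation statistics
# ---------------------------------------------------------------------------

def adaptation_stats(results: list, block_labels: list, k: int = 5) -> dict:
    """Early-trial adaptation scores and their tests.

    Acquisition times are z-scored within each context block; each
    block's score is the mean of its first ``k`` z-scores. One-sample
    Kolmogorov-Smirnov tests the standardized scores against the null of
    no systematic early slowdown; a two-sample KS compares normal against
    off-context block scores. Failed trials are retained here.
    """
    df = pd.DataFrame({
        "acq": [r.acquisition_time_ms for r in results],
        "block": list(block_labels),
        "context": [r.context for r in results],
    })
    scores, contexts, zstats = [], [], []
    for b, grp in df.groupby("block"):
        n = len(grp)
        if n < k:
            logger.warning("block %s has %d < %d trials; skipped", b, n, k)
            continue
        a = grp["acq"].to_numpy(dtype=float)
        sd = a.std()
        z = (a - a.mean()) / sd if sd > 0 else np.zeros(n)
        score = z[:k].mean()
        # variance of the mean of k of n zero-mean unit-variance values
        # drawn without replacement; standardizes scores across block sizes
        se = np.sqrt((n - k) / (k * (n - 1))) if n > 1 else 1.0
        scores.append(score)
        zstats.append(score / se if se > 0 else 0.0)
        contexts.append(grp["context"].iloc[0])
    scores = np.asarray(scores)
    zstats = np.asarray(zstats)
    contexts = np.asarray(contexts)
    out = {"block_scores": scores, "block_contexts": contexts,
           "standardized_scores": zstats}
    if len(zstats) >= 3:
        res = spstats.kstest(zstats, "norm")
        out["ks_one_sample_p"] = float(res.pvalue)
    is_normal = contexts == "normal"
    if is_normal.any() and (~is_normal).any():
        res2 = spstats.ks_2samp(scores[is_normal], scores[~is_normal])
        out["ks_two_sample_p"] = float(res2.pvalue)
    return out
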