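"""Synthetic session generator with planted low-dimensional latent structure.

Emulates a center-out finger-movement session recorded from a 96-channel
intracortical array while the task context (torsional springs, flexed
wrist, rubber bands) alters the muscle activation required for the same
kinematics. The generator plants exactly the structure the downstream
analyses assume, so every stage can be validated by parameter recovery:

* kinematics are minimum-jerk center-out-and-back movements;
* muscle envelopes scale with per-context flexor/extensor gains, with
  optional co-contraction (extensors recruited during resisted flexion);
* neural channels are random linear readouts of latent groups —
  condition-independent trial phase, signed target kinematics, a context
  latent driven by the *difference* between required and normal-context
  muscle activation (zero in the normal context by construction), and
  small target-by-context interaction terms that vanish when all context
  gains are 1;
* per-ms spiking-band power is the rectified channel drive plus Gaussian
  noise; threshold crossings follow an inhomogeneous Poisson process with
  a softplus link.

Because the context latent is derived from the muscle-activation
difference, the correlation between the leading context component and the
active muscle's activation is an emergent property, not a hard-coded one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .session import ContinuousStreams, SessionRecord, TrialRecord

# speed scale used to normalize latent amplitudes: the peak speed of the
# canonical 40%-in-500-ms minimum-jerk movement (15*40/(8*0.5) %/s)
SPEED_SCALE = 150.0

DEFAULT_CONTEXT_GAINS_FLEXOR = {
    "normal": 1.0, "spring": 1.92, "wrist": 1.53, "band": 1.50, "both": 2.45,
}
DEFAULT_CONTEXT_GAINS_EXTENSOR = {
    "normal": 1.0, "spring": 0.92, "wrist": 0.68, "band": 0.90, "both": 0.63,
}
# extensor recruitment during resisted flexion (stiffening co-contraction)
DEFAULT_COCONTRACTION = {
    "normal": 0.0, "spring": 0.35, "wrist": 0.0, "band": 0.15, "both": 0.35,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic session generator.

    Defaults encode the study conditions: spring context raises flexor
    activation ~92% and lowers extensor activation ~8%; wrist flexion
    raises flexors ~53% and lowers extensors ~32%. Velocities are %/s,
    positions percent flexion, times integer ms.
    """

    seed: int = 0
    n_channels: int = 96
    n_latents: int = 16
    latent_loading: Optional[np.ndarray] = None   # (n_channels, n_latents)
    loading_scale: float = 0.4
    context_gain_flexor: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_GAINS_FLEXOR))
    context_gain_extensor: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_GAINS_EXTENSOR))
    cocontraction_gain: dict = field(
        default_factory=lambda: dict(DEFAULT_COCONTRACTION))
    context_shift_scale: float = 1.0
    interaction_scale: float = 0.2
    baseline_drive: float = 1.5      # keeps channel drive mostly positive
    noise_sd_sbp: float = 0.5
    tc_rate_scale: float = 25.0      # Hz per unit softplus(drive)
    emg_baseline: float = 0.10       # envelope at rest, arbitrary units
    emg_noise_sd: float = 0.02
    emg_mode: str = "envelope"       # none | envelope | raw
    trials_per_block: tuple = (175, 350)
    reaction_time_ms: int = 200
    reaction_time_jitter_ms: int = 50
    movement_duration_ms: int = 500
    hold_time_ms: int = 750
    fraction_failed: float = 0.05
    target_width: float = 15.0

    def __post_init__(self):
        if self.latent_loading is None:
            rng = np.random.default_rng(_child_seed(self.seed, "loading"))
            self.latent_loading = self.loading_scale * rng.standard_normal(
                (self.n_channels, self.n_latents))
        self.latent_loading = np.asarray(self.latent_loading, dtype=float)
        for gains in (self.context_gain_flexor, self.context_gain_extensor):
            for ctx, g in gains.items():
                if g <= 0:
                    raise ValueError(f"context gain for {ctx!r} must be > 0")
        if abs(self.context_gain_flexor.get("normal", 1.0) - 1.0) > 1e-12 or \
           abs(self.context_gain_extensor.get("normal", 1.0) - 1.0) > 1e-12:
            raise ValueError("normal-context gains must equal 1")

    def with_(self, **kw) -> "GeneratorConfig":
        cfg = replace(self, **kw)
        if "seed" in kw and "latent_loading" not in kw:
            cfg.latent_loading = None
            cfg.__post_init__()
        return cfg


#: latent index layout (n_latents >= 9; extra latents stay silent)
LATENT_GROUPS = {
    "condition_independent": [0],
    "target": [1, 2, 3, 4],      # pos_index, pos_mrs, vel_index, vel_mrs
    "context": [5, 6],           # flexor-difference, extensor-difference
    "interaction": [7, 8],
}


@dataclass
class LatentTimecourses:
    """Latent trajectories partitioned into labeled groups."""

    z: np.ndarray                    # (t_ms, n_latents)
    groups: dict = field(default_factory=lambda: {
        k: list(v) for k, v in LATENT_GROUPS.items()})


def _child_seed(seed: int, name: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), abs(hash_name(name)) % (2**31)])


def hash_name(name: str) -> int:
    """Stable small-integer hash of a stream name (process-independent)."""
    h = 0
    for c in name:
        h = (h * 131 + ord(c)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def min_jerk(amplitude: float, duration_ms: int) -> np.ndarray:
    """Minimum-jerk displacement profile, one sample per ms.

    Peak speed is 15*A/(8*T) at the temporal midpoint.
    """
    tau = np.arange(duration_ms) / max(duration_ms - 1, 1)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def make_kinematics(
    trial_spec: TrialRecord,
    config: GeneratorConfig,
    start_position: np.ndarray = None,
    reaction_time_ms: int = None,
    reach_fraction: float = 1.0,
) -> tuple:
    """Position and velocity traces (1 kHz) for one trial.

    The fingers hold the start position for the reaction time, follow a
    minimum-jerk trajectory to the target center over
    ``movement_duration_ms``, then hold inside the target until trial
    end. ``reach_fraction < 1`` produces an undershoot (used for failed
    trials). Velocity is the analytic minimum-jerk derivative.
    """
    if start_position is None:
        start_position = np.array([50.0, 50.0])
    start_position = np.asarray(start_position, dtype=float)
    if reaction_time_ms is None:
        reaction_time_ms = config.reaction_time_ms
    n_ms = trial_spec.end_time_ms - trial_spec.presentation_time_ms
    target = np.array([trial_spec.target_center_index, trial_spec.target_center_mrs])
    amp = (target - start_position) * reach_fraction
    dur = min(config.movement_duration_ms, max(n_ms - reaction_time_ms, 2))
    pos = np.tile(start_position, (n_ms, 1))
    vel = np.zeros((n_ms, 2))
    tau = np.arange(dur) / max(dur - 1, 1)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / (max(dur - 1, 1) / 1000.0)  # 1/s
    t0 = min(reaction_time_ms, n_ms - dur)
    for g in range(2):
        pos[t0:t0 + dur, g] = start_position[g] + amp[g] * s
        pos[t0 + dur:, g] = start_position[g] + amp[g]
        vel[t0:t0 + dur, g] = amp[g] * ds
    return np.clip(pos, 0.0, 100.0), vel


# ---------------------------------------------------------------------------
# Muscle activity
# ---------------------------------------------------------------------------

def muscle_envelopes(velocity: np.ndarray, context: str, config: GeneratorConfig) -> np.ndarray:
    """Noise-free 8-channel muscle-activation envelope at 1 kHz.

    Channels 0-3 are flexors, 4-7 extensors. Flexors follow rectified
    flexion velocity scaled by the context's flexor gain; extensors follow
    rectified extension velocity scaled by the extensor gain plus a
    co-contraction term proportional to flexion velocity.
    """
    if context not in config.context_gain_flexor:
        raise KeyError(f"unknown context {context!r}")
    v = np.mean(np.atleast_2d(velocity), axis=1) / SPEED_SCALE
    flex = np.maximum(v, 0.0)
    ext = np.maximum(-v, 0.0)
    gf = config.context_gain_flexor[context]
    ge = config.context_gain_extensor[context]
    cc = config.cocontraction_gain.get(context, 0.0)
    env = np.empty((v.size, 8))
    # mild fixed per-muscle scaling for realism; identical across contexts
    per_muscle = np.array([1.0, 0.9, 1.1, 0.95, 1.0, 1.05, 0.9, 1.0])
    for m in range(4):
        env[:, m] = config.emg_baseline + per_muscle[m] * gf * flex
    for m in range(4, 8):
        env[:, m] = config.emg_baseline + per_muscle[m] * (ge * ext + cc * flex)
    return env


def make_muscle_activity(
    kinematics: tuple,
    context: str,
    config: GeneratorConfig,
    rng: np.random.Generator = None,
    raw: bool = False,
) -> tuple:
    """Envelope (1 kHz, 8 channels) and optional raw EMG (10 kHz).

    Raw EMG is band-limited (100-500 Hz) noise amplitude-modulated by the
    envelope and normalized so that the binned mean absolute value of the
    raw signal recovers the envelope.
    """
    from scipy import signal as sps

    _, vel = kinematics
    env = muscle_envelopes(vel, context, config)
    if not raw:
        return env, None
    if rng is None:
        rng = np.random.default_rng(0)
    n10 = env.shape[0] * 10
    sos = sps.butter(2, [100.0, 500.0], btype="bandpass", fs=10_000.0, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal((n10, 8)), axis=0)
    mav = np.mean(np.abs(carrier), axis=0)
    carrier /= mav
    env10 = np.repeat(env, 10, axis=0)
    emg = carrier * env10 + config.emg_noise_sd * rng.standard_normal((n10, 8))
    return env, emg.astype(np.float32)


# ---------------------------------------------------------------------------
# Latents and neural observations
# ---------------------------------------------------------------------------

def make_latents(
    kinematics: tuple,
    muscle_env: np.ndarray,
    context: str,
    config: GeneratorConfig,
) -> LatentTimecourses:
    """Per-trial latent timecourses on the 1 kHz clock.

    The context group is ``context_shift_scale`` times the difference
    between the required muscle envelope and its normal-context
    counterpart, so it is identically zero for normal trials (and for any
    context whose gains are all 1).
    """
    pos, vel = kinematics
    n = pos.shape[0]
    z = np.zeros((n, config.n_latents))
    speed = np.abs(np.mean(vel, axis=1))
    z[:, 0] = speed / SPEED_SCALE                       # condition-independent phase
    z[:, 1] = (pos[:, 0] - 50.0) / 40.0                 # target: signed position
    z[:, 2] = (pos[:, 1] - 50.0) / 40.0
    z[:, 3] = vel[:, 0] / SPEED_SCALE                   # target: signed velocity
    z[:, 4] = vel[:, 1] / SPEED_SCALE
    env_normal = muscle_envelopes(vel, "normal", config)
    diff = muscle_env - env_normal
    v_raw = np.mean(vel, axis=1)
    flexing = v_raw >= 0
    diff_flex = diff[:, :4].mean(axis=1)
    diff_ext = diff[:, 4:].mean(axis=1)
    # leading context latent follows the ACTIVE muscle group's excess
    # activation (flexors while flexing, extensors while extending); the
    # second carries the non-active group (co-contraction)
    z[:, 5] = config.context_shift_scale * np.where(flexing, diff_flex, diff_ext)
    z[:, 6] = config.context_shift_scale * np.where(flexing, diff_ext, diff_flex)
    c = 0.0 if context == "normal" else 1.0
    gf = config.context_gain_flexor[context]
    ge = config.context_gain_extensor[context]
    v = np.mean(vel, axis=1) / SPEED_SCALE
    z[:, 7] = config.interaction_scale * c * (gf - 1.0) * np.maximum(v, 0.0)
    z[:, 8] = config.interaction_scale * c * (ge - 1.0) * np.maximum(-v, 0.0)
    return LatentTimecourses(z=z)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def make_neural(
    latents: LatentTimecourses,
    config: GeneratorConfig,
    rng: np.random.Generator = None,
) -> tuple:
    """Per-ms SBP stream, raw sample counts, and threshold-crossing times.

    Channel drive is ``baseline + loading @ z``; SBP is the rectified
    drive plus pre-rectification Gaussian noise, with two 2 kHz samples
    behind every millisecond. Crossings are an inhomogeneous Bernoulli
    approximation of a Poisson process with rate
    ``tc_rate_scale * softplus(drive - baseline)`` Hz.
    """
    if rng is None:
        rng = np.random.default_rng(_child_seed(config.seed, "neural"))
    z = latents.z
    drive = config.baseline_drive + z @ config.latent_loading.T
    noise = config.noise_sd_sbp * rng.standard_normal(drive.shape)
    sbp = np.abs(drive + noise).astype(np.float32)
    counts = np.full(drive.shape, 2, dtype=np.int8)
    rate_hz = config.tc_rate_scale * softplus(drive - config.baseline_drive)
    p = np.clip(rate_hz / 1000.0, 0.0, 1.0)
    events = rng.random(drive.shape) < p
    crossings = [np.flatnonzero(events[:, ch]).astype(np.int64)
                 for ch in range(drive.shape[1])]
    return sbp, counts, crossings


# ---------------------------------------------------------------------------
# Whole-session assembly
# ---------------------------------------------------------------------------

def _target_sequence(task: str, n_trials: int, rng: np.random.Generator):
    """Center-out-and-back target centers; None marks the center target."""
    out = []
    need_center = False
    for i in range(n_trials):
        if i % 2 == 0 and not need_center:
            # out target
            if task == "center_out_1dof":
                mag = 40.0
            elif task == "center_out_1dof_random":
                mag = float(rng.choice([20.0, 30.0, 40.0]))
            else:
                mag = float(rng.choice([20.0, 30.0]))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if task.startswith("center_out_1dof"):
                tgt = (50.0 + sign * mag, 50.0 + sign * mag, "one")
            else:
                s2 = 1.0 if rng.random() < 0.5 else -1.0
                tgt = (50.0 + sign * mag, 50.0 + s2 * mag, "two")
            out.append(tgt)
        else:
            dof = "one" if task.startswith("center_out_1dof") else "two"
            out.append((50.0, 50.0, dof))
            need_center = False
    return out


def generate_session(
    config: GeneratorConfig,
    context_schedule=None,
    task: str = "center_out_1dof",
    monkey_id: str = "synthetic",
) -> SessionRecord:
    """Generate a complete, valid session.

    ``context_schedule`` is a list of contexts (block lengths drawn from
    ``config.trials_per_block``) or explicit ``(context, n_trials)``
    pairs. Targets follow the center-out-and-back order, the center is
    re-presented after any failed trial, and failures are injected at
    ``config.fraction_failed`` as undershoots that never settle inside
    the target.
    """
    if context_schedule is None:
        context_schedule = [("normal", 100), ("spring", 100)]
    if not context_schedule:
        raise ValueError("context schedule must be nonempty")
    rng_task = np.random.default_rng(_child_seed(config.seed, "task"))
    rng_emg = np.random.default_rng(_child_seed(config.seed, "emg"))
    rng_neural = np.random.default_rng(_child_seed(config.seed, "neural"))

    blocks = []
    for item in context_schedule:
        if isinstance(item, str):
            lo, hi = config.trials_per_block
            blocks.append((item, int(rng_task.integers(lo, hi + 1))))
        else:
            ctx, n = item
            blocks.append((str(ctx), int(n)))
    for ctx, _ in blocks:
        if ctx not in config.context_gain_flexor:
            raise ValueError(f"schedule names unknown context {ctx!r}")

    trials, block_labels = [], []
    pos_segments, vel_segments, env_segments = [], [], []
    contexts_per_trial = []
    t_now = 0
    current_pos = np.array([50.0, 50.0])
    trial_idx = 0
    for block_id, (ctx, n_trials) in enumerate(blocks):
        targets = _target_sequence(task, n_trials, rng_task)
        i = 0
        force_center = False
        while i < n_trials:
            if force_center:
                tci, tcm, dof = 50.0, 50.0, targets[i][2]
            else:
                tci, tcm, dof = targets[i]
            rt = config.reaction_time_ms + int(rng_task.integers(
                -config.reaction_time_jitter_ms, config.reaction_time_jitter_ms + 1))
            dur = rt + config.movement_duration_ms + config.hold_time_ms
            failed = rng_task.random() < config.fraction_failed
            trial = TrialRecord(
                trial_index=trial_idx,
                context=ctx,
                mode="manipulandum",
                dof=dof,
                target_center_index=tci,
                target_center_mrs=tcm,
                presentation_time_ms=t_now,
                end_time_ms=t_now + dur,
                hold_time_ms=config.hold_time_ms,
                success=not failed,
                target_width=config.target_width,
            )
            reach = 1.0 if not failed else 0.5   # failures stall halfway
            pos, vel = make_kinematics(trial, config, start_position=current_pos,
                                       reaction_time_ms=rt, reach_fraction=reach)
            env = muscle_envelopes(vel, ctx, config)
            trials.append(trial)
            block_labels.append(block_id)
            contexts_per_trial.append(ctx)
            pos_segments.append(pos)
            vel_segments.append(vel)
            env_segments.append(env)
            current_pos = pos[-1].copy()
            t_now += dur
            trial_idx += 1
            force_center = failed
            i += 1

    pos_all = np.concatenate(pos_segments, axis=0)
    vel_all = np.concatenate(vel_segments, axis=0)
    env_all = np.concatenate(env_segments, axis=0)

    # latents trial-by-trial (context differs per trial), then one neural pass
    z_parts = []
    for tr, p, v, e in zip(trials, pos_segments, vel_segments, env_segments):
        z_parts.append(make_latents((p, v), e, tr.context, config).z)
    z_all = np.concatenate(z_parts, axis=0)
    sbp, counts, crossings = make_neural(LatentTimecourses(z=z_all), config, rng_neural)

    emg_raw = None
    emg_env = None
    if config.emg_mode in ("envelope", "raw"):
        emg_env = (env_all + config.emg_noise_sd *
                   rng_emg.standard_normal(env_all.shape)).astype(np.float32)
        emg_env = np.maximum(emg_env, 0.0)
    if config.emg_mode == "raw":
        _, emg_raw = make_muscle_activity((pos_all, vel_all), "normal", config,
                                          rng=rng_emg, raw=True)
        # re-modulate with the actual per-context envelope
        from scipy import signal as sps
        sos = sps.butter(2, [100.0, 500.0], btype="bandpass", fs=10_000.0, output="sos")
        carrier = sps.sosfilt(sos, rng_emg.standard_normal((pos_all.shape[0] * 10, 8)),
                              axis=0)
        carrier /= np.mean(np.abs(carrier), axis=0)
        emg_raw = (carrier * np.repeat(env_all, 10, axis=0) +
                   config.emg_noise_sd *
                   rng_emg.standard_normal(carrier.shape)).astype(np.float32)

    streams = ContinuousStreams(
        sbp_1ms=sbp,
        raw_sample_count_1ms=counts,
        crossing_times=crossings,
        finger_position=pos_all,
        emg_10khz=emg_raw,
        emg_envelope_1khz=emg_env,
    )
    session = SessionRecord(
        monkey_id=monkey_id,
        n_channels=config.n_channels,
        trials=trials,
        streams=streams,
        context_block_labels=np.array(block_labels, dtype=int),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Linear encoder for closed-loop simulation
# ---------------------------------------------------------------------------

@dataclass
class LinearEncoder:
    """Feature encoder mapping a kinematic state to channel features.

    Used by the closed-loop simulator: features = C @ [pos_n, vel_n, 1]
    plus noise, where pos_n = (pos-50)/40 and vel_n = vel/150. A context
    gain > 1 scales the velocity-driven drive on flexor-linked channels
    during flexion (and symmetrically reduces extension drive), emulating
    the context-dependent shift in neural activity.
    """

    C: np.ndarray                # (n_channels, 5)
    noise_sd: float = 0.2
    flexor_channels: np.ndarray = None   # bool mask
    context_dir: np.ndarray = None       # channel direction of the context shift
    tonic_level: float = 0.0             # optional tonic context drive per unit excess gain

    @classmethod
    def from_config(cls, config: GeneratorConfig, noise_sd: float = 0.2) -> "LinearEncoder":
        L = config.latent_loading
        C = np.zeros((config.n_channels, 5))
        C[:, 0:2] = L[:, 1:3]        # position loadings
        C[:, 2:4] = L[:, 3:5]        # velocity loadings
        C[:, 4] = config.baseline_drive
        flexor = L[:, 3:5].sum(axis=1) > 0
        return cls(C=C, noise_sd=noise_sd, flexor_channels=flexor,
                   context_dir=L[:, 5].copy())

    def encode(self, pos: np.ndarray, vel: np.ndarray,
               rng: np.random.Generator, context_gain=1.0) -> np.ndarray:
        """Features for one 32 ms step.

        ``context_gain`` is ``(flexor_gain, extensor_gain)`` or a single
        flexor gain. Off-context, the velocity-driven component of the
        drive is scaled by the flexor gain while the commanded movement is
        toward flexion and by the extensor gain while toward extension —
        the neural correlate of the changed muscle-activation requirement.
        A fixed decoder then over- or under-responds asymmetrically.
        """
        gf, ge = (context_gain if np.ndim(context_gain) else (context_gain, 1.0))
        v = np.asarray(vel, dtype=float)
        s = np.array([(pos[0] - 50) / 40.0, (pos[1] - 50) / 40.0,
                      v[0] / SPEED_SCALE, v[1] / SPEED_SCALE, 1.0])
        base = self.C @ s
        if gf != 1.0 or ge != 1.0:
            # off-context, the velocity-driven drive of muscle-linked
            # channels scales with the changed activation requirement and
            # the context latent adds a tonic shift; a decoder fitted in
            # the normal context sees a distorted observation model plus
            # unmodeled activity it reads out as a velocity bias
            scale = gf if v.mean() >= 0 else ge
            vdrive = self.C[:, 2:4] @ s[2:4]
            base = base + (scale - 1.0) * vdrive \
                + self.tonic_level * (gf - 1.0) * self.context_dir
        return base + self.noise_sd * rng.standard_normal(base.shape)
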