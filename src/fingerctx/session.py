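"""Session and trial data model with HDF5/CSV persistence.

A *session* is one behavioral recording: an ordered trial table plus
continuous streams sharing a single integer-millisecond clock that starts
at 0. Finger position is expressed as percent flexion on a 0 (full
extension) to 100 (full flexion) scale; the two columns are the index
finger and the middle-ring-small (MRS) finger group. All time windows in
the package are half-open ``[start, end)`` in milliseconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: Recognized task contexts. "normal" is the unaltered manipulandum;
#: the others are physical alterations (torsional springs, flexed wrist,
#: rubber bands, springs+wrist combined).
CONTEXTS = ("normal", "spring", "wrist", "band", "both")

#: How the trial was driven: physical finger movement in the manipulandum,
#: or online brain-control with a Kalman / ReFIT-Kalman decoder.
MODES = ("manipulandum", "online_kf", "online_rfkf")

DOFS = ("one", "two")


class SessionFormatError(ValueError):
    """On-disk container does not match the expected layout."""


class SessionValidationError(ValueError):
    """A record violates the session data-model invariants."""


@dataclass
class TrialRecord:
    """One trial of the center-out finger task.

    Target centers are percent of the range of motion; each target spans
    ``target_width`` percent (15% by default). ``hold_time_ms`` is 750 ms
    for manipulandum trials and 500 ms online.
    """

    trial_index: int
    context: str
    mode: str
    dof: str
    target_center_index: float
    target_center_mrs: float
    presentation_time_ms: int
    end_time_ms: int
    hold_time_ms: int
    success: bool
    target_width: float = 15.0
    decoder_id: Optional[str] = None

    def validate(self) -> list:
        problems = []
        if self.context not in CONTEXTS:
            problems.append(f"trial {self.trial_index}: unknown context {self.context!r}")
        if self.mode not in MODES:
            problems.append(f"trial {self.trial_index}: unknown mode {self.mode!r}")
        if self.dof not in DOFS:
            problems.append(f"trial {self.trial_index}: unknown dof {self.dof!r}")
        if not (self.end_time_ms > self.presentation_time_ms):
            problems.append(f"trial {self.trial_index}: end_time_ms <= presentation_time_ms")
        for name in ("target_center_index", "target_center_mrs"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                problems.append(f"trial {self.trial_index}: {name}={v} outside [0, 100]")
        if not self.target_width > 0:
            problems.append(f"trial {self.trial_index}: target_width must be > 0")
        if self.hold_time_ms < 0:
            problems.append(f"trial {self.trial_index}: negative hold_time_ms")
        return problems


@dataclass
class ContinuousStreams:
    """Continuous per-session streams on the shared millisecond clock.

    ``sbp_1ms`` holds per-millisecond rectified sums of the 300-1000 Hz
    band (spiking-band power, arbitrary units); ``raw_sample_count_1ms``
    counts how many 2 kHz samples contributed to each value (0, 1 or 2).
    ``crossing_times`` lists threshold-crossing event times per channel.
    ``emg_10khz`` is optional raw EMG; ``emg_envelope_1khz`` is an
    optional precomputed envelope stream at 1 kHz used when raw EMG is
    not stored.
    """

    sbp_1ms: np.ndarray                      # (t_ms, n_channels)
    raw_sample_count_1ms: np.ndarray         # (t_ms, n_channels), ints in {0,1,2}
    crossing_times: list                     # per channel, sorted int arrays (ms)
    finger_position: np.ndarray              # (t_ms, 2), percent flexion
    emg_10khz: Optional[np.ndarray] = None   # (t_ms*10, 8)
    emg_envelope_1khz: Optional[np.ndarray] = None  # (t_ms, 8)
    time_offset_ms: int = 0                  # offset of sample 0 on the session clock

    @property
    def n_ms(self) -> int:
        return self.sbp_1ms.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sbp_1ms.shape[1]

    def validate(self) -> list:
        problems = []
        if self.sbp_1ms.shape != self.raw_sample_count_1ms.shape:
            problems.append("sbp_1ms and raw_sample_count_1ms shapes differ")
        if len(self.crossing_times) != self.n_channels:
            problems.append("crossing_times length != n_channels")
        counts = np.asarray(self.raw_sample_count_1ms)
        if counts.size and (counts.min() < 0 or counts.max() > 2):
            problems.append("raw_sample_count_1ms entries outside {0,1,2}")
        if self.finger_position.ndim != 2 or self.finger_position.shape[1] != 2:
            problems.append("finger_position must be (t, 2)")
        elif self.finger_position.size:
            lo, hi = self.finger_position.min(), self.finger_position.max()
            if lo < -1e-6 or hi > 100 + 1e-6:
                problems.append(f"finger_position outside [0, 100] (min {lo:.3g}, max {hi:.3g})")
        if self.emg_10khz is not None and self.emg_10khz.shape[1] != 8:
            problems.append("emg_10khz must have 8 channels")
        return problems


@dataclass
class SessionRecord:
    """A full session: trial table, streams, and per-trial block labels."""

    monkey_id: str
    trials: list            # list[TrialRecord], ordered by presentation time
    streams: ContinuousStreams
    context_block_labels: np.ndarray  # int per trial; z-scoring and alternation use this
    n_channels: int = 96

    def validate(self) -> None:
        problems = []
        for tr in self.trials:
            problems.extend(tr.validate())
        times = [tr.presentation_time_ms for tr in self.trials]
        if any(b < a for a, b in zip(times, times[1:])):
            problems.append("trials not ordered by presentation_time_ms")
        if len(self.context_block_labels) != len(self.trials):
            problems.append("context_block_labels length != number of trials")
        if self.streams.n_channels != self.n_channels:
            problems.append(
                f"declared n_channels={self.n_channels} but streams carry "
                f"{self.streams.n_channels}"
            )
        problems.extend(self.streams.validate())
        if problems:
            raise SessionValidationError("; ".join(problems))

    @property
    def contexts(self) -> list:
        seen = []
        for tr in self.trials:
            if tr.context not in seen:
                seen.append(tr.context)
        return seen

    def trial_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(tr) for tr in self.trials]
        df = pd.DataFrame(rows)
        df["block_label"] = np.asarray(self.context_block_labels, dtype=int)
        return df


@dataclass
class BinnedFeatures:
    """Time-binned features: non-overlapping, contiguous, half-open bins."""

    values: np.ndarray           # (n_bins, n_channels)
    bin_width_ms: int
    bin_start_times_ms: np.ndarray
    channel_mask: np.ndarray     # bool per channel
    feature_kind: str            # sbp | tcfr | emg_envelope | kinematics

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def masked_values(self) -> np.ndarray:
        return self.values[:, self.channel_mask]


# ---------------------------------------------------------------------------
# Persistence (HDF5 container; CSV trial-table fallback for tiny fixtures)
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_index", "context", "mode", "dof", "target_center_index",
    "target_center_mrs", "target_width", "presentation_time_ms",
    "end_time_ms", "hold_time_ms", "success", "decoder_id", "block_label",
]


def write_session(session: SessionRecord, path) -> None:
    """Write a session to one HDF5 container; layout is deterministic."""
    session.validate()
    df = session.trial_table()
    with h5py.File(path, "w") as f:
        f.attrs["monkey_id"] = session.monkey_id
        f.attrs["n_channels"] = session.n_channels
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("trials")
        for col in _TRIAL_COLUMNS:
            data = df[col].to_numpy() if len(df) else np.array([])
            if col in ("context", "mode", "dof", "decoder_id"):
                data = np.array(
                    ["" if v is None else str(v) for v in (df[col] if len(df) else [])],
                    dtype=h5py.string_dtype(),
                )
            g.create_dataset(col, data=data)
        s = f.create_group("streams")
        st = session.streams
        s.create_dataset("sbp_1ms", data=st.sbp_1ms)
        s.create_dataset("raw_count_1ms", data=st.raw_sample_count_1ms.astype(np.int8))
        s.create_dataset("finger_pos", data=st.finger_position)
        xg = s.create_group("crossings")
        for ch, times in enumerate(st.crossing_times):
            xg.create_dataset(f"ch{ch:03d}", data=np.asarray(times, dtype=np.int64))
        if st.emg_10khz is not None:
            s.create_dataset("emg", data=st.emg_10khz)
        if st.emg_envelope_1khz is not None:
            s.create_dataset("emg_envelope", data=st.emg_envelope_1khz)


def read_session(path) -> SessionRecord:
    """Read and validate a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise SessionFormatError("container missing /trials group")
        if "streams" not in f:
            raise SessionFormatError("container missing /streams group")
        g = f["trials"]
        cols = {}
        for col in _TRIAL_COLUMNS:
            if col not in g:
                raise SessionFormatError(f"/trials missing column {col!r}")
            cols[col] = g[col][()]
        n = len(cols["trial_index"])
        trials = []
        for i in range(n):
            dec = cols["decoder_id"][i]
            dec = dec.decode() if isinstance(dec, bytes) else str(dec)
            trials.append(TrialRecord(
                trial_index=int(cols["trial_index"][i]),
                context=_s(cols["context"][i]),
                mode=_s(cols["mode"][i]),
                dof=_s(cols["dof"][i]),
                target_center_index=float(cols["target_center_index"][i]),
                target_center_mrs=float(cols["target_center_mrs"][i]),
                target_width=float(cols["target_width"][i]),
                presentation_time_ms=int(cols["presentation_time_ms"][i]),
                end_time_ms=int(cols["end_time_ms"][i]),
                hold_time_ms=int(cols["hold_time_ms"][i]),
                success=bool(cols["success"][i]),
                decoder_id=dec or None,
            ))
        s = f["streams"]
        for name in ("sbp_1ms", "raw_count_1ms", "finger_pos", "crossings"):
            if name not in s:
                raise SessionFormatError(f"/streams missing {name!r}")
        xg = s["crossings"]
        crossings = [xg[k][()] for k in sorted(xg.keys())]
        streams = ContinuousStreams(
            sbp_1ms=s["sbp_1ms"][()],
            raw_sample_count_1ms=s["raw_count_1ms"][()].astype(np.int64),
            crossing_times=crossings,
            finger_position=s["finger_pos"][()],
            emg_10khz=s["emg"][()] if "emg" in s else None,
            emg_envelope_1khz=s["emg_envelope"][()] if "emg_envelope" in s else None,
        )
        session = SessionRecord(
            monkey_id=_s(f.attrs["monkey_id"]),
            n_channels=int(f.attrs["n_channels"]),
            trials=trials,
            streams=streams,
            context_block_labels=np.asarray(
                cols["block_label"] if n else [], dtype=int
            ),
        )
    session.validate()
    return session


def _s(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def write_trial_table_csv(session: SessionRecord, path) -> None:
    session.trial_table().to_csv(path, index=False)


def read_trial_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Trial selection and slicing
# ---------------------------------------------------------------------------

def select_analysis_trials(session: SessionRecord) -> list:
    """Successful trials, excluding any trial following an unsuccessful one.

    Unsuccessful trials carry no usable peri-movement epoch, and the trial
    after a failure is a re-presented center target with atypical initial
    conditions; both are dropped from every offline analysis.
    """
    keep = []
    prev_success = True
    for tr in session.trials:
        if tr.success and prev_success:
            keep.append(tr)
        prev_success = tr.success
    return keep


def slice_trial(
    streams: ContinuousStreams,
    trial: TrialRecord,
    pad_before_ms: int = 0,
    pad_after_ms: int = 0,
) -> ContinuousStreams:
    """Crop streams to ``[presentation - pad_before, end + pad_after)``.

    Times in the returned streams are relative to the window start; the
    original session-clock offset is recorded in ``time_offset_ms``.
    """
    start = trial.presentation_time_ms - pad_before_ms
    stop = trial.end_time_ms + pad_after_ms
    if start < 0 or stop > streams.n_ms:
        raise IndexError(
            f"trial window [{start}, {stop}) outside session bounds [0, {streams.n_ms})"
        )
    crossings = []
    for times in streams.crossing_times:
        t = np.asarray(times)
        crossings.append(t[(t >= start) & (t < stop)] - start)
    return ContinuousStreams(
        sbp_1ms=streams.sbp_1ms[start:stop],
        raw_sample_count_1ms=streams.raw_sample_count_1ms[start:stop],
        crossing_times=crossings,
        finger_position=streams.finger_position[start:stop],
        emg_10khz=(
            streams.emg_10khz[start * 10:stop * 10]
            if streams.emg_10khz is not None else None
        ),
        emg_envelope_1khz=(
            streams.emg_envelope_1khz[start:stop]
            if streams.emg_envelope_1khz is not None else None
        ),
        time_offset_ms=start,
    )
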