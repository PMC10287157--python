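"""Neural-population geometry: manifolds, principal angles, demixed PCA.

Trials are aligned to the peak-movement bin and a window from 400 ms
before to 740 ms after that bin (58 bins at 20 ms) is cut from the
channel-masked 20 ms spiking-band-power. Trial averages per (context,
target) form an N x T x D tensor per context; PCA of the reshaped tensor
gives each context's manifold, and principal angles between manifolds
measure their alignment against a control distribution built from
disjoint resamples of normal trials. Demixed PCA decomposes the
condition-averaged data into additive marginalizations — condition
independent (time), context, target, and their interaction — and finds
paired encoder/decoder axes per marginalization by regularized
reduced-rank regression, with the fraction of variance per
marginalization as the headline statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .session import SessionRecord, select_analysis_trials, slice_trial
from .offline import channel_mask_by_tcfr
from . import signals

logger = logging.getLogger("fingerctx")

# default alignment window: 400 ms before to 740 ms after the peak bin
WINDOW_BEFORE_BINS = 20
WINDOW_AFTER_BINS = 37
BIN_MS = 20


@dataclass
class TrialTensor:
    """Trial-aligned, condition-averaged tensors.

    ``per_context[ctx]`` is channels x bins x targets (trial averaged);
    ``full`` is channels x contexts x targets x bins x trials with trial
    counts balanced by subsampling. ``trial_windows`` keeps the raw
    per-trial windows for resampling controls.
    """

    per_context: dict                  # ctx -> (N, T, D)
    full: np.ndarray                   # (N, C, D, T, n)
    contexts: list
    targets: list
    trial_counts: dict                 # (ctx, target) -> n trials before balancing
    trial_windows: dict                # (ctx, target) -> (n, N, T)
    window_bins: tuple = (WINDOW_BEFORE_BINS, WINDOW_AFTER_BINS)


@dataclass
class ContextManifold:
    """Orthonormal PCA basis for one context's trial-averaged activity."""

    basis: np.ndarray                  # (N, K)
    explained_variance: np.ndarray
    context: str


@dataclass
class DPCAResult:
    """Demixed PCA decomposition of a balanced trial tensor."""

    encoders: dict                     # marginalization -> (N, k)
    decoders: dict                     # marginalization -> (k, N)
    variance_fraction: dict            # marginalization -> float, sums to 1
    component_variance: dict           # marginalization -> per-component fractions
    marginalized: dict                 # marginalization -> (N, C, D, T)
    mean: np.ndarray                   # per-channel mean removed before fitting
    n_components: int = 16


MARGINALIZATIONS = ("condition_independent", "context", "target", "interaction")


# ---------------------------------------------------------------------------
# Tensor construction
# ---------------------------------------------------------------------------

def _trial_window(session: SessionRecord, trial, mask: np.ndarray,
                  n_before: int, n_after: int):
    """Channel x bin window around the trial's peak-movement bin, or None."""
    pad = (n_before + 2) * BIN_MS
    pad_after = (n_after + 2) * BIN_MS
    start_ok = trial.presentation_time_ms - pad >= 0
    end_ok = trial.end_time_ms + pad_after <= session.streams.n_ms
    sl = slice_trial(session.streams, trial,
                     pad_before_ms=pad if start_ok else 0,
                     pad_after_ms=pad_after if end_ok else 0)
    binned = signals.bin_sbp(sl, BIN_MS)
    pos, vel = signals.savgol_velocity(sl.finger_position, bin_width_ms=BIN_MS)
    present_bin = (trial.presentation_time_ms - sl.time_offset_ms) // BIN_MS
    end_bin = (trial.end_time_ms - sl.time_offset_ms) // BIN_MS
    pk = signals.find_peak_movement(vel[:end_bin], presentation_bin=present_bin,
                                    bin_width_ms=BIN_MS)
    lo = pk.peak_bin_index - n_before
    hi = pk.peak_bin_index + n_after + 1
    if lo < 0 or hi > binned.n_bins:
        return None
    return binned.values[lo:hi][:, mask].T    # (N_masked, T)


def _target_label(trial) -> str:
    di = trial.target_center_index - 50.0
    if abs(di) < 1e-9:
        return "center"
    return "flexion" if di > 0 else "extension"


def build_trial_tensor(
    session: SessionRecord,
    contexts=None,
    targets=("flexion", "extension"),
    n_before: int = WINDOW_BEFORE_BINS,
    n_after: int = WINDOW_AFTER_BINS,
    balance_seed: int = 0,
) -> TrialTensor:
    """Align trials to peak movement and average per (context, target).

    Out-and-back center returns are excluded (targets default to flexion
    and extension). Unequal per-condition trial counts are balanced by
    random subsampling to the minimum count for the full dPCA tensor.
    """
    mask = channel_mask_by_tcfr(session)
    trials = select_analysis_trials(session)
    if contexts is None:
        contexts = [c for c in session.contexts]
    windows = {}
    for tr in trials:
        if tr.context not in contexts:
            continue
        lab = _target_label(tr)
        if lab not in targets:
            continue
        w = _trial_window(session, tr, mask, n_before, n_after)
        if w is None:
            continue
        windows.setdefault((tr.context, lab), []).append(w)
    missing = [(c, t) for c in contexts for t in targets if (c, t) not in windows]
    if missing:
        raise ValueError(f"conditions with zero trials: {missing}")
    per_context = {}
    T = n_before + n_after + 1
    N = int(mask.sum())
    for ctx in contexts:
        avg = np.stack([np.mean(windows[(ctx, t)], axis=0) for t in targets], axis=2)
        per_context[ctx] = avg      # (N, T, D)
    n_min = min(len(v) for v in windows.values())
    rng = np.random.default_rng(balance_seed)
    full = np.empty((N, len(contexts), len(targets), T, n_min))
    counts = {}
    tw = {}
    for ci, ctx in enumerate(contexts):
        for di, t in enumerate(targets):
            ws = windows[(ctx, t)]
            counts[(ctx, t)] = len(ws)
            tw[(ctx, t)] = np.stack(ws)
            pick = rng.choice(len(ws), size=n_min, replace=False)
            for ni, pi in enumerate(pick):
                full[:, ci, di, :, ni] = ws[pi]
    return TrialTensor(per_context=per_context, full=full,
                       contexts=list(contexts), targets=list(targets),
                       trial_counts=counts, trial_windows=tw,
                       window_bins=(n_before, n_after))


# ---------------------------------------------------------------------------
# PCA manifolds and principal angles
# ---------------------------------------------------------------------------

def fit_pca_manifold(tensor_ctx: np.ndarray, K: int = 16,
                     context: str = "") -> ContextManifold:
    """Top-K PCA basis of an N x T x D (or N x M) trial-averaged tensor."""
    X = np.asarray(tensor_ctx, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    K = min(K, s.size)
    var = s**2 / max(X.shape[1] - 1, 1)
    return ContextManifold(basis=U[:, :K], explained_variance=var[:K],
                           context=context)


def principal_angles(basis_a: np.ndarray, basis_b: np.ndarray,
                     degrees: bool = True) -> np.ndarray:
    """Principal angles between two subspaces, ascending.

    Computed as arccos of the singular values of ``basis_a.T @ basis_b``.
    Non-orthonormal inputs are re-orthonormalized with a warning.
    """
    A, B = np.asarray(basis_a, float), np.asarray(basis_b, float)
    for name, M in (("first", A), ("second", B)):
        if not np.allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-8):
            warnings.warn(f"{name} basis not orthonormal; re-orthonormalizing")
            Mq, _ = np.linalg.qr(M)
            if name == "first":
                A = Mq
            else:
                B = Mq
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    ang = np.arccos(np.clip(np.sort(s)[::-1], -1.0, 1.0))
    ang = np.sort(ang)
    return np.degrees(ang) if degrees else ang


def control_angle_distribution(
    tensor: TrialTensor,
    set_size: int = 50,
    reps: int = 100,
    K: int = 16,
    seed: int = 0,
    context: str = "normal",
) -> dict:
    """Within-context control distribution of principal angles.

    Per repetition two disjoint random sets of ``set_size`` normal trials
    (pooled over targets, resplit per target) give two manifolds; their
    principal angles estimate the sampling floor against which
    cross-context angles are judged.
    """
    rng = np.random.default_rng(seed)
    per_target = {t: tensor.trial_windows[(context, t)] for t in tensor.targets}
    n_avail = min(w.shape[0] for w in per_target.values())
    per_set = max(1, set_size // len(tensor.targets))
    if n_avail < 2 * per_set:
        per_set = n_avail // 2
        if per_set < 1:
            raise ValueError("too few normal trials for disjoint control sets")
        logger.warning("control sets reduced to %d trials per target", per_set)
    all_angles = []
    for _ in range(reps):
        avg_a, avg_b = [], []
        for t in tensor.targets:
            w = per_target[t]
            idx = rng.permutation(w.shape[0])
            a_idx, b_idx = idx[:per_set], idx[per_set:2 * per_set]
            avg_a.append(w[a_idx].mean(axis=0))
            avg_b.append(w[b_idx].mean(axis=0))
        Xa = np.stack(avg_a, axis=2)
        Xb = np.stack(avg_b, axis=2)
        ma = fit_pca_manifold(Xa, K)
        mb = fit_pca_manifold(Xb, K)
        all_angles.append(principal_angles(ma.basis, mb.basis))
    arr = np.asarray(all_angles)
    return {"angles": arr, "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if reps > 1 else np.zeros(arr.shape[1])}


# ---------------------------------------------------------------------------
# Demixed PCA
# ---------------------------------------------------------------------------

def marginalize(Xbar: np.ndarray) -> dict:
    """Additive marginalization of centered condition averages.

    ``Xbar`` is (N, C, D, T), already centered per channel. The parts —
    time (condition independent), context(+time), target(+time), and the
    context-by-target interaction — are mutually orthogonal under the
    balanced averaging inner product and sum to ``Xbar`` exactly.
    """
    Xt = Xbar.mean(axis=(1, 2), keepdims=True) * np.ones_like(Xbar)
    Xct = Xbar.mean(axis=2, keepdims=True) * np.ones_like(Xbar) - Xt
    Xdt = Xbar.mean(axis=1, keepdims=True) * np.ones_like(Xbar) - Xt
    Xint = Xbar - Xt - Xct - Xdt
    return {"condition_independent": Xt, "context": Xct,
            "target": Xdt, "interaction": Xint}


def marginalization_variance(full: np.ndarray = None, Xbar: np.ndarray = None) -> dict:
    """Fraction of condition-average variance in each marginalization."""
    if Xbar is None:
        Xbar = np.asarray(full, dtype=float).mean(axis=-1)
    Xbar = Xbar - Xbar.mean(axis=(1, 2, 3), keepdims=True)
    parts = marginalize(Xbar)
    total = float((Xbar**2).sum())
    if total == 0:
        return {k: 0.0 for k in parts}
    return {k: float((v**2).sum()) / total for k, v in parts.items()}


def _allocate_components(var_frac: dict, n_components: int) -> dict:
    """Split the component budget across marginalizations by variance share."""
    keys = list(MARGINALIZATIONS)
    raw = np.array([max(var_frac.get(k, 0.0), 0.0) for k in keys])
    if raw.sum() == 0:
        raw = np.ones(len(keys))
    alloc = np.floor(raw / raw.sum() * n_components).astype(int)
    alloc[(raw > 1e-12) & (alloc == 0)] = 1
    while alloc.sum() > n_components:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_components:
        frac = raw / raw.sum() * n_components - alloc
        alloc[np.argmax(frac)] += 1
    return dict(zip(keys, alloc.tolist()))


def dpca_fit(full: np.ndarray, n_components: int = 16,
             regularization: float = 1e-6,
             allocation: dict = None) -> DPCAResult:
    """Demixed PCA by per-marginalization reduced-rank ridge regression.

    ``full`` is the balanced (N, C, D, T, n) tensor. For each
    marginalization X_phi of the centered condition averages X, decoder
    and encoder maps minimize ||X_phi - F D X||^2 + mu ||F D||^2 with
    rank equal to that marginalization's component budget; mu is
    ``regularization`` times the total variance. Components are ordered
    by explained variance within their marginalization.
    """
    full = np.asarray(full, dtype=float)
    if full.ndim != 5:
        raise ValueError("expected balanced (N, C, D, T, n) tensor; "
                         "run build_trial_tensor to balance conditions")
    Xbar = full.mean(axis=-1)
    mean = Xbar.mean(axis=(1, 2, 3), keepdims=True)
    Xbar = Xbar - mean
    parts = marginalize(Xbar)
    var_frac = {k: float((v**2).sum()) for k, v in parts.items()}
    total = sum(var_frac.values())
    var_frac = {k: v / total if total else 0.0 for k, v in var_frac.items()}
    if allocation is None:
        allocation = _allocate_components(var_frac, n_components)
    N = Xbar.shape[0]
    Xf = Xbar.reshape(N, -1)
    mu = regularization * float((Xf**2).sum())
    G = Xf @ Xf.T + mu * np.eye(N)
    Ginv = np.linalg.inv(G)
    encoders, decoders, comp_var = {}, {}, {}
    for k, part in parts.items():
        q = allocation.get(k, 0)
        Pf = part.reshape(N, -1)
        if q == 0 or (Pf**2).sum() == 0:
            encoders[k] = np.zeros((N, 0))
            decoders[k] = np.zeros((0, N))
            comp_var[k] = np.zeros(0)
            continue
        A = Pf @ Xf.T @ Ginv           # full-rank regression map
        Z = A @ Xf
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        U = U[:, :q]
        encoders[k] = U
        decoders[k] = U.T @ A
        proj = decoders[k] @ Xf
        comp_var[k] = (proj**2).sum(axis=1) / float((Xf**2).sum())
    return DPCAResult(encoders=encoders, decoders=decoders,
                      variance_fraction=var_frac, component_variance=comp_var,
                      marginalized=parts, mean=mean,
                      n_components=sum(allocation.values()))


def context_component_vs_muscle(
    dpca_result: DPCAResult,
    tensor: TrialTensor,
    session: SessionRecord,
    peri_bins: int = 10,
    holdout_full: np.ndarray = None,
) -> dict:
    """Correlate the top context component with active-muscle activation.

    Per (context, target) condition: the mean activation of the leading
    context-marginalization component in the peri-movement window is
    paired with the mean envelope of the active muscle group (flexors for
    flexion targets, extensors for extension). Pearson r is computed
    across contexts within each target group.
    """
    if dpca_result.decoders["context"].shape[0] == 0:
        raise ValueError("no context components in the dPCA result")
    dec = dpca_result.decoders["context"][0]     # (N,)
    n_before, _ = tensor.window_bins
    lo, hi = n_before - peri_bins, n_before + peri_bins + 1
    env = session.streams.emg_envelope_1khz
    if env is None:
        raise ValueError("session carries no EMG envelope")
    trials = select_analysis_trials(session)
    # mean active-muscle envelope per (context, target)
    env_by_cond = {}
    for tr in trials:
        lab = _target_label(tr)
        if lab not in tensor.targets or tr.context not in tensor.contexts:
            continue
        seg = env[tr.presentation_time_ms:tr.end_time_ms]
        group = slice(0, 4) if lab == "flexion" else slice(4, 8)
        env_by_cond.setdefault((tr.context, lab), []).append(
            float(seg[:, group].mean()))
    # target-specific context effect: the context marginalization is
    # target-averaged by construction, so add the interaction part.
    # When held-out trials are supplied, project THEIR marginalization so
    # the component's fitting noise is independent of the evaluation data.
    if holdout_full is not None:
        Xbar = np.asarray(holdout_full, dtype=float).mean(axis=-1)
        Xbar = Xbar - Xbar.mean(axis=(1, 2, 3), keepdims=True)
        parts = marginalize(Xbar)
    else:
        parts = dpca_result.marginalized
    Xct = parts["context"] + parts["interaction"]   # (N, C, D, T)
    out = {}
    for di, lab in enumerate(tensor.targets):
        comp_means, muscle_means = [], []
        for ci, ctx in enumerate(tensor.contexts):
            # project the context marginalization: the component's
            # context-specific activation, free of target/time leakage
            proj = dec @ Xct[:, ci, di, :]              # (T,)
            comp_means.append(float(proj[lo:hi].mean()))
            muscle_means.append(float(np.mean(env_by_cond[(ctx, lab)])))
        if len(comp_means) < 4:
            logger.warning("only %d (context) points for %s correlation",
                           len(comp_means), lab)
        r = np.corrcoef(comp_means, muscle_means)[0, 1] \
            if len(comp_means) >= 2 else float("nan")
        out[lab] = {"r": float(r), "component_means": comp_means,
                    "muscle_means": muscle_means}
    return out


def pooled_context_muscle_correlation(per_session: list) -> dict:
    """Pool the component-vs-muscle points of several sessions.

    ``per_session`` holds the dicts returned by
    :func:`context_component_vs_muscle`. Each session's component sign is
    ambiguous (PCA-like), so sessions are oriented to make the
    flexion-group slope positive before pooling; Pearson r is then
    computed per target group across all (session, context) points.
    """
    oriented = []
    for res in per_session:
        cf = np.asarray(res["flexion"]["component_means"])
        mf = np.asarray(res["flexion"]["muscle_means"])
        slope = np.corrcoef(cf, mf)[0, 1] if cf.size >= 2 else 1.0
        flip = -1.0 if slope < 0 else 1.0
        oriented.append({g: {
            "component_means": flip * np.asarray(res[g]["component_means"]),
            "muscle_means": np.asarray(res[g]["muscle_means"]),
        } for g in res})
    out = {}
    for g in oriented[0]:
        comp = np.concatenate([o[g]["component_means"] for o in oriented])
        mus = np.concatenate([o[g]["muscle_means"] for o in oriented])
        out[g] = {"r": float(np.corrcoef(comp, mus)[0, 1]),
                  "n_points": int(comp.size)}
    return out
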