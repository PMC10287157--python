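"""Config-driven pipeline orchestration and report generation.

A YAML run configuration names the stages to execute in order
(simulate -> features -> tuning -> decode_offline -> simulate_online ->
patterns -> geometry -> report), a global seed, and per-stage parameter
blocks. Per-stage seeds are derived deterministically from the global
seed and the stage name so reruns are byte-identical. Each stage writes
its outputs under the run directory and registers them in a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import closed_loop, geometry, offline, patterns, synth, tuning
from .session import read_session, write_session
from .synth import GeneratorConfig, hash_name

logger = logging.getLogger("fingerctx")

STAGE_ORDER = ["simulate", "features", "tuning", "decode_offline",
               "simulate_online", "patterns", "geometry", "report"]


@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    out_dir: str = "fingerctx_run"
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        stages = raw.get("stages", STAGE_ORDER)
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
        return cls(stages=stages, seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir", "fingerctx_run"),
                   log_level=raw.get("log_level", "INFO"),
                   params={k: v for k, v in raw.items()
                           if k not in ("stages", "seed", "out_dir", "log_level")})


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1_000_003 + hash_name(stage)) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the output manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}}
    ctxobj = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.time()
        logger.info("stage %s starting", stage)
        try:
            _STAGES[stage](config, out, manifest, ctxobj)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline aborted in stage {stage!r}") from None
        manifest["stages"][stage] = {"wall_s": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest


def _get_session(config, out, ctxobj):
    if "session" in ctxobj:
        return ctxobj["session"]
    path = out / "session.h5"
    if path.exists():
        ctxobj["session"] = read_session(path)
        return ctxobj["session"]
    raise FileNotFoundError("no session available; run the simulate stage first")


def _stage_simulate(config, out, manifest, ctxobj):
    p = dict(config.params.get("simulate", {}))
    schedule = p.pop("context_schedule",
                     [["normal", 100], ["spring", 100], ["normal", 100]])
    schedule = [tuple(b) if not isinstance(b, str) else b for b in schedule]
    task = p.pop("task", "center_out_1dof")
    cfg = GeneratorConfig(seed=stage_seed(config.seed, "simulate"), **p)
    session = synth.generate_session(cfg, schedule, task=task)
    write_session(session, out / "session.h5")
    ctxobj["session"] = session
    ctxobj["generator_config"] = cfg
    manifest["outputs"]["session"] = str(out / "session.h5")


def _stage_features(config, out, manifest, ctxobj):
    from . import signals
    session = _get_session(config, out, ctxobj)
    p = config.params.get("features", {})
    bw = int(p.get("bin_ms", 32))
    binned = signals.bin_sbp(session.streams, bw)
    df = pd.DataFrame(binned.values)
    df.insert(0, "bin_start_ms", binned.bin_start_times_ms)
    path = out / f"features_sbp_{bw}ms.csv"
    df.to_csv(path, index=False)
    manifest["outputs"]["features"] = str(path)


def _stage_tuning(config, out, manifest, ctxobj):
    session = _get_session(config, out, ctxobj)
    p = config.params.get("tuning", {})
    res = tuning.tuning_summary(session, feature=p.get("feature", "sbp"),
                                fdr_level=float(p.get("fdr", 0.001)))
    path = out / "tuning.csv"
    res.per_channel.to_csv(path, index=False)
    manifest["outputs"]["tuning"] = str(path)
    manifest["outputs"]["tuning_summary"] = {
        "n_tuned": res.n_tuned,
        "n_context_modulated": res.n_context_modulated,
        "pct_modulated_among_tuned": res.pct_modulated_among_tuned,
    }
    ctxobj["tuning"] = res


def _stage_decode_offline(config, out, manifest, ctxobj):
    session = _get_session(config, out, ctxobj)
    p = config.params.get("decode_offline", {})
    res = offline.crossval_generalization(
        session, target=p.get("target", "kinematics"),
        folds=int(p.get("folds", 10)),
        ridge_lambda=p.get("ridge_lambda", "gcv"))
    path = out / "offline_metrics.csv"
    res.summary.to_csv(path, index=False)
    res.per_fold.to_csv(out / "offline_metrics_per_fold.csv", index=False)
    manifest["outputs"]["decode_offline"] = str(path)
    ctxobj["offline"] = res


def _stage_simulate_online(config, out, manifest, ctxobj):
    p = config.params.get("simulate_online", {})
    gen_cfg = ctxobj.get("generator_config") or GeneratorConfig(
        seed=stage_seed(config.seed, "simulate"),
        n_channels=int(p.get("n_channels", 96)))
    seed = stage_seed(config.seed, "simulate_online")
    encoder = synth.LinearEncoder.from_config(gen_cfg)
    decoder = train_decoder_from_encoder(encoder, seed=seed)
    schedule = [tuple(b) for b in p.get(
        "context_schedule", [["normal", 50], ["spring", 50]])]
    gains = {c: (gen_cfg.context_gain_flexor.get(c, 1.0),
                 gen_cfg.context_gain_extensor.get(c, 1.0)) for c, _ in schedule}
    results = closed_loop.simulate_closed_loop(
        encoder, closed_loop.IntentionModel(), decoder,
        context_schedule=schedule, context_gains=gains, seed=seed)
    rows = [{"trial": r.trial_index, "context": r.context, "success": r.success,
             "acquisition_ms": r.acquisition_time_ms,
             "time_to_target_ms": r.time_to_target_ms,
             "orbiting_ms": r.orbiting_time_ms,
             "path_efficiency": r.path_efficiency} for r in results]
    path = out / "online_trials.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    manifest["outputs"]["simulate_online"] = str(path)
    ctxobj["online_results"] = results


def train_decoder_from_encoder(encoder, n_train_trials: int = 60, seed: int = 0):
    """Open-loop training pass: minimum-jerk movements through the encoder."""
    rng = np.random.default_rng(seed)
    kin, feats = [], []
    pos = np.array([50.0, 50.0])
    for i in range(n_train_trials):
        target = np.array([50.0, 50.0]) if i % 2 else \
            50.0 + rng.choice([-40.0, 40.0]) * np.ones(2)
        n_steps = 40
        traj = pos + (target - pos) * (
            10 * (np.arange(n_steps) / (n_steps - 1))**3
            - 15 * (np.arange(n_steps) / (n_steps - 1))**4
            + 6 * (np.arange(n_steps) / (n_steps - 1))**5)[:, None]
        vel = np.gradient(traj, closed_loop.DT_S, axis=0)
        for p_, v_ in zip(traj, vel):
            feats.append(encoder.encode(p_, v_, rng))
            kin.append([p_[0], p_[1], v_[0], v_[1]])
        pos = target
    return closed_loop.fit_kalman(np.asarray(feats), np.asarray(kin))


def _stage_patterns(config, out, manifest, ctxobj):
    session = _get_session(config, out, ctxobj)
    results = ctxobj.get("online_results")
    if results is None:
        raise FileNotFoundError("patterns stage needs simulate_online outputs")
    readout = patterns.fit_pattern_readout(session)
    pats = patterns.extract_patterns(results, readout)
    comp = patterns.compare_pattern_groups(pats)
    path = out / "patterns.csv"
    pd.DataFrame([{
        "trial": p.trial_index, "context": p.context,
        "group": p.movement_group, "push": p.pushing_magnitude,
    } for p in pats]).to_csv(path, index=False)
    comp.to_csv(out / "pattern_comparison.csv", index=False)
    manifest["outputs"]["patterns"] = str(path)
    ctxobj["patterns"] = pats


def _stage_geometry(config, out, manifest, ctxobj):
    session = _get_session(config, out, ctxobj)
    p = config.params.get("geometry", {})
    K = int(p.get("K", 16))
    tensor = geometry.build_trial_tensor(
        session, balance_seed=stage_seed(config.seed, "geometry"))
    manifolds = {c: geometry.fit_pca_manifold(tensor.per_context[c], K, c)
                 for c in tensor.contexts}
    rows = []
    normal = manifolds.get("normal")
    ctrl = geometry.control_angle_distribution(
        tensor, set_size=int(p.get("control_set_size", 50)),
        reps=int(p.get("control_reps", 100)),
        K=K, seed=stage_seed(config.seed, "geometry_ctrl"))
    for c, m in manifolds.items():
        if c == "normal" or normal is None:
            continue
        ang = geometry.principal_angles(normal.basis, m.basis)
        for rank, a in enumerate(ang):
            rows.append({"rank": rank + 1, "context": c, "angle_deg": a,
                         "control_mean": ctrl["mean"][rank],
                         "control_sd": ctrl["sd"][rank]})
    path = out / "principal_angles.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    dp = geometry.dpca_fit(tensor.full, n_components=K)
    with open(out / "dpca_variance.json", "w") as f:
        json.dump(dp.variance_fraction, f, indent=2)
    manifest["outputs"]["geometry"] = str(path)
    manifest["outputs"]["dpca_variance"] = dp.variance_fraction
    ctxobj["tensor"] = tensor
    ctxobj["dpca"] = dp


def _stage_report(config, out, manifest, ctxobj):
    """Summary tables and figures from whatever stages have run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    ang_path = out / "principal_angles.csv"
    if ang_path.exists():
        df = pd.read_csv(ang_path)
        if len(df):
            fig, ax = plt.subplots(figsize=(5, 4))
            for c, grp in df.groupby("context"):
                ax.plot(grp["rank"], grp.angle_deg, marker="o", label=c)
            g0 = df[df.context == df.context.iloc[0]]
            ax.fill_between(g0["rank"], g0.control_mean - 2 * g0.control_sd,
                            g0.control_mean + 2 * g0.control_sd, alpha=0.3,
                            color="gray", label="control ±2 sd")
            ax.set_xlabel("principal angle rank")
            ax.set_ylabel("angle (deg)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / "principal_angles.png", dpi=120)
            plt.close(fig)
            made.append("principal_angles.png")
    dv_path = out / "dpca_variance.json"
    if dv_path.exists():
        with open(dv_path) as f:
            dv = json.load(f)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(list(dv.keys()), [100 * v for v in dv.values()])
        ax.set_ylabel("% variance")
        plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
        fig.tight_layout()
        fig.savefig(out / "dpca_variance.png", dpi=120)
        plt.close(fig)
        made.append("dpca_variance.png")
    om = out / "offline_metrics.csv"
    if om.exists():
        df = pd.read_csv(om)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        piv = df.pivot(index="output", columns="test_set", values="nmse_mean")
        piv.plot.bar(ax=ax)
        ax.set_ylabel("nMSE")
        fig.tight_layout()
        fig.savefig(out / "offline_nmse.png", dpi=120)
        plt.close(fig)
        made.append("offline_nmse.png")
    manifest["outputs"]["report"] = made


_STAGES = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "tuning": _stage_tuning,
    "decode_offline": _stage_decode_offline,
    "simulate_online": _stage_simulate_online,
    "patterns": _stage_patterns,
    "geometry": _stage_geometry,
    "report": _stage_report,
}
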