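"""Trial tensors, PCA manifolds, principal angles, and demixed PCA."""

import numpy as np
import pytest

import fingerctx as fc
from fingerctx.geometry import (
    MARGINALIZATIONS, _allocate_components, marginalize,
)


def _rotation_basis(theta_deg, n=10):
    """Two 2-D planes sharing one axis, rotated by theta about it."""
    th = np.radians(theta_deg)
    A = np.zeros((n, 2))
    A[0, 0] = 1.0
    A[1, 1] = 1.0
    B = np.zeros((n, 2))
    B[0, 0] = 1.0
    B[1, 1] = np.cos(th)
    B[2, 1] = np.sin(th)
    return A, B


def test_principal_angles_identity_and_orthogonal():
    I = np.eye(6)
    np.testing.assert_allclose(fc.principal_angles(I[:, :3], I[:, :3]), 0.0,
                               atol=1e-9)
    assert fc.principal_angles(I[:, :1], I[:, 1:2])[0] == pytest.approx(90.0)


@pytest.mark.parametrize("theta", [10.0, 45.0, 80.0])
def test_principal_angles_planted_rotation(theta):
    A, B = _rotation_basis(theta)
    ang = fc.principal_angles(A, B)
    np.testing.assert_allclose(ang, [0.0, theta], atol=1e-6)


def test_principal_angles_symmetry_and_rotation_invariance():
    rng = np.random.default_rng(0)
    A = np.linalg.qr(rng.standard_normal((12, 4)))[0]
    B = np.linalg.qr(rng.standard_normal((12, 4)))[0]
    ab = fc.principal_angles(A, B)
    ba = fc.principal_angles(B, A)
    np.testing.assert_allclose(ab, ba, atol=1e-9)
    R = np.linalg.qr(rng.standard_normal((4, 4)))[0]
    np.testing.assert_allclose(fc.principal_angles(A @ R, B), ab, atol=1e-8)
    assert (np.diff(ab) >= -1e-12).all()
    assert (ab >= -1e-12).all() and (ab <= 90 + 1e-12).all()


def test_principal_angles_reorthonormalizes_with_warning():
    rng = np.random.default_rng(1)
    A = rng.standard_normal((8, 2)) * 3
    with pytest.warns(UserWarning, match="orthonormal"):
        ang = fc.principal_angles(A, A)
    np.testing.assert_allclose(ang, 0.0, atol=1e-4)


def test_fit_pca_manifold_planted_subspace():
    rng = np.random.default_rng(2)
    basis = np.linalg.qr(rng.standard_normal((20, 3)))[0]
    X = basis @ rng.standard_normal((3, 200))
    man = fc.fit_pca_manifold(X, K=3)
    assert fc.principal_angles(man.basis, basis).max() < 1e-4
    full = fc.fit_pca_manifold(X + rng.standard_normal((20, 200)), K=20)
    assert (np.diff(full.explained_variance) <= 1e-9).all()
    total = (X + 0).var()   # K = N captures everything for the planted case
    assert man.explained_variance.sum() == pytest.approx(
        (X - X.mean(axis=1, keepdims=True)).var(axis=1, ddof=0).sum()
        * 200 / 199, rel=1e-6)


def test_build_trial_tensor_window_and_averaging(multi_context_session):
    tensor = fc.build_trial_tensor(multi_context_session)
    n_before, n_after = tensor.window_bins
    assert n_before + 1 + n_after == 58       # 400 ms + peak bin + 740 ms
    N, C, D, T, n = tensor.full.shape
    assert C == 4 and D == 2 and T == 58 and n >= 2
    # per-context averages equal the mean of the stored per-trial windows
    for (ctx, lab), w in tensor.trial_windows.items():
        di = tensor.targets.index(lab)
        np.testing.assert_allclose(tensor.per_context[ctx][:, :, di],
                                   w.mean(axis=0), atol=1e-10)


def test_build_trial_tensor_missing_condition_raises(two_context_session):
    with pytest.raises(ValueError, match="zero trials"):
        fc.build_trial_tensor(two_context_session, contexts=["normal", "wrist"])


def test_control_angles_noiseless_low_rank():
    """Sampling cannot move an exact subspace: control angles stay ~0."""
    rng = np.random.default_rng(3)
    basis = np.linalg.qr(rng.standard_normal((15, 4)))[0]
    windows = {}
    for lab in ("flexion", "extension"):
        z = rng.standard_normal((30, 4, 25))
        windows[("normal", lab)] = np.einsum("nk,tkb->tnb", basis, z)
    tensor = fc.geometry.TrialTensor(
        per_context={}, full=np.zeros((15, 1, 2, 25, 2)),
        contexts=["normal"], targets=["flexion", "extension"],
        trial_counts={}, trial_windows=windows, window_bins=(12, 12))
    ctrl = fc.control_angle_distribution(tensor, set_size=20, reps=10, K=4)
    assert ctrl["mean"].max() < 1e-4
    one = fc.control_angle_distribution(tensor, set_size=20, reps=1, K=4)
    np.testing.assert_array_equal(one["sd"], 0.0)


def test_control_angles_bracket_offcontext(multi_context_session):
    """Off-context angles fall near the within-context control band."""
    tensor = fc.build_trial_tensor(multi_context_session)
    K = 8
    manifolds = {c: fc.fit_pca_manifold(tensor.per_context[c], K, c)
                 for c in tensor.contexts}
    ctrl = fc.control_angle_distribution(tensor, set_size=20, reps=30, K=K,
                                         seed=0)
    ang = fc.principal_angles(manifolds["normal"].basis,
                              manifolds["spring"].basis)
    within = np.abs(ang - ctrl["mean"]) <= 2.5 * ctrl["sd"] + 5.0
    assert within.mean() > 0.6


# ---------------------------------------------------------------------------
# Demixed PCA
# ---------------------------------------------------------------------------

def _random_tensor(seed=0, N=12, C=3, D=2, T=20, n=5):
    return np.random.default_rng(seed).standard_normal((N, C, D, T, n))


def test_marginalization_parts_sum_exactly():
    full = _random_tensor()
    Xbar = full.mean(axis=-1)
    Xbar -= Xbar.mean(axis=(1, 2, 3), keepdims=True)
    parts = marginalize(Xbar)
    np.testing.assert_allclose(sum(parts.values()), Xbar, atol=1e-10)
    # mutual orthogonality under the averaging inner product
    keys = list(parts)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            assert abs((parts[a] * parts[b]).sum()) < 1e-8


def test_marginalization_variance_fractions_sum_to_one():
    for seed in range(5):
        frac = fc.marginalization_variance(_random_tensor(seed))
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-6)
    # pure condition-independent data: the time fraction takes everything
    N, C, D, T, n = 6, 2, 2, 15, 4
    t_profile = np.sin(np.linspace(0, 3, T))
    pure = np.tile(t_profile, (N, C, D, 1))[..., None] * np.ones(n)
    frac = fc.marginalization_variance(pure)
    assert frac["condition_independent"] == pytest.approx(1.0, abs=1e-9)


def test_dpca_pure_target_structure():
    """Target-only data: target marginalization owns the non-noise variance."""
    rng = np.random.default_rng(4)
    N, C, D, T, n = 16, 2, 2, 30, 60
    dirs = np.linalg.qr(rng.standard_normal((N, 2)))[0]
    profile = np.sin(np.linspace(0, np.pi, T))
    full = 0.02 * rng.standard_normal((N, C, D, T, n))
    for d, sign in enumerate((1.0, -1.0)):
        full[:, :, d] += (dirs[:, :1] * sign * 3.0 * profile)[:, None, :, None]
    frac = fc.marginalization_variance(full)
    nonnoise = frac["target"] + frac["interaction"]
    assert frac["target"] / (frac["target"] + frac["context"]
                             + frac["interaction"]) > 0.99
    dp = fc.dpca_fit(full, n_components=8)
    assert dp.variance_fraction["target"] > 0.9
    # top target component aligns with the planted direction
    ang = fc.principal_angles(dp.encoders["target"][:, :1], dirs[:, :1])
    assert ang[0] < 5.0


def test_dpca_reconstruction_identity_and_errors():
    full = _random_tensor(seed=5)
    dp = fc.dpca_fit(full, n_components=8)
    assert sum(dp.variance_fraction.values()) == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(
        sum(dp.marginalized.values()),
        full.mean(axis=-1) - full.mean(axis=(1, 2, 3, 4), keepdims=True)[..., 0],
        atol=1e-10)
    with pytest.raises(ValueError, match="balance"):
        fc.dpca_fit(full.mean(axis=-1))


def test_dpca_context_subspace_recovery_low_noise():
    """At low noise the top context component lies in the planted span."""
    cfg = fc.GeneratorConfig(seed=55, n_channels=32, noise_sd_sbp=0.1)
    session = fc.generate_session(
        cfg, [("normal", 60), ("spring", 60), ("wrist", 60)])
    tensor = fc.build_trial_tensor(session)
    dp = fc.dpca_fit(tensor.full, n_components=16)
    from fingerctx.offline import channel_mask_by_tcfr
    L = cfg.latent_loading[channel_mask_by_tcfr(session)]
    span = np.linalg.qr(L[:, 5:9])[0]    # context + interaction loadings
    ang = fc.principal_angles(dp.encoders["context"][:, :1], span)[0]
    assert ang < 15.0


def test_component_allocation_budget():
    alloc = _allocate_components(
        {"condition_independent": 0.5, "context": 0.3, "target": 0.2,
         "interaction": 0.0}, 16)
    assert sum(alloc.values()) == 16
    assert alloc["interaction"] == 0
    assert alloc["condition_independent"] >= alloc["context"] >= alloc["target"]


def test_context_component_vs_muscle_recovers_gains(multi_context_session):
    """Split-half context component tracks active-muscle activation."""
    tensor = fc.build_trial_tensor(multi_context_session)
    n = tensor.full.shape[-1]
    dp = fc.dpca_fit(tensor.full[..., :n // 2], n_components=16)
    res = fc.context_component_vs_muscle(
        dp, tensor, multi_context_session,
        holdout_full=tensor.full[..., n // 2:])
    assert abs(res["flexion"]["r"]) >= 0.9
    assert abs(res["extension"]["r"]) >= 0.9
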