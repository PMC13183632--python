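"""Loss closed forms, masking monotonicity, stability, gradients."""

import numpy as np
import pytest

from pharl import (LossConfig, cosine_sim, motion_loss, physics_loss,
                   total_loss, variance_loss, warmup_weight)
from pharl.objectives import BatchEmbeddings, normalize_rows, total_loss_grad
from pharl.relations import AnchorContext, build_relations

from conftest import random_unit_rows

CFG = LossConfig()


def batch_of(z, ctxs):
    return BatchEmbeddings(z=z, raw=z.copy(), contexts=ctxs)


def contexts(spec):
    """spec: list of (traj, ordinal_code)."""
    return [AnchorContext(t, c, int(c > 0)) for t, c in spec]


def test_cosine_sim_basic_and_zero_norm():
    z = np.array([1.0, 0.0])
    assert cosine_sim(z, z) == pytest.approx(1.0)
    assert cosine_sim(z, -z) == pytest.approx(-1.0)
    assert cosine_sim(z, np.array([0.0, 2.0])) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero-norm"):
        cosine_sim(z, np.zeros(2))


def test_uniform_similarity_closed_form():
    """With all pairwise sims equal the softmax cancels and the loss is
    exactly -log(|P| / |A \\ M|) per anchor."""
    z = np.tile(np.array([1.0, 0.0]), (6, 1))
    ctxs = contexts([("a", 2), ("a", 1), ("b", 2), ("b", 0), ("c", 1), ("c", 0)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    b = batch_of(z, ctxs)
    expected = []
    for i in range(6):
        den = len(set(rel.a[i]) - set(rel.m[i]))
        expected.append(-np.log(len(rel.p_traj[i]) / den))
    assert motion_loss(b, rel, CFG) == pytest.approx(np.mean(expected), abs=1e-9)
    # physics term: -log(|P_phys| / |Q|) over contributing contact anchors
    phys = [-np.log(len(rel.p_phys[i]) / len(rel.q[i]))
            for i in range(6) if rel.p_phys[i]]
    assert phys  # cross-trajectory same-class pairs exist by construction
    assert physics_loss(b, rel, CFG) == pytest.approx(np.mean(phys), abs=1e-9)


def test_two_window_trajectory_with_unit_similarity_gives_zero():
    z = np.tile(np.array([0.0, 1.0]), (2, 1))
    ctxs = contexts([("a", 0), ("a", 0)])
    rel = build_relations(ctxs, None, "temporal_only")
    assert motion_loss(batch_of(z, ctxs), rel, CFG) == pytest.approx(0.0, abs=1e-12)


def test_masked_loss_reduces_to_plain_infonce_when_masks_empty():
    """With every mask empty, the masked trajectory loss must equal a
    from-scratch unmasked InfoNCE computed by direct enumeration."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(4, 16)) // 2 * 2
        z = random_unit_rows(rng, n, 8)
        # paired trajectories so every anchor has a temporal positive
        ctxs = contexts([(f"t{i // 2}", 0) for i in range(n)])
        rel = build_relations(ctxs, None, "temporal_only")
        assert all(not m for m in rel.m)
        # independent oracle
        vals = []
        for i in range(n):
            pos = [j for j in range(n) if j != i
                   and ctxs[j].trajectory_id == ctxs[i].trajectory_id]
            if not pos:
                continue
            num = sum(np.exp(z[i] @ z[j] / CFG.tau) for j in pos)
            den = sum(np.exp(z[i] @ z[k] / CFG.tau) for k in range(n) if k != i)
            vals.append(-np.log(num / den))
        got = motion_loss(batch_of(z, ctxs), rel, CFG)
        assert got == pytest.approx(np.mean(vals), abs=1e-9)


def test_masking_never_increases_motion_loss():
    """Removing candidates from the denominator can only shrink it, so the
    masked loss is <= its unmasked counterpart on any batch."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(4, 20))
        z = random_unit_rows(rng, n, 6)
        ctxs = contexts([(f"t{rng.integers(5)}", int(rng.integers(3)))
                         for _ in range(n)])
        rel = build_relations(ctxs, None, "multiclass_physics")
        b = batch_of(z, ctxs)
        masked = motion_loss(b, rel, CFG)
        rel_nomask = build_relations(
            [AnchorContext(c.trajectory_id) for c in ctxs], None, "temporal_only")
        unmasked = motion_loss(b, rel_nomask, CFG)
        assert masked <= unmasked + 1e-12


def test_physics_loss_degenerate_cases():
    z = random_unit_rows(np.random.default_rng(0), 4, 5)
    # all cross-trajectory candidates share the anchor's class: ratio 1
    ctxs = contexts([("a", 2), ("b", 2), ("c", 2), ("d", 2)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    b = batch_of(z, ctxs)
    assert all(set(p) == set(q) for p, q in zip(rel.p_phys, rel.q))
    assert physics_loss(b, rel, CFG) == pytest.approx(0.0, abs=1e-12)
    # Supported anchors never contribute
    ctxs = contexts([("a", 0), ("b", 0), ("c", 0), ("d", 0)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    assert physics_loss(batch_of(z, ctxs), rel, CFG) == 0.0


def test_variance_term_closed_forms():
    gamma = CFG.variance_gamma
    collapsed = np.tile(np.array([0.3, -0.2, 0.5]), (8, 1))
    # identical rows: std 0, penalty gamma up to the sqrt-epsilon
    assert variance_loss(collapsed, CFG) == pytest.approx(gamma - 1e-2, abs=1e-12)
    spread = np.random.default_rng(0).normal(scale=10 * gamma, size=(64, 4))
    assert variance_loss(spread, CFG) == 0.0
    hand = np.array([[0.0, 0.0], [2 * gamma, 2 * gamma]])
    assert variance_loss(hand, CFG) == 0.0  # per-dim std = gamma*sqrt(2) >= gamma
    with pytest.raises(ValueError, match="at least 2"):
        variance_loss(np.ones((1, 3)), CFG)


def test_warmup_schedule_and_composite_weighting():
    assert warmup_weight(0.0, 0.1) == 0.0
    assert warmup_weight(0.05, 0.1) == pytest.approx(0.5)
    assert warmup_weight(0.1, 0.1) == 1.0
    assert warmup_weight(0.9, 0.1) == 1.0
    assert warmup_weight(0.0, 0.0) == 1.0

    rng = np.random.default_rng(8)
    z = random_unit_rows(rng, 10, 6)
    ctxs = contexts([(f"t{i // 2}", int(rng.integers(3))) for i in range(10)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    b = batch_of(z, ctxs)
    # temporal-only control: zero physics and variance weights leave exactly
    # the motion term
    cfg0 = LossConfig(lambda_phys=0.0, lambda_var=0.0)
    total, terms = total_loss(b, rel, cfg0, epoch_progress=1.0)
    assert total == pytest.approx(motion_loss(b, rel, cfg0))
    # during warmup start the physics contribution is zero
    t0, terms0 = total_loss(b, rel, CFG, epoch_progress=0.0)
    assert terms0["physics_weight"] == 0.0
    assert t0 == pytest.approx(terms0["motion"] + CFG.lambda_var * terms0["variance"])


def test_losses_finite_under_similarity_scaling():
    rng = np.random.default_rng(4)
    z = random_unit_rows(rng, 12, 4)
    ctxs = contexts([(f"t{i // 3}", int(rng.integers(3))) for i in range(12)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    sharp = LossConfig(tau=CFG.tau / 50, tau_p=CFG.tau_p / 50)  # sims x50
    total, terms = total_loss(batch_of(z, ctxs), rel, sharp, 1.0)
    assert np.isfinite(total)
    assert all(np.isfinite(v) for v in terms.values())


def test_permutation_equivariance():
    rng = np.random.default_rng(10)
    z = random_unit_rows(rng, 14, 5)
    ctxs = contexts([(f"t{rng.integers(4)}", int(rng.integers(3)))
                     for _ in range(14)])
    rel = build_relations(ctxs, None, "multiclass_physics")
    ref, _ = total_loss(batch_of(z, ctxs), rel, CFG, 1.0)
    perm = rng.permutation(14)
    ctx_p = [ctxs[i] for i in perm]
    rel_p = build_relations(ctx_p, None, "multiclass_physics")
    got, _ = total_loss(batch_of(z[perm], ctx_p), rel_p, CFG, 1.0)
    assert got == pytest.approx(ref, abs=1e-9)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    raw = rng.normal(size=(7, 5))
    ctxs = contexts([("a", 2), ("a", 2), ("b", 1), ("b", 2), ("c", 0),
                     ("c", 1), ("c", 0)])
    rel = build_relations(ctxs, None, "multiclass_physics")

    def value(r):
        return total_loss(
            BatchEmbeddings(z=normalize_rows(r), raw=r, contexts=ctxs),
            rel, CFG, 1.0)[0]

    _, _, grad = total_loss_grad(
        BatchEmbeddings(z=normalize_rows(raw), raw=raw, contexts=ctxs),
        rel, CFG, 1.0)
    eps = 1e-6
    for _ in range(12):
        i, j = rng.integers(7), rng.integers(5)
        bump = np.zeros_like(raw)
        bump[i, j] = eps
        fd = (value(raw + bump) - value(raw - bump)) / (2 * eps)
        assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)
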