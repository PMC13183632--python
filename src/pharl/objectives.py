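"""Composite training objective.

Three terms share one batch of l2-normalized embeddings:

* masked trajectory contrast — an InfoNCE loss whose positives are other
  windows of the anchor's trajectory and whose denominator excludes the
  masked set (cross-trajectory contact windows of a contact anchor), so
  physically equivalent windows are not falsely repelled; with empty
  masks this is exactly the plain trajectory-contrast loss;
* physics alignment — an auxiliary InfoNCE term attracting cross-
  trajectory windows of the same contact class (Head-to-Head,
  Trunk-to-Trunk) against all cross-trajectory candidates;
* a variance regularizer — a hinge on the per-dimension standard
  deviation of the raw (pre-normalization) projector outputs, preventing
  representation collapse.

The total is ``L_motion + w * lambda_phys * L_physics + lambda_var *
L_var`` where ``w`` ramps linearly from 0 to 1 over a warmup fraction of
training. All softmax ratios are computed in log space; each term is
averaged over the anchors that actually contribute to it.

Every loss has a gradient sibling returning d(loss)/d(raw projector
outputs); the backward pass is hand-derived and checked against finite
differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .config import LossConfig
from .relations import AnchorContext, RelationGraph

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-4  # inside the square root of the std estimate


@dataclass
class BatchEmbeddings:
    """Embeddings of one batch: normalized, raw, and anchor metadata."""

    z: np.ndarray                      # (B, d), rows l2-normalized
    raw: np.ndarray                    # (B, d) projector outputs pre-normalization
    contexts: list[AnchorContext] = field(default_factory=list)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.z, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("batch embeddings must be l2-normalized")


def normalize_rows(raw: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding cannot be normalized")
    return raw / norms


def cosine_sim(z_i: np.ndarray, z_k: np.ndarray) -> float:
    """Cosine similarity of two vectors (unit dot product)."""
    ni, nk = np.linalg.norm(z_i), np.linalg.norm(z_k)
    if ni == 0 or nk == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.dot(z_i, z_k) / (ni * nk))


# ---------------------------------------------------------------------------
# Shared InfoNCE core
# ---------------------------------------------------------------------------


def _nce(
    z_batch: np.ndarray,
    z_all: np.ndarray,
    pos_sets: list[list[int]],
    den_sets: list[list[int]],
    tau: float,
    want_grad: bool,
) -> tuple[float, int, np.ndarray | None]:
    """Mean of -log(sum_pos e^{s/tau} / sum_den e^{s/tau}) over anchors
    with nonempty positive and denominator sets. Gradient is with respect
    to ``z_batch``; candidate entries beyond the batch (memory bank) get
    none."""
    B = len(z_batch)
    S = (z_batch @ z_all.T) / tau
    contrib = [i for i in range(B) if pos_sets[i] and den_sets[i]]
    if not contrib:
        return 0.0, 0, (np.zeros_like(z_batch) if want_grad else None)
    total = 0.0
    G = np.zeros((B, len(z_all))) if want_grad else None
    for i in contrib:
        pos, den = pos_sets[i], den_sets[i]
        lse_p = logsumexp(S[i, pos])
        lse_d = logsumexp(S[i, den])
        total += lse_d - lse_p
        if want_grad:
            G[i, den] += np.exp(S[i, den] - lse_d)
            G[i, pos] -= np.exp(S[i, pos] - lse_p)
    loss = total / len(contrib)
    if not want_grad:
        return loss, len(contrib), None
    G /= tau * len(contrib)
    dZ = G @ z_all
    dZ += G[:, :B].T @ z_batch  # batch rows also appear as candidates
    return loss, len(contrib), dZ


def _motion_sets(rel: RelationGraph) -> tuple[list[list[int]], list[list[int]]]:
    dens = []
    for i in range(rel.n_batch):
        m = set(rel.m[i])
        den = [k for k in rel.a[i] if k not in m] if m else rel.a[i]
        if not den and rel.p_traj[i]:
            logger.warning("anchor %d: denominator empty after masking; skipped", i)
        dens.append(den)
    return rel.p_traj, dens


def motion_loss(
    batch: BatchEmbeddings,
    rel: RelationGraph,
    cfg: LossConfig,
    bank_z: np.ndarray | None = None,
) -> float:
    """Masked trajectory-contrast loss, mean over contributing anchors."""
    z_all = _stack(batch.z, bank_z, rel)
    pos, den = _motion_sets(rel)
    loss, _, _ = _nce(batch.z, z_all, pos, den, cfg.tau, want_grad=False)
    return loss


def physics_loss(
    batch: BatchEmbeddings,
    rel: RelationGraph,
    cfg: LossConfig,
    bank_z: np.ndarray | None = None,
) -> float:
    """Physics-alignment loss over contact anchors with nonempty positives.

    Anchors with an empty physics positive set (no cross-trajectory
    same-class partner) are skipped; returns 0 when none contribute.
    """
    z_all = _stack(batch.z, bank_z, rel)
    loss, n, _ = _nce(batch.z, z_all, rel.p_phys, rel.q, cfg.tau_p, want_grad=False)
    if n == 0:
        logger.debug("physics term: no contributing anchors in batch")
    return loss


def variance_loss(raw: np.ndarray, cfg: LossConfig) -> float:
    """Hinge on per-dimension std of raw projector outputs.

    ``mean_j max(0, gamma - sqrt(var_j + eps))`` with the variance taken
    over the batch. A collapsed batch (identical rows) pays the maximal
    penalty of about gamma.
    """
    value, _ = _variance_grad(raw, cfg, want_grad=False)
    return value


def _variance_grad(raw, cfg, want_grad):
    raw = np.asarray(raw, dtype=np.float64)
    B, d = raw.shape
    if B < 2:
        raise ValueError("variance term needs a batch of at least 2")
    mean = raw.mean(axis=0)
    var = ((raw - mean) ** 2).sum(axis=0) / (B - 1)
    std = np.sqrt(var + _VAR_EPS)
    hinge = np.maximum(0.0, cfg.variance_gamma - std)
    value = float(hinge.mean())
    if not want_grad:
        return value, None
    active = hinge > 0
    grad = np.zeros_like(raw)
    if active.any():
        grad[:, active] = -(raw[:, active] - mean[active]) / (
            (B - 1) * std[active] * d
        )
    return value, grad


def warmup_weight(epoch_progress: float, warmup_fraction: float) -> float:
    """Physics-weight schedule: linear 0 -> 1 over the warmup fraction."""
    if not 0.0 <= epoch_progress <= 1.0:
        raise ValueError("epoch_progress must lie in [0, 1]")
    if warmup_fraction <= 0.0:
        return 1.0
    return min(1.0, epoch_progress / warmup_fraction)


def total_loss(
    batch: BatchEmbeddings,
    rel: RelationGraph,
    cfg: LossConfig,
    epoch_progress: float = 1.0,
    bank_z: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Weighted composite loss and its per-term breakdown."""
    loss, breakdown, _ = _total_loss_impl(
        batch, rel, cfg, epoch_progress, bank_z, want_grad=False
    )
    return loss, breakdown


def total_loss_grad(
    batch: BatchEmbeddings,
    rel: RelationGraph,
    cfg: LossConfig,
    epoch_progress: float = 1.0,
    bank_z: np.ndarray | None = None,
) -> tuple[float, dict, np.ndarray]:
    """Composite loss, breakdown, and d(loss)/d(raw projector outputs)."""
    return _total_loss_impl(batch, rel, cfg, epoch_progress, bank_z, want_grad=True)


def _stack(z_batch: np.ndarray, bank_z: np.ndarray | None, rel: RelationGraph) -> np.ndarray:
    if rel.n_bank:
        if bank_z is None or len(bank_z) != rel.n_bank:
            raise ValueError("relation graph references a bank but none was given")
        return np.vstack([z_batch, bank_z])
    return z_batch


def _total_loss_impl(batch, rel, cfg, epoch_progress, bank_z, want_grad):
    z_all = _stack(batch.z, bank_z, rel)
    pos, den = _motion_sets(rel)
    l_mot, n_mot, g_mot = _nce(batch.z, z_all, pos, den, cfg.tau, want_grad)
    l_phy, n_phy, g_phy = _nce(batch.z, z_all, rel.p_phys, rel.q, cfg.tau_p, want_grad)
    l_var, g_var = _variance_grad(batch.raw, cfg, want_grad)
    w = warmup_weight(epoch_progress, cfg.warmup_fraction)
    total = l_mot + w * cfg.lambda_phys * l_phy + cfg.lambda_var * l_var
    breakdown = {
        "total": total,
        "motion": l_mot,
        "physics": l_phy,
        "variance": l_var,
        "physics_weight": w,
        "n_motion_anchors": n_mot,
        "n_physics_anchors": n_phy,
    }
    if not want_grad:
        return total, breakdown, None
    g_z = g_mot + w * cfg.lambda_phys * g_phy
    # z = raw / ||raw||: project the z-gradient onto the tangent space
    norms = np.linalg.norm(batch.raw, axis=1, keepdims=True)
    g_raw = (g_z - (g_z * batch.z).sum(axis=1, keepdims=True) * batch.z) / norms
    g_raw += cfg.lambda_var * g_var
    return total, breakdown, g_raw
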