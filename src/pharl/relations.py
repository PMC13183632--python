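"""Per-anchor contrastive relation construction.

For each anchor window in a batch (optionally extended by a memory bank)
this module materializes the sets the objectives consume:

* ``p_traj`` — temporal positives: other windows of the same trajectory;
* ``a``     — candidate set: every batch/bank entry except the anchor;
* ``m``     — denominator mask: cross-trajectory contact windows removed
  from a contact anchor's denominator (false-negative suppression);
* ``q``     — cross-trajectory candidates;
* ``p_phys``— physics positives: cross-trajectory windows with the same
  contact class (exact Head/Trunk matching in multiclass mode, fused
  contact matching in binary mode).

All sets are materialized as sorted index lists for reproducibility.
Bank entries may appear in candidate sets but are never anchors and never
receive gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODES, ORDINAL, RelationConfig, substream
from .io import Manifest


@dataclass(frozen=True)
class AnchorContext:
    """Metadata a window contributes to relation building."""

    trajectory_id: str
    ordinal_code: int | None = None   # 0/1/2, None in temporal-only data
    contact_flag: int | None = None   # C = 1[class in {Head, Trunk}]
    video_id: str = ""


@dataclass
class RelationGraph:
    """Per-anchor index sets over the concatenated batch+bank candidate pool."""

    n_batch: int
    n_bank: int
    p_traj: list[list[int]]
    a: list[list[int]]
    m: list[list[int]]
    p_phys: list[list[int]]
    q: list[list[int]]
    #: anchors whose physics positive set is empty ("skip physics term")
    skip_physics: list[bool] = field(default_factory=list)


def contexts_from_labels(manifest: Manifest, labels: pd.DataFrame | None) -> list[AnchorContext]:
    """Build anchor contexts for every manifest window, in manifest order."""
    if labels is None:
        return [AnchorContext(w.trajectory_id, video_id=w.video_id) for w in manifest.windows]
    lab = labels.set_index("window_id")
    out = []
    for w in manifest.windows:
        row = lab.loc[w.window_id]
        out.append(
            AnchorContext(
                w.trajectory_id,
                ordinal_code=int(row["ordinal_code"]),
                contact_flag=int(row["contact_flag"]),
                video_id=w.video_id,
            )
        )
    return out


def build_relations(
    batch: list[AnchorContext],
    bank: list[AnchorContext] | None = None,
    mode: str = "multiclass_physics",
    bank_in_physics: bool = True,
) -> RelationGraph:
    """Construct the relation graph for one batch.

    Candidates are indexed 0..B-1 (batch) then B..B+M-1 (bank). Only batch
    entries are anchors. In ``temporal_only`` mode all masks and physics
    positives are empty; otherwise a contact anchor's mask removes all
    cross-trajectory contact candidates from its denominator, and physics
    positives match on the exact class (multiclass) or the fused contact
    flag (binary). Masking itself is class-agnostic: it uses the contact
    flag only, so binary and multiclass modes mask identically.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    bank = bank or []
    physics = mode != "temporal_only"
    if physics:
        for ctx in list(batch) + list(bank):
            if ctx.ordinal_code is None or ctx.contact_flag is None:
                raise ValueError(f"mode {mode!r} requires labeled contexts")

    pool = list(batch) + list(bank)
    n_b, n_all = len(batch), len(pool)
    # factorize ids/labels once; all set logic is boolean matrix algebra so
    # large memory banks stay cheap
    _, traj = np.unique([c.trajectory_id for c in pool], return_inverse=True)
    contact = np.array([c.contact_flag if c.contact_flag is not None else 0
                        for c in pool])
    code = np.array([c.ordinal_code if c.ordinal_code is not None else -1
                     for c in pool])

    not_self = ~np.eye(n_b, n_all, dtype=bool)
    same_traj = traj[:n_b, None] == traj[None, :]
    cross = not_self & ~same_traj
    a_mat = not_self
    q_mat = cross
    p_traj_mat = same_traj[:, :n_b] & ~np.eye(n_b, dtype=bool)
    m_mat = np.zeros((n_b, n_all), dtype=bool)
    p_phys_mat = np.zeros((n_b, n_all), dtype=bool)
    if physics:
        anchor_contact = contact[:n_b].astype(bool)
        phys_pool = cross.copy()
        if not bank_in_physics:
            phys_pool[:, n_b:] = False
        m_mat = anchor_contact[:, None] & phys_pool & contact[None, :].astype(bool)
        if mode == "multiclass_physics":
            p_phys_mat = (anchor_contact[:, None] & phys_pool
                          & (code[:n_b, None] == code[None, :]))
        else:  # binary_physics: Head and Trunk fused
            p_phys_mat = m_mat

    g = RelationGraph(n_batch=n_b, n_bank=len(bank),
                      p_traj=[], a=[], m=[], p_phys=[], q=[], skip_physics=[])
    for i in range(n_b):
        g.p_traj.append(np.flatnonzero(p_traj_mat[i]).tolist())
        g.a.append(np.flatnonzero(a_mat[i]).tolist())
        g.m.append(np.flatnonzero(m_mat[i]).tolist())
        p_phys_i = np.flatnonzero(p_phys_mat[i]).tolist()
        g.p_phys.append(p_phys_i)
        g.q.append(np.flatnonzero(q_mat[i]).tolist())
        g.skip_physics.append(not p_phys_i)
    return g


# ---------------------------------------------------------------------------
# Physics-stratified batching
# ---------------------------------------------------------------------------


def stratified_batches(
    codes: np.ndarray,
    batch_size: int,
    min_per_class: int,
    seed: int,
) -> list[np.ndarray]:
    """Split indices 0..n-1 into batches with per-class minimum occupancy.

    Every batch receives at least ``min_per_class`` members of each physics
    class present (while that class's supply lasts); the epoch covers every
    index exactly once. ``min_per_class=0`` degenerates to a plain shuffle.
    Deterministic under ``seed``.
    """
    codes = np.asarray(codes)
    n = len(codes)
    classes = np.unique(codes)
    if batch_size < len(classes) * min_per_class:
        raise ValueError(
            f"batch_size={batch_size} < classes*min_per_class="
            f"{len(classes) * min_per_class}"
        )
    rng = substream(seed, "batch")
    n_batches = max(1, int(np.ceil(n / batch_size)))
    batches: list[list[int]] = [[] for _ in range(n_batches)]

    leftover: list[int] = []
    for cls in classes:
        members = np.flatnonzero(codes == cls)
        rng.shuffle(members)
        pos = 0
        if min_per_class > 0:
            for b in range(n_batches):
                take = members[pos:pos + min_per_class]
                if len(take) < min_per_class:
                    break
                batches[b].extend(take.tolist())
                pos += min_per_class
        leftover.extend(members[pos:].tolist())

    rng.shuffle(leftover)
    it = iter(leftover)
    for b in range(n_batches):
        while len(batches[b]) < batch_size:
            try:
                batches[b].append(next(it))
            except StopIteration:
                break
    rest = list(it)
    if rest:  # can only happen when reserved seats overfilled early batches
        for idx, b in zip(rest, range(len(rest))):
            batches[b % n_batches].append(idx)
    out = [np.asarray(sorted(b), dtype=np.intp) for b in batches if b]
    for b in out:
        rng.shuffle(b)
    assert sum(len(b) for b in out) == n
    return out


# ---------------------------------------------------------------------------
# Memory bank
# ---------------------------------------------------------------------------


class MemoryBank:
    """FIFO queue of detached embeddings with relation metadata.

    Entries enter candidate sets (and, configurably, the physics sets) but
    never act as anchors and never receive gradient.
    """

    def __init__(self, capacity: int, enabled: bool = True):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.enabled = enabled
        self._z: list[np.ndarray] = []
        self._ctx: list[AnchorContext] = []

    def __len__(self) -> int:
        return len(self._z)

    def push(self, z: np.ndarray, contexts: list[AnchorContext]) -> None:
        """Append embeddings, evicting the oldest entries past capacity."""
        if not self.enabled:
            return
        if len(z) != len(contexts):
            raise ValueError("embedding/context count mismatch")
        self._z.extend(np.array(row, copy=True) for row in z)
        self._ctx.extend(contexts)
        excess = len(self._z) - self.capacity
        if excess > 0:
            del self._z[:excess]
            del self._ctx[:excess]

    @property
    def z(self) -> np.ndarray:
        if not self._z:
            return np.zeros((0, 0))
        return np.stack(self._z)

    @property
    def contexts(self) -> list[AnchorContext]:
        return list(self._ctx)
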