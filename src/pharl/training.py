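"""Window encoder and the training/validation loop.

The encoder is deliberately small and dependency-free: temporal average
pooling over the window's frames, a ReLU MLP trunk, and a projection head
whose output is l2-normalized into the embedding space. Forward and
backward passes are written out explicitly in numpy (the backward pass is
verified against finite differences in the test suite), and optimization
uses Adam. On one CPU the whole loop is bit-reproducible under a fixed
seed, which is the tested contract.

The encode path accepts only motion-feature arrays — labels and contact
descriptors cannot reach it by construction — and inference
(:func:`embed_dataset`) needs nothing beyond a checkpoint and a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (EncoderConfig, LossConfig, RelationConfig, TrainConfig,
                     config_hash, substream, substream_seed)
from .io import EmbeddingTable, Manifest
from .objectives import BatchEmbeddings, normalize_rows, total_loss, total_loss_grad
from .relations import (AnchorContext, MemoryBank, build_relations,
                        contexts_from_labels, stratified_batches)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------


class Encoder:
    """Pooling + MLP trunk + projection head, with explicit backprop."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        dims = [cfg.feature_dim, *cfg.hidden_widths, *cfg.head_widths, cfg.embed_dim]
        rng = substream(cfg.seed, "encoder-init")
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(scale=np.sqrt(2.0 / fan_in),
                                           size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Map (B, T, feature_dim) windows to raw projector outputs (B, d).

        Returns the raw outputs and the per-layer activation cache needed
        by :meth:`backward`. ReLU follows every layer except the last.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.cfg.feature_dim:
            raise ValueError(
                f"expected (B, T, {self.cfg.feature_dim}) features, got {x.shape}"
            )
        h = x.mean(axis=1)  # temporal average pooling
        cache = [h]
        for li in range(self.n_layers):
            h = h @ self.weights[li] + self.biases[li]
            if li < self.n_layers - 1:
                h = np.maximum(h, 0.0)
            cache.append(h)
        return h, cache

    def backward(self, cache: list[np.ndarray], g_raw: np.ndarray
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of a scalar loss w.r.t. weights and biases."""
        gw = [np.empty(0)] * self.n_layers
        gb = [np.empty(0)] * self.n_layers
        g = g_raw
        for li in reversed(range(self.n_layers)):
            if li < self.n_layers - 1:
                g = g * (cache[li + 1] > 0)
            gw[li] = cache[li].T @ g
            gb[li] = g.sum(axis=0)
            g = g @ self.weights[li].T
        return gw, gb

    def encode(self, x: np.ndarray,
               contexts: list[AnchorContext] | None = None) -> BatchEmbeddings:
        """Embed windows: raw projector outputs plus l2-normalized rows."""
        raw, _ = self.forward(x)
        return BatchEmbeddings(z=normalize_rows(raw), raw=raw,
                               contexts=contexts or [])

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = w.copy()
            out[f"b{i}"] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i in range(self.n_layers):
            self.weights[i] = np.array(state[f"W{i}"], dtype=np.float64)
            self.biases[i] = np.array(state[f"b{i}"], dtype=np.float64)

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"config": self.cfg.model_dump(mode="json"),
                           "config_hash": config_hash(self.cfg)})
        np.savez(path, __meta__=np.array(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            enc = cls(EncoderConfig.model_validate(meta["config"]))
            enc.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return enc


class Adam:
    """Standard Adam optimizer over the encoder's parameter list."""

    def __init__(self, encoder: Encoder, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.enc, self.lr, self.b1, self.b2, self.eps = encoder, lr, beta1, beta2, eps
        self.t = 0
        params = encoder.weights + encoder.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, gw: list[np.ndarray], gb: list[np.ndarray]) -> None:
        self.t += 1
        params = self.enc.weights + self.enc.biases
        grads = gw + gb
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    """Outcome of a training run."""

    epochs_run: int
    best_val_loss: float
    best_epoch: int
    encoder: Encoder                      # final-epoch weights
    best_state: dict[str, np.ndarray]     # minimum-validation-loss weights
    history: pd.DataFrame                 # per-step loss breakdown
    best_path: str | None = None
    final_path: str | None = None
    encoder_hash: str = ""

    def best_encoder(self) -> Encoder:
        enc = Encoder(self.encoder.cfg)
        enc.load_state_dict(self.best_state)
        return enc


def _window_features(manifest: Manifest) -> np.ndarray:
    feats = []
    for w in manifest.windows:
        if w.features is None:
            raise ValueError(f"window {w.window_id} carries no feature array")
        feats.append(w.features)
    return np.stack(feats)


def _assert_split_integrity(manifest: Manifest) -> None:
    seen: dict[str, str] = {}
    for w in manifest.windows:
        prev = seen.setdefault(w.trajectory_id, w.split)
        if prev != w.split:
            raise ValueError(
                f"trajectory {w.trajectory_id} leaks across splits "
                f"({prev!r} vs {w.split!r})"
            )


def fit(
    manifest: Manifest,
    labels: pd.DataFrame | None,
    *,
    encoder_cfg: EncoderConfig,
    loss_cfg: LossConfig,
    rel_cfg: RelationConfig,
    train_cfg: TrainConfig,
    mode: str = "multiclass_physics",
    out_dir: str | Path | None = None,
) -> TrainState:
    """Train an encoder on the manifest's train split.

    Validation loss is computed each epoch at the final schedule weights
    (physics weight 1) so epochs are comparable, and the minimum-validation
    checkpoint is kept alongside the final one. In ``temporal_only`` mode
    the label table is ignored for relation building and batching is a
    plain shuffle; physics-stratified batching applies otherwise.
    """
    _assert_split_integrity(manifest)
    if mode != "temporal_only" and labels is None:
        raise ValueError(f"mode {mode!r} requires a label table")

    train_m, val_m = manifest.subset("train"), manifest.subset("val")
    if not train_m.windows:
        raise ValueError("train split is empty")
    x_train = _window_features(train_m)
    ctx_train = contexts_from_labels(train_m, None if mode == "temporal_only" else labels)
    codes = np.array([c.ordinal_code if c.ordinal_code is not None else 0
                      for c in ctx_train])

    have_val = bool(val_m.windows)
    if have_val:
        x_val = _window_features(val_m)
        ctx_val = contexts_from_labels(val_m, None if mode == "temporal_only" else labels)

    encoder = Encoder(encoder_cfg)
    opt = Adam(encoder, train_cfg.learning_rate)
    bank = MemoryBank(rel_cfg.bank_capacity, enabled=rel_cfg.bank_enabled)
    min_pc = 0 if mode == "temporal_only" else rel_cfg.min_per_class

    history: list[dict] = []
    best_val, best_epoch = np.inf, -1
    best_state = encoder.state_dict()
    for epoch in range(train_cfg.epochs):
        progress = epoch / train_cfg.epochs
        batches = stratified_batches(
            codes, rel_cfg.batch_size, min_pc,
            substream_seed(train_cfg.seed, f"epoch{epoch}"),
        )
        for step, idx in enumerate(batches):
            if len(idx) < 2:
                continue
            raw, cache = encoder.forward(x_train[idx])
            z = normalize_rows(raw)
            b_ctx = [ctx_train[i] for i in idx]
            rel = build_relations(b_ctx, bank.contexts if bank.enabled else None,
                                  mode, rel_cfg.bank_in_physics)
            bank_z = bank.z if (bank.enabled and len(bank)) else None
            batch = BatchEmbeddings(z=z, raw=raw, contexts=b_ctx)
            loss, terms, g_raw = total_loss_grad(batch, rel, loss_cfg, progress, bank_z)
            gw, gb = encoder.backward(cache, g_raw)
            opt.step(gw, gb)
            bank.push(z, b_ctx)
            history.append({"epoch": epoch, "step": step, **terms})

        if have_val:
            val_loss = _validation_loss(encoder, x_val, ctx_val, loss_cfg,
                                        rel_cfg, mode)
        else:
            val_loss = history[-1]["total"] if history else np.inf
        history.append({"epoch": epoch, "step": -1, "val_total": val_loss})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = encoder.state_dict()
        logger.info("epoch %d: val loss %.5f (best %.5f @ %d)",
                    epoch, val_loss, best_val, best_epoch)

    state = TrainState(
        epochs_run=train_cfg.epochs,
        best_val_loss=float(best_val),
        best_epoch=best_epoch,
        encoder=encoder,
        best_state=best_state,
        history=pd.DataFrame(history),
        encoder_hash=config_hash(encoder_cfg),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        best = state.best_encoder()
        best.save(out / "best.npz")
        encoder.save(out / "final.npz")
        state.best_path = str(out / "best.npz")
        state.final_path = str(out / "final.npz")
        state.history.to_csv(out / "training_log.csv", index=False)
    return state


def _validation_loss(encoder, x_val, ctx_val, loss_cfg, rel_cfg, mode) -> float:
    """Mean per-window validation loss at final-schedule weights (w = 1)."""
    total, count = 0.0, 0
    bs = rel_cfg.batch_size
    for start in range(0, len(x_val), bs):
        idx = slice(start, start + bs)
        ctx = ctx_val[idx]
        if len(ctx) < 2:
            continue
        batch = encoder.encode(x_val[idx], ctx)
        rel = build_relations(ctx, None, mode)
        loss, _ = total_loss(batch, rel, loss_cfg, epoch_progress=1.0)
        total += loss * len(ctx)
        count += len(ctx)
    return total / count if count else np.inf


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def embed_dataset(checkpoint: str | Path | Encoder, manifest: Manifest,
                  batch_size: int = 256) -> EmbeddingTable:
    """Embed every manifest window with a trained encoder.

    Pure feed-forward inference: consumes only the manifest's feature
    arrays and the checkpoint — no labels, no contact descriptors.
    """
    encoder = checkpoint if isinstance(checkpoint, Encoder) else Encoder.load(checkpoint)
    x = _window_features(manifest)
    zs = []
    for start in range(0, len(x), batch_size):
        raw, _ = encoder.forward(x[start:start + batch_size])
        zs.append(normalize_rows(raw))
    meta = pd.DataFrame(
        {
            "window_id": [w.window_id for w in manifest.windows],
            "trajectory_id": [w.trajectory_id for w in manifest.windows],
            "video_id": [w.video_id for w in manifest.windows],
            "split": [w.split for w in manifest.windows],
            "fall_label": [w.fall_label for w in manifest.windows],
        }
    )
    return EmbeddingTable(meta, np.vstack(zs))
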