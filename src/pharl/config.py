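"""Configuration schemas, shared constants, and seeded random substreams.

All randomness in the package flows from a single integer seed through
named substreams (:func:`substream`), so that independent stages (simulation,
batching, probes, pair sampling, database balancing) can be re-run in
isolation without perturbing each other.
"""

from __future__ import annotations

import zlib
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Domain constants
# ---------------------------------------------------------------------------

#: Coarse contact-outcome classes, ordered by ordinal code 0, 1, 2.
CLASSES: tuple[str, ...] = ("Supported", "Trunk", "Head")

#: Ordinal code per class (Supported < Trunk < Head).
ORDINAL: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Body parts a contact descriptor may name.
BODY_PARTS: tuple[str, ...] = ("head", "torso", "hip", "arm", "hand", "leg", "foot")

#: Descriptor body part -> impulse category used for per-window aggregation.
#: Hip counts as trunk evidence; all limb contacts fall in the non-critical
#: branch and can never raise a label above Supported.
PART_CATEGORY: dict[str, str] = {
    "head": "head",
    "torso": "trunk",
    "hip": "trunk",
    "arm": "limb",
    "hand": "limb",
    "leg": "limb",
    "foot": "limb",
}

#: Impulse categories in dominance order (head beats trunk beats limb).
CATEGORIES: tuple[str, ...] = ("head", "trunk", "limb")

#: Descriptor provenance: contacts observed inside the window vs. contacts
#: from a short-horizon continuation initialized at the window boundary.
SOURCES: tuple[str, ...] = ("window", "continuation")

MODES: tuple[str, ...] = ("temporal_only", "binary_physics", "multiclass_physics")

SPLITS: tuple[str, ...] = ("train", "val", "test")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream of a global seed.

    The child stream is keyed by a CRC32 of ``name`` so that adding a new
    consumer never shifts the draws of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) derived from a named substream."""
    return int(substream(seed, name).integers(0, 2**31))


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


class SimConfig(_Model):
    """Parameters of the synthetic fall-trajectory generator.

    The generator stands in for RGB video plus offline humanoid simulation:
    it emits per-window motion-feature arrays and a contact-descriptor
    stream with a known latent severity ordering, so that label denoising
    and ordinal-structure recovery can be tested against ground truth.
    """

    n_trajectories: int = Field(default=300, ge=1)
    fall_fraction: float = Field(default=0.58, ge=0.0, le=1.0)
    #: Target proportions of (Supported, Trunk, Head) outcomes among falls.
    class_mix: tuple[float, float, float] = (0.56, 0.34, 0.10)
    frames_per_trajectory: int = Field(default=120, ge=1)
    feature_dim: int = Field(default=12, ge=1)
    nuisance_dim: int = Field(default=4, ge=1)
    noise_sd: float = Field(default=0.3, ge=0.0)
    #: Expected number of spurious weak contact events per fall trajectory.
    spurious_impulse_rate: float = Field(default=2.0, ge=0.0)
    #: Upper bound on spurious impulse magnitude (N·s).
    spurious_impulse_max: float = Field(default=0.05, ge=0.0)
    #: Probability that a fall's impact onset straddles a window boundary
    #: (lands within one stride after some window's end).
    boundary_straddle_prob: float = Field(default=0.25, ge=0.0, le=1.0)
    seed: int = 0

    # Windowing geometry (frames at a nominal 25 fps).
    window_len: int = Field(default=16, ge=2)
    window_stride: int = Field(default=8, ge=1)

    # Contact model: true impact impulses are LogNormal(meanlog, sdlog) N·s,
    # well separated from spurious impulses (<= spurious_impulse_max), so any
    # positive threshold in between cleanly removes the noise.
    impulse_meanlog: float = 1.0
    impulse_sdlog: float = 0.3
    impact_duration: int = Field(default=6, ge=1)
    nuisance_scale: float = Field(default=1.0, ge=0.0)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    @field_validator("class_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {sum(v)!r}")
        if any(p < 0 for p in v):
            raise ValueError("class_mix proportions must be nonnegative")
        return v

    @model_validator(mode="after")
    def _windows_fit(self) -> "SimConfig":
        if self.frames_per_trajectory < self.window_len:
            raise ValueError(
                f"frames_per_trajectory={self.frames_per_trajectory} shorter than "
                f"one window (window_len={self.window_len})"
            )
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        return self


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


class LabelConfig(_Model):
    """Contact-labeling protocol: evidence sources, impulse filter, horizon."""

    #: Which descriptor sources contribute evidence.
    sources: tuple[str, ...] = ("window", "continuation")
    #: Minimum impulse (N·s); descriptors with impulse <= threshold are
    #: dropped (strictly-greater rule, so the 0.0 default discards exactly
    #: zero-impulse artifacts while keeping all real contacts).
    threshold: float = Field(default=0.0, ge=0.0)
    #: Continuation admission horizon in frames: a continuation descriptor
    #: counts for window [t0,t1) when its start lies in [t1, t1+horizon).
    horizon: int = Field(default=8, ge=0)
    #: Window-aligned denoised labels (True) vs. trajectory-level labels.
    denoise: bool = True

    @field_validator("sources")
    @classmethod
    def _known_sources(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        bad = set(v) - set(SOURCES)
        if bad:
            raise ValueError(f"unknown descriptor sources: {sorted(bad)}")
        return tuple(dict.fromkeys(v))  # dedupe, keep order


# ---------------------------------------------------------------------------
# Relations
# ---------------------------------------------------------------------------


class RelationConfig(_Model):
    """Batching, memory bank, and relation-graph construction options."""

    batch_size: int = Field(default=64, ge=2)
    min_per_class: int = Field(default=2, ge=0)
    bank_enabled: bool = False
    bank_capacity: int = Field(default=4096, ge=1)
    #: Whether memory-bank entries may appear in the physics sets (masks and
    #: physics positives) in addition to the plain candidate sets.
    bank_in_physics: bool = True


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


class LossConfig(_Model):
    """Weights and temperatures of the composite training objective."""

    tau: float = Field(default=0.2, gt=0.0, description="motion-branch temperature")
    tau_p: float = Field(default=0.2, gt=0.0, description="physics-branch temperature")
    lambda_phys: float = Field(default=1.0, ge=0.0)
    lambda_var: float = Field(default=0.1, ge=0.0)
    #: Fraction of training over which the physics weight ramps 0 -> 1.
    warmup_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    #: Target per-dimension standard deviation in the variance hinge.
    variance_gamma: float = Field(default=1.0, gt=0.0)


# ---------------------------------------------------------------------------
# Encoder / training
# ---------------------------------------------------------------------------


class EncoderConfig(_Model):
    """Shape of the window encoder.

    Temporal average pooling over the window's frames, an MLP trunk, and a
    projection head whose output is l2-normalized into the embedding space.
    """

    feature_dim: int = Field(default=12, ge=1)
    window_len: int = Field(default=16, ge=1)
    hidden_widths: tuple[int, ...] = (64,)
    embed_dim: int = Field(default=32, ge=2)
    head_widths: tuple[int, ...] = (64,)
    seed: int = 0


class TrainConfig(_Model):
    epochs: int = Field(default=100, ge=1)
    learning_rate: float = Field(default=1e-4, gt=0.0)
    seed: int = 0


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class EvalConfig(_Model):
    """Diagnostic-suite options."""

    #: Neighborhood-consistency retrieval depth.
    k: int = Field(default=10, ge=1)
    #: POA pair budget per class pair; exhaustive below, sampled above.
    poa_cap: int = Field(default=100_000, ge=1)
    #: Distance used in the physics consistency ratio.
    pcr_metric: Literal["euclidean", "cosine"] = "euclidean"
    #: Inverse regularization strength of the linear probes.
    probe_c: float = Field(default=1.0, gt=0.0)
    #: Fall-probe granularity: window-level tags (inherited from the
    #: trajectory) or trajectory-pooled embeddings.
    fall_probe: Literal["window", "trajectory"] = "window"
    seed: int = 0


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class RunConfig(_Model):
    """Validated end-to-end pipeline configuration (one training arm)."""

    sim: SimConfig = SimConfig()
    label: LabelConfig = LabelConfig()
    relations: RelationConfig = RelationConfig()
    loss: LossConfig = LossConfig()
    train: TrainConfig = TrainConfig()
    eval: EvalConfig = EvalConfig()
    mode: Literal["temporal_only", "binary_physics", "multiclass_physics"] = (
        "multiclass_physics"
    )
    #: Also train a capacity-matched temporal-only control arm.
    paired_control: bool = True
    seed: int = 0
    out_dir: str = "pharl_run"

    def with_seed(self, seed: int) -> "RunConfig":
        """Copy of the config with every stage seed rewired to ``seed``."""
        cfg = self.model_copy(deep=True)
        cfg.seed = seed
        cfg.sim.seed = substream_seed(seed, "sim")
        cfg.train.seed = substream_seed(seed, "train")
        cfg.eval.seed = substream_seed(seed, "eval")
        return cfg


def load_run_config(path: str) -> RunConfig:
    """Load and validate a YAML or TOML run configuration."""
    import pathlib

    p = pathlib.Path(path)
    text = p.read_text()
    if p.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def _tupleize(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_tupleize(x) for x in obj)
    if isinstance(obj, dict):
        return tuple(sorted((k, _tupleize(v)) for k, v in obj.items()))
    return obj


def config_hash(model: BaseModel) -> str:
    """Stable short hash of a config, used for capacity-parity checks."""
    import hashlib
    import json

    payload = json.dumps(model.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
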