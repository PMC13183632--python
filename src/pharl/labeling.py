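"""Window-level contact labeling with temporal denoising.

Converts a raw contact-descriptor stream into one coarse physics label per
window. The denoised protocol aligns evidence to each window by temporal
overlap, admits short-horizon continuation evidence just past the window
boundary, filters weak impulses, merges surviving evidence by per-category
maximum impulse, and assigns the label by hierarchical dominance:
head contact beats torso/hip contact beats everything else; limb contacts
and empty evidence both map to Supported.

The trajectory-level variant (denoising off) instead gives every window of
a fall trajectory the dominance label of the trajectory's entire stream,
so pre-impact standing poses inherit severe outcome tags — the label-noise
failure mode the denoised protocol exists to remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CATEGORIES, CLASSES, ORDINAL, PART_CATEGORY, LabelConfig
from .io import ContactDescriptor, Manifest, Window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpulseSet:
    """Per-category maximum impulse surviving filtering for one window."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.values) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown impulse categories: {sorted(bad)}")

    def __bool__(self) -> bool:
        return bool(self.values)


@dataclass(frozen=True)
class PhysicsLabel:
    """Coarse contact outcome with ordinal code and binary contact flag."""

    y_phys: str
    ordinal_code: int
    contact_flag: int

    def __post_init__(self) -> None:
        if self.y_phys not in CLASSES:
            raise ValueError(f"unknown class {self.y_phys!r}")
        if self.ordinal_code != ORDINAL[self.y_phys]:
            raise ValueError("ordinal_code inconsistent with class")
        if self.contact_flag != int(self.y_phys in ("Head", "Trunk")):
            raise ValueError("contact_flag inconsistent with class")


def _label(cls: str) -> PhysicsLabel:
    return PhysicsLabel(cls, ORDINAL[cls], int(cls in ("Head", "Trunk")))


def overlaps(window: Window, d: ContactDescriptor) -> bool:
    """Half-open interval overlap: (ts < t1) and (te > t0)."""
    return d.ts < window.t1 and d.te > window.t0


def build_impulse_set(
    window: Window,
    stream: list[ContactDescriptor],
    sources: tuple[str, ...] = ("window", "continuation"),
    threshold: float = 0.0,
    horizon: int = 8,
) -> ImpulseSet:
    """Filter and merge a window's contact evidence.

    Keeps window-source descriptors overlapping the window, plus (when
    ``"continuation"`` is among the sources) continuation-source
    descriptors whose start lies in ``[t1, t1 + horizon)``. Descriptors
    with impulse <= threshold are dropped; survivors are aggregated by
    per-category maximum impulse across sources.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    values: dict[str, float] = {}
    for d in stream:
        if d.video_id != window.video_id:
            continue
        if d.source == "window":
            admit = "window" in sources and overlaps(window, d)
        else:
            admit = "continuation" in sources and window.t1 <= d.ts < window.t1 + horizon
        if not admit or d.impulse <= threshold:
            continue
        cat = PART_CATEGORY[d.body_part]
        values[cat] = max(values.get(cat, 0.0), d.impulse)
    return ImpulseSet(values)


def assign_label(s: ImpulseSet) -> PhysicsLabel:
    """Hierarchical dominance: Head, else Trunk, else Supported.

    Dominance ignores impulse magnitude — any head-category evidence wins
    regardless of how large a trunk impulse is present. Limb-only evidence
    and empty sets both default to Supported.
    """
    if "head" in s.values:
        return _label("Head")
    if "trunk" in s.values:
        return _label("Trunk")
    return _label("Supported")


def _by_video(stream: list[ContactDescriptor]) -> dict[str, list[ContactDescriptor]]:
    out: dict[str, list[ContactDescriptor]] = {}
    for d in stream:
        out.setdefault(d.video_id, []).append(d)
    return out


def _row(window: Window, label: PhysicsLabel, s: ImpulseSet) -> dict:
    return {
        "window_id": window.window_id,
        "y_phys": label.y_phys,
        "ordinal_code": label.ordinal_code,
        "contact_flag": label.contact_flag,
        "max_impulse_head": s.values.get("head", np.nan),
        "max_impulse_trunk": s.values.get("trunk", np.nan),
        "max_impulse_limb": s.values.get("limb", np.nan),
    }


def label_dataset(
    manifest: Manifest,
    stream: list[ContactDescriptor],
    cfg: LabelConfig | None = None,
) -> pd.DataFrame:
    """Denoised window-level labels for every window in the manifest.

    Windows of non-fall trajectories label Supported without touching the
    descriptor stream. Emits a per-split class histogram to the log.
    """
    cfg = cfg or LabelConfig()
    if not cfg.denoise:
        return trajectory_level_labels(manifest, stream, cfg)
    per_video = _by_video(stream)
    rows = []
    empty = ImpulseSet()
    for w in manifest.windows:
        if w.fall_label == 0:
            rows.append(_row(w, _label("Supported"), empty))
            continue
        s = build_impulse_set(
            w, per_video.get(w.video_id, []), cfg.sources, cfg.threshold, cfg.horizon
        )
        rows.append(_row(w, assign_label(s), s))
    table = pd.DataFrame(rows)
    _log_histogram(manifest, table)
    return table


def trajectory_level_labels(
    manifest: Manifest,
    stream: list[ContactDescriptor],
    cfg: LabelConfig | None = None,
) -> pd.DataFrame:
    """Denoising-OFF ablation: every window inherits its trajectory's label.

    The dominance label is computed once from the trajectory's full
    descriptor stream with no temporal alignment (the impulse filter still
    applies), then copied to all of the trajectory's windows — including
    pre-impact ones.
    """
    cfg = cfg or LabelConfig()
    per_video = _by_video(stream)
    traj_sets: dict[str, ImpulseSet] = {}
    rows = []
    empty = ImpulseSet()
    for w in manifest.windows:
        if w.fall_label == 0:
            rows.append(_row(w, _label("Supported"), empty))
            continue
        if w.video_id not in traj_sets:
            values: dict[str, float] = {}
            for d in per_video.get(w.video_id, []):
                if d.source not in cfg.sources or d.impulse <= cfg.threshold:
                    continue
                cat = PART_CATEGORY[d.body_part]
                values[cat] = max(values.get(cat, 0.0), d.impulse)
            traj_sets[w.video_id] = ImpulseSet(values)
        s = traj_sets[w.video_id]
        rows.append(_row(w, assign_label(s), s))
    table = pd.DataFrame(rows)
    _log_histogram(manifest, table)
    return table


def _log_histogram(manifest: Manifest, table: pd.DataFrame) -> None:
    split_of = {w.window_id: w.split for w in manifest.windows}
    counts = (
        table.assign(split=table["window_id"].map(split_of))
        .groupby(["split", "y_phys"], observed=True)
        .size()
    )
    for (split, cls), count in counts.items():
        logger.info("labels: split=%s class=%s n=%d", split, cls, count)
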