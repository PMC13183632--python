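"""Data containers and line-oriented readers/writers.

Windows, trajectories, contact descriptors and embeddings travel between
pipeline stages as plain text: JSONL for the window manifest and the
contact-descriptor stream, CSV for label tables, CSV or Parquet for
embedding tables, JSON for metric reports and provenance sidecars.
All readers validate line by line and report the offending line number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import BODY_PARTS, CLASSES, ORDINAL, SOURCES, SPLITS

# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """One half-open temporal segment [t0, t1) of a trajectory.

    The unit of embedding and labeling. ``features`` holds the per-frame
    motion-feature array of shape (t1 - t0, feature_dim); it is excluded
    from equality so windows compare by identity and geometry.
    """

    window_id: str
    trajectory_id: str
    video_id: str
    split: str
    t0: int
    t1: int
    fall_label: int
    features: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"window {self.window_id}: t0={self.t0} must be < t1={self.t1}")
        if self.split not in SPLITS:
            raise ValueError(f"window {self.window_id}: unknown split {self.split!r}")
        if self.fall_label not in (0, 1):
            raise ValueError(f"window {self.window_id}: fall_label must be 0/1")


@dataclass(frozen=True)
class ContactDescriptor:
    """A simulated contact event: interval, body part, impulse, provenance."""

    video_id: str
    ts: int
    te: int
    body_part: str
    impulse: float
    source: str = "window"

    def __post_init__(self) -> None:
        if not self.ts < self.te:
            raise ValueError(f"descriptor: ts={self.ts} must be < te={self.te}")
        if self.body_part not in BODY_PARTS:
            raise ValueError(f"descriptor: unknown body_part {self.body_part!r}")
        if self.impulse < 0:
            raise ValueError("descriptor: impulse must be >= 0")
        if self.source not in SOURCES:
            raise ValueError(f"descriptor: unknown source {self.source!r}")


@dataclass
class Manifest:
    """Dataset index: all windows, with trajectory-level split assignment."""

    windows: list[Window]

    def __post_init__(self) -> None:
        ids = [w.window_id for w in self.windows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate window_id(s): {dupes[:5]}")
        traj_split: dict[str, str] = {}
        for w in self.windows:
            prev = traj_split.setdefault(w.trajectory_id, w.split)
            if prev != w.split:
                raise ValueError(
                    f"trajectory {w.trajectory_id} spans splits {prev!r} and {w.split!r}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, split: str) -> "Manifest":
        return Manifest([w for w in self.windows if w.split == split])

    @property
    def trajectory_ids(self) -> list[str]:
        return sorted({w.trajectory_id for w in self.windows})


@dataclass
class GroundTruth:
    """Simulator oracle: per-trajectory outcome, severity, onset, nuisance."""

    outcome: dict[str, str]          # trajectory_id -> class name ("" for ADL)
    severity: dict[str, float]       # trajectory_id -> latent severity scalar
    onset: dict[str, int]            # trajectory_id -> impact-onset frame (-1 for ADL)
    impact_end: dict[str, int]       # trajectory_id -> impact interval end (-1 for ADL)
    nuisance: dict[str, list[float]]  # video_id -> per-video nuisance vector


@dataclass
class EmbeddingTable:
    """l2-normalized window embeddings plus alignment metadata."""

    meta: pd.DataFrame  # columns: window_id, trajectory_id, video_id, split, fall_label
    z: np.ndarray       # (n, d), rows aligned with meta

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.z):
            raise ValueError("metadata and embedding row counts differ")

    def subset(self, split: str) -> "EmbeddingTable":
        mask = (self.meta["split"] == split).to_numpy()
        return EmbeddingTable(self.meta.loc[mask].reset_index(drop=True), self.z[mask])


# ---------------------------------------------------------------------------
# JSONL manifest
# ---------------------------------------------------------------------------

_MANIFEST_KEYS = {"window_id", "trajectory_id", "video_id", "split", "t0", "t1", "fall_label"}


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in manifest.windows:
            rec = {
                "window_id": w.window_id,
                "trajectory_id": w.trajectory_id,
                "video_id": w.video_id,
                "split": w.split,
                "t0": w.t0,
                "t1": w.t1,
                "fall_label": w.fall_label,
            }
            if w.features is not None:
                rec["features"] = w.features.tolist()
            fh.write(json.dumps(rec) + "\n")


def read_manifest(path: str | Path) -> Manifest:
    windows: list[Window] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
            missing = _MANIFEST_KEYS - rec.keys()
            if missing:
                raise ValueError(f"missing keys {sorted(missing)}")
            feats = rec.get("features")
            windows.append(
                Window(
                    window_id=str(rec["window_id"]),
                    trajectory_id=str(rec["trajectory_id"]),
                    video_id=str(rec["video_id"]),
                    split=rec["split"],
                    t0=int(rec["t0"]),
                    t1=int(rec["t1"]),
                    fall_label=int(rec["fall_label"]),
                    features=None if feats is None else np.asarray(feats, dtype=np.float64),
                )
            )
        except (ValueError, TypeError, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return Manifest(windows)


# ---------------------------------------------------------------------------
# JSONL contact-descriptor stream
# ---------------------------------------------------------------------------

_DESCRIPTOR_KEYS = {"video_id", "ts", "te", "body_part", "impulse_ns", "source"}


def write_descriptors(stream: Sequence[ContactDescriptor], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in stream:
            fh.write(
                json.dumps(
                    {
                        "video_id": d.video_id,
                        "ts": d.ts,
                        "te": d.te,
                        "body_part": d.body_part,
                        "impulse_ns": d.impulse,
                        "source": d.source,
                    }
                )
                + "\n"
            )


def read_descriptors(path: str | Path) -> list[ContactDescriptor]:
    out: list[ContactDescriptor] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
            missing = _DESCRIPTOR_KEYS - rec.keys()
            if missing:
                raise ValueError(f"missing keys {sorted(missing)}")
            out.append(
                ContactDescriptor(
                    video_id=str(rec["video_id"]),
                    ts=int(rec["ts"]),
                    te=int(rec["te"]),
                    body_part=rec["body_part"],
                    impulse=float(rec["impulse_ns"]),
                    source=rec["source"],
                )
            )
        except (ValueError, TypeError, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Label table (CSV), ground truth (JSON), embeddings (CSV/Parquet)
# ---------------------------------------------------------------------------

LABEL_COLUMNS = [
    "window_id",
    "y_phys",
    "ordinal_code",
    "contact_flag",
    "max_impulse_head",
    "max_impulse_trunk",
    "max_impulse_limb",
]


def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=LABEL_COLUMNS)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"window_id": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing label columns {sorted(missing)}")
    bad = ~df["y_phys"].isin(CLASSES)
    if bad.any():
        raise ValueError(f"{path}: row {int(np.flatnonzero(bad)[0]) + 2}: unknown y_phys")
    return df


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(gt), indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table; the format follows the file extension."""
    df = table.meta.copy()
    for j in range(table.z.shape[1]):
        df[f"z{j}"] = table.z[:, j]
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(
        path, dtype={"window_id": str}
    )
    zcols = sorted((c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    z = df[zcols].to_numpy(dtype=np.float64)
    meta = df.drop(columns=zcols).reset_index(drop=True)
    return EmbeddingTable(meta, z)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Provenance sidecars
# ---------------------------------------------------------------------------


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_provenance(path: str | Path, *, config_hash: str,
                     inputs: dict[str, str] | None = None, stage: str = "") -> None:
    """Write a ``<path>.prov.json`` sidecar recording how a file was made."""
    from . import __version__

    sidecar = Path(str(path) + ".prov.json")
    sidecar.write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": config_hash,
                "code_version": __version__,
                "inputs": inputs or {},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
            indent=1,
            sort_keys=True,
        )
    )
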