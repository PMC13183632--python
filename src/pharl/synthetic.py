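"""Synthetic fall-trajectory generator.

Stands in for RGB video plus offline humanoid contact simulation: emits
multi-phase motion-feature trajectories (pre-impact / impact / rest),
per-video nuisance factors, and a contact-descriptor stream whose latent
severity ordering (Supported < Trunk < Head) is known exactly, so that
label denoising, relation building, training and the ordinal diagnostics
can all be tested against ground truth.

Feature model per frame: a stepwise phase signal (pre-impact row, one
class-dependent impact row per contact stage, a rest row), temporally
smoothed, plus a per-video nuisance vector confined to a low-rank
subspace, plus white noise. Impact and rest rows shift along a fixed
severity direction proportionally to the stage's latent severity, which
makes ordinal recovery possible but not trivial: pre-impact frames carry
no class signal and the nuisance term dominates any single frame.
Head-outcome falls pass through a trunk-impact stage before head contact,
so their early impact windows are genuine trunk-contact windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CLASSES, ORDINAL, SimConfig, substream
from .io import ContactDescriptor, GroundTruth, Manifest, Window

FIXTURE_NAMES = ("toy_labeling", "toy_relations", "toy_training")

# Body parts emitted per outcome class: the class-defining contact first,
# plus a secondary contact in the same interval so hierarchical dominance
# is exercised (a Head fall also touches the torso; falls with a Supported
# outcome land on limbs, exercising the non-critical branch).
_PRIMARY = {"Head": ("head",), "Trunk": ("torso", "hip"), "Supported": ("arm", "hand")}
_SECONDARY = {"Head": ("torso",), "Trunk": ("arm", "hand"), "Supported": ("leg", "foot")}


@dataclass
class FixtureBundle:
    """A hand-sized scenario: manifest + descriptor stream (+ extras)."""

    manifest: Manifest
    stream: list[ContactDescriptor]
    ground_truth: GroundTruth | None = None
    labels: pd.DataFrame | None = None


def _window_starts(cfg: SimConfig) -> list[int]:
    return list(range(0, cfg.frames_per_trajectory - cfg.window_len + 1, cfg.window_stride))


def _largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` matching ``proportions`` exactly."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[Manifest, list[ContactDescriptor], GroundTruth]:
    """Generate a full synthetic dataset.

    Returns the window manifest (with inline per-window feature arrays and
    trajectory-level stratified splits), the contact-descriptor stream, and
    the ground-truth sidecar. Fully reproducible from ``cfg.seed``.
    """
    rng = substream(cfg.seed, "sim")
    # spurious contacts draw from their own substream so that switching the
    # spurious rate leaves every other draw (and hence the clean labels)
    # untouched
    rng_spur = substream(cfg.seed, "sim-spurious")
    n = cfg.n_trajectories
    frames, fdim = cfg.frames_per_trajectory, cfg.feature_dim
    starts = _window_starts(cfg)
    if not starts:
        raise ValueError("trajectory shorter than one window")

    # -- trajectory roles: exact largest-remainder allocation, shuffled ----
    n_fall = int(round(n * cfg.fall_fraction))
    fall_counts = _largest_remainder(n_fall, np.asarray(cfg.class_mix))
    roles: list[str | None] = [None] * (n - n_fall)
    for cls, count in zip(CLASSES, fall_counts):
        roles += [cls] * int(count)
    rng.shuffle(roles)

    # -- shared linear maps --------------------------------------------------
    w_pre = rng.normal(size=fdim)
    w_imp_base = rng.normal(size=fdim)
    w_rest_base = rng.normal(size=fdim)
    sev_dir = rng.normal(size=fdim)
    sev_dir /= np.linalg.norm(sev_dir)
    imp_jitter = {c: rng.normal(size=fdim) * 0.3 for c in CLASSES}
    rest_jitter = {c: rng.normal(size=fdim) * 0.3 for c in CLASSES}
    nuis_proj = rng.normal(size=(fdim, cfg.nuisance_dim))

    boundaries = [t0 + cfg.window_len for t0 in starts]
    lo, hi = int(0.40 * frames), int(0.75 * frames)

    windows: list[Window] = []
    stream: list[ContactDescriptor] = []
    gt = GroundTruth(outcome={}, severity={}, onset={}, impact_end={}, nuisance={})
    strata: dict[str, list[str]] = {}

    for idx, cls in enumerate(roles):
        traj = f"traj{idx:04d}"
        video = f"vid{idx:04d}"
        eps = rng.normal(size=cfg.nuisance_dim)
        nuis = nuis_proj @ eps * (cfg.nuisance_scale / np.sqrt(cfg.nuisance_dim))
        gt.nuisance[video] = nuis.tolist()

        if cls is None:  # ADL: quiescent, no contact at all
            signal = np.tile(w_pre, (frames, 1))
            severity, onset, impact_end = 0.0, -1, -1
            fall = 0
        else:
            code = ORDINAL[cls]
            severity = float(rng.uniform(code + 0.1, code + 0.9))
            if rng.random() < cfg.boundary_straddle_prob:
                # impact onset lands within one stride after a window's end
                feasible = [b for b in boundaries
                            if b + cfg.window_stride + cfg.impact_duration < frames]
                base = feasible[rng.integers(len(feasible))] if feasible else boundaries[0]
                first_onset = base + int(rng.integers(0, cfg.window_stride))
                straddle = True
            else:
                first_onset = int(rng.integers(lo, max(lo + 1, hi)))
                straddle = False
            first_onset = int(np.clip(first_onset, 1, frames - 2))

            # physical stages of the fall: a head-outcome fall strikes the
            # trunk first and the head shortly after, so its early impact
            # windows genuinely carry trunk contact
            stages: list[tuple[str, int, float]] = []  # (class, onset, severity)
            if cls == "Head":
                head_onset = min(first_onset + int(rng.integers(4, 12)), frames - 1)
                stages.append(("Trunk", first_onset, float(rng.uniform(1.1, 1.9))))
                stages.append(("Head", head_onset, severity))
            else:
                stages.append((cls, first_onset, severity))
            onset = stages[-1][1]  # class-defining impact
            impact_end = min(onset + cfg.impact_duration, frames)

            # per-frame signal rows: pre-impact, per-stage impact, rest
            signal = np.tile(w_pre, (frames, 1))
            for s_cls, s_onset, s_sev in stages:
                signal[s_onset:] = (w_imp_base + sev_dir * (1.5 * s_sev)
                                    + imp_jitter[s_cls])
            w_rest = w_rest_base + sev_dir * (0.75 * severity) + rest_jitter[cls]
            signal[impact_end:] = w_rest
            fall = 1

            impact_descs = []
            sustained = []  # (body part, stage impact end)
            for s_cls, s_onset, _ in stages:
                parts = [
                    _PRIMARY[s_cls][rng.integers(len(_PRIMARY[s_cls]))],
                    _SECONDARY[s_cls][rng.integers(len(_SECONDARY[s_cls]))],
                ]
                s_end = min(s_onset + cfg.impact_duration, frames)
                impact_descs += [
                    ContactDescriptor(
                        video_id=video, ts=s_onset, te=s_end, body_part=p,
                        impulse=float(rng.lognormal(cfg.impulse_meanlog,
                                                    cfg.impulse_sdlog)),
                        source="window",
                    )
                    for p in parts
                ]
                sustained.append((parts[0], s_end))
            stream += impact_descs
            if straddle:
                # continuation evidence: the boundary-straddling first impact
                # re-observed from the short-horizon rollout at the boundary
                stream += [dataclasses.replace(d, source="continuation")
                           for d in impact_descs if d.ts == first_onset]
            for part, s_end in sustained:
                if s_end < frames:
                    # ground contact persists while the body rests: sustained
                    # weak-impulse descriptors keep rest windows labeled with
                    # the outcome class, mirroring window-level prevalence
                    stream.append(
                        ContactDescriptor(
                            video_id=video, ts=s_end, te=frames, body_part=part,
                            impulse=float(rng.lognormal(-0.5, cfg.impulse_sdlog)),
                            source="window",
                        )
                    )

            n_spur = rng_spur.poisson(cfg.spurious_impulse_rate)
            for _ in range(n_spur):
                ts = int(rng_spur.integers(0, frames - 2))
                stream.append(
                    ContactDescriptor(
                        video_id=video, ts=ts, te=ts + int(rng_spur.integers(1, 3)),
                        body_part=["head", "torso", "hip", "arm", "hand", "leg",
                                   "foot"][rng_spur.integers(7)],
                        impulse=float(rng_spur.uniform(0.0, cfg.spurious_impulse_max)),
                        source="window",
                    )
                )
            gt.outcome[traj] = cls

        gt.severity[traj] = severity
        gt.onset[traj] = onset
        gt.impact_end[traj] = impact_end

        # temporal smoothing of the stepwise signal mimics motion inertia
        kernel = np.ones(5) / 5.0
        smooth = np.stack([np.convolve(signal[:, j], kernel, mode="same")
                           for j in range(fdim)], axis=1)
        feats = smooth + nuis + rng.normal(scale=cfg.noise_sd, size=(frames, fdim))
        for w_i, t0 in enumerate(starts):
            windows.append(
                Window(
                    window_id=f"{traj}_w{w_i:02d}",
                    trajectory_id=traj,
                    video_id=video,
                    split="train",  # reassigned below
                    t0=t0,
                    t1=t0 + cfg.window_len,
                    fall_label=fall,
                    features=feats[t0:t0 + cfg.window_len].copy(),
                )
            )
        strata.setdefault(cls or "ADL", []).append(traj)

    # -- stratified trajectory-level splits ---------------------------------
    split_of: dict[str, str] = {}
    for key in sorted(strata):
        members = sorted(strata[key])
        rng.shuffle(members)
        counts = _largest_remainder(len(members), np.asarray(cfg.split_fractions))
        pos = 0
        for split, count in zip(("train", "val", "test"), counts):
            for traj in members[pos:pos + count]:
                split_of[traj] = split
            pos += count
    windows = [dataclasses.replace(w, split=split_of[w.trajectory_id]) for w in windows]

    stream.sort(key=lambda d: (d.video_id, d.ts, d.te, d.body_part, d.source))
    return Manifest(windows), stream, gt


# ---------------------------------------------------------------------------
# Bundled toy fixtures
# ---------------------------------------------------------------------------


def make_fixture(name: str) -> FixtureBundle:
    """Return a small bundled scenario with hand-computable expectations.

    ``toy_labeling``: 2 videos (one fall, one ADL), 7 windows, a descriptor
    stream exercising the half-open overlap predicate, the strictly-greater
    impulse filter, boundary-straddling continuation evidence, and the
    non-critical limb branch.

    ``toy_relations``: 3 trajectories x (2,1,1) windows with labels
    (Head, Head), (Trunk,), (Supported,) and tiny feature arrays.

    ``toy_training``: 40 simulated trajectories, feature_dim 8; trains in
    well under a minute on one CPU.
    """
    if name == "toy_labeling":
        return _toy_labeling()
    if name == "toy_relations":
        return _toy_relations()
    if name == "toy_training":
        cfg = SimConfig(
            n_trajectories=40, feature_dim=8, frames_per_trajectory=80,
            nuisance_dim=3, seed=7,
        )
        manifest, stream, gt = simulate_dataset(cfg)
        return FixtureBundle(manifest, stream, gt)
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")


def _toy_window(wid, traj, vid, split, t0, t1, fall, dim=2):
    rng = substream(0, f"fixture-{wid}")
    return Window(wid, traj, vid, split, t0, t1, fall,
                  features=rng.normal(size=(t1 - t0, dim)))


def _toy_labeling() -> FixtureBundle:
    # Fall video: frames 30, windows of 10 with stride 5 -> 5 windows.
    # Impact (head + torso) starts at frame 15/16, just after the end of
    # window [5,15): a boundary straddle, so continuation copies exist.
    windows = [
        _toy_window(f"f_w{i}", "traj_fall", "vid_fall", "train", t0, t0 + 10, 1)
        for i, t0 in enumerate((0, 5, 10, 15, 20))
    ] + [
        _toy_window(f"a_w{i}", "traj_adl", "vid_adl", "train", t0, t0 + 10, 0)
        for i, t0 in enumerate((0, 5))
    ]
    d = ContactDescriptor
    stream = [
        d("vid_fall", 2, 4, "hand", 3.0, "window"),      # limb contact, non-critical
        d("vid_fall", 3, 5, "torso", 0.04, "window"),    # weak spurious trunk contact
        d("vid_fall", 6, 8, "torso", 0.0, "window"),     # zero-impulse artifact
        d("vid_fall", 15, 17, "torso", 2.0, "window"),
        d("vid_fall", 16, 18, "head", 5.0, "window"),
        d("vid_fall", 15, 17, "torso", 2.0, "continuation"),
        d("vid_fall", 16, 18, "head", 5.0, "continuation"),
    ]
    return FixtureBundle(Manifest(windows), stream)


def _toy_relations() -> FixtureBundle:
    layout = [  # (window_id, trajectory, class)
        ("r_w0", "trajA", "Head"),
        ("r_w1", "trajA", "Head"),
        ("r_w2", "trajB", "Trunk"),
        ("r_w3", "trajC", "Supported"),
    ]
    windows = [
        _toy_window(wid, traj, f"vid_{traj}", "train", 0, 8, 1)
        for wid, traj, _ in layout
    ]
    labels = pd.DataFrame(
        {
            "window_id": [wid for wid, _, _ in layout],
            "y_phys": [cls for _, _, cls in layout],
            "ordinal_code": [ORDINAL[cls] for _, _, cls in layout],
            "contact_flag": [int(ORDINAL[cls] > 0) for _, _, cls in layout],
            "max_impulse_head": [np.nan] * 4,
            "max_impulse_trunk": [np.nan] * 4,
            "max_impulse_limb": [np.nan] * 4,
        }
    )
    return FixtureBundle(Manifest(windows), [], labels=labels)
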