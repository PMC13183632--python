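"""End-to-end pipeline: simulate -> label -> train -> embed -> evaluate.

Stages communicate through files in a run directory (JSONL manifest and
descriptor stream, CSV labels, checkpoints, embedding tables, JSON
reports), each with a provenance sidecar. Contact descriptors are consumed
by the labeling stage only: training, embedding and evaluation operate on
the manifest, the label table and checkpoints, mirroring the method's
feed-forward inference contract.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io
from .config import (EncoderConfig, LabelConfig, RunConfig, config_hash,
                     substream_seed)
from .io import Manifest
from .labeling import label_dataset
from .training import embed_dataset, fit

logger = logging.getLogger(__name__)

#: Canonical ablation grid rows, mirroring the component-switch table:
#: (name, denoising, multiclass, window source, continuation source).
ABLATION_ROWS = {
    "temporal_only": (False, False, False, False),
    "no_denoise": (False, True, True, True),
    "binary": (True, False, True, True),
    "continuation_only": (True, True, False, True),
    "window_only": (True, True, True, False),
    "full": (True, True, True, True),
}

ABLATION_SWITCHES = ("denoise", "multiclass", "source_window", "source_continuation")
_SWITCH_ROW = {
    "denoise": "no_denoise",
    "multiclass": "binary",
    "source_window": "continuation_only",
    "source_continuation": "window_only",
}


def _arm_settings(cfg: RunConfig, row: tuple[bool, bool, bool, bool]
                  ) -> tuple[LabelConfig, str]:
    denoise, multiclass, src_w, src_c = row
    sources = tuple(s for s, on in (("window", src_w), ("continuation", src_c)) if on)
    label_cfg = cfg.label.model_copy(
        update={"denoise": denoise, "sources": sources or cfg.label.sources}
    )
    if not (src_w or src_c):
        mode = "temporal_only"
    else:
        mode = "multiclass_physics" if multiclass else "binary_physics"
    return label_cfg, mode


def run_arm(
    manifest: Manifest,
    labels: pd.DataFrame | None,
    cfg: RunConfig,
    mode: str,
    out_dir: Path | None = None,
    eval_labels: pd.DataFrame | None = None,
) -> dict:
    """Train one arm on prepared inputs and return its metrics report.

    ``labels`` supervise training (per the arm's labeling protocol);
    diagnostics always score against ``eval_labels`` (defaulting to the
    training table) so ablation arms stay comparable. The encoder
    configuration and its seed derive only from the shared run seed and
    the simulator geometry, so every arm of a run instantiates a
    byte-identical architecture (capacity parity).
    """
    if eval_labels is None:
        eval_labels = labels
    encoder_cfg = EncoderConfig(
        feature_dim=cfg.sim.feature_dim,
        window_len=cfg.sim.window_len,
        seed=substream_seed(cfg.seed, "encoder"),
    )
    state = fit(
        manifest,
        labels,
        encoder_cfg=encoder_cfg,
        loss_cfg=cfg.loss,
        rel_cfg=cfg.relations,
        train_cfg=cfg.train.model_copy(
            update={"seed": substream_seed(cfg.seed, "train")}
        ),
        mode=mode,
        out_dir=out_dir,
    )
    table = embed_dataset(state.best_encoder(), manifest)
    eval_cfg = cfg.eval.model_copy(update={"seed": substream_seed(cfg.seed, "eval")})
    from .evaluation import evaluate

    report = evaluate(table, eval_labels, eval_cfg)
    report["mode"] = mode
    report["encoder_hash"] = state.encoder_hash
    report["best_epoch"] = state.best_epoch
    report["best_val_loss"] = state.best_val_loss
    if out_dir is not None:
        io.write_embeddings(table, out_dir / "embeddings.csv")
        io.write_json(report, out_dir / "report.json")
        io.write_provenance(out_dir / "report.json", config_hash=config_hash(cfg),
                            stage="eval")
    return report


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns {arm name: metrics report}.

    Simulates the dataset, writes all intermediate files to ``out_dir``,
    labels windows, then trains/embeds/evaluates the configured arm plus
    (by default) a capacity-matched temporal-only control, and writes a
    comparison table.
    """
    from .synthetic import simulate_dataset

    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)

    logger.info("stage simulate: n_trajectories=%d", cfg.sim.n_trajectories)
    manifest, stream, gt = simulate_dataset(cfg.sim)
    io.write_manifest(manifest, out / "manifest.jsonl")
    io.write_descriptors(stream, out / "descriptors.jsonl")
    io.write_ground_truth(gt, out / "ground_truth.json")
    for name in ("manifest.jsonl", "descriptors.jsonl", "ground_truth.json"):
        io.write_provenance(out / name, config_hash=chash, stage="simulate")

    logger.info("stage label: %d descriptors", len(stream))
    labels = label_dataset(manifest, stream, cfg.label)
    io.write_labels(labels, out / "labels.csv")
    io.write_provenance(
        out / "labels.csv", config_hash=chash, stage="label",
        inputs={"manifest": io.file_digest(out / "manifest.jsonl"),
                "descriptors": io.file_digest(out / "descriptors.jsonl")},
    )

    arms = [cfg.mode]
    if cfg.paired_control and cfg.mode != "temporal_only":
        arms.append("temporal_only")
    reports = {}
    for mode in arms:
        logger.info("stage train/embed/eval: arm=%s", mode)
        arm_dir = out / f"arm_{mode}"
        arm_dir.mkdir(exist_ok=True)
        reports[mode] = run_arm(manifest, labels, cfg, mode, out_dir=arm_dir)

    comparison = pd.DataFrame(
        [
            {
                "arm": mode,
                "spearman_rho": r["spearman_rho"],
                "poa_macro": r["poa_macro"],
                "contact_ap": r["contact_ap"],
                "contact_auc": r["contact_auc"],
                "fall_auc": r["fall_auc"],
                "pcr": r["pcr"],
                "kendall_tau": r["kendall_tau"],
            }
            for mode, r in reports.items()
        ]
    )
    comparison.to_csv(out / "comparison.csv", index=False)
    io.write_provenance(out / "comparison.csv", config_hash=chash, stage="compare")
    return reports


def ablation_matrix(
    cfg: RunConfig,
    switches: tuple[str, ...] = ABLATION_SWITCHES,
    include_control: bool = True,
    include_full: bool = True,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run a component-switch grid with a shared seed; one row per arm.

    ``switches`` selects which single-component ablations to run; with all
    four switches plus the control and the full configuration this mirrors
    the canonical six-row grid (temporal-only control, denoising off,
    binary attraction, continuation-only, window-only, full).
    """
    bad = set(switches) - set(ABLATION_SWITCHES)
    if bad:
        raise ValueError(f"unknown ablation switches: {sorted(bad)}")
    names = (["temporal_only"] if include_control else []) \
        + [_SWITCH_ROW[s] for s in ABLATION_SWITCHES if s in switches] \
        + (["full"] if include_full else [])
    if not names:
        raise ValueError("empty ablation grid")

    from .synthetic import simulate_dataset

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest, stream, _ = simulate_dataset(cfg.sim)
    # diagnostics for every arm score against the reference protocol
    eval_labels = label_dataset(manifest, stream, cfg.label)

    rows = []
    for name in names:
        row = ABLATION_ROWS[name]
        label_cfg, mode = _arm_settings(cfg, row)
        labels = label_dataset(manifest, stream, label_cfg)
        arm_dir = None
        if out is not None:
            arm_dir = out / f"ablation_{name}"
            arm_dir.mkdir(exist_ok=True)
        report = run_arm(manifest, labels, cfg, mode, out_dir=arm_dir,
                         eval_labels=eval_labels)
        rows.append(
            {
                "arm": name,
                "denoising": row[0],
                "multiclass": row[1],
                "source_window": row[2],
                "source_continuation": row[3],
                "spearman_rho": report["spearman_rho"],
                "poa_macro": report["poa_macro"],
                "contact_ap": report["contact_ap"],
                "contact_auc": report["contact_auc"],
                "fall_auc": report["fall_auc"],
                "pcr": report["pcr"],
                "kendall_tau": report["kendall_tau"],
                "seed": cfg.seed,
            }
        )
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "ablation.csv", index=False)
        io.write_provenance(out / "ablation.csv", config_hash=config_hash(cfg),
                            stage="ablate")
    return table
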