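"""Rank-prioritized diagnostic suite for learned embeddings.

Everything here is post-hoc: a severity axis is fit from train-split class
centroids (unit vector from the Supported centroid to the Head centroid),
windows are scored by scalar projection onto it, and the suite reports

* Spearman's rho and Kendall's tau-b between ordinal labels {0,1,2} and
  projection scores (primary evidence of ordinal consistency);
* POA — macro-averaged pairwise ordering accuracy over the three ordered
  class pairs, ties counted 0.5, exhaustive below a pair budget and
  seeded-sampled above it;
* linear-probe Binary Contact AP/AUC and Fall Detection AUC (probes are
  diagnostics fit on train embeddings, scored on test, never fed back);
* PCR — mean inter-class over mean intra-class embedding distance;
* cross-video neighborhood consistency: per-class same-class fraction of
  cosine nearest neighbors in a class-balanced database after excluding
  same-video entries.

Degenerate inputs (a missing class, constant scores, single-video classes)
surface as structured nulls with reasons, never as silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import CLASSES, ORDINAL, EvalConfig, substream
from .io import EmbeddingTable

#: The three ordered class pairs (low severity, high severity).
ORDERED_PAIRS = [("Supported", "Trunk"), ("Supported", "Head"), ("Trunk", "Head")]


# ---------------------------------------------------------------------------
# Severity axis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeverityAxis:
    """Unit direction from the Supported centroid to the Head centroid."""

    v_hat: np.ndarray
    mu_head: np.ndarray
    mu_supported: np.ndarray
    source_split: str = "train"


def severity_axis(z_train: np.ndarray, codes_train: np.ndarray,
                  source_split: str = "train") -> SeverityAxis:
    """Fit the post-hoc severity axis from train-split centroids only."""
    codes_train = np.asarray(codes_train)
    head = z_train[codes_train == ORDINAL["Head"]]
    supp = z_train[codes_train == ORDINAL["Supported"]]
    if len(head) == 0 or len(supp) == 0:
        raise ValueError("severity axis needs at least one Head and one "
                         "Supported window in the train split")
    mu_h, mu_s = head.mean(axis=0), supp.mean(axis=0)
    diff = mu_h - mu_s
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("Head and Supported centroids coincide")
    return SeverityAxis(diff / norm, mu_h, mu_s, source_split)


def project(z: np.ndarray, axis: SeverityAxis) -> np.ndarray:
    """Scalar projection scores s_i = z_i . v_hat."""
    return np.asarray(z) @ axis.v_hat


# ---------------------------------------------------------------------------
# Rank metrics
# ---------------------------------------------------------------------------


def spearman_kendall(codes: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average-ranked ties) and Kendall tau-b."""
    codes, scores = np.asarray(codes), np.asarray(scores)
    if len(np.unique(codes)) < 2:
        raise ValueError("rank correlation needs at least 2 distinct codes")
    if np.ptp(scores) == 0:
        raise ValueError("projection scores are constant; correlation undefined")
    rho = spearmanr(codes, scores).statistic
    tau = kendalltau(codes, scores, variant="b").statistic
    return float(rho), float(tau)


def poa_macro(
    codes: np.ndarray,
    scores: np.ndarray,
    cap: int = 100_000,
    seed: int = 0,
    return_detail: bool = False,
):
    """Macro-averaged pairwise ordering accuracy.

    For each ordered class pair, the fraction of cross-class instance
    pairs whose scores rank consistently with severity (ties 0.5);
    exhaustive when the pair count is within ``cap``, otherwise a uniform
    seeded sample of ``cap`` pairs. Pairs with an absent class are skipped
    and reported; the macro mean runs over available pairs.
    """
    codes, scores = np.asarray(codes), np.asarray(scores)
    rng = substream(seed, "poa")
    detail: dict[str, float | None] = {}
    values = []
    for lo, hi in ORDERED_PAIRS:
        s_lo = scores[codes == ORDINAL[lo]]
        s_hi = scores[codes == ORDINAL[hi]]
        key = f"{lo}<{hi}"
        if len(s_lo) == 0 or len(s_hi) == 0:
            detail[key] = None
            continue
        n_pairs = len(s_lo) * len(s_hi)
        if n_pairs <= cap:
            diff = s_hi[:, None] - s_lo[None, :]
            acc = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
        else:
            i = rng.integers(0, len(s_lo), size=cap)
            j = rng.integers(0, len(s_hi), size=cap)
            diff = s_hi[j] - s_lo[i]
            acc = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
        detail[key] = acc
        values.append(acc)
    if not values:
        raise ValueError("POA undefined: no ordered class pair has instances")
    macro = float(np.mean(values))
    return (macro, detail) if return_detail else macro


# ---------------------------------------------------------------------------
# Linear probes
# ---------------------------------------------------------------------------


def _probe_scores(z_train, y_train, z_test, c: float) -> np.ndarray:
    if len(np.unique(y_train)) < 2:
        raise ValueError("probe train split contains a single class")
    clf = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)
    clf.fit(z_train, y_train)
    return clf.decision_function(z_test)


def linear_probes(
    table: EmbeddingTable,
    labels: pd.DataFrame,
    cfg: EvalConfig | None = None,
) -> tuple[float, float, float]:
    """(contact AP, contact AUC, fall AUC) of post-hoc linear probes.

    An l2-regularized logistic probe with a deterministic solver is fit on
    train-split embeddings and scored on the test split. The contact probe
    separates contact (Head, Trunk) from Supported; the fall probe uses
    window-level fall tags inherited from the trajectory (or
    trajectory-pooled embeddings when configured).
    """
    cfg = cfg or EvalConfig()
    lab = labels.set_index("window_id")
    out = {}
    for split in ("train", "test"):
        sub = table.subset(split)
        if not len(sub.meta):
            raise ValueError(f"probe {split} split is empty")
        contact = lab.loc[sub.meta["window_id"], "contact_flag"].to_numpy()
        out[split] = (sub, contact)
    (tr, c_tr), (te, c_te) = out["train"], out["test"]
    if len(np.unique(c_te)) < 2:
        raise ValueError("probe test split contains a single contact class")
    s = _probe_scores(tr.z, c_tr, te.z, cfg.probe_c)
    contact_ap = float(average_precision_score(c_te, s))
    contact_auc = float(roc_auc_score(c_te, s))

    if cfg.fall_probe == "trajectory":
        def pool(sub):
            df = sub.meta.assign(_row=np.arange(len(sub.meta)))
            groups = df.groupby("trajectory_id")
            z = np.stack([sub.z[g["_row"]].mean(axis=0) for _, g in groups])
            y = np.array([g["fall_label"].iloc[0] for _, g in groups])
            return z, y
        z_tr, f_tr = pool(tr)
        z_te, f_te = pool(te)
    else:
        z_tr, f_tr = tr.z, tr.meta["fall_label"].to_numpy()
        z_te, f_te = te.z, te.meta["fall_label"].to_numpy()
    if len(np.unique(f_te)) < 2:
        raise ValueError("fall probe test split contains a single class")
    fall_auc = float(roc_auc_score(f_te, _probe_scores(z_tr, f_tr, z_te, cfg.probe_c)))
    return contact_ap, contact_auc, fall_auc


# ---------------------------------------------------------------------------
# Geometry diagnostics
# ---------------------------------------------------------------------------


def pcr(z: np.ndarray, codes: np.ndarray, metric: str = "euclidean") -> float:
    """Physics consistency ratio: mean inter-class / mean intra-class distance."""
    z, codes = np.asarray(z), np.asarray(codes)
    for cls in np.unique(codes):
        if (codes == cls).sum() < 2:
            raise ValueError(f"PCR needs >= 2 members per present class (code {cls})")
    if metric == "euclidean":
        d = np.sqrt(np.maximum(
            ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1), 0.0))
    elif metric == "cosine":
        d = 1.0 - z @ z.T
    else:
        raise ValueError(f"unknown PCR metric {metric!r}")
    same = codes[:, None] == codes[None, :]
    iu = np.triu_indices(len(z), k=1)
    intra = d[iu][same[iu]]
    inter = d[iu][~same[iu]]
    if inter.size == 0:
        raise ValueError("PCR undefined with a single class present")
    if intra.mean() == 0:
        raise ValueError("intra-class distances are all zero (duplicate embeddings)")
    return float(inter.mean() / intra.mean())


def neighborhood_consistency(
    z: np.ndarray,
    codes: np.ndarray,
    video_ids: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> dict[str, float | None]:
    """Per-class cross-video retrieval consistency.

    The retrieval database subsamples every class to the minority-class
    size (seeded). Queries are all windows of each class; for each query,
    same-video database entries (and the query itself) are excluded before
    taking up to the top-k cosine neighbors, and consistency is the mean
    fraction of retrieved neighbors sharing the query's class. Classes
    whose windows span fewer than two videos are reported as undefined.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    z, codes = np.asarray(z), np.asarray(codes)
    video_ids = np.asarray(video_ids)
    rng = substream(seed, "balance")
    present = [c for c in CLASSES if np.any(codes == ORDINAL[c])]
    minority = min(int((codes == ORDINAL[c]).sum()) for c in present)
    db_idx: list[int] = []
    for c in present:
        members = np.flatnonzero(codes == ORDINAL[c])
        db_idx.extend(sorted(rng.choice(members, size=minority, replace=False)))
    db = np.asarray(db_idx)
    sims = z @ z[db].T  # cosine similarity (rows are unit-norm)

    out: dict[str, float | None] = {}
    for c in CLASSES:
        members = np.flatnonzero(codes == ORDINAL[c])
        if len(members) == 0:
            out[c] = None
            continue
        if len(np.unique(video_ids[members])) < 2:
            out[c] = None  # same-video exclusion empties the pool
            continue
        fractions = []
        for q in members:
            valid = (video_ids[db] != video_ids[q]) & (db != q)
            if not valid.any():
                continue
            cand = np.flatnonzero(valid)
            order = cand[np.argsort(-sims[q, cand], kind="stable")][:k]
            fractions.append(float(np.mean(codes[db[order]] == ORDINAL[c])))
        out[c] = float(np.mean(fractions)) if fractions else None
    return out


# ---------------------------------------------------------------------------
# Report composition
# ---------------------------------------------------------------------------


def _attempt(errors: dict, name: str, fn):
    try:
        return fn()
    except ValueError as exc:
        errors[name] = str(exc)
        return None


def evaluate(
    table: EmbeddingTable,
    labels: pd.DataFrame,
    cfg: EvalConfig | None = None,
    eval_split: str = "test",
) -> dict:
    """Run the full diagnostic suite; a pure function of its inputs.

    The severity axis and probes are fit on the train split and applied
    unchanged to ``eval_split``; all other metrics are computed on
    ``eval_split``. Metric failures become nulls with reason strings.
    """
    cfg = cfg or EvalConfig()
    lab = labels.set_index("window_id")

    train = table.subset("train")
    test = table.subset(eval_split)
    codes_tr = lab.loc[train.meta["window_id"], "ordinal_code"].to_numpy()
    codes_te = lab.loc[test.meta["window_id"], "ordinal_code"].to_numpy()

    errors: dict[str, str] = {}
    report: dict = {
        "spearman_rho": None, "kendall_tau": None,
        "poa_macro": None, "poa_pairs": None,
        "contact_ap": None, "contact_auc": None, "fall_auc": None,
        "pcr": None, "neighborhood": None,
        "mean_projection": None,
        "counts": {
            "train": int(len(train.meta)),
            eval_split: int(len(test.meta)),
            "per_class": {c: int((codes_te == ORDINAL[c]).sum()) for c in CLASSES},
        },
        "seed": cfg.seed,
        "eval_split": eval_split,
    }

    axis = _attempt(errors, "severity_axis", lambda: severity_axis(train.z, codes_tr))
    if axis is not None:
        scores = project(test.z, axis)
        rk = _attempt(errors, "rank_correlation",
                      lambda: spearman_kendall(codes_te, scores))
        if rk is not None:
            report["spearman_rho"], report["kendall_tau"] = rk
        poa = _attempt(errors, "poa", lambda: poa_macro(
            codes_te, scores, cfg.poa_cap, cfg.seed, return_detail=True))
        if poa is not None:
            report["poa_macro"], report["poa_pairs"] = poa
        report["mean_projection"] = {
            c: (float(scores[codes_te == ORDINAL[c]].mean())
                if np.any(codes_te == ORDINAL[c]) else None)
            for c in CLASSES
        }

    probes = _attempt(errors, "linear_probes", lambda: linear_probes(table, labels, cfg))
    if probes is not None:
        report["contact_ap"], report["contact_auc"], report["fall_auc"] = probes
    report["pcr"] = _attempt(errors, "pcr",
                             lambda: pcr(test.z, codes_te, cfg.pcr_metric))
    report["neighborhood"] = _attempt(
        errors, "neighborhood",
        lambda: neighborhood_consistency(
            test.z, codes_te, test.meta["video_id"].to_numpy(), cfg.k, cfg.seed),
    )
    report["errors"] = errors
    return report
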