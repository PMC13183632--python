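"""Diagnostic metrics against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from pharl import (EmbeddingTable, neighborhood_consistency, pcr, poa_macro,
                   project, severity_axis, spearman_kendall)
from pharl.config import ORDINAL, EvalConfig
from pharl.evaluation import evaluate, linear_probes

from conftest import random_unit_rows


def labels_frame(codes):
    classes = {v: k for k, v in ORDINAL.items()}
    return pd.DataFrame(
        {
            "window_id": [f"w{i}" for i in range(len(codes))],
            "y_phys": [classes[c] for c in codes],
            "ordinal_code": codes,
            "contact_flag": [int(c > 0) for c in codes],
            "max_impulse_head": np.nan,
            "max_impulse_trunk": np.nan,
            "max_impulse_limb": np.nan,
        }
    )


# ---------------------------------------------------------------------------
# Severity axis
# ---------------------------------------------------------------------------


def test_axis_projection_algebra():
    rng = np.random.default_rng(0)
    z = random_unit_rows(rng, 30, 6)
    codes = np.array([0, 1, 2] * 10)
    axis = severity_axis(z, codes)
    gap = project(axis.mu_head[None, :], axis) - project(axis.mu_supported[None, :], axis)
    assert gap[0] == pytest.approx(np.linalg.norm(axis.mu_head - axis.mu_supported))
    assert np.linalg.norm(axis.v_hat) == pytest.approx(1.0)


def test_axis_requires_both_extreme_classes_and_distinct_centroids():
    z = np.eye(4)
    with pytest.raises(ValueError, match="Head"):
        severity_axis(z, np.array([0, 0, 1, 1]))
    with pytest.raises(ValueError, match="coincide"):
        severity_axis(np.vstack([z[0], z[0]]), np.array([0, 2]))


def test_one_dimensional_projection_identity():
    z = np.array([[0.0], [1.0], [0.25]])
    axis = severity_axis(z[:2], np.array([0, 2]))
    assert np.allclose(project(z, axis), z.ravel())


# ---------------------------------------------------------------------------
# Rank metrics vs. O(n^2) oracle
# ---------------------------------------------------------------------------


def _rank_average_ties(x):
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _oracle_spearman_kendall(codes, scores):
    rx, ry = _rank_average_ties(codes), _rank_average_ties(scores)
    rho = np.corrcoef(rx, ry)[0, 1]
    conc = disc = tx = ty = 0
    n = len(codes)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i] - codes[j], scores[i] - scores[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    tau = (conc - disc) / np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return rho, tau


def test_rank_correlations_match_bruteforce_oracle():
    rng = np.random.default_rng(31)
    for n in (10, 57, 200):
        codes = rng.integers(0, 3, size=n)
        if len(np.unique(codes)) < 2:
            codes[0], codes[1] = 0, 2
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        rho, tau = spearman_kendall(codes, scores)
        o_rho, o_tau = _oracle_spearman_kendall(codes, scores)
        assert rho == pytest.approx(o_rho, abs=1e-12)
        assert tau == pytest.approx(o_tau, abs=1e-12)


def test_rank_correlation_extremes_and_errors():
    codes = np.array([0, 1, 2])  # tie-free codes so the extremes are exact
    rho, tau = spearman_kendall(codes, np.arange(3.0))
    assert (rho, tau) == (pytest.approx(1.0), pytest.approx(1.0))
    rho, tau = spearman_kendall(codes, -np.arange(3.0))
    assert (rho, tau) == (pytest.approx(-1.0), pytest.approx(-1.0))
    # with tied codes, scores constant within each code still give rho = 1
    tied = np.array([0, 0, 1, 1, 2, 2])
    rho, _ = spearman_kendall(tied, tied.astype(float) * 2.5)
    assert rho == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        spearman_kendall(tied, np.ones(6))
    with pytest.raises(ValueError, match="distinct"):
        spearman_kendall(np.zeros(6), np.arange(6.0))


# ---------------------------------------------------------------------------
# POA
# ---------------------------------------------------------------------------


def test_poa_hand_example():
    """{S: (0.1, 0.4), T: (0.3,), H: (0.2,)} enumerated exhaustively:
    S<T pairs -> 0.5, S<H -> 0.5, T<H -> 0.0, macro 1/3."""
    codes = np.array([0, 0, 1, 2])
    scores = np.array([0.1, 0.4, 0.3, 0.2])
    macro, detail = poa_macro(codes, scores, return_detail=True)
    assert detail == {"Supported<Trunk": 0.5, "Supported<Head": 0.5,
                      "Trunk<Head": 0.0}
    assert macro == pytest.approx(1 / 3)


def test_poa_extremes_ties_and_missing_class():
    codes = np.array([0, 0, 1, 1, 2, 2])
    assert poa_macro(codes, np.arange(6.0)) == 1.0
    assert poa_macro(codes, -np.arange(6.0)) == 0.0
    assert poa_macro(codes, np.zeros(6)) == pytest.approx(0.5)  # all ties
    macro, detail = poa_macro(np.array([0, 0, 1]), np.array([0.0, 0.1, 0.9]),
                              return_detail=True)
    assert detail["Supported<Head"] is None and detail["Trunk<Head"] is None
    assert macro == 1.0  # macro over available pairs only


def test_poa_sampled_agrees_with_exhaustive():
    rng = np.random.default_rng(44)
    codes = rng.choice([0, 1, 2], size=1000, p=[0.5, 0.35, 0.15])
    scores = codes + rng.normal(scale=1.2, size=1000)
    exhaustive = poa_macro(codes, scores, cap=10**9)
    sampled = poa_macro(codes, scores, cap=5000, seed=1)
    assert abs(sampled - exhaustive) < 0.02


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------


def test_pcr_two_point_classes_closed_form():
    # classes on a line: intra distances 1 and 1; inter 2, 3, 1, 2 -> mean 2
    z = np.array([[0.0], [1.0], [2.0], [3.0]])
    assert pcr(z, np.array([0, 0, 1, 1])) == pytest.approx(2.0)


def test_pcr_separated_clusters_much_greater_than_one():
    rng = np.random.default_rng(7)
    centers = np.eye(3) * 50
    z = np.vstack([c + rng.normal(scale=0.01, size=(10, 3)) for c in centers])
    codes = np.repeat([0, 1, 2], 10)
    assert pcr(z, codes) > 10


def test_pcr_permutation_null_is_one():
    rng = np.random.default_rng(11)
    vals = []
    for _ in range(20):
        z = random_unit_rows(rng, 120, 8)
        codes = rng.integers(0, 3, size=120)
        vals.append(pcr(z, codes))
    assert abs(np.mean(vals) - 1.0) < 0.05


def test_pcr_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match=">= 2 members"):
        pcr(np.eye(3), np.array([0, 1, 1]))
    with pytest.raises(ValueError, match="duplicate"):
        pcr(np.ones((4, 2)), np.array([0, 0, 1, 1]))


# ---------------------------------------------------------------------------
# Linear probes
# ---------------------------------------------------------------------------


def _table_from(z, codes, falls, splits, videos=None):
    n = len(z)
    meta = pd.DataFrame(
        {
            "window_id": [f"w{i}" for i in range(n)],
            "trajectory_id": [f"t{i // 2}" for i in range(n)],
            "video_id": videos if videos is not None else [f"v{i // 2}" for i in range(n)],
            "split": splits,
            "fall_label": falls,
        }
    )
    return EmbeddingTable(meta, z)


def test_probes_separable_clusters_are_perfect():
    rng = np.random.default_rng(3)
    n = 80
    codes = np.array([0, 2] * (n // 2))
    z = np.where(codes[:, None] > 0, 1.0, -1.0) + rng.normal(scale=0.05, size=(n, 4))
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    splits = ["train"] * (n // 2) + ["test"] * (n // 2)
    table = _table_from(z, codes, falls=(codes > 0).astype(int), splits=splits)
    ap, auc, fall_auc = linear_probes(table, labels_frame(codes))
    assert (ap, auc, fall_auc) == (1.0, 1.0, 1.0)


def test_probe_auc_near_half_under_label_permutation():
    rng = np.random.default_rng(19)
    aucs = []
    for _ in range(20):
        n = 200
        z = random_unit_rows(rng, n, 6)
        codes = rng.permutation(np.array([0, 2] * (n // 2)))
        splits = ["train"] * (n // 2) + ["test"] * (n // 2)
        table = _table_from(z, codes, falls=(codes > 0).astype(int), splits=splits)
        _, auc, _ = linear_probes(table, labels_frame(codes))
        aucs.append(auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_probe_single_class_split_rejected():
    z = random_unit_rows(np.random.default_rng(0), 8, 3)
    codes = np.array([0, 0, 0, 0, 0, 0, 0, 0])
    table = _table_from(z, codes, falls=[0] * 8, splits=["train"] * 4 + ["test"] * 4)
    with pytest.raises(ValueError, match="single"):
        linear_probes(table, labels_frame(codes))


# ---------------------------------------------------------------------------
# Neighborhood consistency
# ---------------------------------------------------------------------------


def test_neighborhood_pure_separated_clusters():
    rng = np.random.default_rng(23)
    zs, codes, videos = [], [], []
    for c, center in enumerate(np.eye(3) * 20):
        for v in range(3):  # three videos per class
            pts = center + rng.normal(scale=0.01, size=(4, 3))
            zs.append(pts)
            codes += [c] * 4
            videos += [f"c{c}v{v}"] * 4
    z = np.vstack(zs)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    out = neighborhood_consistency(z, np.array(codes), np.array(videos), k=5)
    assert out == {"Supported": 1.0, "Trunk": 1.0, "Head": 1.0}


def test_neighborhood_single_video_class_undefined():
    rng = np.random.default_rng(2)
    z = random_unit_rows(rng, 12, 4)
    codes = np.repeat([0, 1, 2], 4)
    videos = np.array(["v0"] * 4 + ["v1", "v2"] * 2 + ["v3"] * 4)
    out = neighborhood_consistency(z, codes, videos, k=3)
    assert out["Supported"] is None and out["Head"] is None
    assert out["Trunk"] is not None


def test_neighborhood_hand_counted_intruder():
    """2 classes x 2 videos, 1D layout with one cross-class intruder whose
    position makes it the nearest cross-video neighbor of one query."""
    z = np.array([
        [1.0, 0.0],   # q0: class 0, video a
        [1.0, 0.02],  # class 0, video b
        [0.0, 1.0],   # class 1, video c
        [0.05, 1.0],  # class 1, video d
        [0.9, 0.45],  # intruder: class 1, video d, near class 0
    ])
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    codes = np.array([0, 0, 1, 1, 1])
    videos = np.array(["a", "b", "c", "d", "d"])
    out = neighborhood_consistency(z, codes, videos, k=2, seed=0)
    # class 0: db has 2 of each class (minority=2 -> all of class 0, sample
    # of class 1). Queries 0 and 1 both retrieve the other class-0 window
    # plus one class-1 entry -> fraction 0.5 each.
    assert out["Supported"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def _full_table(rng, n=120, d=8, informative=True):
    codes = np.tile([0, 0, 0, 1, 1, 2], n // 6)
    z = rng.normal(size=(n, d))
    if informative:
        z[:, 0] += codes * 3.0
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    splits = np.where(np.arange(n) % 3 == 2, "test", "train")
    # two windows per trajectory/video so PCR and retrieval are defined
    table = _table_from(z, codes, falls=(codes > 0).astype(int), splits=splits)
    return table, labels_frame(codes)


def test_report_is_pure_and_rotation_invariant():
    rng = np.random.default_rng(55)
    table, labels = _full_table(rng)
    r1 = evaluate(table, labels, EvalConfig(seed=3))
    r2 = evaluate(table, labels, EvalConfig(seed=3))
    assert r1 == r2
    # axis metrics are invariant to a global orthogonal rotation
    q, _ = np.linalg.qr(rng.normal(size=(table.z.shape[1],) * 2))
    rotated = EmbeddingTable(table.meta, table.z @ q)
    r3 = evaluate(rotated, labels, EvalConfig(seed=3))
    for key in ("spearman_rho", "poa_macro", "kendall_tau", "pcr"):
        assert r3[key] == pytest.approx(r1[key], abs=1e-9)


def test_report_carries_reasons_for_missing_head_class():
    rng = np.random.default_rng(56)
    table, labels = _full_table(rng)
    no_head = labels.copy()
    no_head.loc[no_head["y_phys"] == "Head", ["y_phys", "ordinal_code",
                                              "contact_flag"]] = ["Trunk", 1, 1]
    report = evaluate(table, no_head, EvalConfig(seed=3))
    assert report["spearman_rho"] is None
    assert "severity_axis" in report["errors"]
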