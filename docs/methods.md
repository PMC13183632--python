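# Methods

## Problem setting

Vision-based fall analysis suffers from kinematic-to-physical ambiguity:
motions that look alike can end in physically different outcomes (an
arm-braced landing vs. a direct head impact). `pharl` learns window-level
motion embeddings in which physics-derived contact outcomes — not visual
similarity alone — organize the geometry, without ever training an outcome
predictor. Supervision is weak and structural: coarse contact classes
(*Supported*, *Trunk*, *Head*, ordinal codes 0/1/2) derived from simulated
contact descriptors reshape the relations of a contrastive objective.
Inference is a pure feed-forward encoder; descriptors, labels and relation
graphs exist only at training time.

## Contact labeling

A contact descriptor is an event `(video, [ts, te), body part, impulse in
N·s, source)`, where `source` distinguishes contacts observed inside a
window from contacts found by a short-horizon continuation rollout started
at the window boundary. For a window `W = [t0, t1)`:

1. **Temporal alignment** keeps window-source descriptors with
   `(ts < t1) and (te > t0)` (half-open intervals, frames, 0-based).
2. **Boundary completion** additionally admits continuation-source
   descriptors whose start lies in `[t1, t1 + horizon)`. The horizon
   defaults to one window stride (8 frames at the nominal 25 fps); the
   admission rule tests the descriptor's *start*, so a continuation event
   overlapping the window body is never window evidence.
3. **Reliability filtering** drops descriptors with `impulse <= threshold`.
   The default threshold of 0.0 N·s is a strict inequality: it discards
   exactly zero-impulse artifacts while keeping every real contact.
4. **Merging** aggregates survivors by per-category maximum impulse over
   three categories: head; trunk (torso or hip); limb (arm/hand/leg/foot).

The label is assigned by hierarchical dominance: *Head* if any
head-category impulse is present, else *Trunk* if any trunk-category
impulse, else *Supported* (limb-only evidence and empty sets alike).
Dominance ignores magnitudes — a 1.2 N·s head contact outranks a 9.9 N·s
trunk contact. Windows of non-fall trajectories label *Supported* without
touching the stream. The contact flag is `C = 1[label ∈ {Head, Trunk}]`.

The denoising-off ablation replaces this with trajectory-level labeling:
every window of a fall trajectory inherits the dominance label of the
trajectory's whole stream, so pre-impact standing poses carry severe
outcome tags — the label-noise failure mode window alignment removes.

## Relations

Within a batch (optionally extended by a memory bank), each anchor `i`
owns: trajectory positives `P_traj(i)` (other windows of its trajectory),
candidates `A(i)` (everything but itself), cross-trajectory candidates
`Q(i)`, a denominator mask `M(i)`, and physics positives `P_phys(i)`.
For contact anchors, `M(i)` holds all cross-trajectory contact candidates:
removing them from the contrastive denominator prevents false repulsion
between physically equivalent windows. Masking uses the contact flag only,
so binary and multiclass modes mask identically. `P_phys(i)` matches the
exact class across trajectories (multiclass) or the fused contact flag
(binary); the temporal-only control has empty masks and physics positives.
Anchors with empty `P_phys` skip the physics term. By construction
`P_traj(i) ∩ M(i) = ∅` (masked entries are cross-trajectory).

Bank entries are FIFO-evicted, enter `A`/`Q` (and, by default, `M`/
`P_phys` — a config flag restores the batch-only reading), never act as
anchors and never receive gradient. The bank is disabled by default
(capacity 4096 when enabled): at the package's desk scale it measurably
degrades every arm — stale embeddings dilute the denominators — whereas
batches of 64 with physics-stratified sampling already supply cross-
trajectory same-class partners for >96% of Head anchors.

Physics-stratified batching covers each training epoch exactly once and
reserves at least `min_per_class = 2` windows of every present class per
batch while supply lasts; the temporal-only control uses a plain shuffle.

## Objectives

With l2-normalized embeddings `z`, cosine similarity `s(·,·)`, and
temperatures `τ = τ_p = 0.2`:

* masked trajectory contrast, averaged over anchors with nonempty
  positives and denominator:
  `L_motion(i) = −log [ Σ_{j∈P_traj} e^{s(z_i,z_j)/τ} / Σ_{k∈A∖M} e^{s(z_i,z_k)/τ} ]`
  — with `M = ∅` this is exactly plain trajectory-level InfoNCE;
* physics alignment over contact anchors with partners:
  `L_phys(i) = −log [ Σ_{j∈P_phys} e^{s/τ_p} / Σ_{k∈Q} e^{s/τ_p} ]`;
* a variance hinge on the *raw* (pre-normalization) projector outputs,
  `mean_j max(0, γ − sqrt(var_j + 1e-4))` with `γ = 1` and the variance
  taken over the batch (ddof 1) — a VICReg-style guard against collapse,
  chosen because the collapse regularizer's exact form is an open design
  point;
* total: `L = L_motion + w·λ_phys·L_phys + λ_var·L_var`, with
  `λ_phys = 1.0`, `λ_var = 0.1`, and `w` ramping linearly from 0 to 1 over
  the first 10% of training. Validation loss is always computed at
  `w = 1` so epochs are comparable for checkpoint selection.

All ratios are computed in log space; each term averages over its own
contributing anchors. Every loss has a hand-derived analytic gradient with
respect to the raw projector outputs (normalization is backpropagated as a
tangent-space projection); the test suite checks the full
encoder-through-loss gradient against central finite differences.

## Encoder and training

The encoder is intentionally small: temporal average pooling over the
window's frames, a ReLU MLP trunk (default width 64), a projection head
(64 → 32), l2 normalization. Forward, backward and Adam (lr 1e-4) are
explicit numpy; on one CPU a run is bit-reproducible from its seed, which
is the tested determinism contract. Labels cannot reach the encode path —
its API accepts feature arrays only — and inference needs exactly a
checkpoint plus a manifest. Splits are trajectory-level (a trajectory
spanning splits is a hard error) and stratified by outcome so each split
retains class diversity. Default training is 100 epochs; the bundled
experiments use 40, at which point the post-warmup loss has flattened at
the problem sizes below. Best-validation and final checkpoints are both
kept.

## Diagnostics

All metrics are post hoc. A severity axis `v̂ = (μ_Head − μ_Supported) /
‖·‖` is fit from train-split centroids only and reused unchanged on the
evaluation split; windows score `s_i = z_i·v̂`.

* Spearman ρ and Kendall τ-b between ordinal codes and scores (primary
  ordinal evidence; constant scores or a single class raise structured
  errors rather than NaNs).
* POA: for each ordered class pair (S<T, S<H, T<H), the fraction of
  cross-class pairs ranked consistently (ties 0.5), exhaustive up to 1e5
  pairs per class pair and seeded-sampled above; macro mean over
  available pairs, absent pairs reported as null with a reason.
* Linear probes (contact vs. Supported; fall vs. ADL): l2-regularized
  logistic regression (C = 1, lbfgs), fit on train embeddings, scored on
  test; AP and ROC-AUC. The fall probe defaults to window-level tags
  inherited from the trajectory; a trajectory-pooled variant is exposed.
* PCR: mean inter-class over mean intra-class pairwise distance,
  Euclidean on normalized embeddings by default (cosine exposed).
* Cross-video neighborhood consistency: the retrieval database subsamples
  every class to the minority size (seeded); queries are all windows of a
  class; same-video entries are excluded before taking up to k = 10
  cosine neighbors; per-class consistency is the mean same-class fraction
  ("row-normalized diagonal"). Classes spanning fewer than two videos are
  undefined.

Rank metrics are validated against O(n²) concordance oracles, the POA
against exhaustive enumeration, and PCR/probes against permutation nulls;
all metrics are permutation- and rotation-invariant (checked).

## Synthetic data generator

The generator stands in for RGB video plus offline humanoid simulation.
It is a statistical stand-in, not a physics emulator: no bodies, surfaces
or restitution are modeled, and impulse magnitudes are distributional
choices, not biomechanics.

Each trajectory (one video) is 120 frames at a nominal 25 fps, windowed
at length 16, stride 8. 58% of trajectories are falls (the aggregate
fall/ADL ratio of the public fall corpora this emulates); fall outcomes
follow the printed mix Supported/Trunk/Head = 0.56/0.34/0.10 by exact
largest-remainder allocation, so the empirical mix converges to the
target by construction. Latent severity is drawn from disjoint per-class
ranges (`code + U(0.1, 0.9)`), guaranteeing the strict ordering
Supported < Trunk < Head.

Per-frame features are a stepwise phase signal — shared pre-impact row,
class-dependent impact row(s), class-dependent rest row — temporally
smoothed, plus a per-video nuisance vector confined to a rank-4 subspace
(i.i.d. across videos, constant within), plus N(0, 0.3²) noise. Impact
and rest rows shift along one fixed severity direction in proportion to
severity, with small class-specific jitter; pre-impact frames carry no
class signal at all, so trajectory-level labels are genuinely noisy and
ordinal recovery requires aligning cross-video structure, not reading a
single frame.

Contact descriptors: impacts last 6 frames with impulses LogNormal(1,
0.3) N·s; Head-outcome falls strike the trunk 4–12 frames before the
head, so their early impact windows are true trunk-contact windows;
ground contact persists through the rest phase as sustained weak
descriptors (LogNormal(−0.5, 0.3)), keeping post-impact windows labeled
with the outcome; spurious contacts (Poisson rate 2 per fall, impulse
≤ 0.05 N·s, any body part, drawn from an independent substream) are
separable from real contacts by any threshold in between. With
probability 0.25 the first impact lands within one stride after a window
boundary and its descriptors are duplicated with continuation source,
exercising boundary completion. ADL trajectories emit no descriptors.

What passing tests on this generator do **not** show: robustness to
viewpoint/illumination nuisance of real video, to contact-detection
errors upstream of the descriptor stream, or to class signatures less
linearly structured than the severity-direction model. One known
consequence of the trajectory-level outcome mix plus window-aligned
labeling is that contact windows are ~18% of all windows, so
window-level rank statistics are dominated by the Supported-vs-contact
boundary; pair-balanced statistics (macro POA, per-pair ordering
accuracy) resolve Trunk/Head structure that window-level Spearman
underweights at this mix.

## Bundled experiments

`scripts/acceptance.py` and the heavyweight tests run, per seed
(5 replicates, 300 trajectories ≈ 4 200 windows each): the full
configuration, a capacity-matched temporal-only control (identical
architecture, init and schedule — differences are attributable to
supervision design alone), a denoising-off arm, and a binary-attraction
arm; 40 epochs each; diagnostics on the test split against the reference
(denoised, both-source) labels for every arm. Typical desk-scale outcome:
full ρ ≈ 0.39–0.55 vs. control ρ ≈ 0.06–0.15, severity ordering
Head > Trunk > Supported in the full arm's mean projections, denoising-off
clearly lower than full, and binary attraction losing Trunk<Head ordering
while remaining competitive on window-level ρ (see the class-mix note
above).

## Numerical and degenerate-input conventions

Half-open frame intervals everywhere; strict-greater impulse filter;
softmax ratios in log space (finite under 50× similarity scaling);
relation sets materialized as sorted index lists; batches of fewer than
two windows are skipped; a batch of one is an error for the variance
term; empty denominators after masking skip the anchor with a warning;
coincident centroids, constant scores, single-class splits and
single-video classes raise or report structured reasons. All randomness
derives from one integer seed through named substreams (sim, spurious,
batch, poa, balance, encoder-init), each independent of the others'
consumption.
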