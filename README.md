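# pharl

Physics-aware alignment representation learning for fall-motion windows.

## The problem

Vision-based fall analysis hits a wall that better video models do not
remove: visually similar motions can have very different physical
outcomes, because the difference lives in contact mechanics (an arm-braced
landing vs. a direct head impact), and clinical injury labels are too
rare, noisy and ethically constrained to supervise on. `pharl` takes the
weak-supervision route: coarse contact outcomes derived from simulated
contact descriptors — *Supported*, *Trunk*, *Head*, with ordinal codes
0/1/2 — are used only to restructure the relations of a contrastive
objective, never as prediction targets. The learned embedding is for
analysts of human-movement and digital-health data who need risk-aligned
motion representations (retrieval, low-shot screening, geometry
diagnostics), not a severity predictor.

## The method

Trajectories are segmented into overlapping windows `[t0, t1)`. Each
window gets a physics label by aligning contact descriptors to it
(half-open overlap `(ts < t1) ∧ (te > t0)`, plus short-horizon
continuation evidence starting in `[t1, t1 + h)`), filtering weak
impulses (strictly greater than a 0.0 N·s threshold), merging by
per-category maximum impulse, and applying hierarchical dominance:
Head ≻ Trunk ≻ everything else. With contact flag
`C_i = 1[y_i ∈ {Head, Trunk}]`, an encoder producing l2-normalized
embeddings `z_i` is trained with

```
L = L_motion + w·λ_phys·L_physics + λ_var·L_var

L_motion(i) = −log  Σ_{j∈P_traj(i)} exp(sim(z_i,z_j)/τ)
                    ─────────────────────────────────────
                    Σ_{k∈A(i)∖M(i)} exp(sim(z_i,z_k)/τ)

L_physics(i) = −log Σ_{j∈P_phys(i)} exp(sim(z_i,z_j)/τ_p)
                    ─────────────────────────────────────
                    Σ_{k∈Q(i)} exp(sim(z_i,z_k)/τ_p)
```

where `P_traj(i)` are same-trajectory windows, `A(i)` all candidates,
`M(i) = {k : C_i = C_k = 1, traj(k) ≠ traj(i)}` the denominator mask that
stops physically equivalent contact windows from being repelled as
negatives, `P_phys(i)` exact-class cross-trajectory positives, `Q(i)`
cross-trajectory candidates, `τ = τ_p = 0.2`, and `L_var` a variance
hinge preventing collapse. `w` warms up linearly over the first 10% of
training. A post-hoc severity axis `v̂ = (μ_Head − μ_Supported)/‖·‖` (train
centroids only) scores windows `s_i = z_i·v̂` for a rank-prioritized
diagnostic suite: Spearman ρ, macro pairwise ordering accuracy (POA),
linear-probe contact AP/AUC and fall AUC, physics consistency ratio
(PCR), Kendall τ, and cross-video neighborhood consistency. The ordinal
structure Supported < Trunk < Head is never optimized — it emerges, and
the diagnostics measure how strongly.

A bundled synthetic generator (multi-phase fall trajectories, per-video
nuisance, latent severity with a known ordering, spurious impulses,
boundary-straddling impacts) stands in for RGB data and offline physics
simulation, so the whole pipeline runs and is tested end-to-end on a
laptop-scale CPU. See `docs/methods.md` for every modeling choice.

## Worked example

Train the physics-aligned encoder and its capacity-matched temporal-only
control on one synthetic dataset (300 trajectories), then compare
diagnostics on the held-out test split:

```python
from pharl import RunConfig, run_pipeline

cfg = RunConfig(seed=0).with_seed(0)
cfg.train.epochs = 40
reports = run_pipeline(cfg, "demo_run")
```

which wrote `demo_run/comparison.csv`:

```
               arm  spearman_rho  poa_macro  contact_ap  contact_auc  fall_auc    pcr  kendall_tau
multiclass_physics        0.3886     0.7495      0.7814       0.8206    0.8035 1.0035       0.3186
     temporal_only        0.1511     0.5705      0.7457       0.8114    0.7333 1.0348       0.1225
```

and the full arm's mean severity projections per class:

```
{'Supported': 0.152, 'Trunk': 0.521, 'Head': 0.612}
```

Read: with identical encoders, data and schedules, physics-aligned
relations nearly triple the rank correlation between the ordinal contact
labels and the severity-axis projection (ρ 0.39 vs 0.15) and lift POA
from near-chance-for-ties 0.57 to 0.75, while the class means order
Head > Trunk > Supported — the emergent ordinal structure the method is
built to induce. Contact AP/AUC improve more modestly (contact
localization is partly learnable from motion alone), and PCR stays near 1
on normalized embeddings.

The same pipeline is scriptable from the shell:

```bash
pharl simulate --seed 3 --out runs/sim
pharl label --manifest runs/sim/manifest.jsonl \
            --descriptors runs/sim/descriptors.jsonl \
            --out runs/labels.csv --threshold 0.0 --denoise on
pharl run --seed 0 --out runs/full        # simulate→label→train→embed→eval
pharl ablate --seed 0 --out runs/ablation # six-row component-switch grid
```

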