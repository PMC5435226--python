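# maturewalk

Connectome-based analysis and modelling of early brain maturation.

In the developing brain, gray-matter (GM) regions and the white-matter
(WM) fibre bundles connecting them appear to mature together, following
the functional hierarchy: subcortical structures (SUB) before primary
sensory/motor cortices (PRIM), before secondary (SEC) and tertiary (TER)
association areas. `maturewalk` implements the full analysis chain used to
study this on structural connectomes, for network-neuroscience researchers
working with tractography-derived networks and quantitative MRI maps:

* **Consensus connectomes** — from per-subject streamline-count matrices,
  keeping edges present in ≥ 50% of subjects and averaging their weights.
* **Maturation scalars** — ADC (10⁻⁶ mm/s²) and T1 (ms) region values with
  a one-pass 1-SD voxel exclusion, and along-tract edge values; both
  scalars decrease as tissue matures.
* **Statistical battery** — a permutation Jonckheere–Terpstra (JT) trend
  test for the ordered gradient `SUB < PRIM < SEC < TER`, GM–WM coupling
  correlations (region vs. incident connections; pair means vs. the
  connecting tract, split by connection length; connected vs. unconnected
  region pairs).
* **Maturation model** — a *non-backtracking* random walk seeded in the
  ten primary sensory cortices: from region *i* (arrived from *prev*) a
  walker steps to neighbour *j* with probability
  `p_ij = w_ij / Σ_{k∈N_i\{prev}} w_ik`. Per-step transit counts are
  maturation scores, correlated with the scalars per random-walk step
  (RWS). An exact oracle on directed-edge states validates the Monte
  Carlo.
* **Null models** — random re-seeding and Maslov–Sneppen degree-preserving
  rewiring (weights travel with edges), plus a randomized control for the
  GM–WM coupling.
* **Synthetic study generator** — no imaging data ship with the package;
  a forward model generates 9-subject cohorts on a 90-region,
  hemisphere-symmetric parcellation (~450-edge consensus networks) whose
  scalars are driven by the walk model itself, so every stage is testable
  end-to-end.

## Worked example

```python
from maturewalk import (GeneratorConfig, WalkConfig, generate_study,
                        jt_test, region_vs_incident, run_model,
                        scores_vs_scalar)

bundle = generate_study(GeneratorConfig(rng_seed=42))
c = bundle.consensus                      # 422 edges, density 10.5%
adc = bundle.scalar_maps["ADC"]

# ordered maturation trend across the four groups
jt = jt_test([adc.node_values[r] for r in range(90)],
             list(c.parcellation.groups), n_perm=9999, rng_seed=0)
print(f"JT z = {jt.z:.1f}, p = {jt.p_perm:.4f}")   # JT z = 5.9, p = 0.0001

# GM-WM coupling
print(f"r = {region_vs_incident(c, adc).r:.2f}")   # r = 0.95

# seeded no-back walk, 10 seeds x 1000 reps x 10 steps
scores = run_model(c, WalkConfig(rng_seed=7))
curve = scores_vs_scalar(scores, adc, c)["node"]
print([round(r.r, 2) for r in curve[:3]])          # [-0.77, -0.83, -0.84]
```

The positive JT z with its permutation floor p confirms that ADC increases
along the maturation order; the strongly negative Spearman correlations at
early RWSs say that regions reached early and often by walkers from the
sensory seeds are the ones that look most mature — the model's central
claim. The `examples/` directory has one narrative script per capability
(consensus building, trend/coupling battery, walk model, null models).

A thin CLI mirrors the pipeline stages:

```bash
maturewalk all --out run1 --seed 7          # synth -> consensus -> stats
                                            #   -> model -> nulls + manifest
```

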