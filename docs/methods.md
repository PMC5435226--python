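# Methods

## Scientific setting

`maturewalk` analyses the joint maturation of gray matter (GM) and the
white-matter (WM) structural network in the early developing brain. The
working objects are:

* a **parcellation** of 90 regions split into four ordered maturation
  groups — subcortical nuclei (SUB, n=12), primary sensory/motor cortices
  (PRIM, n=12), secondary association areas (SEC, n=34) and tertiary
  higher-order areas (TER, n=32) — with ten primary sensory regions
  (rolandic operculum, calcarine, postcentral, paracentral lobule, Heschl;
  both hemispheres) acting as model seeds;
* per-subject **streamline-count matrices** from tractography, reduced to a
  group **consensus connectome**;
* **maturation scalars** — ADC (apparent diffusion coefficient, printed in
  units of 10⁻⁶ mm/s²) and T1 relaxation time (ms) — both of which
  *decrease* as tissue matures.

## Consensus connectome

An edge survives if it is present (nonzero count) in at least
`ceil(threshold × n_subjects)` subjects — at the default 50% with nine
subjects that means ≥ 5. "At least 50%" is read strictly, hence the
ceiling. The surviving weight is the mean count over the subjects where
the edge is present; zeros are treated as absence, not as a weight of 0.
Because the phrase "averaging the connection weights" is genuinely
ambiguous, the mean over *all* subjects is available via
`average_over_all=True`. Edge lengths are pooled with the same presence
rule. Density is reported as `|E| / (N(N−1)/2)` exactly.

## Scalar aggregation

Region values aggregate GM voxel samples with a one-pass 1-SD exclusion:
mean `m` and *sample* (n−1) standard deviation `s` are computed once, then
voxels with `|x − m| > s` are discarded and the rest averaged. One pass
only — `m` and `s` are not re-estimated after discarding. The rule can
never empty the sample (values at distance 0 always survive). Edge values
are plain means of along-tract samples; the exclusion rule is a GM
partial-volume control and is not applied to WM. Whether voxel pooling
happens per subject or across subjects is upstream of this package: the
aggregator operates on whatever sample it is handed.

## Trend and correlation battery

The ordered-group trend uses a Jonckheere–Terpstra statistic with 0.5 tie
credit, `U = Σ_{g<h} #{x∈g, y∈h : x<y} + 0.5·#ties`, standardized by the
no-tie null moments `μ₀ = (N² − Σn_k²)/4` and
`σ₀² = [N²(2N+3) − Σn_k²(2n_k+3)]/72`. The reported "JT" is the z value;
the raw U is carried along. p comes from label permutation with the
add-one estimator `(1 + #{U* ≥ U})/(n_perm + 1)`, so p is never exactly 0;
an exact mode enumerates all distinct group assignments when their number
is small (used by the worked-example tests). Under the null the test is
calibrated: the acceptance suite checks a rejection rate of 0.05 ± 0.02 at
α = 0.05 over 1000 simulations at the study's group sizes.

Correlations: region scalar vs. mean over incident connections (Pearson,
all four groups); endpoint pair mean vs. connecting tract value, overall
and split at the mean connection length (ties at the mean go to "short" —
the strict inequalities of a long/short split leave equality to be owned
by one side, and this choice is logged here); and scalar similarity of
connected vs. unconnected region pairs. The pair analysis enters each
unordered pair in both orderings so the estimate is invariant to i↔j
labelling, and its p therefore comes from permuting node values over
regions (999 permutations, add-one), not from the inflated analytic n.
The unconnected side (3555 pairs at 450 edges) is computed exactly, no
sampling. No multiple-testing correction is applied anywhere; all p values
are reported raw with their n.

The group-pair edge table counts each edge once, in its
(lower-rank, higher-rank) group cell, so the entries sum to the edge
count.

## Maturation walk model

Maturation is modelled as particles spreading from primary sensory
cortices over the weighted network. From region `i`, arrived from `prev`,
the step probability is `p_ij = w_ij / Σ_{k∈N_i\{prev\}} w_ik`
(non-backtracking). Defaults follow the protocol: 10 seeds × 1000
repetitions × 10 random-walk steps (RWS), per-seed patterns summed.
Numerical choices:

* **Scores are cumulative in t.** Per-step transit counts are retained,
  but the quantity correlated with scalars is the cumulative count, which
  is monotone over RWSs as maturation scores should be.
* **Seed occupancy at t = 0 is not a transit** (a transit is an arrival
  through an edge); a flag adds it to cumulative scores if wanted.
* **Dead ends terminate the walk** under the default policy ("no back"
  read strictly); `allow_backtrack` bounces instead. The 90-region
  networks used here have no degree-1 nodes, so the policy only matters on
  toy graphs.
* Transition probabilities are normalized per vertex, so any global weight
  normalization (e.g. dividing streamline counts by their total) leaves
  the model invariant — asserted by test.
* The sampler advances all repetitions of a seed in lock-step through
  vectorized directed-edge transitions and is bit-reproducible from the
  RNG seed.

Because the no-back walk is non-Markovian on vertices, the **exact
oracle** propagates a probability mass vector over directed-edge states
(i→j) — 2|E| states, the Hashimoto construction — with transitions
(i→j)→(j→k), k≠i. Dead-end states absorb and leave the "alive" mass.
Expected per-step node/edge transit probabilities are read off the mass
vector; Monte Carlo and oracle agree with no systematic deviation (the
per-entity 3σ check and its statistical form live in the acceptance
suite).

Score–scalar coupling is assessed per RWS with Spearman correlation by
default (Pearson available, as both conventions appear in this
literature), over regions *excluding* SUB: the model propagates sensory
input through cortico-cortical pathways, and subcortical structures —
thalami included, since modelling the thalamus as one region would create
an artificial hub — do not follow one maturation clock. On the edge side
only connections between two included regions enter.

## Null models

1. **Random seeding**: 10 regions drawn uniformly from all 90 (subcortical
   included), model re-run, per-RWS r distribution over 50 realizations.
2. **Degree-preserving rewiring**: Maslov–Sneppen double-edge swaps —
   pick edges (a,b), (c,d), rewire to (a,d), (c,b) unless a self-loop or
   duplicate would result; 10 accepted swaps per edge by default. Weights,
   lengths and scalar values travel with the edge records, so degree
   sequence, edge count and weight multiset are preserved exactly. Walks
   start from the true seeds.
3. **Randomized incident control**: the region-vs-incident correlation
   recomputed on rewired networks (scalars traveling with edges); a
   topology-fixed alternative permutes edge scalar values instead. Which
   randomization the original citation used is not recoverable, so both
   variants are exposed, with the degree-preserving swap as the default
   reading.

## Synthetic data generator

No imaging data are distributed with this package; the generator emulates
the statistical structure the analyses assume, and its defaults define the
study conditions used by the tests.

* **Topology**: hemisphere-symmetric modular random graph on 90 regions,
  target density 11.2% (~450 edges), group-pair affinities qualitatively
  matching the observed repartition (SUB and SEC connect broadly, PRIM
  mainly to SEC, TER avoids PRIM), homotopic pairs boosted. Mirror-image
  pairs are sampled jointly, so hemisphere symmetry is exact. Presence
  probabilities are solved by bisection so the expected edge count hits
  the target even when some saturate at 1. Resampled until connected with
  no isolated node.
* **Weights**: integer lognormal streamline counts. Sensorimotor edges
  get multiplicative boosts (PRIM–PRIM ×8, PRIM–SEC ×2.5, SUB–PRIM ×2,
  homotopic ×4), reflecting the disproportionately heavy short
  sensorimotor and callosal bundles in tractography. This is what
  concentrates early walk transits around the seeds, so the cortical
  hierarchy gradient *emerges from network propagation* instead of being
  painted onto group baselines.
* **Subjects**: each of 9 subjects keeps each reference edge with
  probability 0.9, jitters weights lognormally (σ = 0.3), and gains
  spurious low-weight edges at rate 0.02 per absent pair — exercising the
  consensus rule in both directions (true edges occasionally missing,
  spurious edges essentially never reaching 5-of-9 presence).
* **Scalars** (forward model of the hypothesis that the WM backbone relays
  maturation): node value = baseline − b·z(exact cumulative walk score at
  t\*=2) + noise, with z() standardizing over regions and the score coming
  from the exact oracle, not Monte Carlo, so recovery experiments separate
  model noise from generator noise. Baselines: subcortical 1150 /
  cortical 1480 (ADC, ×10⁻⁶ mm/s²), 1750 / 2230 (T1, ms); the cortical
  baseline is deliberately flat — PRIM < SEC < TER arises from the walk
  term, which also makes the noise-free closure exact. Slope b = 120 ADC
  units per score SD, noise SD 60 (T1 scaled ×1.5). A fraction (0.6) of
  the noise variance is graph-smooth (two-hop neighbourhood averaging),
  mimicking the spatial autocorrelation of MRI maps; it scales with the
  noise SD and vanishes in the noise-free limit. Edge value =
  ρ·mean(endpoint values) + (1−ρ)·independent noise, ρ = 0.7. Edge
  lengths are lognormal (median ≈ 30 mm), drawn independently of topology
  since only the mean-length split consumes them.
* **Voxels**: Gaussian per-region samples (SD 50, 200 voxels)
  contaminated at rate 0.05 by a +8 SD offset, exercising the 1-SD
  exclusion.

What the generator does *not* emulate: tract geometry, distance-dependent
connection probabilities, subject-level covariance structure, scanner
noise spectra, or partial-volume physics beyond a crude outlier component.
Passing tests therefore demonstrate that the pipeline recovers the
structure this forward model plants — coupling step, effect sign, ordered
trend, null contrasts — not that it would recover them from real MRI under
arbitrary artefacts. One visible difference from real data: with ρ = 0.7
and ~10 incident edges per region the GM–WM incident correlation comes out
near 0.95, higher than typically measured, because averaging suppresses
the independent edge noise.

## Problem sizes and determinism

Default analyses run the full protocol (10×1000×10 walks, 9999 JT
permutations, 50 null realizations) in seconds, because walkers advance
vectorized over repetitions. The acceptance suite uses: 10 random
connectomes with 10⁵ repetitions for the oracle comparison, 1000
simulations for JT calibration, 50 generator seeds with 50+50 null
realizations each for parameter recovery, and 100 rewiring realizations
for the invariant check. Every random component takes an explicit integer
seed and is bit-reproducible; pipeline runs write a manifest with a config
hash and per-file checksums.

## Known limitations

* The JT permutation p floors at 1/(n_perm+1); "p ≈ 0" is representable
  only as that floor.
* The walk model treats maturation as conservative particle traffic; no
  decay, saturation or continuous-time variant is implemented.
* Strength-preserving (weighted-degree) and geometry-preserving nulls are
  out of scope; only degree-preserving rewiring and seed randomization are
  provided.
* Within this literature the pair-mean-vs-tract correlation has been
  quoted with small inconsistencies between text and figure captions
  (0.53 vs 0.54); this package computes and reports its own value.
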