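"""Synthetic study generator: connectomes, subject matrices and scalars.

Emulates the statistical structure of a 9-subject neonatal connectome
study: a 90-region parcellation split into the four maturation groups
(SUB 12, PRIM 12, SEC 34, TER 32), a hemisphere-symmetric consensus
network of ~450 edges (~11.2% density), and ADC/T1 maturation scalars
generated by a forward model of the study hypothesis — scalars decrease
where the seeded walk deposits more transits, so primary cortices look
most mature and the hierarchy gradient emerges from network propagation
rather than from hand-assigned cortical group means.

Scalars are derived from the *exact* expected walk scores (directed-edge
chain), not Monte Carlo, so recovery experiments separate model noise from
generator noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import (Connectome, Edge, GROUP_ORDER, Parcellation,
                         RegionRecord, SubjectMatrix)
from .scalars import ScalarMap, VoxelSamples
from .walk import expected_scores_all_seeds

SEED_LABELS = ("Rolandic_Oper", "Calcarine", "Postcentral",
               "Paracentral_Lobule", "Heschl")


class SynthError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Forward-model parameters; defaults emulate the study conditions."""

    n_regions: int = 90
    group_sizes: dict = field(default_factory=lambda: {
        "SUB": 12, "PRIM": 12, "SEC": 34, "TER": 32})
    n_subjects: int = 9
    target_density: float = 0.112
    weight_law: tuple[float, float] = (2.5, 1.0)  # lognormal (mu, sigma) of counts
    length_law: tuple[float, float] = (3.4, 0.6)  # lognormal (mu, sigma), mm
    coupling_step: int = 2  # t*: RWS at which scalars couple to walk scores
    effect_slope: float = 120.0  # ADC units per score SD
    noise_sd: float = 60.0  # ADC units
    noise_spatial_corr: float = 0.6  # fraction of noise variance that is
    # graph-smooth, mimicking the spatial autocorrelation of MRI scalars
    gm_wm_coupling: float = 0.7  # rho
    subject_dropout: float = 0.9  # per-edge presence probability per subject
    weight_jitter_sd: float = 0.3  # lognormal sigma of subject weight jitter
    spurious_edge_rate: float = 0.02  # per-pair per-subject spurious edges
    n_voxels: int = 200
    voxel_sd: float = 50.0
    outlier_rate: float = 0.05
    rng_seed: int = 0
    # ADC baselines: one subcortical offset + a uniform cortical baseline;
    # the PRIM < SEC < TER gradient comes from the walk term, not from here.
    adc_sub_baseline: float = 1150.0
    adc_cortical_baseline: float = 1480.0
    t1_sub_baseline: float = 1750.0
    t1_cortical_baseline: float = 2230.0
    t1_scale: float = 1.5  # T1 slope/noise relative to ADC

    def __post_init__(self) -> None:
        if sum(self.group_sizes.values()) != self.n_regions:
            raise SynthError("group sizes must sum to n_regions")
        if not 0 < self.target_density <= 1:
            raise SynthError("target_density must be in (0, 1]")
        for g, n in self.group_sizes.items():
            if n % 2:
                raise SynthError(f"group {g} size must be even (hemisphere split)")


def default_parcellation(cfg: GeneratorConfig | None = None) -> Parcellation:
    """Hemisphere-symmetric parcellation; left block then right block.

    Region i in the left hemisphere mirrors region i + n/2 on the right.
    Five of the six PRIM regions per hemisphere are the walk seeds (primary
    sensory cortices, both hemispheres).
    """
    cfg = cfg or GeneratorConfig()
    half = cfg.n_regions // 2
    regions = []
    for hemi_idx, hemi in enumerate(("L", "R")):
        rid = hemi_idx * half
        for group in GROUP_ORDER:
            n_half = cfg.group_sizes[group] // 2
            for k in range(n_half):
                if group == "PRIM" and k < len(SEED_LABELS):
                    label = f"{SEED_LABELS[k]}_{hemi}"
                    is_seed = True
                else:
                    label = f"{group}_{k:02d}_{hemi}"
                    is_seed = False
                regions.append(RegionRecord(
                    region_id=rid, label=label, hemisphere=hemi, group=group,
                    is_seed=is_seed,
                    exclude_from_model_correlation=(group == "SUB")))
                rid += 1
    return Parcellation(regions)


# group-pair connection propensities (qualitative repartition: SUB and SEC
# connect everywhere, PRIM mainly to SEC, TER avoids PRIM)
_AFFINITY = {
    ("SUB", "SUB"): 1.0, ("SUB", "PRIM"): 0.8, ("SUB", "SEC"): 1.0,
    ("SUB", "TER"): 0.8, ("PRIM", "PRIM"): 0.9, ("PRIM", "SEC"): 1.6,
    ("PRIM", "TER"): 0.3, ("SEC", "SEC"): 1.2, ("SEC", "TER"): 1.0,
    ("TER", "TER"): 1.2,
}

# streamline-count multipliers: sensorimotor (PRIM) connections are short
# and dense in tractography, so they carry disproportionately large counts;
# this is what concentrates early walk transits around the seed regions
_WEIGHT_BOOST = {
    ("PRIM", "PRIM"): 8.0, ("PRIM", "SEC"): 2.5, ("SUB", "PRIM"): 2.0,
}
_HOMOTOPIC_WEIGHT = 4.0


def _affinity(g1: str, g2: str) -> float:
    return _AFFINITY.get((g1, g2), _AFFINITY.get((g2, g1)))


def _weight_boost(g1: str, g2: str) -> float:
    return _WEIGHT_BOOST.get((g1, g2), _WEIGHT_BOOST.get((g2, g1), 1.0))


def generate_connectome(cfg: GeneratorConfig,
                        max_tries: int = 200) -> Connectome:
    """Hemisphere-symmetric modular random connectome.

    Pair-presence probabilities combine the group-pair affinity table with
    hemisphere factors (homotopic pairs boosted, heterotopic cross-hemisphere
    pairs damped) and are scaled to the target density. Mirror-image pairs
    are sampled jointly, so topology, weights and lengths are exactly
    hemisphere-symmetric. Resampled until the graph has no isolated node and
    is connected; density is required within 10% of target.
    """
    parc = default_parcellation(cfg)
    n = cfg.n_regions
    half = n // 2
    groups = parc.groups
    rng = np.random.default_rng(cfg.rng_seed)

    def mirror(i: int) -> int:
        return (i + half) % n

    # orbit representatives of unordered pairs under the mirror map
    orbits: list[list[tuple[int, int]]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in seen:
                continue
            mi, mj = sorted((mirror(i), mirror(j)))
            orbit = [(i, j)] if (mi, mj) == (i, j) else [(i, j), (mi, mj)]
            for p in orbit:
                seen.add(p)
            orbits.append(orbit)

    prop = np.empty(len(orbits))
    for k, orbit in enumerate(orbits):
        i, j = orbit[0]
        a = _affinity(groups[i], groups[j])
        same_hemi = (i < half) == (j < half)
        if mirror(i) == j:
            hemi_f = 3.0  # homotopic
        elif same_hemi:
            hemi_f = 1.0
        else:
            hemi_f = 0.25
        prop[k] = a * hemi_f
    orbit_sizes = np.array([len(o) for o in orbits])
    target_edges = cfg.target_density * n * (n - 1) / 2

    def expected_edges(scale: float) -> float:
        return float((np.clip(prop * scale, 0, 1) * orbit_sizes).sum())

    # probabilities saturate at 1, so solve for the scale by bisection
    lo, hi = 0.0, 1.0
    while expected_edges(hi) < target_edges - 1e-9 and hi < 1e9:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_edges(mid) < target_edges:
            lo = mid
        else:
            hi = mid
    p_orbit = np.clip(prop * hi, 0, 1)

    mu_w, sg_w = cfg.weight_law
    mu_l, sg_l = cfg.length_law
    for _ in range(max_tries):
        keep = rng.random(len(orbits)) < p_orbit
        edges = []
        for k in np.flatnonzero(keep):
            i0, j0 = orbits[k][0]
            boost = _weight_boost(groups[i0], groups[j0])
            if mirror(i0) == j0:
                boost *= _HOMOTOPIC_WEIGHT
            w = max(1.0, float(np.round(boost * rng.lognormal(mu_w, sg_w))))
            length = float(rng.lognormal(mu_l, sg_l))
            for (i, j) in orbits[k]:
                edges.append(Edge(i=i, j=j, weight=w, length_mm=length,
                                  presence_count=cfg.n_subjects))
        n_edges = len(edges)
        if not (0.9 * target_edges <= n_edges <= 1.1 * target_edges):
            continue
        deg = np.zeros(n, dtype=int)
        for e in edges:
            deg[e.i] += 1
            deg[e.j] += 1
        if (deg == 0).any():
            continue
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((e.i, e.j) for e in edges)
        if not nx.is_connected(g):
            continue
        return Connectome(parcellation=parc, edges=edges)
    raise SynthError(f"could not generate a connected connectome in {max_tries} tries")


def generate_subject_matrices(cfg: GeneratorConfig,
                              c: Connectome) -> list[SubjectMatrix]:
    """Per-subject streamline matrices derived from a reference connectome.

    Each subject keeps each reference edge with probability
    ``subject_dropout`` and jitters its weight lognormally; subject-unique
    spurious low-weight edges are added at ``spurious_edge_rate`` per
    absent pair, exercising the consensus rule in both directions.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    n = c.n_regions
    ref = c.weight_matrix()
    iu, ju = np.triu_indices(n, k=1)
    absent = ref[iu, ju] == 0
    out = []
    for s_idx in range(cfg.n_subjects):
        m = np.zeros((n, n))
        for e in c.edges:
            if rng.random() < cfg.subject_dropout:
                if cfg.weight_jitter_sd > 0:
                    w = max(1.0, np.round(e.weight * rng.lognormal(
                        0.0, cfg.weight_jitter_sd)))
                else:
                    w = e.weight
                m[e.i, e.j] = m[e.j, e.i] = w
        if cfg.spurious_edge_rate > 0:
            hit = absent & (rng.random(iu.size) < cfg.spurious_edge_rate)
            for i, j in zip(iu[hit].tolist(), ju[hit].tolist()):
                w = float(rng.integers(1, 4))
                m[i, j] = m[j, i] = w
        out.append(SubjectMatrix(subject_id=f"sub-{s_idx + 1:02d}", matrix=m))
    return out


def generate_scalars(cfg: GeneratorConfig, c: Connectome,
                     ) -> dict[str, ScalarMap]:
    """Forward-model ADC-like and T1-like scalar maps on a connectome.

    Node scalar = baseline − slope * z(exact cumulative walk score at t*)
    + noise, where z() standardizes over regions. Baselines use a single
    cortical level plus a lower subcortical offset; the cortical
    PRIM < SEC < TER ordering is produced by the walk term itself (seeds sit
    in PRIM and sensorimotor connections are heavily weighted, so transits
    decay along the hierarchy). A fraction ``noise_spatial_corr`` of the
    noise variance is graph-smooth (two-hop neighbourhood averaging), as
    MRI scalars are spatially autocorrelated; it scales with ``noise_sd``
    and vanishes in the noise-free limit. Edge scalar =
    rho * mean(endpoint scalars) + (1 - rho) * (cortical baseline + noise).
    """
    parc = c.parcellation
    rng = np.random.default_rng(cfg.rng_seed + 2)
    seeds = parc.seeds
    exp = expected_scores_all_seeds(c, seeds, max(cfg.coupling_step, 1))
    score = exp.node_cumulative()[:, cfg.coupling_step - 1]
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)

    # smoothing operator: two passes of closed-neighbourhood averaging
    n = parc.n_regions
    a_hat = np.eye(n)
    for e in c.edges:
        a_hat[e.i, e.j] = a_hat[e.j, e.i] = 1.0
    a_hat /= a_hat.sum(axis=1, keepdims=True)

    def spatial_noise(size_rng: np.random.Generator) -> np.ndarray:
        phi = cfg.noise_spatial_corr
        eps = size_rng.standard_normal(n)
        eta = a_hat @ (a_hat @ size_rng.standard_normal(n))
        eta_sd = eta.std()
        if eta_sd > 0:
            eta = eta / eta_sd
        return np.sqrt(1 - phi) * eps + np.sqrt(phi) * eta

    is_sub = parc.groups == "SUB"
    maps = {}
    for mod, sub_base, cort_base, scale in (
        ("ADC", cfg.adc_sub_baseline, cfg.adc_cortical_baseline, 1.0),
        ("T1", cfg.t1_sub_baseline, cfg.t1_cortical_baseline, cfg.t1_scale),
    ):
        baseline = np.where(is_sub, sub_base, cort_base)
        node = (baseline - scale * cfg.effect_slope * z
                + scale * cfg.noise_sd * spatial_noise(rng))
        m = ScalarMap(modality=mod, provenance="synthetic")
        m.node_values = {int(r): float(node[r]) for r in range(parc.n_regions)}
        rho = cfg.gm_wm_coupling
        for e in c.edges:
            pair_mean = 0.5 * (node[e.i] + node[e.j])
            indep = cort_base + scale * cfg.noise_sd * rng.standard_normal()
            m.edge_values[(e.i, e.j)] = float(rho * pair_mean + (1 - rho) * indep)
        maps[mod] = m
    return maps


def generate_voxels(region_means: dict[int, float], sd: float, n_voxels: int,
                    outlier_rate: float, rng: np.random.Generator,
                    modality: str = "ADC",
                    outlier_offset_sds: float = 8.0) -> list[VoxelSamples]:
    """Gaussian voxel samples per region, contaminated at ``outlier_rate``
    by a large positive offset (partial-volume-like outliers)."""
    out = []
    for rid, mean in sorted(region_means.items()):
        vals = mean + sd * rng.standard_normal(n_voxels)
        if outlier_rate > 0:
            hit = rng.random(n_voxels) < outlier_rate
            vals = np.where(hit, vals + outlier_offset_sds * sd, vals)
        vals = np.clip(vals, 1e-6, None)
        out.append(VoxelSamples(region_id=rid, modality=modality, values=vals))
    return out


@dataclass
class StudyBundle:
    """One complete synthetic study, ready for the analysis pipeline."""

    config: GeneratorConfig
    parcellation: Parcellation
    true_connectome: Connectome
    subject_matrices: list[SubjectMatrix]
    consensus: Connectome
    scalar_maps: dict[str, ScalarMap]
    voxel_samples: list[VoxelSamples]


def generate_study(cfg: GeneratorConfig | None = None) -> StudyBundle:
    """Generate the full bundle: network, subjects, consensus, scalars, voxels.

    The consensus is rebuilt from the generated subject matrices with the
    50% presence rule (lengths carried over from the reference network), and
    scalar maps are generated on that consensus so edge values line up with
    the analysed edge set.
    """
    from .connectome import build_consensus

    cfg = cfg or GeneratorConfig()
    true_c = generate_connectome(cfg)
    subjects = generate_subject_matrices(cfg, true_c)
    lengths = {(e.i, e.j): e.length_mm for e in true_c.edges}
    consensus = build_consensus(subjects, true_c.parcellation,
                                presence_threshold=0.5, lengths=lengths)
    maps = generate_scalars(cfg, consensus)
    rng = np.random.default_rng(cfg.rng_seed + 3)
    voxels = generate_voxels(maps["ADC"].node_values, cfg.voxel_sd,
                             cfg.n_voxels, cfg.outlier_rate, rng,
                             modality="ADC")
    return StudyBundle(config=cfg, parcellation=true_c.parcellation,
                       true_connectome=true_c, subject_matrices=subjects,
                       consensus=consensus, scalar_maps=maps,
                       voxel_samples=voxels)
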