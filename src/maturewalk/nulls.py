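"""Randomization controls for the maturation model and the GM-WM coupling.

Two model nulls: (i) re-seeding the walk at 10 regions drawn uniformly from
all regions, keeping the network; (ii) degree-preserving rewiring of the
network (Maslov-Sneppen double-edge swaps, weights and lengths traveling
with the swapped edges), keeping the true sensory seeds. A third control
recomputes the region-vs-incident correlation on a rewired network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .connectome import Connectome, Edge
from .scalars import ScalarMap
from .stats import CorrelationResult, region_vs_incident
from .walk import WalkConfig, run_model, scores_vs_scalar


class NullModelError(ValueError):
    pass


@dataclass
class NullConfig:
    kind: str = "random_seeds"  # or "rewired_network"
    n_realizations: int = 50
    n_seed_sample: int = 10
    rng_seed: int = 0
    swaps_per_edge: int = 10

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise NullModelError("n_realizations must be >= 1")
        if self.kind not in ("random_seeds", "rewired_network"):
            raise NullModelError(f"unknown null kind {self.kind!r}")


def rewire_preserving_degree(c: Connectome, rng: np.random.Generator,
                             swaps_per_edge: int = 10,
                             max_attempt_factor: int = 100) -> Connectome:
    """Degree-preserving randomization by double-edge swaps.

    Picks two edges (a, b) and (c, d) and rewires to (a, d) and (c, b) when
    no self-loop or duplicate edge would result. Weight, length and
    presence count travel with the half-edge kept at a (resp. c), i.e. each
    original edge record keeps its attributes under a new endpoint. Degrees,
    edge count and the weight multiset are exactly preserved. The procedure
    attempts swaps until ``swaps_per_edge * n_edges`` are accepted or a
    capped number of attempts is exhausted (warning).
    """
    if c.n_edges < 2:
        raise NullModelError("need at least 2 edges to rewire")
    edges = [(e.i, e.j) for e in c.edges]
    attrs = [(e.weight, e.length_mm, e.presence_count) for e in c.edges]
    edge_set = {tuple(sorted(e)) for e in edges}
    target = swaps_per_edge * len(edges)
    max_attempts = max_attempt_factor * target
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, len(edges), size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        cc, d = edges[k2]
        if rng.random() < 0.5:
            cc, d = d, cc
        # propose (a, d) and (c, b)
        if a == d or cc == b:
            continue
        new1, new2 = tuple(sorted((a, d))), tuple(sorted((cc, b)))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(tuple(sorted((a, b))))
        edge_set.discard(tuple(sorted((cc, d))))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[k1] = (a, d)
        edges[k2] = (cc, b)
        accepted += 1
    if accepted < target:
        warnings.warn(
            f"rewiring accepted only {accepted}/{target} swaps after "
            f"{attempts} attempts (graph too small or rigid)")
    new_edges = [
        Edge(i=min(i, j), j=max(i, j), weight=w, length_mm=l, presence_count=pc)
        for (i, j), (w, l, pc) in zip(edges, attrs)
    ]
    return Connectome(parcellation=c.parcellation, edges=new_edges)


def shuffle_edge_scalars(s: ScalarMap, rng: np.random.Generator) -> ScalarMap:
    """Weight-shuffle alternative control: permute edge scalar values over a
    fixed topology."""
    keys = sorted(s.edge_values)
    vals = np.array([s.edge_values[k] for k in keys])
    perm = rng.permutation(vals)
    out = ScalarMap(modality=s.modality, provenance=s.provenance)
    out.node_values = dict(s.node_values)
    out.edge_values = {k: float(v) for k, v in zip(keys, perm)}
    return out


def random_seed_null(c: Connectome, cfg: NullConfig, walk_cfg: WalkConfig,
                     s: ScalarMap, method: str = "spearman",
                     ) -> list[dict[str, list[CorrelationResult]]]:
    """Per-realization score-vs-scalar curves under random re-seeding.

    Each realization draws ``n_seed_sample`` distinct regions uniformly from
    all regions (subcortical included) and reruns the model with them.
    """
    if cfg.n_seed_sample > c.n_regions:
        raise NullModelError("n_seed_sample exceeds number of regions")
    rng = np.random.default_rng(cfg.rng_seed)
    curves = []
    for k in range(cfg.n_realizations):
        seeds = rng.choice(c.n_regions, size=cfg.n_seed_sample, replace=False)
        wc = replace(walk_cfg, seeds=[int(x) for x in seeds],
                     rng_seed=int(rng.integers(2**31)))
        scores = run_model(c, wc)
        curves.append(scores_vs_scalar(scores, s, c, method=method))
    return curves


def rewired_model_null(c: Connectome, cfg: NullConfig, walk_cfg: WalkConfig,
                       s: ScalarMap, method: str = "spearman",
                       ) -> list[dict[str, list[CorrelationResult]]]:
    """Per-realization curves on degree-preserving rewired networks, walked
    from the true sensory seeds.

    Edge scalar values travel with the rewired edges (each original edge
    record keeps its measured value under its new endpoints), so the edge
    side of the correlation is evaluated on the full rewired edge set.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    true_seeds = walk_cfg.resolve_seeds(c.parcellation)
    curves = []
    for k in range(cfg.n_realizations):
        rc = rewire_preserving_degree(c, rng, swaps_per_edge=cfg.swaps_per_edge)
        smap = ScalarMap(modality=s.modality, provenance=s.provenance)
        smap.node_values = dict(s.node_values)
        smap.edge_values = {(e2.i, e2.j): s.edge_values[(e1.i, e1.j)]
                            for e1, e2 in zip(c.edges, rc.edges)}
        wc = replace(walk_cfg, seeds=true_seeds,
                     rng_seed=int(rng.integers(2**31)))
        scores = run_model(rc, wc)
        curves.append(scores_vs_scalar(scores, smap, rc, method=method))
    return curves


def randomized_incident_control(c: Connectome, s: ScalarMap,
                                rng: np.random.Generator,
                                n_realizations: int = 1,
                                swaps_per_edge: int = 10,
                                mode: str = "rewire",
                                ) -> CorrelationResult:
    """Region-vs-incident correlation after connectivity randomization.

    ``mode="rewire"`` rewires the topology degree-preservingly with edge
    scalars traveling along; ``mode="shuffle"`` keeps the topology and
    permutes edge scalar values. With several realizations, r and p are
    averaged.
    """
    rs, ps, n = [], [], None
    for _ in range(n_realizations):
        if mode == "rewire":
            rc = rewire_preserving_degree(c, rng, swaps_per_edge=swaps_per_edge)
            # edge scalars travel with the rewired edges (same edge order)
            smap = ScalarMap(modality=s.modality, provenance=s.provenance)
            smap.node_values = dict(s.node_values)
            smap.edge_values = {
                (e2.i, e2.j): s.edge_values[(e1.i, e1.j)]
                for e1, e2 in zip(c.edges, rc.edges)
            }
            res = region_vs_incident(rc, smap)
        elif mode == "shuffle":
            res = region_vs_incident(c, shuffle_edge_scalars(s, rng))
        else:
            raise NullModelError(f"unknown mode {mode!r}")
        rs.append(res.r)
        ps.append(res.p)
        n = res.n
    return CorrelationResult(method="pearson", r=float(np.mean(rs)),
                             p=float(np.mean(ps)), n=int(n),
                             stratum=f"randomized:{mode}")


def null_summary(curves: list[dict[str, list[CorrelationResult]]],
                 entity: str = "node") -> np.ndarray:
    """Stack per-realization r values into a (n_realizations, n_steps) array."""
    return np.array([[cr.r for cr in curve[entity]] for curve in curves])
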