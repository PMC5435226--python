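"""Seeded non-backtracking random-walk model of network-mediated maturation.

Maturation is modelled as particles released in the ten primary sensory
cortices and diffusing along the weighted structural network. From vertex i
(having arrived from vertex ``prev``) a particle steps to neighbour j with
probability ``w_ij / sum_k w_ik`` over the neighbours k of i excluding
``prev`` (no-back walk). The number of particle transits through each
region or connection at each random-walk step (RWS) is the local maturation
score; per-seed patterns are summed over seeds into whole-brain scores.

Because the no-back constraint makes the walk non-Markovian on vertices,
both the sampler and the exact oracle operate on directed-edge states
(i -> j): the walk is Markovian there, and expected per-step transit
probabilities follow from propagating a mass vector through the
2*|edges|-state transition system (the Hashimoto construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import Connectome, Parcellation
from .stats import CorrelationResult, correlate


class WalkError(ValueError):
    pass


@dataclass
class WalkConfig:
    """Protocol constants of the maturation model.

    Defaults follow the study protocol: walks start in each of the ten
    primary sensory regions, propagate for ten RWSs, and are repeated 1000
    times per seeding area.
    """

    seeds: list[int] | None = None  # None -> parcellation's seed regions
    n_steps: int = 10
    n_reps: int = 1000
    rng_seed: int = 0
    dead_end_policy: str = "terminate"  # or "allow_backtrack"
    count_seed_occupancy: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_reps < 1:
            raise WalkError("n_steps and n_reps must be >= 1")
        if self.dead_end_policy not in ("terminate", "allow_backtrack"):
            raise WalkError(f"unknown dead_end_policy {self.dead_end_policy!r}")

    def resolve_seeds(self, parc: Parcellation) -> list[int]:
        seeds = self.seeds if self.seeds is not None else parc.seeds
        if not seeds:
            raise WalkError("no seed regions configured")
        return list(seeds)


@dataclass(frozen=True)
class WalkState:
    current: int
    previous: int | None = None
    step: int = 0


@dataclass
class MaturationScores:
    """Per-step and cumulative transit counts, summed over seeds and reps.

    ``node_per_step[v, t-1]`` is the number of particle arrivals at region v
    at RWS t (t = 1..n_steps); likewise for edges. Seed occupancy at t = 0
    is recorded separately and only added to the cumulative scores when the
    config asks for it. ``alive[t-1]`` counts particles still walking at
    RWS t, so per-step node (and edge) counts each sum to alive(t).
    """

    node_per_step: np.ndarray  # (n_regions, n_steps)
    edge_per_step: np.ndarray  # (n_edges, n_steps)
    alive: np.ndarray  # (n_steps,)
    seed_occupancy: np.ndarray  # (n_regions,)
    config: WalkConfig

    @property
    def n_steps(self) -> int:
        return self.node_per_step.shape[1]

    def node_cumulative(self) -> np.ndarray:
        cum = np.cumsum(self.node_per_step, axis=1)
        if self.config.count_seed_occupancy:
            cum = cum + self.seed_occupancy[:, None]
        return cum

    def edge_cumulative(self) -> np.ndarray:
        return np.cumsum(self.edge_per_step, axis=1)


# ---------------------------------------------------------------------------
# Directed-edge (non-backtracking) transition system
# ---------------------------------------------------------------------------

@dataclass
class _Transition:
    """Precomputed non-backtracking transition tables over directed edges.

    Directed state 2k is i->j and 2k+1 is j->i for undirected edge k=(i,j);
    ``heads[s]`` is the vertex a particle in state s has just arrived at.
    """

    n_regions: int
    n_edges: int
    heads: np.ndarray
    tails: np.ndarray
    outdeg: np.ndarray
    succ: np.ndarray  # (S, maxd) successor states, -1 padded
    cum: np.ndarray  # (S, maxd) cumulative probs, +inf padded
    flat_src: np.ndarray
    flat_dst: np.ndarray
    flat_p: np.ndarray
    adj: list[list[tuple[int, float]]]
    state_of: dict[tuple[int, int], int]


def _build_transition(c: Connectome, dead_end_policy: str = "terminate") -> _Transition:
    n_edges = c.n_edges
    S = 2 * n_edges
    heads = np.empty(S, dtype=np.int64)
    tails = np.empty(S, dtype=np.int64)
    state_of: dict[tuple[int, int], int] = {}
    for k, e in enumerate(c.edges):
        heads[2 * k], tails[2 * k] = e.j, e.i
        heads[2 * k + 1], tails[2 * k + 1] = e.i, e.j
        state_of[(e.i, e.j)] = 2 * k
        state_of[(e.j, e.i)] = 2 * k + 1
    adj = c.neighbors()

    succ_lists: list[list[int]] = []
    prob_lists: list[list[float]] = []
    for s in range(S):
        j, i = int(heads[s]), int(tails[s])
        nbrs = [(k, w) for k, w in adj[j] if k != i]
        if not nbrs and dead_end_policy == "allow_backtrack":
            nbrs = [(i, 1.0)]
        if nbrs:
            total = sum(w for _, w in nbrs)
            succ_lists.append([state_of[(j, k)] for k, _ in nbrs])
            prob_lists.append([w / total for _, w in nbrs])
        else:
            succ_lists.append([])
            prob_lists.append([])

    outdeg = np.array([len(sl) for sl in succ_lists], dtype=np.int64)
    maxd = max(1, int(outdeg.max()) if S else 1)
    succ = np.full((S, maxd), -1, dtype=np.int64)
    cum = np.full((S, maxd), np.inf)
    flat_src, flat_dst, flat_p = [], [], []
    for s in range(S):
        if succ_lists[s]:
            succ[s, : len(succ_lists[s])] = succ_lists[s]
            cum[s, : len(succ_lists[s])] = np.cumsum(prob_lists[s])
            flat_src.extend([s] * len(succ_lists[s]))
            flat_dst.extend(succ_lists[s])
            flat_p.extend(prob_lists[s])
    return _Transition(
        n_regions=c.n_regions, n_edges=n_edges, heads=heads, tails=tails,
        outdeg=outdeg, succ=succ, cum=cum,
        flat_src=np.array(flat_src, dtype=np.int64),
        flat_dst=np.array(flat_dst, dtype=np.int64),
        flat_p=np.array(flat_p), adj=adj, state_of=state_of,
    )


def _initial(tr: _Transition, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Initial directed states (seed -> j) and their probabilities."""
    nbrs = tr.adj[seed]
    if not nbrs:
        raise WalkError(f"seed region {seed} is isolated")
    total = sum(w for _, w in nbrs)
    states = np.array([tr.state_of[(seed, k)] for k, _ in nbrs], dtype=np.int64)
    probs = np.array([w / total for _, w in nbrs])
    return states, probs


# ---------------------------------------------------------------------------
# Single-walk primitives
# ---------------------------------------------------------------------------

def step_distribution(c: Connectome, state: WalkState) -> dict[int, float]:
    """Transition probabilities from the current vertex, excluding the
    previous one; empty when the previous vertex is the only neighbour
    (dead end under the terminate policy)."""
    adj = c.neighbors()
    nbrs = adj[state.current]
    if not nbrs:
        raise WalkError(f"region {state.current} is isolated")
    nbrs = [(k, w) for k, w in nbrs if k != state.previous]
    if not nbrs:
        return {}
    total = sum(w for _, w in nbrs)
    return {k: w / total for k, w in nbrs}


def sample_walk(c: Connectome, seed_region: int, n_steps: int,
                rng: np.random.Generator,
                dead_end_policy: str = "terminate") -> list[int]:
    """Sample one no-back walk; the path may stop early at a dead end."""
    adj = c.neighbors()
    if not adj[seed_region]:
        raise WalkError(f"seed region {seed_region} is isolated")
    path = [seed_region]
    prev: int | None = None
    for _ in range(n_steps):
        nbrs = [(k, w) for k, w in adj[path[-1]] if k != prev]
        if not nbrs:
            if dead_end_policy == "allow_backtrack" and prev is not None:
                nbrs = [(prev, 1.0)]
            else:
                break
        ks = [k for k, _ in nbrs]
        ws = np.array([w for _, w in nbrs])
        nxt = int(rng.choice(ks, p=ws / ws.sum()))
        prev = path[-1]
        path.append(nxt)
    return path


# ---------------------------------------------------------------------------
# Monte Carlo model
# ---------------------------------------------------------------------------

def run_model(c: Connectome, cfg: WalkConfig) -> MaturationScores:
    """Run the full maturation model: per-seed repetitions, summed over seeds.

    All repetitions of one seed advance in lock-step through vectorized
    directed-state transitions, so the cost is O(n_steps * n_reps) numpy
    operations rather than per-particle Python loops. Output is bit-identical
    for a fixed ``rng_seed``. Transition probabilities are normalized per
    vertex, so globally rescaling all weights changes nothing.
    """
    seeds = cfg.resolve_seeds(c.parcellation)
    for s in seeds:
        if not (0 <= s < c.n_regions):
            raise WalkError(f"seed {s} absent from connectome")
    tr = _build_transition(c, cfg.dead_end_policy)
    rng = np.random.default_rng(cfg.rng_seed)

    node_per_step = np.zeros((c.n_regions, cfg.n_steps))
    edge_per_step = np.zeros((c.n_edges, cfg.n_steps))
    alive = np.zeros(cfg.n_steps)
    seed_occ = np.zeros(c.n_regions)

    for seed in seeds:
        seed_occ[seed] += cfg.n_reps
        init_states, init_probs = _initial(tr, seed)
        states = rng.choice(init_states, size=cfg.n_reps, p=init_probs)
        for t in range(1, cfg.n_steps + 1):
            node_per_step[:, t - 1] += np.bincount(
                tr.heads[states], minlength=c.n_regions)
            edge_per_step[:, t - 1] += np.bincount(
                states // 2, minlength=c.n_edges)
            alive[t - 1] += states.size
            if t == cfg.n_steps:
                break
            states = states[tr.outdeg[states] > 0]
            if states.size == 0:
                break
            r = rng.random(states.size)
            idx = (tr.cum[states] <= r[:, None]).sum(axis=1)
            states = tr.succ[states, idx]

    return MaturationScores(node_per_step=node_per_step,
                            edge_per_step=edge_per_step, alive=alive,
                            seed_occupancy=seed_occ, config=cfg)


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

@dataclass
class ExpectedScores:
    """Exact per-step transit probabilities for one seed (mass <= 1)."""

    node_mass: np.ndarray  # (n_regions, n_steps)
    edge_mass: np.ndarray  # (n_edges, n_steps)
    alive: np.ndarray  # (n_steps,)

    def node_cumulative(self) -> np.ndarray:
        return np.cumsum(self.node_mass, axis=1)

    def edge_cumulative(self) -> np.ndarray:
        return np.cumsum(self.edge_mass, axis=1)


def expected_scores_exact(c: Connectome, seed_region: int, n_steps: int,
                          dead_end_policy: str = "terminate",
                          state_cap: int = 200_000) -> ExpectedScores:
    """Exact expected per-step transit probabilities for a single seed.

    Propagates a probability mass vector through the directed-edge
    transition system. Mass on a dead-end state is recorded as an arrival
    and then removed (the particle terminates), so ``alive(t)`` is
    non-increasing and node masses at step t sum to alive(t).
    """
    if 2 * c.n_edges > state_cap:
        raise WalkError(
            f"directed-state space of size {2 * c.n_edges} exceeds "
            f"state_cap={state_cap}")
    tr = _build_transition(c, dead_end_policy)
    init_states, init_probs = _initial(tr, seed_region)
    mass = np.zeros(2 * c.n_edges)
    mass[init_states] = init_probs

    node_mass = np.zeros((c.n_regions, n_steps))
    edge_mass = np.zeros((c.n_edges, n_steps))
    alive = np.zeros(n_steps)
    for t in range(1, n_steps + 1):
        np.add.at(node_mass[:, t - 1], tr.heads, mass)
        edge_mass[:, t - 1] = mass[0::2] + mass[1::2]
        alive[t - 1] = mass.sum()
        if t == n_steps:
            break
        mass = np.bincount(tr.flat_dst, weights=mass[tr.flat_src] * tr.flat_p,
                           minlength=2 * c.n_edges)
    return ExpectedScores(node_mass=node_mass, edge_mass=edge_mass, alive=alive)


def expected_scores_all_seeds(c: Connectome, seeds: Sequence[int],
                              n_steps: int, **kw) -> ExpectedScores:
    """Sum of per-seed exact expected transits (mass <= len(seeds))."""
    parts = [expected_scores_exact(c, s, n_steps, **kw) for s in seeds]
    return ExpectedScores(
        node_mass=np.sum([p.node_mass for p in parts], axis=0),
        edge_mass=np.sum([p.edge_mass for p in parts], axis=0),
        alive=np.sum([p.alive for p in parts], axis=0),
    )


# ---------------------------------------------------------------------------
# Score-vs-scalar correlations
# ---------------------------------------------------------------------------

def scores_vs_scalar(scores: MaturationScores, s, c: Connectome,
                     method: str = "spearman",
                     ) -> dict[str, list[CorrelationResult]]:
    """Per-RWS correlation of cumulative maturation scores with a scalar map.

    Subcortical regions (``exclude_from_model_correlation``) are left out on
    the node side; on the edge side only connections between two included
    regions enter. Scalars that decrease with maturation are expected to
    correlate negatively.
    """
    parc = c.parcellation
    included = set(parc.included_regions())
    node_regions = sorted(r for r in included if r in s.node_values)
    if len(node_regions) < 3:
        raise WalkError("fewer than 3 included regions with scalar values")
    node_cum = scores.node_cumulative()
    edge_cum = scores.edge_cumulative()
    edge_ids, edge_scalars = [], []
    for k, e in enumerate(c.edges):
        if e.i in included and e.j in included and (e.i, e.j) in s.edge_values:
            edge_ids.append(k)
            edge_scalars.append(s.edge_values[(e.i, e.j)])
    out: dict[str, list[CorrelationResult]] = {"node": [], "edge": []}
    scalar_nodes = np.array([s.node_values[r] for r in node_regions])
    scalar_edges = np.array(edge_scalars)
    for t in range(scores.n_steps):
        out["node"].append(correlate(node_cum[np.array(node_regions), t],
                                     scalar_nodes, method=method,
                                     stratum=f"RWS{t + 1}"))
        if len(edge_ids) >= 3:
            out["edge"].append(correlate(edge_cum[np.array(edge_ids), t],
                                         scalar_edges, method=method,
                                         stratum=f"RWS{t + 1}"))
    return out
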