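"""Ordered-trend and correlation battery for maturation scalars.

Centrepiece is a permutation Jonckheere–Terpstra (JT) test for an ordered
difference across the four maturation groups (SUB < PRIM < SEC < TER),
reported as the standardized statistic z alongside the raw U and a
permutation p. The correlation analyses cover: region scalar vs. mean over
incident connections; GM pair means vs. the connecting tract, with a
long/short split at the mean connection length; and connected vs.
unconnected region pairs (order-invariant, permutation p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import GROUP_ORDER, GROUP_RANK, Connectome
from .scalars import ScalarMap, incident_means


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class JTResult:
    U: float
    z: float
    p_perm: float
    n_perm: int
    group_sizes: tuple[int, ...]
    exact: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int
    stratum: str | None = None


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra
# ---------------------------------------------------------------------------

def _jt_u_rows(values: np.ndarray, group_slices: list[tuple[int, int]]) -> np.ndarray:
    """JT statistic (0.5 tie credit) for each row of a (P, N) value matrix.

    Columns are assumed ordered by group; ``group_slices`` gives the column
    span of each ordered group.
    """
    v = np.atleast_2d(values)
    u = np.zeros(v.shape[0])
    for a in range(len(group_slices)):
        ga0, ga1 = group_slices[a]
        x = v[:, ga0:ga1]
        for b in range(a + 1, len(group_slices)):
            gb0, gb1 = group_slices[b]
            y = v[:, gb0:gb1]
            lt = x[:, :, None] < y[:, None, :]
            eq = x[:, :, None] == y[:, None, :]
            u += lt.sum(axis=(1, 2)) + 0.5 * eq.sum(axis=(1, 2))
    return u


def _jt_null_moments(sizes: np.ndarray) -> tuple[float, float]:
    """No-tie null mean and variance of the JT statistic."""
    n = sizes.sum()
    mu = (n**2 - (sizes**2).sum()) / 4.0
    var = (n**2 * (2 * n + 3) - (sizes**2 * (2 * sizes + 3)).sum()) / 72.0
    return float(mu), float(var)


def _group_assignments(n: int, sizes: Sequence[int]):
    """Yield all distinct assignments of n items into ordered groups of the
    given sizes, as index tuples per group."""
    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail
    yield from rec(tuple(range(n)), list(sizes))


def n_distinct_assignments(sizes: Sequence[int]) -> int:
    from math import comb
    n = sum(sizes)
    total = 1
    rem = n
    for k in sizes:
        total *= comb(rem, k)
        rem -= k
    return total


def jt_test(
    values: Sequence[float] | Mapping[int, float],
    groups: Sequence[str | int] | Mapping[int, str],
    n_perm: int = 9999,
    rng_seed: int | np.random.Generator | None = 0,
    exact: bool = False,
    exact_cap: int = 200_000,
) -> JTResult:
    """Jonckheere–Terpstra permutation test for an ordered group trend.

    ``U`` counts, over ordered group pairs g < h, the observation pairs
    (x in g, y in h) with x < y, crediting ties 0.5. ``z`` standardizes U by
    the no-tie null moments. ``p_perm`` permutes group labels; the add-one
    estimator ``(1 + #{U_perm >= U_obs}) / (n_perm + 1)`` keeps p > 0. With
    ``exact=True`` every distinct group assignment is enumerated instead
    (feasible only for small samples) and p is the exact tail fraction.
    """
    if isinstance(values, Mapping):
        keys = sorted(values)
        vals = np.array([values[k] for k in keys], dtype=float)
        grp = [groups[k] for k in keys]
    else:
        vals = np.asarray(values, dtype=float)
        grp = list(groups)
    ranks = np.array([GROUP_RANK[g] if isinstance(g, str) else int(g) for g in grp])
    levels = np.unique(ranks)
    if len(levels) < 2:
        raise StatsError("need at least 2 groups")
    order = np.argsort(ranks, kind="stable")
    vals_sorted = vals[order]
    sizes = np.array([(ranks == lv).sum() for lv in levels])
    if (sizes == 0).any():
        raise StatsError("every group must have at least one observation")
    slices, start = [], 0
    for s in sizes:
        slices.append((start, start + int(s)))
        start += int(s)

    u_obs = float(_jt_u_rows(vals_sorted[None, :], slices)[0])
    mu, var = _jt_null_moments(sizes)
    z = (u_obs - mu) / np.sqrt(var) if var > 0 else 0.0

    if exact:
        total = n_distinct_assignments(sizes.tolist())
        if total > exact_cap:
            raise StatsError(
                f"{total} distinct assignments exceed exact_cap={exact_cap}"
            )
        count = 0
        n = len(vals_sorted)
        for assignment in _group_assignments(n, sizes.tolist()):
            perm = np.empty(n, dtype=float)
            pos = 0
            for g_idx, members in enumerate(assignment):
                k = len(members)
                perm[pos:pos + k] = vals_sorted[list(members)]
                pos += k
            if _jt_u_rows(perm[None, :], slices)[0] >= u_obs - 1e-12:
                count += 1
        return JTResult(U=u_obs, z=float(z), p_perm=count / total,
                        n_perm=total, group_sizes=tuple(int(s) for s in sizes),
                        exact=True)

    if n_perm < 999:
        raise StatsError("n_perm must be at least 999")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    # permute values over group labels in blocks to bound memory
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7 // max(1, len(vals_sorted) ** 2))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(vals_sorted, (m, 1)), axis=1)
        u_perm = _jt_u_rows(perms, slices)
        exceed += int((u_perm >= u_obs - 1e-12).sum())
        done += m
    p = (1 + exceed) / (n_perm + 1)
    return JTResult(U=u_obs, z=float(z), p_perm=float(p), n_perm=n_perm,
                    group_sizes=tuple(int(s) for s in sizes))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson",
              stratum: str | None = None) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise StatsError("x and y must have equal length")
    if xa.size < 3:
        raise StatsError("need at least 3 observations")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise StatsError("non-finite values")
    if np.ptp(xa) == 0:
        raise StatsError("zero variance in x")
    if np.ptp(ya) == 0:
        raise StatsError("zero variance in y")
    if method == "pearson":
        res = sps.pearsonr(xa, ya)
    elif method == "spearman":
        res = sps.spearmanr(xa, ya)
    else:
        raise StatsError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(res.statistic),
                             p=float(res.pvalue), n=int(xa.size), stratum=stratum)


def region_vs_incident(c: Connectome, s: ScalarMap,
                       method: str = "pearson") -> CorrelationResult:
    """Region scalar vs. mean scalar of the incident connections.

    All four groups enter; isolated regions are skipped.
    """
    inc = incident_means(c, s)
    regions = sorted(r for r in inc if r in s.node_values)
    x = [s.node_values[r] for r in regions]
    y = [inc[r] for r in regions]
    return correlate(x, y, method=method, stratum="all")


def pairmean_vs_tract(c: Connectome, s: ScalarMap, stratum: str = "all",
                      method: str = "pearson") -> CorrelationResult:
    """Mean of the two endpoint region scalars vs. the connecting tract scalar.

    ``stratum`` splits edges at the mean connection length over the whole
    connectome: "long" keeps lengths strictly above the mean, "short" keeps
    the rest (ties at the mean go to "short").
    """
    if stratum not in ("all", "long", "short"):
        raise StatsError(f"unknown stratum {stratum!r}")
    lengths = np.array([e.length_mm for e in c.edges])
    if lengths.size == 0:
        raise StatsError("empty connectome")
    mean_len = lengths.mean()
    x, y = [], []
    for e in c.edges:
        if stratum == "long" and not e.length_mm > mean_len:
            continue
        if stratum == "short" and e.length_mm > mean_len:
            continue
        x.append(0.5 * (s.node_values[e.i] + s.node_values[e.j]))
        y.append(s.edge_values[(e.i, e.j)])
    return correlate(x, y, method=method, stratum=stratum)


def connected_vs_unconnected(
    c: Connectome, s: ScalarMap, n_perm: int = 999,
    rng_seed: int | np.random.Generator | None = 0,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Scalar correlation across region pairs, split by structural connection.

    Each unordered pair contributes both orderings (i, j) and (j, i), making
    the estimate invariant to within-pair labelling. Because the duplication
    inflates the analytic sample size, p comes from a permutation of the
    node scalar values over regions (add-one estimator).
    """
    n = c.n_regions
    connected = {(e.i, e.j) for e in c.edges}
    iu, ju = np.triu_indices(n, k=1)
    mask_conn = np.array([(i, j) in connected for i, j in zip(iu.tolist(), ju.tolist())])
    vals = np.array([s.node_values[r] for r in range(n)])

    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def _r(values: np.ndarray, sel: np.ndarray) -> float:
        a = np.concatenate([values[iu[sel]], values[ju[sel]]])
        b = np.concatenate([values[ju[sel]], values[iu[sel]]])
        return float(np.corrcoef(a, b)[0, 1])

    out = []
    for sel, label in ((mask_conn, "connected"), (~mask_conn, "unconnected")):
        if sel.sum() < 3:
            raise StatsError(f"fewer than 3 {label} pairs")
        r_obs = _r(vals, sel)
        exceed = 0
        for _ in range(n_perm):
            if abs(_r(rng.permutation(vals), sel)) >= abs(r_obs) - 1e-15:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        out.append(CorrelationResult(method="pearson", r=r_obs, p=p,
                                     n=int(sel.sum()), stratum=label))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Descriptive network tables
# ---------------------------------------------------------------------------

def group_edge_counts(c: Connectome) -> pd.DataFrame:
    """4x4 table of edge counts by unordered group pair.

    Each edge is counted once, in the (lower-rank, higher-rank) cell; the
    lower triangle is zero, so the entries sum to the edge count.
    """
    table = pd.DataFrame(0, index=list(GROUP_ORDER), columns=list(GROUP_ORDER))
    ranks = c.parcellation.group_ranks
    for e in c.edges:
        a, b = sorted((int(ranks[e.i]), int(ranks[e.j])))
        table.iloc[a, b] += 1
    return table


def length_summary(c: Connectome) -> dict:
    """Connection-length distribution summary with the long/short split."""
    lengths = np.array([e.length_mm for e in c.edges])
    if lengths.size == 0:
        raise StatsError("empty connectome")
    mean_len = float(lengths.mean())
    n_long = int((lengths > mean_len).sum())
    return {
        "n_edges": int(lengths.size),
        "mean_length_mm": mean_len,
        "median_length_mm": float(np.median(lengths)),
        "n_long": n_long,
        "n_short": int(lengths.size - n_long),
    }
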