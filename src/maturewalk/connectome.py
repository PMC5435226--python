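"""Parcellations, subject streamline matrices and group-consensus connectomes.

The data model mirrors a standard tractography-derived study design: each
subject contributes a square symmetric matrix of streamline counts over a
fixed parcellation, and the group-level network keeps only connections
present in at least a stated fraction of subjects, averaging their weights.

Region groups follow the function-related maturation ordering
``SUB < PRIM < SEC < TER`` (subcortical nuclei, primary sensory/motor
cortex, secondary association areas, tertiary higher-order areas).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

GROUP_ORDER = ("SUB", "PRIM", "SEC", "TER")
GROUP_RANK = {g: k for k, g in enumerate(GROUP_ORDER)}


class ConnectomeError(ValueError):
    """Raised on invariant violations in parcellation/connectome inputs."""


@dataclass(frozen=True)
class RegionRecord:
    region_id: int
    label: str
    hemisphere: str  # "L" or "R"
    group: str  # one of GROUP_ORDER
    is_seed: bool = False
    exclude_from_model_correlation: bool = False


@dataclass
class Parcellation:
    """Ordered region table with hemisphere and maturation-group metadata.

    Invariants enforced at construction:

    * region_ids unique and contiguous from 0;
    * every group label is one of ``SUB/PRIM/SEC/TER``;
    * subcortical (SUB) regions are always excluded from model-scalar
      correlations (thalami included);
    * walk seeds are a subset of the PRIM group.
    """

    regions: list[RegionRecord]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if ids != list(range(len(ids))):
            raise ConnectomeError(
                f"region_ids must be unique and contiguous from 0, got {ids[:10]}..."
            )
        for r in self.regions:
            if r.group not in GROUP_RANK:
                raise ConnectomeError(f"unknown group {r.group!r} in region {r.region_id}")
            if r.hemisphere not in ("L", "R"):
                raise ConnectomeError(
                    f"hemisphere must be L or R, got {r.hemisphere!r} in region {r.region_id}"
                )
            if r.is_seed and r.group != "PRIM":
                raise ConnectomeError(
                    f"seed region {r.region_id} ({r.label}) has group {r.group}; "
                    "seeds must belong to PRIM"
                )
            if r.group == "SUB" and not r.exclude_from_model_correlation:
                raise ConnectomeError(
                    f"SUB region {r.region_id} must have exclude_from_model_correlation=True"
                )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def seeds(self) -> list[int]:
        return [r.region_id for r in self.regions if r.is_seed]

    @property
    def groups(self) -> np.ndarray:
        """Group label per region, aligned with region_id."""
        return np.array([r.group for r in self.regions])

    @property
    def group_ranks(self) -> np.ndarray:
        return np.array([GROUP_RANK[r.group] for r in self.regions])

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUP_ORDER}
        for r in self.regions:
            sizes[r.group] += 1
        return sizes

    def included_regions(self) -> list[int]:
        """Regions entering model-scalar correlations (non-SUB by default)."""
        return [r.region_id for r in self.regions if not r.exclude_from_model_correlation]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "label": [r.label for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "group": [r.group for r in self.regions],
                "is_seed": [int(r.is_seed) for r in self.regions],
            }
        )


@dataclass(frozen=True)
class Edge:
    """Undirected consensus edge (i < j) with averaged streamline weight."""

    i: int
    j: int
    weight: float
    length_mm: float
    presence_count: int

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ConnectomeError(f"edge must have i < j, got ({self.i}, {self.j})")
        if not self.weight > 0:
            raise ConnectomeError(f"edge ({self.i},{self.j}) weight must be > 0")


@dataclass
class SubjectMatrix:
    """One subject's square symmetric streamline-count matrix.

    The diagonal (intra-region connections) is ignored everywhere.
    """

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConnectomeError(f"subject {self.subject_id}: matrix must be square")
        if not np.array_equal(m, m.T):
            raise ConnectomeError(f"subject {self.subject_id}: matrix is not symmetric")
        if (m < 0).any():
            raise ConnectomeError(f"subject {self.subject_id}: negative streamline counts")
        self.matrix = m


@dataclass
class Connectome:
    """Weighted undirected group network over a parcellation."""

    parcellation: Parcellation
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.parcellation.n_regions
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            if e.j >= n:
                raise ConnectomeError(
                    f"edge ({e.i},{e.j}) references region {e.j} outside the "
                    f"{n}-region parcellation"
                )
            key = (e.i, e.j)
            if key in seen:
                raise ConnectomeError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        n = self.n_regions
        return self.n_edges / (n * (n - 1) / 2)

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(e.i, e.j): k for k, e in enumerate(self.edges)}

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_regions, dtype=int)
        for e in self.edges:
            deg[e.i] += 1
            deg[e.j] += 1
        return deg

    def neighbors(self) -> list[list[tuple[int, float]]]:
        """Adjacency list: per region, (neighbor, weight) pairs."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_regions)]
        for e in self.edges:
            adj[e.i].append((e.j, e.weight))
            adj[e.j].append((e.i, e.weight))
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        for e in self.edges:
            g.add_edge(e.i, e.j, weight=e.weight, length_mm=e.length_mm,
                       presence_count=e.presence_count)
        return g

    def is_connected(self) -> bool:
        if self.n_regions == 0:
            return True
        return nx.is_connected(self.to_networkx())

    def isolated_regions(self) -> list[int]:
        return [int(r) for r in np.flatnonzero(self.degrees() == 0)]

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((self.n_regions, self.n_regions))
        for e in self.edges:
            w[e.i, e.j] = w[e.j, e.i] = e.weight
        return w


# ---------------------------------------------------------------------------
# I/O: tab-separated region tables and edge lists
# ---------------------------------------------------------------------------

def read_parcellation(path: str | Path) -> Parcellation:
    """Read a region table (TSV: region_id, label, hemisphere, group, is_seed)."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "label", "hemisphere", "group", "is_seed"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeError(f"region table missing columns: {sorted(missing)}")
    ids = df["region_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = df[df["region_id"].duplicated()].iloc[0]
        raise ConnectomeError(f"duplicate region_id in row: {dup.to_dict()}")
    df = df.sort_values("region_id")
    regions = []
    for _, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUP_RANK:
            raise ConnectomeError(f"unknown group label in row: {row.to_dict()}")
        is_seed = bool(int(row["is_seed"]))
        if is_seed and group != "PRIM":
            raise ConnectomeError(f"seed outside PRIM in row: {row.to_dict()}")
        regions.append(
            RegionRecord(
                region_id=int(row["region_id"]),
                label=str(row["label"]),
                hemisphere=str(row["hemisphere"]),
                group=group,
                is_seed=is_seed,
                exclude_from_model_correlation=(group == "SUB"),
            )
        )
    return Parcellation(regions)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def write_connectome(c: Connectome, edge_path: str | Path,
                     region_path: str | Path | None = None) -> None:
    """Write the edge list (TSV: i, j, weight, length_mm, presence_count)."""
    pd.DataFrame(
        {
            "i": [e.i for e in c.edges],
            "j": [e.j for e in c.edges],
            "weight": [e.weight for e in c.edges],
            "length_mm": [e.length_mm for e in c.edges],
            "presence_count": [e.presence_count for e in c.edges],
        }
    ).to_csv(edge_path, sep="\t", index=False)
    if region_path is not None:
        write_parcellation(c.parcellation, region_path)


def read_connectome(edge_path: str | Path, parc: Parcellation) -> Connectome:
    df = pd.read_csv(edge_path, sep="\t")
    required = {"i", "j", "weight", "length_mm", "presence_count"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeError(f"edge list missing columns: {sorted(missing)}")
    n = parc.n_regions
    edges = []
    for _, row in df.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if not (0 <= i < n and 0 <= j < n):
            raise ConnectomeError(
                f"edge ({i},{j}) references unknown region (parcellation has {n})"
            )
        edges.append(Edge(i=min(i, j), j=max(i, j), weight=float(row["weight"]),
                          length_mm=float(row["length_mm"]),
                          presence_count=int(row["presence_count"])))
    return Connectome(parcellation=parc, edges=edges)


def read_subject_matrix(path: str | Path, subject_id: str | None = None) -> SubjectMatrix:
    """Read a square CSV with a region_id header row/column."""
    df = pd.read_csv(path, index_col=0)
    return SubjectMatrix(subject_id=subject_id or Path(path).stem,
                         matrix=df.to_numpy(dtype=float))


def write_subject_matrix(sm: SubjectMatrix, path: str | Path) -> None:
    n = sm.matrix.shape[0]
    pd.DataFrame(sm.matrix, index=range(n), columns=range(n)).to_csv(path)


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def build_consensus(
    matrices: Sequence[SubjectMatrix],
    parcellation: Parcellation,
    presence_threshold: float = 0.5,
    lengths: Mapping[tuple[int, int], float] | np.ndarray | None = None,
    average_over_all: bool = False,
) -> Connectome:
    """Build the group-consensus connectome from subject streamline matrices.

    An edge (i, j) is retained iff its streamline count is nonzero in at
    least ``ceil(presence_threshold * n_subjects)`` subjects ("present for
    at least 50% of the subjects" at the default threshold). The retained
    weight is the mean streamline count over the subjects where the edge is
    present; with ``average_over_all=True`` zeros from absent subjects enter
    the average instead.

    ``lengths`` supplies the mean streamline length (mm) per edge, either as
    a mapping on unordered pairs or as a square array; subject-wise length
    matrices are averaged upstream with the same presence rule. Missing
    lengths default to 1.0 (a neutral placeholder).
    """
    if len(matrices) == 0:
        raise ConnectomeError("need at least one subject matrix")
    n = parcellation.n_regions
    for sm in matrices:
        if sm.matrix.shape[0] != n:
            raise ConnectomeError(
                f"subject {sm.subject_id}: matrix dimension {sm.matrix.shape[0]} "
                f"!= {n} parcellation regions"
            )
    stack = np.stack([sm.matrix for sm in matrices]).astype(float)  # (S, n, n)
    n_subjects = stack.shape[0]
    min_count = math.ceil(presence_threshold * n_subjects)
    presence = (stack > 0).sum(axis=0)  # per-pair presence count

    edges = []
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu.tolist(), ju.tolist()):
        pc = int(presence[i, j])
        if pc < min_count or pc == 0:
            continue
        vals = stack[:, i, j]
        if average_over_all:
            w = float(vals.mean())
        else:
            w = float(vals[vals > 0].mean())
        if lengths is None:
            length = 1.0
        elif isinstance(lengths, np.ndarray):
            length = float(lengths[i, j])
        else:
            length = float(lengths.get((i, j), lengths.get((j, i), 1.0)))
        edges.append(Edge(i=i, j=j, weight=w, length_mm=length, presence_count=pc))
    return Connectome(parcellation=parcellation, edges=edges)


def consensus_report(c: Connectome) -> dict:
    """Density/connectedness summary reported alongside a consensus build."""
    return {
        "n_regions": c.n_regions,
        "n_edges": c.n_edges,
        "n_possible_pairs": c.n_regions * (c.n_regions - 1) // 2,
        "density": c.density(),
        "density_percent": 100.0 * c.density(),
        "connected": c.is_connected(),
        "isolated_regions": c.isolated_regions(),
    }
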