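"""Maturation scalars: region/edge aggregation of ADC and T1 samples.

ADC (apparent diffusion coefficient, printed in units of 1e-6 mm/s^2) and
T1 relaxation time (ms) both decrease with tissue maturation. Regions
aggregate gray-matter voxel samples with a one-pass 1-SD outlier exclusion
(partial-volume control); edges average the voxel-wise scalars sampled
along the connecting streamline trajectories, without exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome

MODALITIES = ("ADC", "T1")


class ScalarError(ValueError):
    pass


@dataclass
class VoxelSamples:
    region_id: int
    modality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ScalarError(f"region {self.region_id}: empty voxel sample")
        if not np.all(np.isfinite(v)) or not np.all(v > 0):
            raise ScalarError(f"region {self.region_id}: non-finite or non-positive voxels")
        self.values = v


@dataclass
class ScalarMap:
    """Per-region and per-edge values for one modality."""

    modality: str
    node_values: dict[int, float] = field(default_factory=dict)
    edge_values: dict[tuple[int, int], float] = field(default_factory=dict)
    provenance: str = "measured"  # or "synthetic"

    def edge_value(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return self.edge_values[key]


def aggregate_region(v: VoxelSamples | Sequence[float]) -> float:
    """Mean voxel value after one-pass exclusion of >1-SD outliers.

    Mean ``m`` and sample standard deviation ``s`` are computed once over
    all voxels; values with ``|x - m| > s`` are discarded and the mean of
    the remainder returned. With ``s = 0`` everything is kept. The kept set
    is never empty: values at distance 0 from the mean always survive.
    """
    x = v.values if isinstance(v, VoxelSamples) else np.asarray(v, dtype=float)
    if x.size == 0:
        raise ScalarError("empty voxel sample")
    m = x.mean()
    if x.size == 1:
        return float(m)
    s = x.std(ddof=1)
    if s == 0:
        return float(m)
    kept = x[np.abs(x - m) <= s]
    return float(kept.mean())


def aggregate_edge(samples: Sequence[float]) -> float:
    """Arithmetic mean of along-tract samples; no outlier exclusion."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ScalarError("empty along-tract sample")
    return float(x.mean())


def incident_mean(c: Connectome, s: ScalarMap, region: int) -> float:
    """Unweighted mean of the edge scalar over connections incident to a region."""
    vals = [s.edge_values[(e.i, e.j)] for e in c.edges if region in (e.i, e.j)]
    if not vals:
        raise ScalarError(f"region {region} has no incident edges")
    return float(np.mean(vals))


def incident_means(c: Connectome, s: ScalarMap) -> dict[int, float]:
    """Incident-connection mean per non-isolated region."""
    sums = np.zeros(c.n_regions)
    counts = np.zeros(c.n_regions, dtype=int)
    for e in c.edges:
        v = s.edge_values[(e.i, e.j)]
        sums[e.i] += v
        sums[e.j] += v
        counts[e.i] += 1
        counts[e.j] += 1
    return {int(r): float(sums[r] / counts[r]) for r in np.flatnonzero(counts > 0)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_voxel_samples(path: str | Path) -> list[VoxelSamples]:
    """Long-format TSV: region_id, modality, value."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (rid, mod), grp in df.groupby(["region_id", "modality"], sort=True):
        out.append(VoxelSamples(region_id=int(rid), modality=str(mod),
                                values=grp["value"].to_numpy(dtype=float)))
    return out


def write_voxel_samples(samples: Iterable[VoxelSamples], path: str | Path) -> None:
    rows = []
    for vs in samples:
        for x in vs.values:
            rows.append((vs.region_id, vs.modality, x))
    pd.DataFrame(rows, columns=["region_id", "modality", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_scalar_maps(maps: dict[str, ScalarMap], node_path: str | Path,
                      edge_path: str | Path) -> None:
    """Node table (region_id, ADC, T1) and edge table (i, j, ADC, T1)."""
    node_ids = sorted(set().union(*(m.node_values for m in maps.values())))
    node_df = pd.DataFrame({"region_id": node_ids})
    for mod, m in maps.items():
        node_df[mod] = [m.node_values.get(r, np.nan) for r in node_ids]
    node_df.to_csv(node_path, sep="\t", index=False)

    edge_keys = sorted(set().union(*(m.edge_values for m in maps.values())))
    edge_df = pd.DataFrame({"i": [k[0] for k in edge_keys], "j": [k[1] for k in edge_keys]})
    for mod, m in maps.items():
        edge_df[mod] = [m.edge_values.get(k, np.nan) for k in edge_keys]
    edge_df.to_csv(edge_path, sep="\t", index=False)


def read_scalar_maps(node_path: str | Path, edge_path: str | Path,
                     provenance: str = "measured") -> dict[str, ScalarMap]:
    node_df = pd.read_csv(node_path, sep="\t")
    edge_df = pd.read_csv(edge_path, sep="\t")
    maps = {}
    for mod in node_df.columns:
        if mod == "region_id":
            continue
        m = ScalarMap(modality=mod, provenance=provenance)
        m.node_values = {int(r): float(v) for r, v in
                         zip(node_df["region_id"], node_df[mod]) if np.isfinite(v)}
        if mod in edge_df.columns:
            m.edge_values = {
                (min(int(i), int(j)), max(int(i), int(j))): float(v)
                for i, j, v in zip(edge_df["i"], edge_df["j"], edge_df[mod])
                if np.isfinite(v)
            }
        maps[mod] = m
    return maps


def scalar_map_from_voxels(samples: Iterable[VoxelSamples], modality: str,
                           edge_samples: dict[tuple[int, int], Sequence[float]] | None = None,
                           ) -> ScalarMap:
    """Aggregate raw voxel samples into a ScalarMap for one modality."""
    m = ScalarMap(modality=modality)
    for vs in samples:
        if vs.modality != modality:
            continue
        m.node_values[vs.region_id] = aggregate_region(vs)
    if edge_samples:
        for (i, j), vals in edge_samples.items():
            m.edge_values[(min(i, j), max(i, j))] = aggregate_edge(vals)
    return m
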