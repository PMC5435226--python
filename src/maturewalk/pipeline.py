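"""End-to-end orchestration: synthetic study -> consensus -> stats -> model -> nulls.

Each stage reads and writes plain tab-separated tables in an output
directory and appends to a JSON manifest (config, seed, checksums), so a
run is reproducible bit-for-bit from its config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (Connectome, Parcellation, build_consensus,
                         consensus_report, read_connectome, read_parcellation,
                         read_subject_matrix, write_connectome,
                         write_parcellation, write_subject_matrix)
from .nulls import (NullConfig, null_summary, random_seed_null,
                    randomized_incident_control, rewired_model_null)
from .scalars import read_scalar_maps, write_scalar_maps, write_voxel_samples
from .stats import (connected_vs_unconnected, group_edge_counts, jt_test,
                    length_summary, pairmean_vs_tract, region_vs_incident)
from .synth import GeneratorConfig, generate_study
from .walk import WalkConfig, run_model, scores_vs_scalar

log = logging.getLogger("maturewalk")

KEY_RWS = (1, 2, 5, 10)  # four key random-walk steps for the per-step trend table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _update_manifest(out: Path, stage: str, cfg: dict, seed: int,
                     files: list[Path]) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "version": __version__, "stages": {}}
    manifest["stages"][stage] = {
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "files": {f.name: _sha256(f) for f in files if f.exists()},
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _prepare_out(out: str | Path, force: bool, stage_files: list[str]) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if not force:
        existing = [f for f in stage_files if (out / f).exists()]
        if existing:
            raise FileExistsError(
                f"outputs already exist in {out}: {existing}; use force=True")
    return out


def _walk_config(cfg: dict, seed: int) -> WalkConfig:
    w = dict(cfg.get("walk", {}))
    w.setdefault("rng_seed", seed)
    return WalkConfig(**w)


def _generator_config(cfg: dict, seed: int) -> GeneratorConfig:
    g = dict(cfg.get("generator", {}))
    g.setdefault("rng_seed", seed)
    if "group_sizes" in g:
        g["group_sizes"] = dict(g["group_sizes"])
    if "weight_law" in g:
        g["weight_law"] = tuple(g["weight_law"])
    if "length_law" in g:
        g["length_law"] = tuple(g["length_law"])
    return GeneratorConfig(**g)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_synth(cfg: dict, out: str | Path, seed: int, force: bool = False) -> Path:
    """Generate and write a complete synthetic study bundle."""
    out = _prepare_out(out, force, ["regions.tsv"])
    gcfg = _generator_config(cfg, seed)
    bundle = generate_study(gcfg)
    write_parcellation(bundle.parcellation, out / "regions.tsv")
    write_connectome(bundle.true_connectome, out / "true_edges.tsv")
    for sm in bundle.subject_matrices:
        write_subject_matrix(sm, out / f"{sm.subject_id}.csv")
    write_scalar_maps(bundle.scalar_maps, out / "node_scalars.tsv",
                      out / "edge_scalars.tsv")
    write_voxel_samples(bundle.voxel_samples, out / "voxels.tsv")
    files = sorted(out.glob("*.tsv")) + sorted(out.glob("sub-*.csv"))
    _update_manifest(out, "synth", dataclasses.asdict(gcfg), seed, files)
    log.info("synth stage=done seed=%d regions=%d subjects=%d", seed,
             bundle.parcellation.n_regions, len(bundle.subject_matrices))
    return out


def load_bundle_dir(out: Path) -> tuple[Parcellation, list, dict]:
    parc = read_parcellation(out / "regions.tsv")
    subjects = [read_subject_matrix(p) for p in sorted(out.glob("sub-*.csv"))]
    maps = read_scalar_maps(out / "node_scalars.tsv", out / "edge_scalars.tsv")
    return parc, subjects, maps


def cmd_consensus(cfg: dict, out: str | Path, seed: int,
                  force: bool = False) -> Connectome:
    """Build the group consensus from subject matrices in the output dir."""
    out = _prepare_out(Path(out), True, [])
    parc = read_parcellation(out / "regions.tsv")
    subjects = [read_subject_matrix(p) for p in sorted(out.glob("sub-*.csv"))]
    if not subjects:
        raise FileNotFoundError(f"no subject matrices (sub-*.csv) in {out}")
    lengths = None
    if (out / "true_edges.tsv").exists():
        ref = read_connectome(out / "true_edges.tsv", parc)
        lengths = {(e.i, e.j): e.length_mm for e in ref.edges}
    threshold = float(cfg.get("consensus", {}).get("presence_threshold", 0.5))
    c = build_consensus(subjects, parc, presence_threshold=threshold,
                        lengths=lengths)
    write_connectome(c, out / "consensus_edges.tsv")
    report = consensus_report(c)
    (out / "consensus_report.json").write_text(json.dumps(report, indent=2))
    _update_manifest(out, "consensus", {"presence_threshold": threshold}, seed,
                     [out / "consensus_edges.tsv", out / "consensus_report.json"])
    log.info("consensus stage=done edges=%d density=%.4f connected=%s",
             c.n_edges, c.density(), report["connected"])
    return c


def _load_consensus(out: Path) -> tuple[Connectome, dict]:
    parc = read_parcellation(out / "regions.tsv")
    c = read_connectome(out / "consensus_edges.tsv", parc)
    maps = read_scalar_maps(out / "node_scalars.tsv", out / "edge_scalars.tsv")
    return c, maps


def cmd_stats(cfg: dict, out: str | Path, seed: int,
              force: bool = False) -> pd.DataFrame:
    """Run the full trend/correlation battery and write a tidy table."""
    out = Path(out)
    c, maps = _load_consensus(out)
    n_perm = int(cfg.get("stats", {}).get("n_perm", 9999))
    rng = np.random.default_rng(seed)
    rows = []

    def add(analysis, modality, res):
        rows.append(dict(analysis=analysis, modality=modality,
                         stratum=res.stratum or "all", n=res.n,
                         statistic=res.r, p=res.p, method=res.method))

    from .scalars import incident_means
    ranks = c.parcellation.group_ranks
    for mod, smap in maps.items():
        node_vals = np.array([smap.node_values[r] for r in range(c.n_regions)])
        jt_node = jt_test(node_vals, list(c.parcellation.groups),
                          n_perm=n_perm, rng_seed=rng)
        rows.append(dict(analysis="jt_trend_regions", modality=mod, stratum="all",
                         n=c.n_regions, statistic=jt_node.z, p=jt_node.p_perm,
                         method="jt_z"))
        inc = incident_means(c, smap)
        regions = sorted(inc)
        jt_inc = jt_test([inc[r] for r in regions],
                         [c.parcellation.groups[r] for r in regions],
                         n_perm=n_perm, rng_seed=rng)
        rows.append(dict(analysis="jt_trend_incident", modality=mod, stratum="all",
                         n=len(regions), statistic=jt_inc.z, p=jt_inc.p_perm,
                         method="jt_z"))
        add("region_vs_incident", mod, region_vs_incident(c, smap))
        for stratum in ("all", "long", "short"):
            add("pairmean_vs_tract", mod,
                pairmean_vs_tract(c, smap, stratum=stratum))
        conn, unconn = connected_vs_unconnected(c, smap, rng_seed=rng)
        add("pair_scalar_correlation", mod, conn)
        add("pair_scalar_correlation", mod, unconn)
    df = pd.DataFrame(rows)
    df.to_csv(out / "stats_results.tsv", sep="\t", index=False)
    group_edge_counts(c).to_csv(out / "group_edge_counts.tsv", sep="\t")
    (out / "length_summary.json").write_text(
        json.dumps(length_summary(c), indent=2))
    _update_manifest(out, "stats", {"n_perm": n_perm}, seed,
                     [out / "stats_results.tsv", out / "group_edge_counts.tsv",
                      out / "length_summary.json"])
    log.info("stats stage=done analyses=%d", len(df))
    return df


def cmd_model(cfg: dict, out: str | Path, seed: int,
              force: bool = False) -> pd.DataFrame:
    """Run the maturation model, write scores and per-RWS correlations."""
    out = Path(out)
    c, maps = _load_consensus(out)
    wcfg = _walk_config(cfg, seed)
    scores = run_model(c, wcfg)

    node_cum = scores.node_cumulative()
    edge_cum = scores.edge_cumulative()
    long_rows = []
    for v in range(c.n_regions):
        for t in range(scores.n_steps):
            long_rows.append(("node", v, t + 1, scores.node_per_step[v, t],
                              node_cum[v, t]))
    for k, e in enumerate(c.edges):
        for t in range(scores.n_steps):
            long_rows.append(("edge", f"{e.i}-{e.j}", t + 1,
                              scores.edge_per_step[k, t], edge_cum[k, t]))
    pd.DataFrame(long_rows, columns=["entity_type", "id", "step",
                                     "per_step_count", "cumulative_count"]
                 ).to_csv(out / "model_scores.tsv", sep="\t", index=False)

    corr_rows = []
    for mod, smap in maps.items():
        for method in ("spearman", "pearson"):
            curves = scores_vs_scalar(scores, smap, c, method=method)
            for entity in ("node", "edge"):
                for t, res in enumerate(curves[entity], start=1):
                    corr_rows.append(dict(entity=entity, modality=mod,
                                          method=method, step=t, r=res.r,
                                          p=res.p, n=res.n))
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(out / "model_correlations.tsv", sep="\t", index=False)

    # per-RWS ordered trend of the model's own scores over the cortical
    # groups; scores *decrease* along PRIM < SEC < TER, so the trend is
    # tested on negated scores (JT alternative is an ascending shift)
    cortical = [r for r in range(c.n_regions)
                if c.parcellation.groups[r] != "SUB"]
    jt_rows = []
    rng = np.random.default_rng(seed + 1)
    for t in KEY_RWS:
        if t > scores.n_steps:
            continue
        res = jt_test(-node_cum[cortical, t - 1],
                      [c.parcellation.groups[r] for r in cortical],
                      n_perm=int(cfg.get("stats", {}).get("n_perm", 9999)),
                      rng_seed=rng)
        jt_rows.append(dict(step=t, jt_z_decreasing=res.z, p=res.p_perm,
                            n=len(cortical)))
    pd.DataFrame(jt_rows).to_csv(out / "model_jt.tsv", sep="\t", index=False)

    _update_manifest(out, "model", dataclasses.asdict(wcfg), seed,
                     [out / "model_scores.tsv", out / "model_correlations.tsv",
                      out / "model_jt.tsv"])
    log.info("model stage=done steps=%d reps=%d", wcfg.n_steps, wcfg.n_reps)
    return corr


def cmd_nulls(cfg: dict, out: str | Path, seed: int,
              force: bool = False) -> dict:
    """Run both model nulls and the randomized incident control."""
    out = Path(out)
    c, maps = _load_consensus(out)
    smap = maps["ADC"]
    wcfg = _walk_config(cfg, seed)
    ncfg_kw = dict(cfg.get("nulls", {}))
    n_real = int(ncfg_kw.pop("n_realizations", 50))

    rs_cfg = NullConfig(kind="random_seeds", n_realizations=n_real,
                        rng_seed=seed + 10, **ncfg_kw)
    rw_cfg = NullConfig(kind="rewired_network", n_realizations=n_real,
                        rng_seed=seed + 11, **ncfg_kw)
    rs_curves = random_seed_null(c, rs_cfg, wcfg, smap)
    rw_curves = rewired_model_null(c, rw_cfg, wcfg, smap)

    rows = []
    for kind, curves in (("random_seeds", rs_curves), ("rewired", rw_curves)):
        for k, curve in enumerate(curves):
            for entity in ("node", "edge"):
                for t, res in enumerate(curve[entity], start=1):
                    rows.append(dict(kind=kind, realization=k, entity=entity,
                                     step=t, r=res.r, p=res.p))
    pd.DataFrame(rows).to_csv(out / "null_curves.tsv", sep="\t", index=False)

    true_scores = run_model(c, wcfg)
    true_curve = scores_vs_scalar(true_scores, smap, c)
    rng = np.random.default_rng(seed + 12)
    inc_ctrl = randomized_incident_control(c, smap, rng, n_realizations=10)
    summary = {
        "true_node_r": [res.r for res in true_curve["node"]],
        "random_seed_mean_abs_node_r": np.abs(
            null_summary(rs_curves, "node")).mean(axis=0).tolist(),
        "rewired_mean_abs_node_r": np.abs(
            null_summary(rw_curves, "node")).mean(axis=0).tolist(),
        "randomized_incident_r": inc_ctrl.r,
        "randomized_incident_p": inc_ctrl.p,
    }
    (out / "null_summary.json").write_text(json.dumps(summary, indent=2))
    _update_manifest(out, "nulls", {"n_realizations": n_real}, seed,
                     [out / "null_curves.tsv", out / "null_summary.json"])
    log.info("nulls stage=done realizations=%d", n_real)
    return summary


def cmd_all(cfg: dict, out: str | Path, seed: int, force: bool = False) -> dict:
    """Full reproduce-on-synthetic run: synth -> consensus -> stats -> model
    -> nulls, one manifest."""
    out = Path(out)
    cmd_synth(cfg, out, seed, force=force)
    cmd_consensus(cfg, out, seed)
    cmd_stats(cfg, out, seed)
    cmd_model(cfg, out, seed)
    summary = cmd_nulls(cfg, out, seed)
    log.info("all stage=done out=%s", out)
    return summary
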