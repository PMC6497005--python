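"""End-to-end pipeline orchestration.

Stage order mirrors the analysis: motion QC -> graph construction ->
community detection -> nodal cartography -> association statistics ->
post hoc checks.  A :class:`RunConfig` (YAML-loadable) carries every
threshold and seed; outputs land in a config-hash-named directory and every
written file is checksummed into ``run_manifest.json``, so identical config
+ cohort reproduce identical manifests.  The association stage reads only
the cached metric tables, so it can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cartography, community, graphs, motion, posthoc, stats, synthetic

log = logging.getLogger("modcart")

_GLOBAL_MEASURES = (
    "q",
    "number_of_modules",
    "average_module_size",
    "variability_in_module_size",
)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the printed analysis choices.

    ``motion_covariate`` selects the nuisance motion covariate: subject mean
    FD (default) or the number of low-motion frames (FD < fd_threshold).
    ``k_min='auto'`` calibrates the cluster-extent threshold by Monte-Carlo
    permutation; an integer fixes it (26 is the reference value at the
    original voxel grid).
    """

    cohort_dir: str = "cohort"
    output_dir: str = "runs"
    densities: tuple[float, ...] = graphs.DENSITIES
    min_dist: float = graphs.MIN_DISTANCE_MM
    fd_threshold: float = motion.FD_THRESHOLD_MM
    louvain_seed: int = 0
    louvain_restarts: int = 20
    covariates: tuple[str, ...] = stats.DEFAULT_COVARIATES
    alpha: float = 0.05
    voxel_p: float = stats.VOXEL_P
    k_min: int | str = "auto"
    n_null_iter: int = 1000
    adjacency_mode: str = "faces"
    motion_covariate: str = "mean_fd"
    extreme_group_n: int = 20
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.densities = tuple(float(d) for d in self.densities)
        if not self.densities:
            raise ValueError("densities must be non-empty")
        if any(not (0 < d <= 1) for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")
        for name in ("min_dist", "fd_threshold", "alpha", "voxel_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.motion_covariate not in ("mean_fd", "n_low_motion_frames"):
            raise ValueError("motion_covariate must be mean_fd or n_low_motion_frames")
        if self.k_min != "auto" and int(self.k_min) < 0:
            raise ValueError("k_min must be 'auto' or a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("densities", "covariates"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["densities"] = list(self.densities)
        d["covariates"] = list(self.covariates)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _run_dir(config: RunConfig) -> Path:
    out = Path(config.output_dir) / f"run-{config.config_hash()}"
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages

def stage_qc(cohort: synthetic.Cohort, config: RunConfig, out: Path) -> pd.DataFrame:
    """FD series, QC summary and motion-based exclusion."""
    fd_dir = out / "fd"
    fd_dir.mkdir(exist_ok=True)
    traces = dict(zip(cohort.subject_ids, cohort.motion_traces))
    for sid, trace in traces.items():
        motion.write_fd_series(motion.framewise_displacement(trace), fd_dir / f"{sid}.tsv")
    summary = motion.qc_summary(traces, config.fd_threshold)
    _write_csv(summary, out / "qc_summary.csv")
    n_excl = int(summary["excluded"].sum())
    log.info("QC: %d/%d subjects excluded (mean FD > %.2g mm)",
             n_excl, len(summary), config.fd_threshold)
    return summary


def stage_graph(cohort: synthetic.Cohort, config: RunConfig, out: Path,
                retained=None) -> None:
    """Write per-subject edge lists and graph manifests (artifact export)."""
    gdir = out / "graphs"
    gdir.mkdir(exist_ok=True)
    coords = cohort.coordinates[["x", "y", "z"]].to_numpy()
    ids = retained if retained is not None else cohort.subject_ids
    index = {s: i for i, s in enumerate(cohort.subject_ids)}
    for sid in ids:
        ts = cohort.timeseries[index[sid]]
        r = graphs.correlation_matrix(ts)
        conn = graphs.apply_distance_exclusion(r, coords, config.min_dist)
        gset = graphs.build_graph_set(conn=conn, densities=config.densities)
        sdir = gdir / sid
        sdir.mkdir(exist_ok=True)
        for d, g in gset.items():
            graphs.write_edge_list(g, sdir / f"density_{d:.2f}.tsv")
        (sdir / "manifest.json").write_text(
            json.dumps(graphs.graph_manifest(gset, conn), indent=2, sort_keys=True)
        )


def stage_metrics(
    cohort: synthetic.Cohort, config: RunConfig, out: Path, retained
) -> dict:
    """Per-subject graph metrics: global modularity stats and nodal maps.

    Returns the in-memory maps/tables reused by later stages and caches
    them as CSV for isolated reruns of the association stage.
    """
    coords = cohort.coordinates[["x", "y", "z"]].to_numpy()
    index = {s: i for i, s in enumerate(cohort.subject_ids)}
    global_rows, p_maps, z_maps, prop_rows = [], [], [], []
    for sid in retained:
        ts = cohort.timeseries[index[sid]]
        r = graphs.correlation_matrix(ts)
        conn = graphs.apply_distance_exclusion(r, coords, config.min_dist)
        gset = graphs.build_graph_set(conn=conn, densities=config.densities)
        partitions, per_density = {}, {}
        for d, g in gset.items():
            labels = community.louvain_partition(
                g, seed=config.louvain_seed, n_restarts=config.louvain_restarts
            )
            partitions[d] = labels
            dec = community.modularity_q(g, labels)
            gs = community.global_module_stats(labels, q=dec.q)
            per_density[d] = gs
            global_rows.append(
                {"subject_id": sid, "density": f"{d:.2f}", "q": gs.q,
                 "number_of_modules": gs.number_of_modules,
                 "average_module_size": gs.average_module_size,
                 "variability_in_module_size": gs.variability_in_module_size}
            )
        avg = {
            name: community.average_across_thresholds(
                [getattr(per_density[d], name) for d in config.densities]
            )
            for name in _GLOBAL_MEASURES
        }
        global_rows.append({"subject_id": sid, "density": "avg", **avg})
        maps = cartography.threshold_averaged_maps(gset, partitions)
        p_maps.append(maps["p_mean"])
        z_maps.append(maps["z_mean"])
        prop_rows.append(maps["proportions"])
    node_ids = list(cohort.coordinates["node_id"])
    result = {
        "global": pd.DataFrame(global_rows),
        "p_maps": pd.DataFrame(np.array(p_maps), index=retained, columns=node_ids),
        "z_maps": pd.DataFrame(np.array(z_maps), index=retained, columns=node_ids),
        "proportions": pd.DataFrame(prop_rows, index=retained),
    }
    _write_csv(result["global"], out / "global_metrics.csv")
    for key, fname in (
        ("p_maps", "maps_participation.csv"),
        ("z_maps", "maps_within_degree.csv"),
        ("proportions", "node_type_proportions.csv"),
    ):
        result[key].rename_axis("subject_id").reset_index().to_csv(
            out / fname, index=False, float_format=_FLOAT_FMT
        )
    return result


def _load_metrics(out: Path) -> dict:
    """Reload cached metric tables (association-stage isolation)."""
    result = {"global": pd.read_csv(out / "global_metrics.csv")}
    for key, fname in (
        ("p_maps", "maps_participation.csv"),
        ("z_maps", "maps_within_degree.csv"),
        ("proportions", "node_type_proportions.csv"),
    ):
        df = pd.read_csv(out / fname).set_index("subject_id")
        result[key] = df
    return result


def _analysis_inputs(cohort, config, out, metrics):
    """Aligned phenotypes, covariate design and symptom scores for retained subjects."""
    retained = list(metrics["p_maps"].index)
    pheno = cohort.phenotypes.set_index("subject_id").loc[retained].reset_index()
    qc = pd.read_csv(out / "qc_summary.csv").set_index("subject_id").loc[retained]
    covariate_names = list(config.covariates)
    if config.motion_covariate == "n_low_motion_frames":
        pheno = pheno.assign(
            n_low_motion_frames=qc["n_low_motion_frames"].to_numpy(dtype=float)
        )
        covariate_names = [
            "n_low_motion_frames" if c == "mean_fd" else c for c in covariate_names
        ]
    design = stats.covariate_design(pheno, covariate_names)
    y = pheno["adhd_index"].to_numpy(dtype=float)
    return retained, pheno, design, y


def stage_associate(cohort, config: RunConfig, out: Path) -> dict:
    """Global partial correlations + Bayes factors, nodal cluster analysis.

    Always reads the cached metric tables written by the metrics stage, so
    an isolated rerun reproduces byte-identical statistics.
    """
    metrics = _load_metrics(out)
    retained, pheno, design, y = _analysis_inputs(cohort, config, out, metrics)

    gl = metrics["global"]
    avg = gl[gl["density"] == "avg"].set_index("subject_id").loc[retained]
    global_tab = stats.associate_global_measures(
        y, avg[list(_GLOBAL_MEASURES)], design, config.alpha
    )
    prop_tab = stats.associate_global_measures(
        y, metrics["proportions"].loc[retained], design, config.alpha
    )
    _write_csv(global_tab, out / "global_associations.csv")
    _write_csv(prop_tab, out / "node_type_associations.csv")

    coords = cohort.coordinates[["x", "y", "z"]].to_numpy()
    adjacency = stats.lattice_adjacency(coords, config.adjacency_mode)
    n, k = len(y), design.shape[1]
    df_resid = n - k - 2
    cluster_tables = {}
    kmins = {}
    for label, maps in (("participation", metrics["p_maps"]),
                        ("within_degree", metrics["z_maps"])):
        m = maps.loc[retained].to_numpy(dtype=float)
        t, p = stats.mass_univariate_regression(m, y, design)
        pd.DataFrame(
            {"node_id": maps.columns, "t": t, "p": p}
        ).to_csv(out / f"tmap_{label}.csv", index=False, float_format=_FLOAT_FMT)
        if config.k_min == "auto":
            k_min, _ = stats.monte_carlo_cluster_null(
                adjacency,
                voxel_p=config.voxel_p,
                fwe_alpha=config.alpha,
                n_iter=config.n_null_iter,
                seed=config.seed,
                mode="permutation",
                maps=m,
                covariates=design,
                y=y,
            )
        else:
            k_min = int(config.k_min)
        kmins[label] = k_min
        table = stats.cluster_extent_threshold(
            np.nan_to_num(t), adjacency, config.voxel_p, k_min,
            df=df_resid, coords=coords,
        )
        cluster_tables[label] = table
        exportable = table.assign(nodes=table["nodes"].map(lambda v: ";".join(map(str, v))))
        _write_csv(exportable, out / f"cluster_table_{label}.csv")
    (out / "cluster_thresholds.json").write_text(
        json.dumps({"voxel_p": config.voxel_p, "k_min": kmins}, indent=2, sort_keys=True)
    )
    return {"global": global_tab, "proportions": prop_tab,
            "clusters": cluster_tables, "k_min": kmins, "retained": retained}


def stage_posthoc(cohort, config: RunConfig, out: Path, assoc=None) -> dict:
    """Extreme groups, 7-network block FC, distance-motion QC, cluster ranks."""
    metrics = _load_metrics(out)
    retained, pheno, design, y = _analysis_inputs(cohort, config, out, metrics)
    gl = metrics["global"]
    avg = gl[gl["density"] == "avg"].set_index("subject_id").loc[retained]

    n_group = min(config.extreme_group_n, len(retained) // 2)
    eg_rows = []
    for name in _GLOBAL_MEASURES:
        res = posthoc.extreme_group_compare(
            avg[name].to_numpy(), y, n_per_group=n_group, test="t"
        )
        eg_rows.append({"measure": name, "test": "welch_t",
                        "statistic": res.statistic, "p_value": res.p_value,
                        "n_per_group": n_group})
    _write_csv(pd.DataFrame(eg_rows), out / "extreme_groups.csv")

    # per-subject 7-network block FC + its association with the symptom score
    assignment = synthetic.synthetic_network_assignment(cohort.spec.n_nodes)
    net = assignment["network"].to_numpy()
    coords = cohort.coordinates[["x", "y", "z"]].to_numpy()
    index = {s: i for i, s in enumerate(cohort.subject_ids)}
    blocks, edge_fc = [], []
    iu = ju = None
    for sid in retained:
        r = graphs.correlation_matrix(cohort.timeseries[index[sid]])
        conn = graphs.apply_distance_exclusion(r, coords, config.min_dist)
        blocks.append(posthoc.network_block_fc(conn, net).to_numpy())
        if iu is None:
            iu, ju = np.where(np.triu(conn.admissible, 1))
        edge_fc.append(conn.r[iu, ju])
    blocks = np.array(blocks)
    names = list(posthoc.NETWORKS_7)
    rows = []
    n_pairs = len(names) * (len(names) + 1) // 2
    raw_thr, _ = stats.bonferroni_threshold(config.alpha, n_pairs)
    for a in range(len(names)):
        for b in range(a, len(names)):
            vals = blocks[:, a, b]
            res = stats.partial_correlation(y, vals, design,
                                            name=f"{names[a]}|{names[b]}")
            rows.append({"network_a": names[a], "network_b": names[b],
                         "r_part": res.r_part, "p_part": res.p_part,
                         "significant": res.p_part < raw_thr})
    _write_csv(pd.DataFrame(rows), out / "network_block_associations.csv")
    _write_csv(
        pd.DataFrame(blocks.mean(axis=0), index=names, columns=names)
        .rename_axis("network").reset_index(),
        out / "network_block_mean.csv",
    )

    # distance-dependent motion diagnostic on admissible edges
    mean_fd = pheno["mean_fd"].to_numpy(dtype=float)
    lengths = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    edge_r, dist_r, dist_p = posthoc.distance_dependence_qc(
        np.array(edge_fc), mean_fd, lengths
    )
    pd.DataFrame({"edge_length_mm": lengths, "r_fc_fd": edge_r}).to_csv(
        out / "distance_qc.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    (out / "distance_qc_summary.json").write_text(
        json.dumps({"distance_r": dist_r, "distance_p": dist_p}, indent=2,
                   sort_keys=True)
    )

    # rank positions of significant clusters in the group-average maps
    rank_rows = []
    if assoc is not None:
        for label, maps_key in (("participation", "p_maps"),
                                ("within_degree", "z_maps")):
            group_map = metrics[maps_key].loc[retained].to_numpy().mean(axis=0)
            for ci, row in assoc["clusters"][label].iterrows():
                rep = posthoc.cluster_rank_position(group_map, row["nodes"])
                rank_rows.append({"metric": label, "cluster": ci,
                                  "sign": row["sign"], "k": row["k"],
                                  "mean_value": rep.value,
                                  "percentile": rep.percentile,
                                  "band": rep.band})
    _write_csv(
        pd.DataFrame(rank_rows, columns=["metric", "cluster", "sign", "k",
                                         "mean_value", "percentile", "band"]),
        out / "cluster_rank_positions.csv",
    )
    return {"extreme_groups": eg_rows, "distance_r": dist_r}


_STAGES = ("qc", "graph", "metrics", "associate", "posthoc")


def run_pipeline(config: RunConfig, stages=("all",)) -> dict:
    """Execute the pipeline stages and write the checksum manifest.

    ``stages`` is a sequence of stage names (``qc``, ``graph``, ``metrics``,
    ``associate``, ``posthoc``) or ``('all',)``.  Any stage failure raises
    with the stage name in the message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    todo = _STAGES if "all" in stages else tuple(stages)
    unknown = set(todo) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = _run_dir(config)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    cohort = synthetic.read_cohort(config.cohort_dir)
    results: dict = {"output_dir": str(out)}
    retained = None
    metrics = assoc = None
    for stage in todo:
        log.info("stage: %s", stage)
        try:
            if stage == "qc":
                summary = stage_qc(cohort, config, out)
                retained = list(summary.loc[~summary["excluded"], "subject_id"])
            elif stage == "graph":
                if retained is None:
                    retained, _ = motion.exclude_high_motion(
                        cohort.phenotypes, config.fd_threshold
                    )
                stage_graph(cohort, config, out, retained)
            elif stage == "metrics":
                if retained is None:
                    retained, _ = motion.exclude_high_motion(
                        cohort.phenotypes, config.fd_threshold
                    )
                metrics = stage_metrics(cohort, config, out, retained)
            elif stage == "associate":
                assoc = stage_associate(cohort, config, out)
                results["associate"] = assoc
            elif stage == "posthoc":
                results["posthoc"] = stage_posthoc(cohort, config, out, assoc)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    results["manifest"] = write_manifest(out)
    return results


def write_manifest(out: Path) -> dict:
    """SHA-256 checksums of every output file, written to run_manifest.json."""
    entries = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            entries[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out / "run_manifest.json").write_text(
        json.dumps(entries, indent=2, sort_keys=True)
    )
    return entries
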