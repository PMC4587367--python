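"""End-to-end orchestration of the top-down workflow.

``run_pipeline`` executes, in order: per-system RMSD-vs-reference traces with
1000-bin histograms → the three artificial frame sets (scan stride all
sources; finer stride all sources; scan stride long-runs only) → Cα/Cβ RMSD
matrices → a k-medoids validation scan → a GROMOS cutoff scan → final
clustering with per-cluster similarity centroids, the system×cluster
contingency table and transition counts → Cα PCA projections → per-cluster
RMSF and mutant−reference RMSF differences → solvation profiles (g(r) and
coordination numbers around the start-point atom) → hydrogen-bond occupancy
tables and network differences against the reference system → tunnel search
on channel fixtures with pathway statistics.

Every stage is seeded from the config, logs its parameters, writes its tables
under the output directory as TSV/JSON, and on failure aborts with the stage
name while retaining partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .clustering import (
    contingency,
    count_transitions,
    gromos_cluster,
    scan_k,
)
from .errors import PipelineError, UsageError
from .hbonds import HBondCriteria, filter_by_lifetime, hbond_occupancy, network_difference
from .pca import cumulative_variance, fit_pca, project
from .solvation import coordination_number, rdf
from .superpose import kabsch_rmsd, pairwise_rmsd_matrix, rmsf, rmsf_difference, similarity_centroid
from .trajectory import (
    SamplingProtocol,
    build_artificial_trajectory,
    read_trajectory,
)
from .tunnels import TunnelSearchConfig, cluster_tunnels, find_tunnels, pathway_statistics

logger = logging.getLogger("mdtop.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "report", "validate_report"]


@dataclass(eq=False)
class PipelineConfig:
    """All knobs of the workflow, with the study-design defaults.

    The ensemble defaults are the full study conditions (150 ns long runs,
    two 10 ns restarts, 20 ps frames, five systems); pass smaller durations
    for desk-scale runs.
    """

    # synthetic ensemble
    n_residues: int = 12
    seed: int = 0
    long_ns: float = 150.0
    restart_ns: tuple[float, ...] = (10.0, 10.0)
    restart_branch_ns: tuple[float, ...] = (60.0, 130.0)
    interval_ps: float = 20.0
    sigma_basin: float = 0.7
    basin_separation: float = 2.9
    # optional file input instead of generation: label -> (long, [restarts])
    system_paths: dict | None = None
    # sampling
    scan_stride_ps: float = 80.0
    final_stride_ps: float = 40.0
    discard_ns: float = 30.0
    exclusion: float = 0.10
    # selections
    cluster_selection: str = "name CA or name CB"
    backbone_selection: str = "name CA"
    # clustering
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    kmedoids_restarts: int = 10
    gromos_cutoffs_nm: tuple[float, ...] = (0.18, 0.20, 0.22, 0.24, 0.26)
    final_cutoff_nm: float = 0.22
    # hydrogen bonds
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    lifetime_threshold: float = 0.5
    hbond_frames: int = 400
    # solvation
    solvent_density: float = 0.0334  # bulk water number density, Å^-3
    solvent_box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    rdf_bin_width: float = 0.1
    rdf_r_max: float = 12.0
    coordination_cutoff: float = 7.0
    solvation_frames: int = 60
    # tunnels (channel fixtures: wide open channel vs narrower side channel)
    probe_radius: float = 1.3
    channel_body_radius: float = 10.0
    channel_radii: tuple[float, float] = (2.2, 1.7)
    tunnel_frames: int = 4

    histogram_bins: int = 1000  # RMSD histogram convention


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("load")
def _load_systems(config: PipelineConfig):
    if config.system_paths is not None:
        from .trajectory import SystemTrajectories

        systems = []
        for label, (long_path, restart_paths) in config.system_paths.items():
            for p in (long_path, *restart_paths):
                if not Path(p).exists():
                    raise UsageError(f"system {label}: missing trajectory file {p}")
            long = read_trajectory(long_path, interval_ps=config.interval_ps)
            long.label, long.source = label, "long"
            restarts = []
            for k, p in enumerate(restart_paths, start=1):
                t = read_trajectory(p, interval_ps=config.interval_ps)
                t.label, t.source = label, f"restart{k}"
                restarts.append(t)
            systems.append(
                SystemTrajectories(label=label, long=long, restarts=tuple(restarts))
            )
        topology = systems[0].long.topology
        return topology, systems
    topology = synthetic.generate_topology(config.n_residues, config.seed)
    spec = synthetic.five_system_spec(
        topology,
        seed=config.seed,
        sigma=config.sigma_basin,
        separation=config.basin_separation,
        long_ns=config.long_ns,
        restart_ns=config.restart_ns,
        restart_branch_ns=config.restart_branch_ns,
        interval_ps=config.interval_ps,
    )
    return topology, synthetic.generate_ensemble(topology, spec)


@_stage("rmsd_reference")
def _rmsd_vs_reference(config, topology, systems, outdir):
    from .selection import select_atoms

    sel = select_atoms(topology, config.backbone_selection)
    ref = topology.reference_coords[sel]
    rows = []
    for system in systems:
        traj = system.long
        for f in range(traj.n_frames):
            r, _, _ = kabsch_rmsd(ref, traj.coords[f][sel])
            rows.append(
                {"system": system.label, "time_ps": traj.times[f], "rmsd_nm": r / 10.0}
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "rmsd_vs_reference.tsv", sep="\t", index=False)
    hists = {}
    for label, group in df.groupby("system"):
        counts, edges = np.histogram(
            group["rmsd_nm"], bins=config.histogram_bins
        )
        hists[label] = {"counts": counts.tolist(), "edges": edges.tolist()}
    (outdir / "rmsd_histograms.json").write_text(json.dumps(hists))
    return df


@_stage("frame_sets")
def _frame_sets(config, systems):
    base = dict(exclusion=config.exclusion, discard_ns=config.discard_ns)
    proto1 = SamplingProtocol(config.scan_stride_ps, seed=config.seed + 1, **base)
    proto2 = SamplingProtocol(config.final_stride_ps, seed=config.seed + 2, **base)
    proto3 = SamplingProtocol(config.scan_stride_ps, seed=config.seed + 3, **base)
    longs_only = [
        type(s)(label=s.label, long=s.long, restarts=()) for s in systems
    ]
    return {
        "set1": build_artificial_trajectory(systems, proto1),
        "set2": build_artificial_trajectory(systems, proto2),
        "set3": build_artificial_trajectory(longs_only, proto3),
    }


@_stage("distance_matrices")
def _distance_matrices(config, topology, frame_sets, outdir):
    matrices = {}
    for name in ("set1", "set2"):
        at = frame_sets[name]
        matrices[name] = pairwise_rmsd_matrix(
            at.coords, topology, config.cluster_selection
        )
    matrices["set1"].to_tsv(outdir / "rmsd_matrix_set1.tsv")
    return matrices


@_stage("scan_k")
def _scan_k(config, matrices, outdir):
    scores = scan_k(
        matrices["set1"],
        config.k_range,
        seed=config.seed,
        restarts=config.kmedoids_restarts,
    )
    scores.to_tsv(outdir / "kmedoids_scan.tsv")
    return scores


@_stage("gromos_scan")
def _gromos_scan(config, matrices, outdir):
    rows, models = [], {}
    for cutoff_nm in config.gromos_cutoffs_nm:
        model = gromos_cluster(matrices["set1"], cutoff_nm * 10.0)
        sizes = model.sizes()
        rows.append(
            {
                "cutoff_nm": cutoff_nm,
                "n_clusters": model.n_clusters,
                "largest": int(sizes.max()),
                "sizes": ",".join(map(str, sizes.tolist())),
            }
        )
        models[cutoff_nm] = model
    pd.DataFrame(rows).to_csv(outdir / "gromos_scan.tsv", sep="\t", index=False)
    return models


@_stage("final_clustering")
def _final_clustering(config, matrices, frame_sets, outdir):
    at = frame_sets["set2"]
    model = gromos_cluster(matrices["set2"], config.final_cutoff_nm * 10.0)
    model.to_frame(at.provenance).to_csv(
        outdir / "clusters_set2.tsv", sep="\t", index=False
    )
    cont = contingency(model, at.provenance)
    cont.to_csv(outdir / "contingency.tsv", sep="\t")
    trans = count_transitions(model, at.provenance)
    np.savetxt(outdir / "transitions.tsv", trans, fmt="%d", delimiter="\t")
    centroids = {}
    D = matrices["set2"].values
    for c in range(min(model.n_clusters, 3)):
        members = model.members(c)
        sub = D[np.ix_(members, members)]
        from .superpose import DistanceMatrix

        local = similarity_centroid(DistanceMatrix(sub))
        frame_idx = int(members[local])
        centroids[c] = {
            "frame": frame_idx,
            "system": str(at.provenance.loc[frame_idx, "system"]),
            "time_ps": float(at.provenance.loc[frame_idx, "time_ps"]),
        }
    (outdir / "centroids.json").write_text(json.dumps(centroids))
    return model, cont, trans, centroids


@_stage("pca")
def _pca_stage(config, topology, frame_sets, outdir):
    at = frame_sets["set2"]
    model = fit_pca(at.coords, topology, config.backbone_selection)
    n_comp = min(3, max(model.rank, 1))
    scores = project(at.coords, model, n_comp)
    df = pd.DataFrame(scores, columns=[f"pc{i + 1}" for i in range(n_comp)])
    df.insert(0, "system", at.provenance["system"])
    df.to_csv(outdir / "pca_projections.tsv", sep="\t", index=False)
    cum = cumulative_variance(model)
    return model, scores, cum


@_stage("rmsf")
def _rmsf_stage(config, topology, frame_sets, cluster_model, outdir):
    at = frame_sets["set2"]
    profiles = {}
    for c in range(min(cluster_model.n_clusters, 3)):
        members = cluster_model.members(c)
        if members.size < 2:
            continue
        profiles[f"cluster{c + 1}"] = rmsf(
            at.coords[members], topology, config.backbone_selection,
            label=f"cluster{c + 1}",
        )
    by_system = {}
    for label, group in at.provenance.groupby("system", sort=False):
        idx = group.index.to_numpy()
        by_system[label] = rmsf(
            at.coords[idx], topology, config.backbone_selection, label=str(label)
        )
    ref_label = at.system_order[0]
    diffs = {
        label: rmsf_difference(profile, by_system[ref_label])
        for label, profile in by_system.items()
        if label != ref_label
    }
    rows = []
    for name, profile in profiles.items():
        for atom, val in zip(profile.selection, profile.values_nm):
            rows.append({"set": name, "atom_index": int(atom), "rmsf_nm": val})
    pd.DataFrame(rows).to_csv(outdir / "rmsf_clusters.tsv", sep="\t", index=False)
    return profiles, by_system, diffs


@_stage("solvation")
def _solvation_stage(config, topology, systems, outdir):
    """Hydration of the start-point atom per system.

    The reference system gets a full depletion shell (buried, dry start
    point), the bulky-hydrophobic last system a partial one, the shared-basin
    systems open access — emulating the contrast the g(r) comparison probes.
    """
    shells = {}
    labels = [s.label for s in systems]
    for i, label in enumerate(labels):
        if i == 0:
            shells[label] = ((0.0, 4.0, 0.0),)
        elif i == len(labels) - 1:
            shells[label] = ((0.0, 4.0, 0.25),)
        else:
            shells[label] = ()
    results = {}
    for i, label in enumerate(labels):
        spec = synthetic.SolventShellSpec(
            bulk_density=config.solvent_density,
            box=config.solvent_box,
            shells=shells[label],
        )
        frames = synthetic.generate_solvated_frames(
            topology, spec, config.solvation_frames, seed=config.seed + 100 + i
        )
        profile = rdf(
            frames, bin_width=config.rdf_bin_width, r_max=config.rdf_r_max
        )
        profile.to_tsv(outdir / f"rdf_{label}.tsv")
        coord = coordination_number(frames, cutoff=config.coordination_cutoff)
        results[label] = {
            "coordination_mean": coord,
            "coordination_int": int(round(coord)),
        }
    (outdir / "coordination.json").write_text(json.dumps(results))
    return results


@_stage("hbonds")
def _hbond_stage(config, topology, systems, outdir):
    """Occupancy tables per system plus diffs against the reference system.

    Mutant-like systems carry an extra stable bond the reference lacks,
    emulating a network difference localised to the mutated site.
    """
    labels = [s.label for s in systems]
    n_trip = len(topology.donor_triplets)
    acceptors = list(topology.acceptors)
    base_pair = synthetic.HBondPairSpec(
        donor_triplet=0, acceptor=acceptors[-1], occupancy=0.9
    )
    extra_pair = synthetic.HBondPairSpec(
        donor_triplet=min(1, n_trip - 1), acceptor=acceptors[-2], occupancy=0.8
    )
    tables = {}
    for i, label in enumerate(labels):
        pairs = [base_pair] if i == 0 else [base_pair, extra_pair]
        spec = synthetic.HBondSeriesSpec(
            pairs=tuple(pairs), n_frames=config.hbond_frames,
            seed=config.seed + 200 + i, interval_ps=config.interval_ps,
        )
        traj = synthetic.generate_hbond_series(topology, spec)
        traj.label = label
        table = hbond_occupancy(traj, config.hbond_criteria)
        table = filter_by_lifetime(table, 0.0)
        table.to_tsv(outdir / f"hbonds_{label}.tsv")
        tables[label] = table
    ref = labels[0]
    diffs = {
        label: network_difference(
            tables[label], tables[ref], threshold=config.lifetime_threshold
        )
        for label in labels[1:]
    }
    summary = {
        label: {
            "unique_to_system": diff.unique_to_a["donor_label"]
            .str.cat(diff.unique_to_a["acceptor_label"], sep="->")
            .tolist(),
            "unique_to_reference": diff.unique_to_b["donor_label"]
            .str.cat(diff.unique_to_b["acceptor_label"], sep="->")
            .tolist(),
        }
        for label, diff in diffs.items()
    }
    (outdir / "hbond_network_diffs.json").write_text(json.dumps(summary))
    return tables, diffs


@_stage("tunnels")
def _tunnel_stage(config, outdir):
    """Channel-fixture tunnel search: two channels of different radii, a few
    jittered frames each; pathway statistics mirror the published table
    layout (frames present, mean bottleneck, length, throughput)."""
    wide, narrow = config.channel_radii
    spec = synthetic.ChannelSpec(
        body_radius=config.channel_body_radius,
        channels=(
            synthetic.ChannelDef(
                axis=(0.0, 0.0, 1.0),
                profile=((0.0, wide), (config.channel_body_radius, wide)),
            ),
            synthetic.ChannelDef(
                axis=(1.0, 0.0, 0.0),
                profile=((0.0, narrow), (config.channel_body_radius, narrow)),
            ),
        ),
    )
    tcfg = TunnelSearchConfig(
        probe_radius=config.probe_radius, start=np.zeros(3)
    )
    all_tunnels = []
    for f in range(config.tunnel_frames):
        traj, truth = synthetic.generate_channel_system(
            spec, seed=config.seed + 300 + f
        )
        all_tunnels.extend(
            find_tunnels(traj.coords[0], traj.topology, tcfg, frame=f)
        )
    pathways = cluster_tunnels(all_tunnels, linkage_cutoff=4.0)
    stats = pathway_statistics(pathways, total_frames=config.tunnel_frames)
    stats.to_csv(outdir / "pathway_statistics.tsv", sep="\t", index=False)
    return pathways, stats


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the whole workflow; returns the in-memory results bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d", config.seed)
    results: dict = {"config_seed": config.seed}
    topology, systems = _load_systems(config)
    results["systems"] = [s.label for s in systems]
    results["rmsd_reference"] = _rmsd_vs_reference(config, topology, systems, outdir)
    frame_sets = _frame_sets(config, systems)
    results["frame_counts"] = {k: v.n_frames for k, v in frame_sets.items()}
    matrices = _distance_matrices(config, topology, frame_sets, outdir)
    results["scan"] = _scan_k(config, matrices, outdir)
    results["gromos_scan"] = _gromos_scan(config, matrices, outdir)
    model, cont, trans, centroids = _final_clustering(
        config, matrices, frame_sets, outdir
    )
    results["cluster_model"] = model
    results["contingency"] = cont
    results["transitions"] = trans
    results["centroids"] = centroids
    results["pca"] = _pca_stage(config, topology, frame_sets, outdir)
    results["rmsf"] = _rmsf_stage(config, topology, frame_sets, model, outdir)
    results["solvation"] = _solvation_stage(config, topology, systems, outdir)
    results["hbonds"] = _hbond_stage(config, topology, systems, outdir)
    results["tunnels"] = _tunnel_stage(config, outdir)
    report(results, outdir)
    return results


REPORT_SCHEMA = {
    "systems": list,
    "frame_counts": dict,
    "kmedoids_scan": list,
    "contingency": dict,
    "coordination": dict,
    "pathways": list,
}


def validate_report(obj: dict) -> None:
    """Structural validation of the JSON report against the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in obj:
            raise UsageError(f"report missing key {key!r}")
        if not isinstance(obj[key], typ):
            raise UsageError(f"report key {key!r} has wrong type")


def report(results: dict, outdir) -> dict:
    """Condense results into a JSON report mirroring the published tables."""
    outdir = Path(outdir)
    scan = results.get("scan")
    scan_rows = []
    if scan is not None:
        for _, row in scan.table.iterrows():
            scan_rows.append(
                {
                    "k": int(row["k"]),
                    "wss": float(row["wss"]),
                    "dunn": float(row["dunn"]),
                    "davies_bouldin": float(row["davies_bouldin"]),
                    "sizes": list(row["sizes"]),
                }
            )
    cont = results.get("contingency")
    pathways_stats = results.get("tunnels", (None, None))[1]
    obj = {
        "systems": list(results.get("systems", [])),
        "frame_counts": dict(results.get("frame_counts", {})),
        "kmedoids_scan": scan_rows,
        "contingency": {} if cont is None else {
            str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in cont.iterrows()
        },
        "coordination": results.get("solvation", {}),
        "pathways": []
        if pathways_stats is None
        else json.loads(pathways_stats.to_json(orient="records")),
    }
    validate_report(obj)
    (outdir / "report.json").write_text(json.dumps(obj, indent=1))
    return obj
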