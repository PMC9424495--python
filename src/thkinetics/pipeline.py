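"""End-to-end orchestration: simulate/ingest -> preprocess -> kinetics ->
differential kinetics -> hybrid decomposition -> enrichment -> exploration.

A :class:`PipelineConfig` (flat YAML file or constructed in Python) drives
:func:`run_full_analysis`, which executes the stages in dependency order,
writes every result table as TSV with a provenance header, and records a
:class:`RunManifest` of parameters, row counts, wall times and SHA-256
digests — reruns with the same config and seed reproduce every output
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, explore, hybrid, kinetics, preprocess
from .data_io import (ExpressionMatrix, ProbeMap, SampleDesign,
                      collapse_probes_to_genes, read_expression_matrix,
                      read_gmt, read_sample_design, write_result_table)
from .enrichment import run_ora
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "validate_config",
           "run_full_analysis", "load_config"]


@dataclass
class PipelineConfig:
    """All parameters of one pipeline run (flat, with per-stage fields)."""

    out_dir: str = "thkinetics_out"
    seed: int = 0
    # input: either simulate=True (synthetic data) or paths to TSVs
    simulate: bool = True
    expression_path: str | None = None
    design_path: str | None = None
    probe_map_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # preprocessing
    normalize: bool = False
    apply_expression_filter: bool = False
    reference_time: float = 0.0
    # kinetic genes
    degree: int = 3
    alpha: float = 0.05
    k_clusters: int = 3
    linkage: str = "complete"
    fc_threshold: float = 1.0
    fc_consecutive: int = 2
    fc_two_sided: bool = True
    # differential kinetics
    pairs: list[str] = field(default_factory=lambda: ["Th1:Th2"])
    reference_condition: str = "Th0"
    index_threshold: float = 0.3
    # hybrid decomposition
    hybrid_target: str = "Th12"
    hybrid_alpha: float = 0.05
    hybrid_center: bool = True
    # enrichment
    enrich_min_size: int = 3
    enrich_max_size: int = 1000
    enrich_fdr: float = 0.1
    # exploration
    n_components: int = 4
    r_threshold: float = 0.9
    divergence_fraction: float = 0.2
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a flat YAML file (simulation: subsection)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    if sim_raw:
        for key in ("times", "conditions"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        raw["simulation"] = SimulationConfig(**sim_raw)
    return PipelineConfig(**raw)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return the aggregated list of configuration errors (empty = valid)."""
    errors: list[str] = []
    if not 0 < cfg.alpha < 1:
        errors.append(f"alpha must lie in (0, 1), got {cfg.alpha}")
    if not 0 < cfg.hybrid_alpha < 1:
        errors.append(f"hybrid_alpha must lie in (0, 1), got {cfg.hybrid_alpha}")
    if not 0 <= cfg.index_threshold <= 2:
        errors.append(f"index_threshold must lie in [0, 2], got {cfg.index_threshold}")
    if cfg.degree < 1:
        errors.append("polynomial degree must be >= 1")
    if cfg.k_clusters < 2:
        errors.append("k_clusters must be >= 2")
    if cfg.linkage not in ("complete", "average", "single", "ward"):
        errors.append(f"unknown linkage {cfg.linkage!r}")
    if not 0 < cfg.divergence_fraction < 1:
        errors.append("divergence_fraction must lie in (0, 1)")
    if cfg.simulate:
        conditions = list(cfg.simulation.conditions)
    else:
        for name in ("expression_path", "design_path"):
            p = getattr(cfg, name)
            if not p:
                errors.append(f"{name} required when simulate is false")
            elif not Path(p).exists():
                errors.append(f"{name} does not exist: {p}")
        conditions = None
    for path in cfg.gmt_paths:
        if not Path(path).exists():
            errors.append(f"GMT file does not exist: {path}")
    if conditions is not None:
        for pair in cfg.pairs:
            parts = pair.split(":")
            if len(parts) != 2:
                errors.append(f"pair {pair!r} is not of the form A:B")
                continue
            for c in parts:
                if c not in conditions:
                    errors.append(f"pair {pair!r} names unknown condition {c!r}")
        if cfg.hybrid_target not in conditions:
            errors.append(f"hybrid_target {cfg.hybrid_target!r} not among "
                          f"conditions {conditions}")
        if cfg.reference_condition not in conditions:
            errors.append(f"reference_condition {cfg.reference_condition!r} "
                          f"not among conditions {conditions}")
    return errors


@dataclass
class RunManifest:
    """Per-stage record of parameters, outputs, digests and timings."""

    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, t0: float, outputs: dict[str, Path],
               **info) -> None:
        entry = {"wall_time_s": round(time.perf_counter() - t0, 3), **info,
                 "outputs": {}}
        for label, path in outputs.items():
            entry["outputs"][label] = {
                "path": str(path),
                "sha256": _sha256(path),
                "n_rows": _count_rows(path),
            }
        self.stages[stage] = entry

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if not line.startswith("#")) - 1


def run_full_analysis(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage of the analysis and write all outputs.

    The qualitative Th1-vs-Th2 DEG feed the hybrid decomposition
    automatically; if no qualitative DEG exist (e.g. on a null dataset)
    the hybrid stage is skipped gracefully and noted in the manifest.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed)
    prov = {"seed": cfg.seed}

    # ---- stage: input -----------------------------------------------------
    t0 = time.perf_counter()
    if cfg.simulate:
        from dataclasses import replace
        sim_cfg = replace(cfg.simulation, seed=cfg.seed)
        matrix, design, truth = simulate_dataset(sim_cfg)
        truth_path = out_dir / "ground_truth.tsv"
        write_result_table(truth.table, truth_path, step="simulate",
                           parameters={"n_genes": sim_cfg.n_genes}, **prov)
        expr_path = out_dir / "expression.tsv"
        from .data_io import write_expression_matrix
        write_expression_matrix(matrix, expr_path)
        design_path = out_dir / "design.tsv"
        design.table.to_csv(design_path, sep="\t", index=False)
        manifest.record("input", t0, {"expression": expr_path,
                                      "design": design_path,
                                      "ground_truth": truth_path},
                        mode="simulate", n_genes=matrix.shape[0])
    else:
        matrix = read_expression_matrix(cfg.expression_path)
        design = read_sample_design(cfg.design_path)
        if cfg.probe_map_path:
            pm = pd.read_csv(cfg.probe_map_path, sep="\t")
            probe_map = ProbeMap(dict(zip(pm.iloc[:, 0], pm.iloc[:, 1])))
            matrix = collapse_probes_to_genes(matrix, probe_map)
        manifest.record("input", t0, {}, mode="load",
                        n_genes=matrix.shape[0])

    # ---- stage: preprocess ------------------------------------------------
    t0 = time.perf_counter()
    if cfg.normalize:
        matrix = preprocess.quantile_normalize(matrix)
    if cfg.apply_expression_filter:
        matrix, report = preprocess.filter_expressed(matrix, design)
        logger.info("expression filter: %d -> %d genes",
                    report.n_input, report.n_retained)
    fc_table = preprocess.log2_fold_change(matrix, design,
                                           reference_time=cfg.reference_time)
    fc_path = out_dir / "fold_changes.tsv"
    write_result_table(fc_table, fc_path, step="preprocess",
                       parameters={"reference_time": cfg.reference_time}, **prov)
    manifest.record("preprocess", t0, {"fold_changes": fc_path},
                    n_genes=matrix.shape[0])

    # ---- stage: kinetics --------------------------------------------------
    t0 = time.perf_counter()
    fits = pd.concat([
        kinetics.fit_condition_polynomials(matrix, design, c, degree=cfg.degree)
        for c in design.conditions], ignore_index=True)
    flags = kinetics.foldchange_rule(
        fc_table, threshold_log2=cfg.fc_threshold,
        consecutive=cfg.fc_consecutive, two_sided=cfg.fc_two_sided,
        reference_time=cfg.reference_time)
    calls, union = kinetics.call_kinetic_genes(fits, flags, alpha=cfg.alpha)
    calls_path = out_dir / "kinetic_calls.tsv"
    write_result_table(calls, calls_path, step="kinetics",
                       parameters={"alpha": cfg.alpha, "degree": cfg.degree},
                       **prov)
    assignments = {}
    cluster_frames = []
    for cond in design.conditions:
        kin = list(calls.loc[(calls["condition"] == cond) & calls["kinetic"],
                             "gene_id"])
        if len(kin) < cfg.k_clusters:
            logger.warning("condition %s: %d kinetic genes < k=%d, skipping "
                           "clustering", cond, len(kin), cfg.k_clusters)
            continue
        ca = kinetics.cluster_profiles(matrix, design, kin, cond,
                                       k=cfg.k_clusters, linkage=cfg.linkage)
        assignments[cond] = ca
        cluster_frames.append(pd.DataFrame({
            "gene_id": ca.labels.index, "condition": cond,
            "cluster": ca.labels.values,
            "archetype": [ca.archetypes[c] for c in ca.labels.values]}))
    clusters_path = out_dir / "clusters.tsv"
    write_result_table(
        pd.concat(cluster_frames, ignore_index=True) if cluster_frames
        else pd.DataFrame(columns=["gene_id", "condition", "cluster",
                                   "archetype"]),
        clusters_path, step="kinetics.cluster",
        parameters={"k": cfg.k_clusters, "linkage": cfg.linkage}, **prov)
    manifest.record("kinetics", t0, {"calls": calls_path,
                                     "clusters": clusters_path},
                    n_kinetic_union=len(union))

    # ---- stage: differential kinetics -------------------------------------
    t0 = time.perf_counter()
    qualitative_th1_th2: list[str] = []
    deg_outputs: dict[str, Path] = {}
    if union:
        gm = differential.fit_group_model(
            matrix, design, union, degree=cfg.degree,
            reference=cfg.reference_condition, alpha=cfg.alpha)
        for pair_str in cfg.pairs:
            a, b = pair_str.split(":")
            contr = differential.contrast_test(gm, (a, b))
            corr = differential.correlation_index_table(
                matrix, design, gm.genes, (a, b))
            contr = contr.merge(corr[["gene_id", "pearson_r",
                                      "correlation_index"]], on="gene_id")
            contr = differential.qualitative_deg(
                contr, index_threshold=cfg.index_threshold)
            if a in assignments and b in assignments:
                cond_calls = {c: calls[calls["condition"] == c]
                              for c in (a, b)}
                switches = kinetics.detect_cluster_switches(
                    cond_calls[a], assignments[a], cond_calls[b],
                    assignments[b])
            else:
                switches = None
            volcano = differential.build_volcano_table(
                calls, contr, (a, b), switches=switches)
            tag = f"{a}_vs_{b}"
            p1 = out_dir / f"contrast_{tag}.tsv"
            write_result_table(contr, p1, step=f"deg.{tag}",
                               parameters={"alpha": cfg.alpha,
                                           "index_threshold": cfg.index_threshold},
                               **prov)
            p2 = out_dir / f"volcano_{tag}.tsv"
            write_result_table(volcano, p2, step=f"deg.volcano.{tag}", **prov)
            deg_outputs[f"contrast_{tag}"] = p1
            deg_outputs[f"volcano_{tag}"] = p2
            if {a, b} == {"Th1", "Th2"}:
                qualitative_th1_th2 = list(
                    contr.loc[contr["qualitative_deg"], "gene_id"])
    manifest.record("differential", t0, deg_outputs,
                    n_qualitative_th1_th2=len(qualitative_th1_th2))

    # ---- stage: hybrid decomposition --------------------------------------
    t0 = time.perf_counter()
    if qualitative_th1_th2:
        fit_table, fractions = hybrid.decompose_all(
            matrix, design, qualitative_th1_th2, target=cfg.hybrid_target,
            alpha=cfg.hybrid_alpha, center=cfg.hybrid_center)
        p1 = out_dir / "hybrid_fits.tsv"
        write_result_table(fit_table, p1, step="hybrid",
                           parameters={"target": cfg.hybrid_target,
                                       "alpha": cfg.hybrid_alpha}, **prov)
        p2 = out_dir / "hybrid_fractions.tsv"
        write_result_table(fractions.as_frame(), p2, step="hybrid.fractions",
                           **prov)
        manifest.record("hybrid", t0, {"fits": p1, "fractions": p2},
                        n_analyzed=fractions.n_analyzed)
    else:
        logger.warning("hybrid stage skipped: no qualitative Th1-vs-Th2 DEG")
        manifest.record("hybrid", t0, {}, skipped=True,
                        reason="no qualitative Th1-vs-Th2 DEG")

    # ---- stage: enrichment -------------------------------------------------
    t0 = time.perf_counter()
    enrich_outputs: dict[str, Path] = {}
    if cfg.gmt_paths and qualitative_th1_th2:
        collection = read_gmt(cfg.gmt_paths[0])
        for extra in cfg.gmt_paths[1:]:
            collection = collection.merged(read_gmt(extra))
        ora = run_ora(qualitative_th1_th2, matrix.gene_ids, collection,
                      min_size=cfg.enrich_min_size,
                      max_size=cfg.enrich_max_size, fdr=cfg.enrich_fdr)
        p = out_dir / "enrichment.tsv"
        write_result_table(ora, p, step="enrichment",
                           parameters={"fdr": cfg.enrich_fdr}, **prov)
        enrich_outputs["enrichment"] = p
    manifest.record("enrichment", t0, enrich_outputs,
                    skipped=not bool(enrich_outputs))

    # ---- stage: exploration -------------------------------------------------
    t0 = time.perf_counter()
    reduced, removed = explore.remove_correlated_genes(
        matrix, design, r_threshold=cfg.r_threshold)
    use = reduced if reduced.shape[0] >= cfg.n_components else matrix
    pca = explore.pca_timecourse(use, design, n_components=cfg.n_components)
    traj = explore.pc_difference_trajectory(
        pca, design, reference=cfg.reference_condition)
    bif = explore.bifurcation_time(traj, fraction=cfg.divergence_fraction)
    p1 = out_dir / "pc_trajectories.tsv"
    write_result_table(traj, p1, step="explore.trajectories", **prov)
    p2 = out_dir / "bifurcation.tsv"
    write_result_table(bif, p2, step="explore.bifurcation",
                       parameters={"fraction": cfg.divergence_fraction}, **prov)
    manifest.record("explore", t0, {"trajectories": p1, "bifurcation": p2},
                    n_removed_correlated=len(removed))

    manifest.write(out_dir / "manifest.json")
    return manifest
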