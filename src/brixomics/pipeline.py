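"""End-to-end orchestration: simulate → normalize → QC → ANOVA → cluster →
enrich → cross-hyb screen → quantify, under one config and one seed.

Every stage writes plain TSV/JSON artifacts into the output directory so
any stage can be re-run or audited standalone, and the whole run is
deterministic: the same config and seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova, cluster, enrichment, preprocess, probes, quantify, synthetic
from .preprocess import ExpressionExperiment
from .synthetic import GroundTruth, OutlierSpec, SimulationConfig

logger = logging.getLogger("brixomics")
__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with the study's default thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    plant_outliers: bool = True
    normalize: bool = True
    cv_scrutiny: float = 0.5
    sd_mult: float = 1.35
    cv_exclude: float = 0.85
    alpha: float = 0.05
    k_clusters: int = 10
    cluster_max_iter: int = 50
    min_identity: float = 80.0
    min_coverage: float = 80.0
    tm_delta: float = 10.0
    n_go_terms: int = 200
    enrichment_propagate: bool = False
    probe_screen_genes: int = 500     # probe/hit simulation size
    true_ibmp_ng_L: float = 25.0
    output_dir: str = "brixomics_run"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("cv_scrutiny", "cv_exclude", "sd_mult", "tm_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_identity", "min_coverage"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        outlier_raw = sim_raw.pop("outlier_spec", {})
        sim = SimulationConfig(outlier_spec=OutlierSpec(**outlier_raw), **sim_raw)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["effect_model"] = {
            k: list(v) for k, v in d["simulation"]["effect_model"].items()}
        return d


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str = __version__
    counts: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "seed": self.seed,
                           "counts": self.counts, "results": self.results,
                           "config": self.config},
                          indent=2, sort_keys=True, default=_jsonify)

    def to_text(self) -> str:
        lines = [f"brixomics {self.version} run report (seed {self.seed})", ""]
        for section, payload in (("counts", self.counts),
                                 ("results", self.results)):
            lines.append(f"[{section}]")
            for key in sorted(payload):
                lines.append(f"  {key} = {payload[key]}")
            lines.append("")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name: str, t0: float, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, kv)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing artifacts under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.simulation.seed
    report = RunReport(config=config.to_dict(), seed=seed)

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    experiment, truth = synthetic.simulate_expression_experiment(
        config.simulation)
    if config.plant_outliers:
        experiment, outlier_truth = synthetic.plant_outliers(
            experiment, config.simulation.outlier_spec, seed)
        truth.outlier_positions = outlier_truth.outlier_positions
    experiment.to_tsv(out / "expression.tsv", out / "samples.tsv")
    report.counts["n_genes"] = len(experiment.genes)
    report.counts["n_samples"] = len(experiment.samples)
    report.counts["n_planted_outlier_values"] = len(truth.outlier_positions)
    _stage("simulate", t0, genes=len(experiment.genes),
           samples=len(experiment.samples))

    # -- normalize ---------------------------------------------------------
    t0 = time.perf_counter()
    if config.normalize:
        experiment = ExpressionExperiment(
            preprocess.quantile_normalize(experiment.values),
            experiment.design)
    _stage("normalize", t0, applied=config.normalize)

    # -- replicate QC ------------------------------------------------------
    t0 = time.perf_counter()
    experiment, qc = preprocess.apply_replicate_qc(
        experiment, cv_scrutiny=config.cv_scrutiny, sd_mult=config.sd_mult,
        cv_exclude=config.cv_exclude)
    if not qc.conservation_holds():
        raise RuntimeError("QC conservation identity violated")
    experiment.to_tsv(out / "expression_qc.tsv", out / "samples.tsv")
    qc.to_json(out / "qc_report.json")
    qc.to_tsv(out / "qc_ledger.tsv")
    report.counts.update(
        n_values_retained=qc.n_values_retained,
        n_single_removed=qc.n_single_removed,
        n_pair_removed_values=qc.n_pair_removed_values,
        n_sets_excluded=qc.n_sets_excluded)
    _stage("qc", t0, retained=qc.n_values_retained,
           excluded_sets=qc.n_sets_excluded)

    # -- ANOVA -------------------------------------------------------------
    t0 = time.perf_counter()
    table = anova.fit_two_way_anova(experiment, alpha=config.alpha)
    bx = experiment.brix_levels
    for tissue in experiment.tissues:
        contrast = anova.compute_log2_contrast(
            experiment, (bx[1], tissue), (bx[0], tissue))
        table[contrast.name] = contrast
    table.to_csv(out / "anova.tsv", sep="\t", na_rep="NA", index_label="gene")
    sig = anova.call_significant(table, alpha=config.alpha)
    for eff, genes in sig.items():
        report.counts[f"n_significant_{eff}"] = len(genes)
    report.counts["n_genes_tested"] = int((table["status"] != "dropped_degenerate"
                                           ).sum())
    _stage("anova", t0, **{f"sig_{k}": len(v) for k, v in sig.items()})

    # -- clustering --------------------------------------------------------
    t0 = time.perf_counter()
    cluster_genes = sig["interaction"] if sig["interaction"] else sig["brix"]
    report.results["clustered_effect"] = ("interaction" if sig["interaction"]
                                          else "brix")
    if len(cluster_genes) >= config.k_clusters:
        profiles = experiment.condition_means().loc[cluster_genes].dropna()
        profiles = profiles[profiles.apply(np.ptp, axis=1) > 0]
        model = cluster.kmeans_cluster(profiles, config.k_clusters,
                                       max_iter=config.cluster_max_iter,
                                       seed=seed)
        model.assignments.rename("cluster").to_csv(
            out / "clusters.tsv", sep="\t", index_label="gene")
        pd.DataFrame(model.centroids, columns=profiles.columns).to_csv(
            out / "centroids.tsv", sep="\t", index_label="cluster")
        report.counts["n_clusters"] = model.k
        report.results["cluster_sizes"] = model.sizes.tolist()
    else:
        report.counts["n_clusters"] = 0
    _stage("cluster", t0, genes=len(cluster_genes))

    # -- enrichment --------------------------------------------------------
    t0 = time.perf_counter()
    true_set = (list(truth.effects.index[truth.effects["brix"]])
                if truth.effects is not None else [])
    n_genes = len(experiment.genes)
    term_size = min(100, max(5, n_genes // 20))
    planted = {f"GO:{i:07d}": (term_size, 5.0) for i in range(3)}
    ann, go_truth = synthetic.simulate_go_annotation(
        n_genes=n_genes, n_terms=config.n_go_terms,
        planted_terms=planted, seed=seed, genes=experiment.genes,
        significant_set=true_set or None,
        term_size_range=(min(10, max(2, n_genes // 10)),
                         max(11, min(200, n_genes // 2))))
    ann.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
    truth.enriched_terms = go_truth.enriched_terms
    index = enrichment.build_annotation_index(
        ann, propagate=config.enrichment_propagate)
    enr = enrichment.enrich_gene_set(sig["brix"], index, alpha=config.alpha)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    n_enriched = int(enr["significant"].sum()) if len(enr) else 0
    report.counts["n_enriched_terms"] = n_enriched
    recovered = set(enr.loc[enr["significant"], "term"]) & \
        set(go_truth.enriched_terms) if len(enr) else set()
    report.results["planted_terms_recovered"] = len(recovered)
    _stage("enrich", t0, enriched=n_enriched)

    # -- probe specificity -------------------------------------------------
    t0 = time.perf_counter()
    probe_seqs, target_seqs, hits, probe_truth = synthetic.simulate_probe_hits(
        n_genes=config.probe_screen_genes, seed=seed, tm_delta=config.tm_delta)
    synthetic.write_fasta(probe_seqs, out / "probes.fasta")
    synthetic.write_fasta(target_seqs, out / "targets.fasta")
    hits.to_csv(out / "hits.tsv", sep="\t", index=False, header=False)
    truth.crosshyb_genes = probe_truth.crosshyb_genes
    phits = probes.build_probe_hits(hits, probe_seqs, target_seqs)
    retained = probes.filter_hits(phits, config.min_identity,
                                  config.min_coverage)
    pm = {}
    for pid, seq in probe_seqs.items():
        pm.setdefault(pid.rsplit("_p", 1)[0], []).append(
            probes.compute_tm(seq, seq))
    calls = probes.classify_cross_hyb(
        [h for h in retained if h.probe_gene != h.target_gene], pm,
        delta=config.tm_delta)
    probes.calls_to_frame(calls).to_csv(out / "crosshyb_calls.tsv", sep="\t",
                                        index=False)
    flags, n_flagged = probes.flag_genes(calls)
    flags.rename("flagged").to_csv(out / "flagged_genes.tsv", sep="\t",
                                   index_label="gene")
    report.counts["n_crosshyb_flagged_genes"] = n_flagged
    _stage("crosshyb", t0, flagged=n_flagged)

    # -- metabolite quantification -----------------------------------------
    t0 = time.perf_counter()
    sa_table, sa_truth = synthetic.simulate_standard_addition(
        true_conc=config.true_ibmp_ng_L, seed=seed)
    sa_table.to_csv(out / "standard_addition.tsv", sep="\t", index=False)
    truth.true_concentration = sa_truth.true_concentration
    fit = quantify.fit_standard_addition(sa_table["spike_ng_L"],
                                         sa_table["ratio"])
    fruit = quantify.correct_dilution(fit.estimated_conc)
    report.results["supernatant_ng_L"] = round(fit.estimated_conc, 4)
    report.results["fruit_ng_L"] = round(fruit, 4)
    report.results["standard_addition_r2"] = round(fit.r_squared, 6)

    # transcript-metabolite correlation: pulp profile of the strongest
    # decreasing gene against a ripening-declining metabolite series
    decreasing = (truth.archetype == "monotone_decrease"
                  ) if truth.archetype is not None else None
    if decreasing is not None and decreasing.any():
        gene = truth.archetype.index[decreasing][0]
        pulp_means = [experiment.values[
            experiment.condition_samples(bx, "pulp")].loc[gene].mean()
            for bx in experiment.brix_levels]
        ibmp = config.true_ibmp_ng_L * np.linspace(1.0, 0.2,
                                                   len(pulp_means))
        r, ci, p = quantify.correlate_transcript_metabolite(pulp_means, ibmp)
        report.results["transcript_metabolite_r"] = round(r, 4)
        report.results["transcript_metabolite_ci"] = [round(c, 4) for c in ci]
    _stage("quantify", t0, fruit_ng_L=round(fruit, 3))

    truth.to_json(out / "ground_truth.json")
    write_report(report, out)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
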