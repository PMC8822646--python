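"""End-to-end orchestration: validated config in, reproducible tables out.

``run_full_study`` sequences the whole analysis — normalization, adjusted
clustering, DEG counts per Ashcroft stratum, per-patient expression
diversity, the integrated and per-case fold-change rankings, the
inhibitor-subpanel profile, and the weighted-voting severity classifier —
writing every artifact as a delimiter-separated table plus a JSON manifest
(config echo, config hash, seed, library versions). Given the same config
and seed the result tables are byte-identical.
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
from .cluster import DISTANCES, LINKAGES, adjust_matrix, cluster_samples
from .differential import TEST_MODES, deg_count_table, rank_upregulated
from .diversity import compute_diversity, test_group_diversity
from .normalize import (compute_rpkm, filter_inhibitor_subpanel,
                        write_expression_matrix)
from .panel import (GROUP_IPF, GenePanel, SampleSheet, ValidationError,
                    read_count_matrix, write_count_matrix, write_result_table)
from .simulate import default_study_config, simulate_dataset
from .voting import SCALES, evaluate_model, fit_model, score_samples

log = logging.getLogger("ipfkinome")


@dataclasses.dataclass
class RunConfig:
    """Resolved options for a full pipeline run; every field has a default."""

    counts_path: str | None = None
    sample_sheet_path: str | None = None
    gene_panel_path: str | None = None
    simulate: bool = False
    outdir: str = "results"
    seed: int = 0
    sep: str = "\t"
    # normalization
    sd_mode: str = "per_gene"
    sd_ddof: int = 0
    log_pseudocount: float = 1.0
    subpanel_summary: str = "median"
    # clustering
    distance: str = "uncentered_correlation"
    linkage: str = "average"
    cut_k: int = 2
    # diversity
    diversity_summary: str = "median"
    # differential
    epsilon: float = 0.1
    test_mode: str = "welch"
    top_k: int = 10
    # weighted voting
    voting_training_patient: str | None = None
    voting_threshold: float = 1.0
    voting_scale: str = "log2"
    voting_log_pseudocount: float = 0.1

    def validate(self) -> None:
        if self.distance not in DISTANCES:
            raise ValidationError(f"unknown distance: {self.distance!r}")
        if self.linkage not in LINKAGES:
            raise ValidationError(f"unknown linkage: {self.linkage!r}")
        if self.test_mode not in TEST_MODES:
            raise ValidationError(f"unknown test mode: {self.test_mode!r}")
        if self.voting_scale not in SCALES:
            raise ValidationError(f"unknown voting scale: {self.voting_scale!r}")
        if self.sd_mode not in ("per_gene", "pooled"):
            raise ValidationError(f"unknown sd_mode: {self.sd_mode!r}")
        if self.diversity_summary not in ("median", "upper_quartile", "mean"):
            raise ValidationError(
                f"unknown diversity summary: {self.diversity_summary!r}")
        if self.subpanel_summary not in ("median", "mean"):
            raise ValidationError(
                f"unknown subpanel summary: {self.subpanel_summary!r}")
        if self.cut_k < 1:
            raise ValidationError("cut_k must be >= 1")
        if not self.simulate:
            for name in ("counts_path", "sample_sheet_path", "gene_panel_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(
                        f"{name} required unless simulate=true")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_full_study(config: RunConfig) -> dict[str, str]:
    """Run every stage in order; returns a name -> path artifact map.

    The whole configuration is validated before any computation starts; a
    stage failure aborts with the stage name while preserving the artifacts
    already written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}

    def emit(name: str, fname: str, table: pd.DataFrame, sort_by=None,
             ascending=False, comment=None, index=True) -> None:
        path = outdir / fname
        write_result_table(table, path, sep=config.sep, sort_by=sort_by,
                           ascending=ascending, header_comment=comment,
                           index=index)
        artifacts[name] = str(path)

    stage = "load inputs"
    try:
        if config.simulate:
            sim_cfg = default_study_config(seed=config.seed)
            ds = simulate_dataset(sim_cfg)
            counts, sheet, panel = ds.counts, ds.sheet, ds.panel
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            write_count_matrix(counts, inputs / "counts.tsv", sep=config.sep)
            sheet.write(inputs / "sample_sheet.tsv", sep=config.sep)
            panel.write(inputs / "gene_panel.tsv", sep=config.sep)
            truth = ds.truth.to_frame()
            if len(truth):
                emit("ground_truth", "inputs/ground_truth.tsv", truth,
                     comment="planted effect genes of the simulated study")
            artifacts.update(counts=str(inputs / "counts.tsv"),
                             sample_sheet=str(inputs / "sample_sheet.tsv"),
                             gene_panel=str(inputs / "gene_panel.tsv"))
        else:
            counts = read_count_matrix(config.counts_path, sep=config.sep)
            sheet = SampleSheet.read(config.sample_sheet_path, sep=config.sep)
            panel = GenePanel.read(config.gene_panel_path, sep=config.sep)
        missing = [s for s in sheet.samples if s not in counts.samples]
        if missing:
            raise ValidationError(
                f"sample sheet sample(s) absent from counts: {missing}")

        stage = "normalization"
        expr = compute_rpkm(counts, panel)
        write_expression_matrix(expr, outdir / "rpkm.tsv", sep=config.sep)
        artifacts["rpkm"] = str(outdir / "rpkm.tsv")

        stage = "clustering"
        adj = adjust_matrix(expr, sd_mode=config.sd_mode, ddof=config.sd_ddof)
        if adj.dropped_genes:
            log.info("clustering: dropped %d zero-variance gene(s)",
                     len(adj.dropped_genes))
        dend = cluster_samples(adj, distance=config.distance,
                               linkage=config.linkage)
        (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        artifacts["dendrogram_newick"] = str(outdir / "dendrogram.nwk")
        emit("merge_table", "dendrogram_merges.tsv", dend.merge_table(),
             comment=[f"distance: {config.distance}",
                      f"linkage: {config.linkage}"])
        labels = dend.cut(config.cut_k).to_frame()
        emit("cluster_labels", "cluster_labels.tsv", labels,
             comment=f"flat labels at k={config.cut_k}")

        stage = "DEG counts"
        degs = deg_count_table(expr, sheet, epsilon=config.epsilon)
        emit("deg_counts", "deg_counts.tsv", degs,
             comment=f"genes beyond twofold vs control; epsilon={config.epsilon}")

        stage = "diversity"
        report = compute_diversity(expr, sheet, sd_mode=config.sd_mode,
                                   ddof=config.sd_ddof)
        emit("diversity_long", "diversity_long.tsv", report.long,
             sort_by=["patient_id", "gene_id"], ascending=True, index=False,
             comment="per-patient per-gene scaled expression range")
        emit("diversity_summary", "diversity_patient_summary.tsv",
             report.patient_summary,
             sort_by="median", ascending=False,
             comment="patient-level diversity summaries over genes")
        try:
            gt = test_group_diversity(report, sheet,
                                      summary=config.diversity_summary)
            diversity_test = {"direction": gt.direction,
                              "statistic": gt.statistic, "p_value": gt.p_value}
        except ValidationError as exc:
            log.warning("diversity group test skipped: %s", exc)
            diversity_test = {"skipped": str(exc)}

        stage = "integrated ranking"
        ranking = rank_upregulated(expr, sheet, case=GROUP_IPF,
                                   reference="control",
                                   epsilon=config.epsilon,
                                   mode=config.test_mode)
        emit("integrated_ranking", "integrated_ranking.tsv", ranking,
             comment=[f"IPF vs control; epsilon={config.epsilon}; "
                      f"test={config.test_mode}"])

        stage = "per-case rankings"
        for p in sheet.patients:
            if sheet.group_of(p) != GROUP_IPF:
                continue
            if len(sheet.samples_of(p)) < 2:
                log.info("per-case ranking for %s skipped (single sample)", p)
                continue
            r = rank_upregulated(expr, sheet, case=p, reference="control",
                                 epsilon=config.epsilon, mode=config.test_mode,
                                 top=config.top_k)
            emit(f"ranking_{p}", f"ranking_{p}.tsv", r,
                 comment=f"top {config.top_k} upregulated genes, {p} vs control")

        stage = "inhibitor subpanel"
        sub = filter_inhibitor_subpanel(expr, panel,
                                        summary=config.subpanel_summary)
        if len(sub.excluded):
            emit("subpanel_excluded", "subpanel_excluded.tsv", sub.excluded,
                 comment=f"overall median RPKM threshold {sub.threshold:.6g}")
        ipf_s, ctl_s = sheet.ipf_samples, sheet.control_samples
        sv = sub.expression.values
        profile = pd.DataFrame({
            "ipf_mean": sv[ipf_s].mean(axis=1),
            "ipf_sem": sv[ipf_s].std(axis=1, ddof=1) / np.sqrt(len(ipf_s)),
            "control_mean": sv[ctl_s].mean(axis=1),
            "control_sem": sv[ctl_s].std(axis=1, ddof=1) / np.sqrt(len(ctl_s)),
        })
        profile.index.name = "gene_id"
        emit("subpanel_profile", "subpanel_profile.tsv", profile,
             sort_by="ipf_mean",
             comment="surviving inhibitor-subpanel genes, group mean +/- SEM")

        stage = "weighted voting"
        training = config.voting_training_patient
        if training is None:
            for p in sheet.patients:
                if sheet.group_of(p) != GROUP_IPF:
                    continue
                scores = sheet.frame.loc[sheet.samples_of(p), "ashcroft_score"]
                if (scores >= 6).sum() >= 2 and (scores < 6).sum() >= 2:
                    training = p
                    break
        voting_summary: dict = {}
        if training is None:
            log.warning("weighted voting skipped: no patient with >= 2 samples "
                        "in each Ashcroft stratum")
            voting_summary = {"skipped": "no eligible training patient"}
        else:
            model = fit_model(expr, sheet, training,
                              threshold=config.voting_threshold,
                              scale=config.voting_scale,
                              log_pseudocount=config.voting_log_pseudocount)
            model.save(outdir / "voting_model.tsv", sep=config.sep)
            artifacts["voting_model"] = str(outdir / "voting_model.tsv")
            held = [s for p in sheet.patients
                    if p != training and sheet.group_of(p) == GROUP_IPF
                    for s in sheet.samples_of(p)]
            if held:
                scores = score_samples(model, expr, held)
                scores["true_stratum"] = [sheet.stratum_of(s) for s in held]
                emit("voting_scores", "voting_scores.tsv", scores,
                     sort_by="total_score",
                     comment=f"fit on {training}; scored held-out IPF samples")
                ev = evaluate_model(scores, sheet)
                voting_summary = {
                    "training_patient": training,
                    "n_induced": len(model.induced_genes),
                    "n_suppressed": len(model.suppressed_genes),
                    "holdout_accuracy": ev.accuracy,
                }
            else:
                voting_summary = {"training_patient": training,
                                  "n_induced": len(model.induced_genes),
                                  "n_suppressed": len(model.suppressed_genes)}

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "diversity_group_test": diversity_test,
            "weighted_voting": voting_summary,
            "artifacts": sorted(artifacts),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts["manifest"] = str(outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts


#: Artifacts every complete run must contain (checked by the report command).
REQUIRED_ARTIFACTS = (
    "rpkm.tsv", "dendrogram.nwk", "dendrogram_merges.tsv", "cluster_labels.tsv",
    "deg_counts.tsv", "diversity_long.tsv", "diversity_patient_summary.tsv",
    "integrated_ranking.tsv", "subpanel_profile.tsv", "manifest.json",
)


def check_artifacts(outdir: str | Path) -> list[str]:
    """Return the required artifacts missing from a run directory."""
    outdir = Path(outdir)
    return [name for name in REQUIRED_ARTIFACTS if not (outdir / name).exists()]
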