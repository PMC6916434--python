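"""End-to-end orchestration: simulate/load -> filter -> differential
methylation -> signature classification -> aging/lifestyle rates ->
clustering -> precursor deltas, with a machine-readable JSON run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aging_lifestyle import age_hyper_probes, fit_age_rates, lifestyle_mrr, mrr
from .clustering import rpmm_cluster, select_variable_probes
from .core_io import (
    ProbeAnnotation,
    ProbeMatrix,
    SampleSheet,
    ValidationError,
    align_samples,
    filter_probes,
    write_probe_list,
)
from .cpg_classes import (
    assemble_signatures,
    partition_hyper_sets,
    reallocate_common,
    write_signature_table,
)
from .diffmeth import MethylationModel, call_dmc
from .precursor import group_delta_vs_reference, median_shift_test, paired_delta_beta
from .synthetic_data import SimConfig, TruthLabels, simulate_study, write_truth

STAGES = ("simulate", "filter", "diffmeth", "classify", "aging", "cluster", "precursor")


@dataclass
class PipelineConfig:
    """All pipeline thresholds, paths, and stage toggles.

    Thresholds default to the DMC and classification rules used throughout:
    adjusted p < 1e-4, logFC > 2, delta-beta > 0.10 for DMC calling;
    p < 0.01 and delta-beta > 0.10 for common-CpG reallocation;
    SD > 0.16 for variable-probe selection; logit clamp epsilon 1e-6.
    """

    out_dir: str = "methsig_out"
    matrix_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    seed: int = 0
    adj_p_max: float = 1e-4
    logfc_min: float = 2.0
    dbeta_min: float = 0.10
    realloc_p: float = 0.01
    realloc_dbeta: float = 0.10
    sd_min: float = 0.16
    epsilon: float = 1e-6
    max_missing_fraction: float = 0.2
    drop_sex_chroms: bool = True
    min_leaf: int = 5
    max_depth: int = 4
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        for name in ("adj_p_max", "logfc_min", "dbeta_min", "realloc_p", "realloc_dbeta",
                     "sd_min", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d.update(overrides)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def run_pipeline(
    config: PipelineConfig,
    sim_config: SimConfig | None = None,
) -> dict:
    """Execute the enabled stages in order and return the run report.

    With no input paths configured, the synthetic cohort defined by
    ``sim_config`` (default study conditions otherwise) is generated with
    the pipeline seed.  The report records counts at every stage, the full
    configuration echo, and every file written; identical config + seed
    give identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = asdict(config)
    cfg_echo["stages"] = list(config.stages)
    report: dict = {"version": __version__, "seed": config.seed, "config": cfg_echo,
                    "stages": {}, "files": []}
    stages = set(config.stages)

    def emit(path: Path) -> None:
        report["files"].append(str(path))

    truth: TruthLabels | None = None
    annotation: ProbeAnnotation | None = None
    if config.matrix_path is None:
        if "simulate" not in stages:
            raise ValidationError("no input matrix configured and simulate stage disabled")
        sim = sim_config or SimConfig(seed=config.seed)
        sim.seed = config.seed
        matrix, sheet, annotation, truth = simulate_study(sim)
        matrix.write(out / "beta_matrix.tsv")
        sheet.write(out / "sample_sheet.tsv")
        annotation.write(out / "probe_annotation.tsv")
        write_truth(truth, out / "probe_truth.tsv")
        for name in ("beta_matrix.tsv", "sample_sheet.tsv", "probe_annotation.tsv",
                     "probe_truth.tsv"):
            emit(out / name)
        report["stages"]["simulate"] = {
            "n_probes": matrix.n_probes,
            "n_samples": matrix.n_samples,
        }
    else:
        matrix = ProbeMatrix.read(config.matrix_path, "beta")
        sheet = SampleSheet.read(config.sheet_path)
        if config.annotation_path:
            annotation = ProbeAnnotation.read(config.annotation_path)
        report["stages"]["load"] = {"n_probes": matrix.n_probes, "n_samples": matrix.n_samples}

    if "filter" in stages:
        matrix, flog = filter_probes(
            matrix,
            annotation,
            drop_sex_chroms=config.drop_sex_chroms and annotation is not None,
            max_missing_fraction=config.max_missing_fraction,
        )
        matrix, sheet, alog = align_samples(matrix, sheet)
        report["stages"]["filter"] = {**flog, **alog}

    signatures = None
    hyper_non = hyper_cimp = None
    if "diffmeth" in stages:
        model = MethylationModel(
            matrix, sheet, ["HNM", "nonCIMP_CC", "CIMP_CC"], epsilon=config.epsilon
        )
        res_non = model.contrast("nonCIMP_CC", "HNM")
        res_cimp = model.contrast("CIMP_CC", "HNM")
        res_cvn = model.contrast("CIMP_CC", "nonCIMP_CC")
        res_non.write(out / "diffmeth_nonCIMP_vs_HNM.tsv")
        res_cimp.write(out / "diffmeth_CIMP_vs_HNM.tsv")
        res_cvn.write(out / "diffmeth_CIMP_vs_nonCIMP.tsv")
        for name in ("diffmeth_nonCIMP_vs_HNM.tsv", "diffmeth_CIMP_vs_HNM.tsv",
                     "diffmeth_CIMP_vs_nonCIMP.tsv"):
            emit(out / name)
        dmc_non = call_dmc(res_non, config.adj_p_max, config.logfc_min, config.dbeta_min)
        dmc_cimp = call_dmc(res_cimp, config.adj_p_max, config.logfc_min, config.dbeta_min)
        hyper_non, hyper_cimp = dmc_non.hyper, dmc_cimp.hyper
        report["stages"]["diffmeth"] = {
            "d0": model.moderation.d0 if np.isfinite(model.moderation.d0) else "inf",
            "s0_sq": model.moderation.s0_sq,
            "hyper_nonCIMP": len(dmc_non.hyper),
            "hypo_nonCIMP": len(dmc_non.hypo),
            "hyper_CIMP": len(dmc_cimp.hyper),
            "hypo_CIMP": len(dmc_cimp.hypo),
            "excluded_missing_stats": dmc_non.n_excluded_missing,
        }

    if "classify" in stages:
        if hyper_non is None:
            raise ValidationError("classify stage requires diffmeth stage")
        part = partition_hyper_sets(hyper_non, hyper_cimp)
        realloc = reallocate_common(
            part.common, res_cvn.table, p_max=config.realloc_p, dbeta_min=config.realloc_dbeta
        )
        cimp_sig, ccn_sig = assemble_signatures(part, realloc)
        signatures = {"CIMP_CpG": cimp_sig, "CCN_CpG": ccn_sig}
        write_signature_table([cimp_sig, ccn_sig], out / "signatures.tsv")
        write_probe_list(cimp_sig.probes, out / "CIMP_CpG.txt")
        write_probe_list(ccn_sig.probes, out / "CCN_CpG.txt")
        if annotation is not None:
            annotation.write_bed(out / "CIMP_CpG.bed", cimp_sig.probes)
            annotation.write_bed(out / "CCN_CpG.bed", ccn_sig.probes)
        for name in ("signatures.tsv", "CIMP_CpG.txt", "CCN_CpG.txt"):
            emit(out / name)
        report["stages"]["classify"] = {
            "nonCIMP_specific": len(part.nonCIMP_specific),
            "CIMP_specific": len(part.CIMP_specific),
            "common": len(part.common),
            "common_reallocated": len(realloc),
            "CIMP_CpG": len(cimp_sig),
            "CCN_CpG": len(ccn_sig),
            "hyper_union": len(hyper_non | hyper_cimp),
        }

    if "aging" in stages and signatures is not None:
        hnm_ids = sheet.samples_in_group("HNM")
        hnm = matrix.subset(samples=hnm_ids)
        hnm_meta = sheet.subset(hnm_ids).data
        ages = hnm_meta["age"].to_numpy(dtype=float)
        ccn_probes = sorted(signatures["CCN_CpG"].probes)
        cimp_probes = sorted(signatures["CIMP_CpG"].probes)
        aging_report: dict = {}
        if ccn_probes and cimp_probes:
            rates_ccn = fit_age_rates(hnm, ages, ccn_probes, stratum="CCN_CpG")
            rates_cimp = fit_age_rates(hnm, ages, cimp_probes, stratum="CIMP_CpG")
            rates_ccn.write(out / "age_rates_CCN.tsv")
            rates_cimp.write(out / "age_rates_CIMP.tsv")
            emit(out / "age_rates_CCN.tsv")
            emit(out / "age_rates_CIMP.tsv")
            res = mrr(rates_ccn, rates_cimp)
            aging_report["mrr_ccn_vs_cimp"] = res.mrr
            aging_report["mrr_p"] = res.p_value
            age_set = age_hyper_probes(hnm, ages)
            aging_report["n_age_hyper"] = len(age_set)
            from .cpg_classes import enrichment_or

            enr = enrichment_or(set(ccn_probes), age_set, set(matrix.probe_ids))
            aging_report["age_enrichment_or_ccn"] = enr.odds_ratio
            aging_report["age_enrichment_p_ccn"] = enr.p_value
            for exposure, col in (("aspirin", "aspirin_user"), ("hrt", "hrt_user")):
                try:
                    lres = lifestyle_mrr(hnm, ages, hnm_meta[col].to_numpy(), ccn_probes)
                    aging_report[f"mrr_{exposure}"] = lres.mrr
                    aging_report[f"mrr_{exposure}_p"] = lres.p_value
                except ValidationError as exc:
                    aging_report[f"mrr_{exposure}"] = f"skipped: {exc}"
        report["stages"]["aging"] = aging_report

    if "cluster" in stages:
        cc_ids = sheet.samples_in_group("nonCIMP_CC") + sheet.samples_in_group("CIMP_CC")
        cluster_report: dict = {}
        if len(cc_ids) >= 2 * config.min_leaf:
            cc = matrix.subset(samples=cc_ids)
            var_probes = select_variable_probes(cc, config.sd_min)
            cluster_report["variable_probes"] = len(var_probes)
            if len(var_probes) >= 2:
                tree = rpmm_cluster(
                    cc.subset(probes=var_probes),
                    min_leaf=config.min_leaf,
                    max_depth=config.max_depth,
                    seed=config.seed,
                )
                tree.to_json(out / "cluster_tree.json")
                tree.write_assignments(out / "cluster_assignments.tsv")
                emit(out / "cluster_tree.json")
                emit(out / "cluster_assignments.tsv")
                cluster_report["n_leaves"] = len(tree.leaves)
        report["stages"]["cluster"] = cluster_report

    if "precursor" in stages and signatures is not None:
        prec_report: dict = {}
        cimp_probes = sorted(signatures["CIMP_CpG"].probes)
        if cimp_probes:
            for group in ("TA", "SSAP"):
                if sheet.pairs(group):
                    pd_res = paired_delta_beta(matrix, sheet, group, cimp_probes, "CIMP_CpG")
                    pd_res.write(out / f"paired_delta_{group}.tsv")
                    emit(out / f"paired_delta_{group}.tsv")
                    shift = median_shift_test(pd_res.deltas.to_numpy())
                    prec_report[f"{group}_cimp_delta_median"] = shift.median
                    prec_report[f"{group}_cimp_delta_p"] = shift.p_value
            for group in ("nonCIMP_CC", "CIMP_CC"):
                delta = group_delta_vs_reference(matrix, sheet, group, "HNM", cimp_probes)
                prec_report[f"{group}_cimp_delta_median"] = float(delta.median())
        report["stages"]["precursor"] = prec_report

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
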