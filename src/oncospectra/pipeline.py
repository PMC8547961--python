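"""End-to-end study orchestration.

Stage order is fixed: preprocess -> outlier QC -> covariate matching ->
cross-validated SVM evaluation -> per-wavenumber statistics. QC runs before
matching so that references are not wasted on spectra that are later
removed; matching happens once per clinical question on the retained cohort
(it uses only covariates, never spectra, so it cannot leak spectral
information into the cross-validation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, matching, outliers, stats
from .preprocess import PreprocessConfig, apply_pipeline, fig_variants
from .spectra import CohortSet
from .synthetic import (DiseaseSignature, SimConfig, default_disease_signature,
                        generate_cohort, generate_multigroup_cohort)

__all__ = ["StudyConfig", "StudyReport", "run_binary_study",
           "run_multiclass_study", "run_stage_comparison"]

log = logging.getLogger("oncospectra")


@dataclass
class StudyConfig:
    sim: SimConfig | None = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lof_k: int = 20
    lof_cutoff: float | None = 1.5
    lof_top_fraction: float | None = None
    do_qc: bool = True
    caliper_sd_mult: float = 0.2
    match_ratio: int = 1
    do_matching: bool = True
    folds: int = 10
    repeats: int = 10
    svm_c: float = 100.0  # unit-norm spectra need a large soft-margin C
    seed: int = 0
    case_label: str = "case"
    ref_label: str = "reference"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        pre = raw.pop("preprocess", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim) if isinstance(sim, dict) else None
        if pre is not None:
            cfg.preprocess = PreprocessConfig(**pre)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyReport:
    n_before_qc: int
    n_after_qc: int
    n_matched: dict
    balance: pd.DataFrame | None
    evaluation: classify.CVEvaluation | None
    confusion: classify.ConfusionSummary | None
    wn_stats: stats.WavenumberStats | None
    area_abs_diff: float | None
    provenance: dict

    def summary(self) -> dict:
        out = {
            "n_before_qc": self.n_before_qc,
            "n_after_qc": self.n_after_qc,
            "n_matched": self.n_matched,
        }
        if self.balance is not None:
            out["balance"] = self.balance.round(4).to_dict()
        if self.evaluation is not None:
            ev = self.evaluation
            out.update(auc_mean=round(ev.auc_mean, 4),
                       auc_sd=round(ev.auc_sd, 4),
                       pooled_auc=round(ev.pooled_auc, 4),
                       sensitivity=round(ev.operating_point.sensitivity, 4),
                       specificity=round(ev.operating_point.specificity, 4),
                       sens_at_95spec=round(ev.sens_at_95spec, 4))
        if self.confusion is not None:
            c = self.confusion
            out.update(
                overall_accuracy_mean=round(c.overall_accuracy_mean, 4),
                overall_accuracy_sd=round(c.overall_accuracy_sd, 4),
                per_class_accuracy={k: round(v, 4)
                                    for k, v in c.per_class_accuracy.items()})
        if self.area_abs_diff is not None:
            out["area_abs_diff"] = round(self.area_abs_diff, 6)
        out["provenance"] = self.provenance
        return out

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "report.json").write_text(json.dumps(self.summary(), indent=2,
                                                  default=str))
        lines = [f"{k}: {v}" for k, v in self.summary().items()]
        (d / "report.txt").write_text("\n".join(lines) + "\n")
        if self.wn_stats is not None:
            self.wn_stats.to_frame().to_csv(d / "wavenumber_stats.csv",
                                            index=False)
        if self.evaluation is not None:
            self.evaluation.pooled_roc.to_csv(d / "roc.csv", index=False)
        if self.confusion is not None:
            self.confusion.counts.to_csv(d / "confusion.csv")


# ----------------------------------------------------------------- QC + match
def _qc_stage(cohort: CohortSet, cfg: StudyConfig) -> CohortSet:
    if not cfg.do_qc:
        return cohort
    feats = outliers.qc_features(cohort, cfg.preprocess)
    res = outliers.lof_scores(feats, k=min(cfg.lof_k, len(feats) - 1))
    flagged = outliers.flag_outliers(res, cutoff=cfg.lof_cutoff,
                                     top_fraction=cfg.lof_top_fraction)
    keep = cohort.sample_ids.difference(flagged)
    log.info("QC removed %d of %d spectra", len(flagged),
             len(cohort.sample_ids))
    return cohort.subset(keep)


def _match_stage(cohort: CohortSet, cfg: StudyConfig, case_label: str):
    if not cfg.do_matching:
        return cohort, None
    meta = cohort.meta.copy()
    meta["group"] = np.where(meta["group"] == case_label, "case", "reference")
    match, balance = matching.match_cohort(
        meta, caliper_sd_mult=cfg.caliper_sd_mult, k=cfg.match_ratio)
    return cohort.subset(match.matched_ids), balance


# -------------------------------------------------------------------- studies
def run_binary_study(cfg: StudyConfig, cohort: CohortSet | None = None,
                     signature: DiseaseSignature | None = None,
                     outdir=None) -> StudyReport:
    """Simulate (or take) a cohort, then preprocess, QC, match, evaluate and
    compute spectral statistics for one binary clinical question."""
    if cohort is None:
        if cfg.sim is None:
            raise ValueError("no cohort given and no simulation configured")
        cohort, _ = generate_cohort(cfg.sim, signature=signature,
                                    case_label=cfg.case_label,
                                    ref_label=cfg.ref_label)
    n0 = len(cohort.sample_ids)
    cohort = _qc_stage(cohort, cfg)
    n1 = len(cohort.sample_ids)
    cohort, balance = _match_stage(cohort, cfg, cfg.case_label)
    feats = apply_pipeline(cohort, cfg.preprocess)

    y = (feats.meta["group"] == cfg.case_label).astype(int).to_numpy()
    n_matched = {cfg.case_label: int(y.sum()),
                 cfg.ref_label: int((1 - y).sum())}
    ev = classify.cv_evaluate(feats.X, y, folds=cfg.folds,
                              repeats=cfg.repeats, seed=cfg.seed, C=cfg.svm_c)
    ws = stats.compare_groups(feats.X[y == 1], feats.X[y == 0],
                              feats.wavenumbers)
    report = StudyReport(
        n_before_qc=n0, n_after_qc=n1, n_matched=n_matched,
        balance=balance, evaluation=ev, confusion=None, wn_stats=ws,
        area_abs_diff=stats.area_abs_diff(ws.delta, ws.wavenumbers),
        provenance={"config": cfg.to_dict(), "stage": "binary"})
    if outdir is not None:
        report.save(outdir)
    return report


def run_multiclass_study(cfg: StudyConfig,
                         cohort: CohortSet | None = None,
                         signatures: dict | None = None,
                         outdir=None) -> StudyReport:
    """As :func:`run_binary_study` but for >= 3 diagnosis groups, reporting
    a confusion matrix of per-class accuracies."""
    if cohort is None:
        if cfg.sim is None:
            raise ValueError("no cohort given and no simulation configured")
        if signatures is None:
            raise ValueError("multiclass simulation needs group signatures")
        cohort, _ = generate_multigroup_cohort(cfg.sim, signatures)
    groups = cohort.meta["group"].unique()
    if len(groups) < 3:
        raise ValueError("multiclass study requires at least 3 groups")
    n0 = len(cohort.sample_ids)
    cohort = _qc_stage(cohort, cfg)
    n1 = len(cohort.sample_ids)
    feats = apply_pipeline(cohort, cfg.preprocess)
    y = feats.meta["group"].to_numpy()
    conf = classify.multiclass_cv(feats.X, y, folds=cfg.folds,
                                  repeats=cfg.repeats, seed=cfg.seed,
                                  C=cfg.svm_c)
    report = StudyReport(
        n_before_qc=n0, n_after_qc=n1,
        n_matched={g: int((y == g).sum()) for g in groups},
        balance=None, evaluation=None, confusion=conf, wn_stats=None,
        area_abs_diff=None,
        provenance={"config": cfg.to_dict(), "stage": "multiclass"})
    if outdir is not None:
        report.save(outdir)
    return report


def run_stage_comparison(cfg: StudyConfig, by: str = "t_class",
                         cohort: CohortSet | None = None,
                         signature: DiseaseSignature | None = None,
                         min_cases: int | None = None) -> pd.DataFrame:
    """One binary evaluation per stratum (e.g. tumour T class) or per
    preprocessing variant.

    ``by='t_class'`` (or any metadata column) re-matches and re-evaluates
    cases of each stratum against all references; strata with fewer cases
    than the fold count are skipped with a warning. ``by='preprocessing'``
    runs the standard variants on one fixed cohort. Returns a comparison
    table (stratum, n_cases, n_refs, auc_mean, auc_sd, area_abs_diff).
    """
    if cohort is None:
        if cfg.sim is None:
            raise ValueError("no cohort given and no simulation configured")
        cohort, _ = generate_cohort(cfg.sim, signature=signature,
                                    case_label=cfg.case_label,
                                    ref_label=cfg.ref_label)
    rows = []
    if by == "preprocessing":
        for name, pre in fig_variants(cfg.preprocess).items():
            sub_cfg = replace(cfg, preprocess=pre)
            rep = run_binary_study(sub_cfg, cohort=cohort)
            rows.append({"stratum": name,
                         "n_cases": rep.n_matched[cfg.case_label],
                         "n_refs": rep.n_matched[cfg.ref_label],
                         "auc_mean": rep.evaluation.auc_mean,
                         "auc_sd": rep.evaluation.auc_sd,
                         "area_abs_diff": rep.area_abs_diff})
        return pd.DataFrame(rows)

    min_cases = cfg.folds if min_cases is None else min_cases
    is_case = cohort.meta["group"] == cfg.case_label
    strata = sorted(v for v in cohort.meta.loc[is_case, by].unique() if v)
    for stratum in strata:
        in_stratum = is_case & (cohort.meta[by] == stratum)
        n = int(in_stratum.sum())
        if n < min_cases:
            log.warning("stratum %s=%r has %d cases (< %d) - skipped",
                        by, stratum, n, min_cases)
            continue
        ids = cohort.sample_ids[in_stratum | ~is_case]
        rep = run_binary_study(cfg, cohort=cohort.subset(ids))
        rows.append({"stratum": stratum,
                     "n_cases": rep.n_matched[cfg.case_label],
                     "n_refs": rep.n_matched[cfg.ref_label],
                     "auc_mean": rep.evaluation.auc_mean,
                     "auc_sd": rep.evaluation.auc_sd,
                     "area_abs_diff": rep.area_abs_diff})
    return pd.DataFrame(rows)
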