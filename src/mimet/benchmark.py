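"""End-to-end benchmark driver.

Runs each selected pipeline — linkage-based set prediction, community
metabolic potential, or the elastic-net regression — on one paired cohort
and scores it: occurrence P/R/F1 against the measured metabolome with a
random-dictionary null, differential-metabolite P/R/F1 with the matching
label-shuffling null, and (for abundance pipelines) Procrustes similarity.
One global seed fans out to per-stage child seeds keyed by stage name, so
adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .diffstats import (
    Thresholds,
    diff_metabolites_ranksum,
    diff_metabolites_ttest,
    nb_wald_diff_functions,
    prevalence_filter,
    significant_features,
)
from .evaluation import (
    null_coverage,
    null_differential,
    occurrence_from_abundance,
    procrustes_compare,
    set_metrics,
)
from .ml import loso_predict
from .predict import compute_cmp, mangosteen_differential, mangosteen_occurrence
from .reference import ReferenceMap
from .tables import AbundanceTable, read_metadata, read_table, write_table

__all__ = ["child_seed", "run_pipeline", "run_benchmark", "metric_table"]

log = logging.getLogger("mimet")


def child_seed(seed: int, stage: str) -> int:
    """Stage-keyed child seed below 2^31, stable across runs and stages."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stage(name: str, t0: float, **dims) -> None:
    extras = " ".join(f"{k}={v}" for k, v in dims.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, extras)


def run_pipeline(
    pipeline: str,
    funcs: AbundanceTable,
    metab: AbundanceTable,
    ref: ReferenceMap,
    case: str,
    control: str,
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> dict:
    """Run one prediction pipeline end to end and evaluate it.

    Returns a JSON-ready dict with occurrence metrics + coverage null,
    differential metrics + shuffling null, and a Procrustes block for the
    abundance-valued pipelines (``cmp``, ``ml``).
    """
    th = thresholds or Thresholds()
    groups = funcs.groups(case, control)
    report: dict = {"pipeline": pipeline}

    # -- prediction -----------------------------------------------------
    t0 = time.time()
    pred_matrix: AbundanceTable | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if pipeline == "mangosteen":
            predicted_occurrence = mangosteen_occurrence(funcs, ref)
        elif pipeline == "cmp":
            pred_matrix = compute_cmp(funcs, ref)
            predicted_occurrence = occurrence_from_abundance(
                pred_matrix, th.prevalence_metabolites
            )
        elif pipeline == "ml":
            pred_matrix, _ = loso_predict(
                metab, funcs,
                seed=child_seed(seed, f"{pipeline}:loso"),
                prevalence_min=th.ml_prevalence,
                mean_relabund_min=th.ml_mean_relabund,
                min_model_size=th.min_model_size,
            )
            predicted_occurrence = occurrence_from_abundance(
                pred_matrix, th.prevalence_metabolites
            )
        else:
            raise ValueError(f"unknown pipeline {pipeline!r}")
    _stage(f"{pipeline}:predict", t0, n_predicted=len(predicted_occurrence))

    # -- occurrence evaluation ------------------------------------------
    t0 = time.time()
    measured_occurrence = occurrence_from_abundance(metab, th.prevalence_metabolites)
    occ = set_metrics(predicted_occurrence, measured_occurrence)
    k = len(predicted_occurrence)
    occ_null = None
    if 0 < k <= len(ref.dictionary):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            occ_null = null_coverage(
                ref.dictionary, k, measured_occurrence, observed=occ,
                n_null=th.n_null, seed=child_seed(seed, f"{pipeline}:coverage_null"),
            )
    report["occurrence"] = {
        "metrics": occ.to_dict(),
        "n_measured": len(measured_occurrence),
        "null": {m: d.to_dict() for m, d in occ_null.items()} if occ_null else None,
    }
    _stage(f"{pipeline}:occurrence", t0, f1=round(occ.f1, 4))

    # -- differential evaluation ----------------------------------------
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        measured_filtered = prevalence_filter(metab, th.prevalence_metabolites)
        measured_diff = significant_features(
            diff_metabolites_ttest(measured_filtered, groups, th.alpha_fdr)
        )
        if pipeline == "mangosteen":
            funcs_filtered = prevalence_filter(funcs, th.prevalence_functions)
            diff_funcs = significant_features(
                nb_wald_diff_functions(funcs_filtered, groups, th.alpha_fdr)
            )
            predicted_diff = mangosteen_differential(diff_funcs, ref)
            null = null_differential(
                "shuffle-genes", metab, groups, funcs=funcs, ref=ref,
                thresholds=th, n_null=th.n_null,
                seed=child_seed(seed, f"{pipeline}:diff_null"),
            )
        else:
            test = diff_metabolites_ranksum if pipeline == "cmp" else diff_metabolites_ttest
            pred_filtered = prevalence_filter(pred_matrix, th.prevalence_metabolites)
            predicted_diff = significant_features(
                test(pred_filtered, groups, th.alpha_fdr)
            )
            null = null_differential(
                "shuffle-metabolites", metab, groups, pred=pred_matrix,
                predicted_test="ranksum" if pipeline == "cmp" else "ttest",
                thresholds=th, n_null=th.n_null,
                seed=child_seed(seed, f"{pipeline}:diff_null"),
            )
    diff = set_metrics(predicted_diff, measured_diff)
    report["differential"] = {
        "metrics": diff.to_dict(),
        "n_measured_differential": len(measured_diff),
        "n_predicted_differential": len(predicted_diff),
        "null": {m: d.to_dict() for m, d in null.items() if m != "observed_metrics"},
    }
    _stage(f"{pipeline}:differential", t0, f1=round(diff.f1, 4))

    # -- abundance similarity -------------------------------------------
    report["procrustes"] = None
    if pred_matrix is not None:
        t0 = time.time()
        proc = procrustes_compare(
            pred_matrix, metab, n_perm=th.n_procrustes_perm,
            seed=child_seed(seed, f"{pipeline}:procrustes"),
        )
        report["procrustes"] = proc.to_dict()
        _stage(f"{pipeline}:procrustes", t0, m12sq=round(proc.m12_squared, 4))
    return report


def run_benchmark(config: RunConfig) -> dict:
    """Load inputs, run the selected pipelines, write the report.

    Emits ``report.json`` (sorted keys, so identical configs give
    byte-identical reports) plus per-pipeline metric TSVs and, for abundance
    pipelines, the predicted matrices, all under ``config.output_dir``.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref = ReferenceMap.from_json(config.reference)
    meta = read_metadata(config.metadata)
    funcs = read_table(config.functions, metadata=meta)
    metab = read_table(config.metabolites, metadata=meta)
    for label in (config.case, config.control):
        if label not in set(meta["group"]):
            raise ValueError(f"contrast label {label!r} absent from metadata groups")

    report: dict = {
        "config": config.to_dict(),
        "thresholds": config.thresholds.to_dict(),
        "pipelines": {},
    }
    rows = []
    for pipeline in config.pipelines:
        try:
            result = run_pipeline(
                pipeline, funcs, metab, ref,
                config.case, config.control,
                thresholds=config.thresholds, seed=config.seed,
            )
        except Exception as exc:  # stage-labeled failure, partial outputs kept
            _flush(report, out_dir)
            raise RuntimeError(f"pipeline {pipeline!r} failed: {exc}") from exc
        report["pipelines"][pipeline] = result
        for kind in ("occurrence", "differential"):
            m = result[kind]["metrics"]
            rows.append(
                {"pipeline": pipeline, "kind": kind, **m}
            )
    pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    _flush(report, out_dir)
    return report


def _flush(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))


def metric_table(reports: dict[str, dict], metric: str = "f1", kind: str = "occurrence") -> pd.DataFrame:
    """Pipelines x datasets frame of one metric, ready for the pairwise
    signed-rank comparison (datasets = keys of ``reports``)."""
    out: dict[str, dict[str, float]] = {}
    for dataset, report in reports.items():
        for pipeline, result in report["pipelines"].items():
            out.setdefault(pipeline, {})[dataset] = result[kind]["metrics"][metric]
    return pd.DataFrame(out).T
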