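"""End-to-end orchestration: clean → filter → split → fit → select → validate.

``run_workflow`` executes the whole pipeline behind one call:

1. load the response-first table (or take a ready :class:`Dataset`),
2. remove incomplete cases,
3. near-zero-variance filter → scaling → correlation filter,
4. repeated random train/test splits,
5. every (method, split, CV type) task: tune by minimum mean CV RMSE,
   refit, and record the standardized 17-value statistics row,
6. average per method × CV type, select the best model (tolerance band on
   mean test R², then minimal test RMSE),
7. Y-randomization of the best model on the last split,
8. applicability-domain diagnostics on the winning split's training design.

Tasks are independent; seeds derive from task identity, so the worker
count never changes any emitted number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .applicability import ADReport, assess_domain
from .dataset import Dataset, read_dataset
from .preprocess import FilterReport, ScalingParams, preprocess
from .regressors import METHOD_NAMES, FittedModel, MethodSpec, method_spec
from .resampling import CVScheme, SplitPlan, derive_seed, make_splits
from .selection import (
    MethodSummary,
    YRandResult,
    select_best_model,
    summarize_methods,
    y_randomization,
)
from .stats import STAT_COLUMNS, CVMetrics, StatRecord, evaluate_split


class WorkflowError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything that determines a run.  Defaults follow the standard recipe:

    all cleaning steps on, 10 random splits at 75% train, repeated 10-fold
    CV with 10 repeats plus LOO where a method allows it, all ten methods,
    selection tolerance 0.005, 100 Y-randomization runs.
    """

    data_path: str | None = None
    output_dir: str | None = None
    delimiter: str = ","
    drop_na: bool = True
    nzv_filter: bool = True
    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 10.0
    scaling: str = "standardize"  # none | standardize | normalize
    corr_filter: bool = True
    corr_cutoff: float = 0.9
    n_splits: int = 10
    train_fraction: float = 0.75
    cv_types: tuple = ("repeated_kfold", "loo")
    cv_folds: int = 10
    cv_repeats: int = 10
    methods: tuple = METHOD_NAMES
    tuning_overrides: dict = field(default_factory=dict)  # method -> MethodSpec kwargs
    selection_tolerance: float = 0.005
    y_randomization_runs: int = 100
    base_seed: int = 1
    workers: int = 1
    detailed_output: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise WorkflowError(f"unknown methods: {sorted(unknown)}")
        for cv in self.cv_types:
            if cv not in ("repeated_kfold", "loo"):
                raise WorkflowError(f"unknown cv type {cv!r}")

    def spec_for(self, name: str) -> MethodSpec:
        kwargs = dict(self.tuning_overrides.get(name, {}))
        grid = kwargs.pop("tuning_grid", None)
        return method_spec(name, tuning_grid=grid, **kwargs)

    def scheme_for(self, cv_type: str) -> CVScheme:
        if cv_type == "loo":
            return CVScheme("loo")
        return CVScheme("repeated_kfold", folds=self.cv_folds, repeats=self.cv_repeats)


@dataclass
class TaskResult:
    record: StatRecord
    model: FittedModel
    predictions_train: np.ndarray
    predictions_test: np.ndarray


@dataclass
class RunResult:
    dataset: Dataset  # after preprocessing
    filter_reports: list[FilterReport]
    scaling_params: ScalingParams
    splits: list[SplitPlan]
    records: list[StatRecord]
    summaries: list[MethodSummary]
    best: MethodSummary
    rationale: str
    yrand: YRandResult | None
    ad_report: ADReport | None
    tasks: dict  # (method, split_index, cv_type) -> TaskResult
    load_report: dict
    output_files: list[str] = field(default_factory=list)

    @property
    def best_method(self) -> str:
        return self.best.method


def _run_task(config: RunConfig, ds: Dataset, split: SplitPlan, method: str, cv_type: str):
    """One independent (method, split, CV type) unit of work."""
    spec = config.spec_for(method)
    scheme = config.scheme_for(cv_type)
    seed = derive_seed(config.base_seed, split.split_index, method,
                       salt=0 if cv_type == "repeated_kfold" else 1)
    train = ds.subset_rows(split.train_ids)
    test = ds.subset_rows(split.test_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, cv_metrics = tune_and_fit_cached(spec, train, scheme, seed)
        record = evaluate_split(model, train, test, cv_metrics, split.split_index, cv_type)
    return (method, split.split_index, cv_type), TaskResult(
        record=record,
        model=model,
        predictions_train=model.predict(train.X),
        predictions_test=model.predict(test.X),
    )


def tune_and_fit_cached(spec: MethodSpec, train: Dataset, scheme: CVScheme, seed: int):
    # thin indirection kept so library users can monkeypatch/instrument fits
    from .regressors import tune_and_fit

    return tune_and_fit(spec, train.X, train.y, scheme, seed=seed,
                        feature_names=train.feature_names)


def run_workflow(config: RunConfig, dataset: Dataset | None = None) -> RunResult:
    """Execute the full pipeline; see the module docstring for the steps."""
    # --- load & clean -----------------------------------------------------
    load_report: dict = {}
    if dataset is None:
        if config.data_path is None:
            raise WorkflowError("either a dataset or config.data_path is required")
        try:
            dataset, load_report = read_dataset(config.data_path, delimiter=config.delimiter)
        except Exception as exc:
            raise WorkflowError(f"step 'load dataset' failed: {exc}") from exc
    ds = dataset

    # --- preprocess -------------------------------------------------------
    try:
        ds, filter_reports, scaling_params = preprocess(
            ds,
            nzv=config.nzv_filter,
            freq_cut=config.freq_cut,
            unique_cut=config.unique_cut,
            scaling=config.scaling,
            corr_filter=config.corr_filter,
            corr_cutoff=config.corr_cutoff,
        )
    except Exception as exc:
        raise WorkflowError(f"step 'preprocess' failed: {exc}") from exc

    # --- splits -----------------------------------------------------------
    splits = make_splits(
        ds.n_cases, config.n_splits, config.train_fraction, config.base_seed
    )
    # map local row positions back to surviving case ids
    id_of = ds.case_ids
    splits = [
        SplitPlan(
            split_index=s.split_index,
            seed=s.seed,
            train_ids=id_of[s.train_ids],
            test_ids=id_of[s.test_ids],
            train_fraction=s.train_fraction,
        )
        for s in splits
    ]

    # --- per-task fits ----------------------------------------------------
    tasks = []
    for method in config.methods:
        allowed = config.spec_for(method).cv_schemes_allowed
        for cv_type in config.cv_types:
            if cv_type not in allowed:
                continue
            for split in splits:
                tasks.append((split, method, cv_type))
    if not tasks:
        raise WorkflowError("no (method, split, cv_type) tasks to run")

    if config.workers > 1:
        results = Parallel(n_jobs=config.workers)(
            delayed(_run_task)(config, ds, split, method, cv_type)
            for split, method, cv_type in tasks
        )
    else:
        results = [_run_task(config, ds, split, method, cv_type)
                   for split, method, cv_type in tasks]
    task_map = dict(results)
    records = [task_map[k].record for k in sorted(task_map)]

    # --- summaries & selection --------------------------------------------
    summaries = summarize_methods(records)
    pool = [s for s in summaries if s.cv_type == "repeated_kfold"] or summaries
    best, rationale = select_best_model(pool, tolerance=config.selection_tolerance)

    # --- Y-randomization on the best model, last split ----------------------
    yrand = None
    if config.y_randomization_runs > 0:
        last = splits[-1]
        key = (best.method, last.split_index, best.cv_type)
        observed = task_map[key].record.r2_test
        scheme = config.scheme_for(best.cv_type)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yrand = y_randomization(
                config.spec_for(best.method),
                last,
                ds,
                scheme,
                config.y_randomization_runs,
                derive_seed(config.base_seed, last.split_index, best.method, salt=97),
                observed_r2_test=observed,
            )

    # --- applicability domain on the winning split's training design -------
    best_recs = [
        (k, t) for k, t in task_map.items()
        if k[0] == best.method and k[2] == best.cv_type
    ]
    win_key, win_task = max(
        best_recs,
        key=lambda kt: (-1e9 if math.isnan(kt[1].record.r2_test) else kt[1].record.r2_test),
    )
    win_split = next(s for s in splits if s.split_index == win_key[1])
    train = ds.subset_rows(win_split.train_ids)
    ad_report = None
    sel = win_task.model.selected_features
    if sel and train.n_cases > len(sel) + 1:
        ad_report = assess_domain(
            train.subset_features(sel).X, train.y, case_ids=train.case_ids
        )

    result = RunResult(
        dataset=ds,
        filter_reports=filter_reports,
        scaling_params=scaling_params,
        splits=splits,
        records=records,
        summaries=summaries,
        best=best,
        rationale=rationale,
        yrand=yrand,
        ad_report=ad_report,
        tasks=task_map,
        load_report=load_report,
    )
    if config.output_dir is not None:
        write_outputs(result, config)
    return result


# --------------------------------------------------------------------------
# Output files


def _records_frame(records: list[StatRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records], columns=list(STAT_COLUMNS))


def _summary_frame(summaries: list[MethodSummary]) -> pd.DataFrame:
    rows = []
    for s in sorted(summaries, key=lambda s: (s.method, s.cv_type)):
        row = {"method": s.method, "cv_type": s.cv_type,
               "mean_n_features": s.mean_n_features,
               "n_splits_contributing": s.n_splits_contributing}
        row.update({k: s.means[k] for k in StatRecord.NUMERIC_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: RunResult, config: RunConfig) -> list[str]:
    """Write all standardized CSV outputs plus a manifest; returns the paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(str(path))

    emit("statistics.csv", _records_frame(result.records))
    emit("summary.csv", _summary_frame(result.summaries))

    best_rows = [{
        "best_method": result.best.method,
        "cv_type": result.best.cv_type,
        "mean_r2_test": result.best.means["r2_test"],
        "mean_rmse_test": result.best.means["rmse_test"],
        "mean_n_features": result.best.mean_n_features,
        "selection_tolerance": config.selection_tolerance,
        "yrand_runs": result.yrand.n_runs if result.yrand else 0,
        "yrand_observed_r2_test": result.yrand.observed_r2_test if result.yrand else float("nan"),
        "yrand_mean_permuted_r2": (
            float(np.mean(result.yrand.permuted_r2_test))
            if result.yrand and result.yrand.permuted_r2_test else float("nan")
        ),
        "yrand_exceedance_fraction": (
            result.yrand.exceedance_fraction if result.yrand else float("nan")
        ),
        "rationale": result.rationale.replace("\n", " | "),
    }]
    emit("best_model.csv", pd.DataFrame(best_rows))

    if result.yrand is not None:
        emit("y_randomization.csv", pd.DataFrame({
            "run": np.arange(1, len(result.yrand.permuted_r2_test) + 1),
            "permuted_r2_test": result.yrand.permuted_r2_test,
        }))

    if result.ad_report is not None:
        ad = result.ad_report
        emit("applicability_domain.csv", pd.DataFrame({
            "case_id": ad.case_ids,
            "hat": ad.hat_values,
            "high_leverage": [int(c in set(ad.high_leverage_ids)) for c in ad.case_ids],
            "cooks_d": ad.cooks_distances,
            "influential": [int(c in set(ad.influential_ids)) for c in ad.case_ids],
            "mean_hat": ad.mean_hat,
            "leverage_threshold": ad.leverage_threshold,
            "cooks_cutoff": ad.cooks_cutoff,
        }))

    filt_rows = [
        {"filter": rep.filter_name, "feature": name, "reason": reason, "diagnostic": diag}
        for rep in result.filter_reports
        for name, reason, diag in rep.removed_features
    ]
    emit("filters.csv", pd.DataFrame(filt_rows, columns=["filter", "feature", "reason", "diagnostic"]))

    split_rows = [
        {"split": s.split_index, "case_id": int(c), "role": role}
        for s in result.splits
        for role, ids in (("train", s.train_ids), ("test", s.test_ids))
        for c in ids
    ]
    emit("splits.csv", pd.DataFrame(split_rows))

    if config.detailed_output:
        det = out / "detailed"
        det.mkdir(exist_ok=True)
        for (method, split_index, cv_type), task in sorted(result.tasks.items()):
            split = next(s for s in result.splits if s.split_index == split_index)
            tag = f"{method}_{split_index}_{cv_type}".replace("-", "")
            obs = np.concatenate([
                result.dataset.subset_rows(split.train_ids).y,
                result.dataset.subset_rows(split.test_ids).y,
            ])
            pred = np.concatenate([task.predictions_train, task.predictions_test])
            df = pd.DataFrame({
                "case_id": np.concatenate([split.train_ids, split.test_ids]),
                "partition": ["train"] * len(split.train_ids) + ["test"] * len(split.test_ids),
                "observed": obs,
                "predicted": pred,
                "residual": obs - pred,
            })
            path = det / f"predictions_{tag}.csv"
            df.to_csv(path, index=False)
            written.append(str(path))
            imp = task.model.importances
            path = det / f"importance_{tag}.csv"
            pd.DataFrame({"feature": list(imp), "importance": list(imp.values())}).to_csv(
                path, index=False
            )
            written.append(str(path))

    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        fh.write("# output manifest, schema v1\n")
        for p in written:
            fh.write(f"{Path(p).relative_to(out)}\n")
    written.append(str(manifest))
    result.output_files = written
    return written
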