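"""Split-averaged summaries, best-model selection, and Y-randomization.

The selection rule: average the per-split statistics for each method and
CV type, form the candidate set of methods whose mean test R² lies within
a tolerance (default 0.005) of the best, and pick the candidate with the
lowest mean test RMSE.  Ties fall to the model with fewer features, then
to method-name order.

Y-randomization (response scrambling) guards against chance correlation:
the training responses are permuted, the model is re-tuned and refit, and
its test R² is compared with the observed one.  A genuine model should
leave every permuted run far behind.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .regressors import MethodSpec, tune_and_fit
from .resampling import CVScheme, SplitPlan
from .stats import StatRecord, r_squared


class SelectionError(ValueError):
    pass


@dataclass
class MethodSummary:
    """Across-split arithmetic means of every numeric StatRecord field."""

    method: str
    cv_type: str
    means: dict  # field name -> mean over non-missing entries
    mean_n_features: float
    n_splits_contributing: int


@dataclass
class YRandResult:
    n_runs: int
    permuted_r2_test: list[float]
    observed_r2_test: float
    exceedance_fraction: float


def summarize_methods(records: list[StatRecord]) -> list[MethodSummary]:
    """One summary per (method, cv_type); means over non-missing entries."""
    if not records:
        raise SelectionError("no records to summarize")
    groups: dict[tuple[str, str], list[StatRecord]] = {}
    for rec in records:
        groups.setdefault((rec.method, rec.cv_type), []).append(rec)
    summaries = []
    for (method, cv_type), recs in groups.items():
        means = {}
        for name in StatRecord.NUMERIC_FIELDS:
            vals = [getattr(r, name) for r in recs]
            vals = [v for v in vals if not math.isnan(v)]
            means[name] = float(np.mean(vals)) if vals else float("nan")
        summaries.append(
            MethodSummary(
                method=method,
                cv_type=cv_type,
                means=means,
                mean_n_features=float(np.mean([r.n_features for r in recs])),
                n_splits_contributing=len(recs),
            )
        )
    return summaries


def select_best_model(
    summaries: list[MethodSummary], tolerance: float = 0.005
) -> tuple[MethodSummary, str]:
    """Tolerance band on mean test R², then minimum mean test RMSE.

    Candidates: summaries with mean r2_test >= best − tolerance.  Winner:
    minimal mean rmse_test; ties broken by fewer mean features, then by
    method name.  Returns (winner, human-readable rationale).
    """
    if not summaries:
        raise SelectionError("no summaries to select from")
    if tolerance < 0:
        raise SelectionError("tolerance must be >= 0")
    scored = [s for s in summaries if not math.isnan(s.means["r2_test"])]
    if not scored:
        raise SelectionError("every summary has missing r2_test")
    best_r2 = max(s.means["r2_test"] for s in scored)
    candidates = [s for s in scored if s.means["r2_test"] >= best_r2 - tolerance]
    winner = min(
        candidates,
        key=lambda s: (s.means["rmse_test"], s.mean_n_features, s.method),
    )
    lines = [
        f"best mean R2_test = {best_r2:.6g}; tolerance band {tolerance:g}",
        "candidates (method/cv, R2_test, RMSE_test, margin to best):",
    ]
    for s in sorted(candidates, key=lambda s: s.means["rmse_test"]):
        lines.append(
            f"  {s.method}/{s.cv_type}: R2={s.means['r2_test']:.6g} "
            f"RMSE={s.means['rmse_test']:.6g} margin={best_r2 - s.means['r2_test']:.6g}"
        )
    lines.append(
        f"selected {winner.method} ({winner.cv_type}) by minimal RMSE_test within the band"
    )
    return winner, "\n".join(lines)


def y_randomization(
    spec: MethodSpec,
    split: SplitPlan,
    ds: Dataset,
    scheme: CVScheme,
    n_runs: int,
    seed: int,
    observed_r2_test: float,
    retune: bool = True,
    fitted_hyperparameters: dict | None = None,
) -> YRandResult:
    """Response-scrambling validation of the selected model.

    Per run r: the training-partition responses are permuted (seed + r),
    the method is re-tuned and refit on the scrambled training data, and
    its R² on the *unpermuted* test partition is recorded.  The exceedance
    fraction is the share of permuted runs with R² at or above the
    observed value — for a genuine model it should be zero.
    """
    if n_runs < 1:
        raise SelectionError("n_runs must be >= 1")
    train = ds.subset_rows(split.train_ids)
    test = ds.subset_rows(split.test_ids)
    run_spec = spec
    if not retune and fitted_hyperparameters is not None:
        run_spec = MethodSpec(
            name=spec.name, tuning_grid=[dict(fitted_hyperparameters)], options=spec.options
        )
    permuted: list[float] = []
    for r in range(n_runs):
        rng = np.random.default_rng((seed + r) % (2**31))
        y_perm = rng.permutation(train.y)
        try:
            model, _ = tune_and_fit(
                run_spec, train.X, y_perm, scheme, seed=(seed + r) % (2**31),
                feature_names=train.feature_names,
            )
            pred = model.predict(test.X)
            if np.std(pred) == 0:
                # a constant predictor carries no association with the response
                r2 = 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r2 = r_squared(test.y, pred)
        except Exception as exc:  # noqa: BLE001 — failed runs excluded, not fatal
            warnings.warn(f"Y-randomization run {r} failed: {exc}")
            continue
        if not math.isnan(r2):
            permuted.append(float(r2))
    if permuted:
        exceed = float(np.mean([r2 >= observed_r2_test for r2 in permuted]))
    else:
        exceed = float("nan")
    return YRandResult(
        n_runs=len(permuted),
        permuted_r2_test=permuted,
        observed_r2_test=float(observed_r2_test),
        exceedance_fraction=exceed,
    )
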