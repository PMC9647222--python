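"""Cost-sensitive logistic models with bootstrapped cross-validation.

Three model types are compared per endpoint and per week of imaging:
mean dose only (the pre-treatment reference), the selected radiomics
slope predictors only, and radiomics plus mean dose.  Evaluation uses
stratified 3-fold cross-validation whose fold allocation is re-drawn 200
times; every metric is summarised by its median and 5th-95th percentile
interval over the bootstrap x fold evaluations.  The classification
threshold minimises a 3:1 false-negative:false-positive cost on the
training folds (failing to flag a future toxicity case is three times
as costly as a spurious flag) and is applied unchanged to the test fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from ._glm import LogisticFit, fit_logistic_core
from .errors import ConfigurationError, InvalidInputError
from .kinetics import DOSE_COLUMN, SlopeMatrix, build_slope_matrix, standardize, week_cutoffs
from .select import SelectionConfig, SelectionTally, run_three_stage

logger = logging.getLogger(__name__)

MODEL_TYPES = ("dose_only", "radiomics_only", "radiomics_plus_dose")
METRICS = ("auc", "sensitivity", "specificity", "accuracy")


# ---------------------------------------------------------------------------
# model spec

@dataclass
class ModelSpec:
    """A fitted logistic model with its decision threshold."""

    model_type: str
    predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    threshold: float = 0.5
    endpoint: str | None = None
    week: int | None = None

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ConfigurationError(f"unknown model type {self.model_type!r}")
        if self.model_type == "dose_only" and self.predictors != [DOSE_COLUMN]:
            raise ConfigurationError("dose_only must use exactly the dose column")
        if self.model_type == "radiomics_plus_dose" and DOSE_COLUMN not in self.predictors:
            raise ConfigurationError("radiomics_plus_dose must include the dose column")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        if self.predictors:
            arr = X[self.predictors].to_numpy(dtype=float)
            eta = eta + arr @ np.array([self.coefficients[p] for p in self.predictors])
        return expit(eta)


def fit_logistic(X: pd.DataFrame, y: np.ndarray, model_type: str = "radiomics_only",
                 predictors: list[str] | None = None) -> ModelSpec:
    """Maximum-likelihood logistic fit of the named predictors.

    IRLS with convergence at relative log-likelihood change < 1e-8; a
    perfectly separated fit is stabilised by a weak L2 penalty with a
    warning.  An intercept-only model (empty predictor list) is allowed
    for degenerate selections.
    """
    predictors = list(X.columns) if predictors is None else list(predictors)
    arr = X[predictors].to_numpy(dtype=float) if predictors else np.empty((len(X), 0))
    core = fit_logistic_core(arr, y)
    return ModelSpec(
        model_type=model_type,
        predictors=predictors,
        intercept=float(core.beta[0]),
        coefficients={p: float(b) for p, b in zip(predictors, core.beta[1:])},
    )


# ---------------------------------------------------------------------------
# metrics

def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Probability of concordance (Mann-Whitney AUC), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).astype(int).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("AUC undefined with a single class")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def choose_threshold(probs: np.ndarray, y: np.ndarray, cost_ratio: float = 3.0) -> float:
    """Threshold minimising ``cost_ratio * FN + FP`` on (probs, y).

    Candidates are midpoints between consecutive sorted unique
    probabilities plus one below the minimum and one above the maximum.
    Ties break to the highest sensitivity, then the lowest threshold.
    Classification is ``prob >= threshold``.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y).astype(int).ravel()
    uniq = np.unique(probs)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for t in cands:
        pred = probs >= t
        fn = int(np.sum((y == 1) & ~pred))
        fp = int(np.sum((y == 0) & pred))
        sens = 1.0 - fn / max(int(y.sum()), 1)
        key = (cost_ratio * fn + fp, -sens, t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def classification_metrics(probs: np.ndarray, y: np.ndarray, threshold: float) -> dict[str, float]:
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y).astype(int).ravel()
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    n1 = int(y.sum())
    n0 = y.size - n1
    return {
        "sensitivity": tp / n1 if n1 else float("nan"),
        "specificity": tn / n0 if n0 else float("nan"),
        "accuracy": (tp + tn) / y.size,
    }


def cost_sensitive_metrics(probs: np.ndarray, y: np.ndarray,
                           cost_ratio: float = 3.0) -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, accuracy) at the
    cost-optimal threshold chosen on these data."""
    t = choose_threshold(probs, y, cost_ratio)
    m = classification_metrics(probs, y, t)
    return t, m["sensitivity"], m["specificity"], m["accuracy"]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalConfig:
    k_folds: int = 3
    n_bootstrap: int = 200
    cost_ratio: float = 3.0
    ci_percentiles: tuple[float, float] = (5.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.cost_ratio <= 0:
            raise ConfigurationError("cost_ratio must be positive")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")


@dataclass
class PerformanceReport:
    """Median and percentile CIs of every metric, per model type, plus
    pooled test-fold scores for ROC/calibration curves.

    ``selection_tally`` records the predictor combination chosen on each
    training fold set when selection ran inside the evaluation."""

    summary: pd.DataFrame
    raw: dict[str, dict[str, np.ndarray]]
    pooled_test: dict[str, tuple[np.ndarray, np.ndarray]]
    endpoint: str | None = None
    week: int | None = None
    selection_tally: SelectionTally | None = None

    def median(self, model_type: str, metric: str, split: str = "test") -> float:
        q = self.summary
        row = q[(q.model_type == model_type) & (q.metric == metric) & (q.split == split)]
        return float(row["median"].iloc[0])

    def roc_points(self, model_type: str) -> pd.DataFrame:
        probs, y = self.pooled_test[model_type]
        order = np.argsort(-probs, kind="stable")
        p, yy = probs[order], y[order]
        tps = np.cumsum(yy)
        fps = np.cumsum(1 - yy)
        n1, n0 = max(int(y.sum()), 1), max(int((1 - y).sum()), 1)
        df = pd.DataFrame({"fpr": fps / n0, "tpr": tps / n1, "threshold": p})
        return pd.concat(
            [pd.DataFrame({"fpr": [0.0], "tpr": [0.0], "threshold": [np.inf]}), df],
            ignore_index=True,
        )

    def calibration_points(self, model_type: str, n_bins: int = 10) -> pd.DataFrame:
        probs, y = self.pooled_test[model_type]
        edges = np.quantile(probs, np.linspace(0, 1, n_bins + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        which = np.digitize(probs, edges[1:-1])
        rows = []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            rows.append({"bin": b, "mean_predicted": float(probs[sel].mean()),
                         "observed_rate": float(y[sel].mean()), "n": int(sel.sum())})
        return pd.DataFrame(rows)

    def to_json(self, path: Path) -> None:
        payload = {
            "endpoint": self.endpoint,
            "week": self.week,
            "rows": self.summary.round(10).to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _stratified_allocations(y: np.ndarray, config: EvalConfig):
    """Yield n_bootstrap stratified k-fold allocations, re-drawing any
    allocation that leaves a fold without both classes."""
    base = np.random.default_rng(config.seed)
    seeds = base.integers(0, 2**31 - 1, size=config.n_bootstrap * 4)
    produced = 0
    i = 0
    while produced < config.n_bootstrap and i < seeds.size:
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                              random_state=int(seeds[i]))
        i += 1
        splits = list(skf.split(np.zeros(y.size), y))
        ok = all(np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2
                 for tr, te in splits)
        if not ok:
            logger.info("re-drawing fold allocation missing a class")
            continue
        produced += 1
        yield splits


def evaluate(X: pd.DataFrame, y: np.ndarray,
             predictors_by_type: dict[str, list[str] | None],
             config: EvalConfig | None = None,
             selector=None,
             endpoint: str | None = None, week: int | None = None) -> PerformanceReport:
    """Bootstrapped stratified k-fold evaluation of the model types.

    For every bootstrap fold allocation and every rotation, each model
    is fitted on the two training folds (including the cost-sensitive
    threshold choice) and all metrics are computed on both the training
    and the held-out fold.  All bootstrap x fold values are aggregated
    into medians and percentile CIs.

    A model type whose predictor list is ``None`` has its radiomics
    predictors chosen anew on each training fold set by ``selector`` —
    a callable ``(X_train, y_train) -> list of predictor names``.  The
    training two-folds are the two-thirds subsamples of the resampled
    selection, so the held-out fold never informs the selection, and the
    per-training-set combinations are tallied in the returned report.
    """
    config = config or EvalConfig()
    y = np.asarray(y).astype(int).ravel()
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.k_folds:
        raise InvalidInputError(
            f"minority class ({counts.min()}) smaller than k_folds ({config.k_folds})"
        )
    needs_selector = any(p is None for p in predictors_by_type.values())
    if needs_selector and selector is None:
        raise ConfigurationError("predictor list None requires a selector")
    raw: dict[str, dict[str, list[float]]] = {
        mt: {f"{m}_{s}": [] for m in METRICS for s in ("train", "test")}
        for mt in predictors_by_type
    }
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {mt: [] for mt in predictors_by_type}
    tally_counts: dict[frozenset, int] = {}
    n_selections = 0
    for splits in _stratified_allocations(y, config):
        for tr, te in splits:
            selected: list[str] | None = None
            if needs_selector:
                selected = list(selector(X.iloc[tr], y[tr]))
                combo = frozenset(selected)
                tally_counts[combo] = tally_counts.get(combo, 0) + 1
                n_selections += 1
            for mt, preds in predictors_by_type.items():
                if preds is None:
                    preds = selected if mt != "radiomics_plus_dose" else selected + [DOSE_COLUMN]
                spec = fit_logistic(X.iloc[tr], y[tr], model_type=mt, predictors=preds)
                p_tr = spec.predict_proba(X.iloc[tr])
                p_te = spec.predict_proba(X.iloc[te])
                thr = choose_threshold(p_tr, y[tr], config.cost_ratio)
                m_tr = classification_metrics(p_tr, y[tr], thr)
                m_te = classification_metrics(p_te, y[te], thr)
                raw[mt]["auc_train"].append(auc(p_tr, y[tr]))
                raw[mt]["auc_test"].append(auc(p_te, y[te]))
                for k in ("sensitivity", "specificity", "accuracy"):
                    raw[mt][f"{k}_train"].append(m_tr[k])
                    raw[mt][f"{k}_test"].append(m_te[k])
                pooled[mt].append((p_te, y[te]))
    lo, hi = config.ci_percentiles
    rows = []
    raw_arr: dict[str, dict[str, np.ndarray]] = {}
    for mt in predictors_by_type:
        raw_arr[mt] = {k: np.asarray(v, dtype=float) for k, v in raw[mt].items()}
        for metric in METRICS:
            for split in ("train", "test"):
                vals = raw_arr[mt][f"{metric}_{split}"]
                vals = vals[np.isfinite(vals)]
                rows.append({
                    "model_type": mt, "endpoint": endpoint, "week": week,
                    "metric": metric, "split": split,
                    "median": float(np.median(vals)),
                    "ci_lo": float(np.percentile(vals, lo)),
                    "ci_hi": float(np.percentile(vals, hi)),
                })
    pooled_test = {
        mt: (np.concatenate([p for p, _ in chunks]),
             np.concatenate([t for _, t in chunks]))
        for mt, chunks in pooled.items()
    }
    tally = None
    if n_selections:
        tally = SelectionTally(counts=tally_counts, n_repeats=n_selections,
                               predictor_names=[c for c in X.columns
                                                if c != DOSE_COLUMN])
    return PerformanceReport(summary=pd.DataFrame(rows), raw=raw_arr,
                             pooled_test=pooled_test, endpoint=endpoint,
                             week=week, selection_tally=tally)


# ---------------------------------------------------------------------------
# weekly sweep and final model choice

@dataclass
class SweepResult:
    """Per-(endpoint, week) selection tallies and performance reports."""

    reports: dict[tuple[str, int], PerformanceReport]
    tallies: dict[tuple[str, int], SelectionTally]
    matrices: dict[tuple[str, int], SlopeMatrix] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        frames = [r.summary for r in self.reports.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def weekly_sweep(table: pd.DataFrame, outcomes: pd.DataFrame, doses: pd.Series,
                 sel_config: SelectionConfig | None = None,
                 eval_config: EvalConfig | None = None,
                 weeks: list[int] | None = None,
                 min_patients: int = 10) -> SweepResult:
    """One model family per (endpoint, week-of-imaging) grid cell.

    For each endpoint and each complete-week cut-off X: build the slope
    predictors from fractions 1..X, standardise across all patients, and
    evaluate the three model types with the three-stage selection re-run
    on every training fold set (so each cell's tally holds
    n_bootstrap x k_folds combinations; ``sel_config`` supplies the
    stage thresholds).  Endpoints with fewer than ``min_patients``
    outcomes are skipped with a warning.
    """
    sel_config = sel_config or SelectionConfig()
    eval_config = eval_config or EvalConfig()
    if weeks is None:
        weeks = week_cutoffs(int(table["fraction"].max()))
    reports: dict[tuple[str, int], PerformanceReport] = {}
    tallies: dict[tuple[str, int], SelectionTally] = {}
    matrices: dict[tuple[str, int], SlopeMatrix] = {}
    for ep_i, endpoint in enumerate(outcomes.columns):
        y_full = outcomes[endpoint].dropna()
        if len(y_full) < min_patients:
            logger.warning("endpoint %s: only %d patients; skipped", endpoint, len(y_full))
            continue
        pts = y_full.index
        sub_table = table[table["patient_id"].isin(pts)]
        for w_i, x in enumerate(weeks):
            matrix = build_slope_matrix(sub_table, weeks=[x], doses=doses)
            matrix = standardize(matrix)
            y = y_full.reindex(matrix.data.index).to_numpy()
            predictors_by_type: dict[str, list[str] | None] = {
                "dose_only": [DOSE_COLUMN],
                "radiomics_only": None,
                "radiomics_plus_dose": None,
            }
            # the three-stage selection runs on each training two-folds
            # (the two-thirds subsamples of the resampled selection); the
            # held-out fold never informs it
            selector = lambda Xt, yt: run_three_stage(Xt, yt, sel_config)  # noqa: E731
            report = evaluate(
                matrix.data, y, predictors_by_type,
                config=EvalConfig(
                    k_folds=eval_config.k_folds,
                    n_bootstrap=eval_config.n_bootstrap,
                    cost_ratio=eval_config.cost_ratio,
                    ci_percentiles=eval_config.ci_percentiles,
                    # fold allocations shared across weeks of one endpoint,
                    # so the dose-only reference is week-independent
                    seed=eval_config.seed + 1000 * ep_i,
                ),
                selector=selector,
                endpoint=endpoint, week=x,
            )
            reports[(endpoint, x)] = report
            tallies[(endpoint, x)] = report.selection_tally
            matrices[(endpoint, x)] = matrix
    return SweepResult(reports=reports, tallies=tallies, matrices=matrices)


@dataclass
class FinalModel:
    endpoint: str
    model_type: str
    week: int
    spec: ModelSpec
    auc_test_median: float


def select_final_model(sweep: SweepResult, outcomes: pd.DataFrame,
                       endpoint: str, max_week: int = 15) -> dict[str, FinalModel]:
    """Pick, per model type, the week maximising median test AUC subject
    to the slopes coming from the first three weeks (fractions <= 15).

    Ties break to the earliest week.  The chosen model is refitted on
    all patients with the endpoint available.
    """
    eligible = sorted(
        x for (ep, x) in sweep.reports if ep == endpoint and x <= max_week
    )
    if not eligible:
        raise InvalidInputError(
            f"no evaluated week <= {max_week} for endpoint {endpoint!r}"
        )
    y_full = outcomes[endpoint].dropna()
    out: dict[str, FinalModel] = {}
    for mt in MODEL_TYPES:
        best_week, best_auc = None, -np.inf
        for x in eligible:
            med = sweep.reports[(endpoint, x)].median(mt, "auc", "test")
            if med > best_auc + 1e-12:
                best_week, best_auc = x, med
        matrix = sweep.matrices[(endpoint, best_week)]
        y = y_full.reindex(matrix.data.index).to_numpy()
        if mt == "dose_only":
            preds = [DOSE_COLUMN]
        else:
            combo = sweep.tallies[(endpoint, best_week)].modal_combination
            preds = combo if mt == "radiomics_only" else combo + [DOSE_COLUMN]
        spec = fit_logistic(matrix.data, y, model_type=mt, predictors=preds)
        spec.endpoint = endpoint
        spec.week = best_week
        probs = spec.predict_proba(matrix.data)
        spec.threshold = choose_threshold(probs, y)
        out[mt] = FinalModel(endpoint=endpoint, model_type=mt, week=best_week,
                             spec=spec, auc_test_median=best_auc)
    return out
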