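"""Resampled three-stage predictor selection.

The slope predictors go through three stages, repeated on many
two-thirds subsamples of the patients:

1. **correlation pruning** — of every pair of radiomics predictors whose
   Pearson correlation exceeds the threshold, the member with the weaker
   univariable rank-sum association with the endpoint is removed;
2. **univariate filtering** — predictors with a two-sided Wilcoxon
   rank-sum p-value above alpha are excluded (alpha defaults to 0.051,
   no multiplicity correction at this stage);
3. **sequential forward/backward (floating) selection** — a stepwise
   search over logistic models scored by BIC on the deviance.

Each repeat records the resulting predictor combination; the modal
combination over repeats is taken as the robust signature.  The mean
dose is a structural model term, not a radiomics predictor, and is
exempt from all three stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic_core
from .errors import ConfigurationError, InvalidInputError
from .kinetics import DOSE_COLUMN

logger = logging.getLogger(__name__)

#: largest group size for which the exact rank-sum null distribution is
#: enumerated (ties force the asymptotic path regardless)
_EXACT_LIMIT = 10


# ---------------------------------------------------------------------------
# rank-sum test

def wilcoxon_rank_sum(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have at most 10 observations and
    no ties span the groups; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= _EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def _columnwise_rank_sum(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum p-value per column of X."""
    y = np.asarray(y).astype(int)
    a = X[y == 1]
    b = X[y == 0]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InvalidInputError("both outcome classes must be present")
    if min(a.shape[0], b.shape[0]) <= _EXACT_LIMIT:
        return np.array([wilcoxon_rank_sum(a[:, j], b[:, j]) for j in range(X.shape[1])])
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True, axis=0)
    return np.asarray(res.pvalue, dtype=float)


# ---------------------------------------------------------------------------
# configuration / tally

@dataclass
class SelectionConfig:
    """Parameters of the three-stage resampled selection."""

    correlation_threshold: float = 0.8
    univariate_alpha: float = 0.051
    n_repeats: int = 200
    subsample_fraction: float = 2.0 / 3.0
    seed: int = 0
    criterion: str = "bic"

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold < 1.0:
            raise ConfigurationError("correlation_threshold must be in (0,1)")
        if not 0.0 < self.univariate_alpha <= 1.0:
            raise ConfigurationError("univariate_alpha must be in (0,1]")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ConfigurationError("subsample_fraction must be in (0,1]")
        if self.criterion != "bic":
            raise ConfigurationError(f"unsupported criterion {self.criterion!r}")


@dataclass
class SelectionTally:
    """Frequency of each predictor combination over the repeats."""

    counts: dict[frozenset, int]
    n_repeats: int
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_repeats:
            raise InvalidInputError("tally counts must sum to n_repeats")

    @property
    def modal_combination(self) -> list[str]:
        """Most frequent combination; ties break to the smallest set,
        then lexicographically."""
        best = min(
            self.counts.items(),
            key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))),
        )
        return sorted(best[0])

    @property
    def modal_frequency(self) -> int:
        return self.counts[frozenset(self.modal_combination)]

    def marginal_frequencies(self) -> pd.Series:
        """Per-predictor selection frequency (fraction of repeats)."""
        tally: dict[str, int] = {p: 0 for p in self.predictor_names}
        for combo, n in self.counts.items():
            for p in combo:
                tally[p] = tally.get(p, 0) + n
        sr = pd.Series(tally, dtype=float) / self.n_repeats
        return sr.sort_values(ascending=False)

    def to_json(self, path: Path) -> None:
        payload = {
            "n_repeats": self.n_repeats,
            "combinations": [
                {"predictors": sorted(c), "count": n}
                for c, n in sorted(self.counts.items(),
                                   key=lambda kv: (-kv[1], sorted(kv[0])))
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# the three stages

def correlation_prune(
    X: pd.DataFrame,
    y: np.ndarray,
    threshold: float = 0.8,
    pvalues: pd.Series | None = None,
) -> list[str]:
    """Remove the weaker member of each highly correlated predictor pair.

    Pairs with |Pearson r| > threshold are processed in descending |r|
    order (ties by column order); within a pair the predictor with the
    larger rank-sum p-value is dropped.  The dose column is exempt.
    """
    cols = [c for c in X.columns if c != DOSE_COLUMN]
    if not cols:
        return list(X.columns)
    if pvalues is None:
        pv = _columnwise_rank_sum(X[cols].to_numpy(dtype=float), y)
        pvalues = pd.Series(pv, index=cols)
    arr = X[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r = np.atleast_2d(np.nan_to_num(r, nan=0.0))
    iu, ju = np.triu_indices(len(cols), k=1)
    absr = np.abs(r[iu, ju])
    over = absr > threshold
    order = np.argsort(-absr[over], kind="stable")
    removed: set[str] = set()
    for a_idx, b_idx in zip(iu[over][order], ju[over][order]):
        ca, cb = cols[a_idx], cols[b_idx]
        if ca in removed or cb in removed:
            continue
        pa, pb = pvalues[ca], pvalues[cb]
        removed.add(cb if pb >= pa else ca)  # tie keeps the first column
    retained = [c for c in X.columns if c == DOSE_COLUMN or c not in removed]
    return [c for c in retained if c != DOSE_COLUMN] + (
        [DOSE_COLUMN] if DOSE_COLUMN in X.columns else []
    )


def univariate_filter(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.051,
    pvalues: pd.Series | None = None,
) -> list[str]:
    """Keep predictors whose two-sided rank-sum p-value is <= alpha.

    No multiplicity correction is applied at this stage.  The dose
    column, if present, passes through untouched.
    """
    cols = [c for c in X.columns if c != DOSE_COLUMN]
    if not cols:
        return list(X.columns)
    if pvalues is None:
        pv = _columnwise_rank_sum(X[cols].to_numpy(dtype=float), y)
        pvalues = pd.Series(pv, index=cols)
    kept = [c for c in cols if pvalues[c] <= alpha]
    if DOSE_COLUMN in X.columns:
        kept.append(DOSE_COLUMN)
    return kept


def sequential_selection(X: pd.DataFrame, y: np.ndarray,
                         criterion: str = "bic") -> list[str]:
    """Floating stepwise search over logistic models scored by BIC.

    Forward step: add the predictor giving the largest BIC improvement;
    floating backward step: remove any predictor whose removal improves
    BIC further.  Stops when no forward move improves.  Deterministic
    given column order (ties break to the lower column index).  An empty
    input yields an empty combination.
    """
    cols = [c for c in X.columns if c != DOSE_COLUMN]
    if not cols:
        return []
    y = np.asarray(y, dtype=float)
    arr = X[cols].to_numpy(dtype=float)

    def score(subset: list[int]) -> float:
        return fit_logistic_core(arr[:, subset], y).bic()

    current: list[int] = []
    best = score(current)
    while True:
        # forward
        cand_scores = [
            (score(current + [j]), j) for j in range(len(cols)) if j not in current
        ]
        if not cand_scores:
            break
        fwd_best, fwd_j = min(cand_scores, key=lambda t: (t[0], t[1]))
        if fwd_best >= best - 1e-10:
            break
        current = current + [fwd_j]
        best = fwd_best
        # floating backward
        improved = True
        while improved and len(current) > 1:
            improved = False
            back = [
                (score([j for j in current if j != r]), r) for r in current[:-1]
            ]
            bk_best, bk_r = min(back, key=lambda t: (t[0], t[1]))
            if bk_best < best - 1e-10:
                current = [j for j in current if j != bk_r]
                best = bk_best
                improved = True
    return [cols[j] for j in sorted(current)]


# ---------------------------------------------------------------------------
# resampled wrapper

def _stratified_subsample(y: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Class-stratified subsample of row indices (without replacement)."""
    idx = []
    for cls in np.unique(y):
        members = np.nonzero(y == cls)[0]
        m = max(2, int(round(fraction * members.size)))
        m = min(m, members.size)
        idx.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(idx))


def run_three_stage(X: pd.DataFrame, y: np.ndarray,
                    config: SelectionConfig) -> list[str]:
    """One pass of prune -> filter -> stepwise on the given patients."""
    cols = [c for c in X.columns if c != DOSE_COLUMN]
    if not cols:
        return []
    pv = pd.Series(_columnwise_rank_sum(X[cols].to_numpy(dtype=float), y), index=cols)
    keep = correlation_prune(X[cols], y, config.correlation_threshold, pvalues=pv)
    keep = univariate_filter(X[keep], y, config.univariate_alpha, pvalues=pv[keep])
    return sequential_selection(X[keep], y, criterion=config.criterion)


def robust_select(X: pd.DataFrame, y: np.ndarray,
                  config: SelectionConfig | None = None,
                  subsamples: list[np.ndarray] | None = None) -> SelectionTally:
    """Repeat the three-stage selection over stratified subsamples.

    Each repeat draws a class-stratified two-thirds subsample of the
    patients (or uses an entry of ``subsamples`` when provided, e.g. the
    training folds of a cross-validation), runs the three stages, and
    records the resulting predictor combination.  Fully reproducible
    from the config seed.
    """
    config = config or SelectionConfig()
    y = np.asarray(y).astype(int).ravel()
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    for rep in range(config.n_repeats):
        if subsamples is not None:
            rows = subsamples[rep % len(subsamples)]
        else:
            rows = _stratified_subsample(y, config.subsample_fraction, rng)
        combo = frozenset(
            run_three_stage(X.iloc[rows], y[rows], config)
        )
        counts[combo] = counts.get(combo, 0) + 1
    return SelectionTally(counts=counts, n_repeats=config.n_repeats,
                          predictor_names=[c for c in X.columns if c != DOSE_COLUMN])
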