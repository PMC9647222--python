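"""Weekly slope predictors from daily feature trajectories.

Each feature's values are regressed on fraction number from fraction 1
up to every complete week (cut-offs at multiples of five fractions); the
ordinary-least-squares slope is the predictor, named
``<feature>_fx1_<X>``.  The mean contra-lateral parotid dose is appended
as an additional predictor, and all predictors are z-scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

DOSE_COLUMN = "mean_dose"


def week_cutoffs(n_fractions: int) -> list[int]:
    """Fraction cut-offs at complete weeks: multiples of five up to
    ``n_fractions``."""
    return [x for x in range(5, n_fractions + 1, 5)]


def fit_slope(fractions: np.ndarray, values: np.ndarray, last_fraction: int) -> float:
    """OLS slope of value on fraction number over fractions 1..last_fraction.

    Missing fractions are simply absent from the fit.  Fewer than two
    usable points yields NaN (the missing-predictor sentinel, imputed at
    matrix level).
    """
    fractions = np.asarray(fractions, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = (fractions <= last_fraction) & np.isfinite(values)
    f, v = fractions[keep], values[keep]
    if f.size < 2 or np.unique(f).size < 2:
        return float("nan")
    fbar, vbar = f.mean(), v.mean()
    return float(((f - fbar) * (v - vbar)).sum() / ((f - fbar) ** 2).sum())


@dataclass
class SlopeMatrix:
    """Patients x predictors (feature slopes per week cut-off + mean dose).

    ``transform`` holds the per-column (mean, sd) of the z-scoring once
    :func:`standardize` has been applied; the SD uses the population
    (divisor n) convention.
    """

    data: pd.DataFrame
    transform: dict[str, tuple[float, float]] | None = None
    imputed_counts: dict[str, int] = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    @property
    def radiomics_predictors(self) -> list[str]:
        return [c for c in self.data.columns if c != DOSE_COLUMN]

    def to_csv(self, path: Path) -> None:
        self.data.to_csv(path)
        if self.transform is not None:
            side = Path(path).with_suffix(".transform.json")
            with open(side, "w") as fh:
                json.dump(
                    {k: list(v) for k, v in self.transform.items()},
                    fh, sort_keys=True, indent=1,
                )


def build_slope_matrix(
    table: pd.DataFrame,
    weeks: list[int] | None = None,
    doses: pd.Series | None = None,
) -> SlopeMatrix:
    """Slope predictors ``<feature>_fx1_<X>`` for every (feature, week).

    ``table`` is the long feature table (patient_id, fraction, feature,
    value).  Missing slopes (fewer than two usable fractions) are imputed
    by the population median of the column, with the count logged.
    Columns that are entirely missing are dropped with a warning.
    """
    if table.empty:
        raise InvalidInputError("empty feature table")
    max_fx = int(table["fraction"].max())
    if weeks is None:
        weeks = week_cutoffs(max_fx)
    patients = list(pd.unique(table["patient_id"]))
    features = list(pd.unique(table["feature"]))

    # wide values: one row per (patient, feature), columns = fractions
    wide = table.pivot_table(
        index=["patient_id", "feature"], columns="fraction", values="value",
        aggfunc="first",
    )
    fracs = wide.columns.to_numpy(dtype=float)
    vals = wide.to_numpy(dtype=float)

    cols: dict[str, np.ndarray] = {}
    for x in weeks:
        sel = fracs <= x
        f = fracs[sel]
        v = vals[:, sel]
        finite = np.isfinite(v)
        n = finite.sum(axis=1)
        fmat = np.where(finite, f[None, :], np.nan)
        fbar = np.nanmean(fmat, axis=1)
        vbar = np.nanmean(np.where(finite, v, np.nan), axis=1)
        num = np.nansum((fmat - fbar[:, None]) * (v - vbar[:, None]) * finite, axis=1)
        den = np.nansum((fmat - fbar[:, None]) ** 2 * finite, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slopes = np.where((n >= 2) & (den > 0), num / np.maximum(den, 1e-300), np.nan)
        sl = pd.Series(slopes, index=wide.index)
        for feat in features:
            col = sl.xs(feat, level="feature").reindex(patients)
            cols[f"{feat}_fx1_{x}"] = col.to_numpy()

    df = pd.DataFrame(cols, index=pd.Index(patients, name="patient_id"))
    imputed: dict[str, int] = {}
    drop = []
    for c in df.columns:
        n_missing = int(df[c].isna().sum())
        if n_missing == len(df):
            drop.append(c)
        elif n_missing:
            df[c] = df[c].fillna(df[c].median())
            imputed[c] = n_missing
            logger.info("column %s: imputed %d missing slope(s) by median", c, n_missing)
    if drop:
        logger.warning("dropping entirely missing columns: %s", drop)
        df = df.drop(columns=drop)
    if doses is not None:
        df[DOSE_COLUMN] = doses.reindex(df.index).to_numpy()
    return SlopeMatrix(df, imputed_counts=imputed)


def standardize(matrix: SlopeMatrix, population: np.ndarray | list | None = None) -> SlopeMatrix:
    """Z-score every column using means/SDs from the stated population.

    ``population`` selects the patients whose statistics define the
    transform (default: all patients — the verbatim replication of the
    published procedure; pass train-fold indices for the leakage-safe
    variant).  The SD uses divisor n.  Zero-SD columns are dropped with a
    warning.  The transform is stored so held-out data can be mapped with
    :func:`apply_standardization`.
    """
    df = matrix.data
    pop = df if population is None else df.loc[population]
    transform: dict[str, tuple[float, float]] = {}
    out = {}
    dropped = []
    for c in df.columns:
        mu = float(pop[c].mean())
        sd = float(pop[c].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            dropped.append(c)
            continue
        transform[c] = (mu, sd)
        out[c] = (df[c] - mu) / sd
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
    return SlopeMatrix(pd.DataFrame(out, index=df.index), transform=transform,
                       imputed_counts=dict(matrix.imputed_counts))


def apply_standardization(df: pd.DataFrame, transform: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Map new data through a stored standardisation transform."""
    out = {}
    for c, (mu, sd) in transform.items():
        out[c] = (df[c] - mu) / sd
    return pd.DataFrame(out, index=df.index)


def invert_standardization(df: pd.DataFrame, transform: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Inverse of :func:`apply_standardization`."""
    out = {}
    for c in df.columns:
        mu, sd = transform[c]
        out[c] = df[c] * sd + mu
    return pd.DataFrame(out, index=df.index)
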