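"""Secondary analyses and deterministic report artefacts.

Covers the added-value check of texture kinetics against simple gland
shrinkage (correlation of each feature's slope with the mask-volume
slope across patients), selection-frequency tables, and the performance
grid / ROC / calibration figures.  All outputs are byte-deterministic
for identical inputs so that whole-pipeline runs can be diffed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .kinetics import fit_slope
from .model import METRICS, MODEL_TYPES, SweepResult
from .preprocess import ImageSeries
from .select import SelectionTally

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "radkinetics"
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)

_SAVEFIG_KW = {"metadata": {"Date": None}, "format": "svg"}


def mask_volume_cm3(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume = voxel count x voxel volume (spacing product), in cm^3."""
    voxel_mm3 = float(np.prod(spacing))
    return float(mask.sum()) * voxel_mm3 / 1000.0


def volume_trajectory(series: ImageSeries) -> pd.DataFrame:
    """(fraction, volume_cm3) pairs for one patient's mask series."""
    rows = [
        {"patient_id": series.patient_id, "fraction": fx,
         "volume_cm3": mask_volume_cm3(series.masks[fx - 1], series.spacing)}
        for fx in range(1, series.n_fractions + 1)
        if series.usable[fx - 1]
    ]
    return pd.DataFrame(rows)


def volume_slopes(series_list: list[ImageSeries], last_fraction: int) -> pd.Series:
    """Per-patient OLS slope of mask volume on fraction number."""
    out = {}
    for s in series_list:
        df = volume_trajectory(s)
        out[s.patient_id] = fit_slope(df["fraction"].to_numpy(),
                                      df["volume_cm3"].to_numpy(), last_fraction)
    return pd.Series(out, name="volume_slope")


def volume_feature_correlation(
    vol_slopes: pd.Series,
    feature_slopes: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of each feature's slope with the volume-change slope.

    ``feature_slopes`` is patients x features.  Features with zero
    variance (or fewer than three complete patients) are reported with a
    missing correlation.  ``method`` is ``"pearson"`` (default) or
    ``"spearman"``.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidInputError(f"unknown correlation method {method!r}")
    common = vol_slopes.index.intersection(feature_slopes.index)
    if len(common) < 3:
        raise InvalidInputError("need >= 3 patients with both slope kinds")
    v = vol_slopes.loc[common]
    rows = []
    for feat in feature_slopes.columns:
        f = feature_slopes.loc[common, feat]
        ok = f.notna() & v.notna()
        n = int(ok.sum())
        if n < 3 or f[ok].std(ddof=0) == 0 or v[ok].std(ddof=0) == 0:
            rows.append({"feature": feat, "r": np.nan, "n": n})
            continue
        if method == "pearson":
            r = stats.pearsonr(v[ok], f[ok]).statistic
        else:
            r = stats.spearmanr(v[ok], f[ok]).statistic
        rows.append({"feature": feat, "r": float(r), "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artefact rendering

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_selection_frequencies(tally: SelectionTally, path: Path) -> None:
    """Per-predictor marginal selection frequency as CSV (header-only
    when the tally is empty of predictors)."""
    freq = tally.marginal_frequencies()
    df = pd.DataFrame({"predictor": freq.index, "frequency": freq.to_numpy()})
    df = df.sort_values(["frequency", "predictor"],
                        ascending=[False, True], kind="stable")
    _write_csv(df, path)


def plot_performance_grid(summary: pd.DataFrame, path: Path) -> None:
    """Metric-by-week grid per endpoint and model type (test split)."""
    endpoints = sorted(summary["endpoint"].dropna().unique())
    fig, axes = plt.subplots(len(METRICS), max(len(endpoints), 1),
                             figsize=(4 * max(len(endpoints), 1), 2.6 * len(METRICS)),
                             squeeze=False)
    for j, ep in enumerate(endpoints):
        for i, metric in enumerate(METRICS):
            ax = axes[i][j]
            for mt in MODEL_TYPES:
                q = summary[(summary.endpoint == ep) & (summary.metric == metric)
                            & (summary.model_type == mt) & (summary.split == "test")]
                q = q.sort_values("week")
                if q.empty:
                    continue
                ax.errorbar(q["week"], q["median"],
                            yerr=[q["median"] - q["ci_lo"], q["ci_hi"] - q["median"]],
                            label=mt, marker="o", capsize=2)
            ax.set_ylim(0.0, 1.05)
            if i == 0:
                ax.set_title(f"endpoint {ep}")
            if j == 0:
                ax.set_ylabel(metric)
            if i == len(METRICS) - 1:
                ax.set_xlabel("week cut-off (fractions)")
    if endpoints:
        axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def plot_roc(report, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    for mt in sorted(report.pooled_test):
        pts = report.roc_points(mt)
        ax.plot(pts["fpr"], pts["tpr"], label=mt)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def plot_calibration(report, path: Path, n_bins: int = 10) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    for mt in sorted(report.pooled_test):
        pts = report.calibration_points(mt, n_bins=n_bins)
        ax.plot(pts["mean_predicted"], pts["observed_rate"], marker="o", label=mt)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed toxicity rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def render_reports(
    outdir: Path,
    sweep: SweepResult | None = None,
    correlations: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the full deterministic artefact set into ``outdir``.

    Performance grid (SVG), per-cell ROC and calibration curves for the
    best radiomics week, selection-frequency CSVs, the performance
    summary CSV and the feature-vs-volume correlation CSV.  A missing
    input section skips its artefacts with a warning.  Identical inputs
    produce identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if sweep is not None and sweep.reports:
        summary = sweep.summary()
        p = outdir / "performance_summary.csv"
        _write_csv(summary.sort_values(
            ["endpoint", "week", "model_type", "metric", "split"],
            kind="stable").reset_index(drop=True), p)
        written.append(p)
        p = outdir / "performance_grid.svg"
        plot_performance_grid(summary, p)
        written.append(p)
        for (ep, week), tally in sorted(sweep.tallies.items()):
            p = outdir / f"selection_frequency_{ep}_wk{week:02d}.csv"
            write_selection_frequencies(tally, p)
            written.append(p)
        # ROC/calibration for the earliest evaluated week of each endpoint
        seen = set()
        for (ep, week) in sorted(sweep.reports):
            if ep in seen:
                continue
            seen.add(ep)
            rep = sweep.reports[(ep, week)]
            p = outdir / f"roc_{ep}_wk{week:02d}.svg"
            plot_roc(rep, p)
            written.append(p)
            p = outdir / f"calibration_{ep}_wk{week:02d}.svg"
            plot_calibration(rep, p)
            written.append(p)
    else:
        warnings.warn("no performance input; skipping performance artefacts",
                      stacklevel=2)
    if correlations is not None:
        p = outdir / "volume_feature_correlation.csv"
        _write_csv(correlations, p)
        written.append(p)
    else:
        warnings.warn("no correlation input; skipping correlation artefact",
                      stacklevel=2)
    return written
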