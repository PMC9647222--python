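"""Synthetic cohorts with known ground truth.

The study this pipeline targets — daily mega-voltage CT texture of the
spared parotid gland as a predictor of radiation-induced dry mouth — was
built on a clinical cohort that is not publicly deposited.  This module
generates cohorts with the same structure so that every downstream stage
(feature extraction, slope kinetics, resampled selection, bootstrapped
evaluation) can be exercised and validated against known truth:

* **trajectory level** — per-feature time series are drawn directly from
  the linear-drift model the kinetics stage assumes, so slope recovery
  and selection power have closed-form references;
* **image level** — small 3-D HU phantoms with an ellipsoidal "parotid"
  mask whose internal texture drifts with fraction number at an
  outcome-dependent rate, exercising the full image path.

Default cohort dimensions mirror the clinical study: ~117 patients,
30 daily fractions, binary outcome prevalence 46 % / 33 % / 26 % at
6 / 12 / 24 months, two treatment machines with an HU calibration
offset, and occasional dental-artefact slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .errors import ConfigurationError
from .preprocess import ImageSeries, MachineOffsetTable

# ---------------------------------------------------------------------------
# configuration

#: Phantom grid (axial slices, rows, cols) and isotropic voxel spacing (mm).
#: 32 x 32 in-plane with 16 slices is large enough for stable co-occurrence
#: and run-length statistics yet keeps per-volume extraction sub-second.
PHANTOM_SHAPE = (16, 32, 32)
PHANTOM_SPACING_MM = (2.0, 2.0, 2.0)

#: HU of the two tissue populations mixed inside the phantom mask, and of
#: the soft-tissue background outside it.
HU_POP_A = 0.0
HU_POP_B = 120.0
HU_BACKGROUND = 40.0

#: HU written into injected dental-artefact voxels (well above the 2000 HU
#: exclusion threshold, in the metal range).
DENTAL_ARTEFACT_HU = 3500.0

DEFAULT_PREVALENCE = {"6m": 0.46, "12m": 0.33, "24m": 0.26}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a simulated cohort.

    Parameters
    ----------
    n_patients, n_fractions
        Cohort size and number of daily treatment fractions (>= 5).
    prevalence
        Marginal probability of the binary toxicity outcome per endpoint,
        e.g. ``{"6m": 0.46, "12m": 0.33, "24m": 0.26}``.  A bare float is
        accepted and treated as a single ``"6m"`` endpoint.
    n_features
        Number of feature trajectories (trajectory-level cohorts).
    informative_features
        ``[(feature_index, d), ...]``: features whose per-patient slope
        mean is shifted by ``d`` within-class standard deviations in
        outcome-positive patients (the class-separation effect size).
    informative_endpoint
        Endpoint whose outcome defines the slope shift (default: first).
    noise_sd
        SD of additive Gaussian noise, in feature units (trajectory
        cohorts) or HU (image cohorts).
    dose_mean, dose_sd
        Mean and SD of the contra-lateral parotid mean dose (Gy).
    dose_effect
        Log-odds of toxicity per standardised dose unit.
    latent_effect
        Log-odds per unit of a patient-level latent frailty shared across
        endpoints, inducing outcome correlation between follow-up times.
    machine_offsets
        HU shift of each machine relative to the reference (first key).
    machine_schedule
        ``"alternate"`` (default), ``"fixed:<id>"``, or an explicit list
        of machine IDs per fraction.
    dental_slice_rate
        Per-slice probability of injecting a dental-artefact voxel block.
    slope_scale
        Within-class SD of the per-patient feature slopes (feature units
        per fraction); the effect size ``d`` is expressed in these units.
    drift_rate, drift_ratio
        Image phantoms: per-fraction increase of the tissue mixing weight
        in outcome-negative patients, and the positive:negative ratio.
    shrink_rate
        Optional fractional mask-volume loss per fraction (image cohorts).
    """

    n_patients: int
    n_fractions: int = 30
    prevalence: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    n_features: int = 123
    informative_features: list[tuple[int, float]] = field(default_factory=list)
    informative_endpoint: str | None = None
    noise_sd: float = 0.5
    dose_mean: float = 27.0
    dose_sd: float = 12.0
    dose_effect: float = 0.5
    latent_effect: float = 0.8
    machine_offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 30.0}
    )
    machine_schedule: str | list[str] = "alternate"
    dental_slice_rate: float = 0.0
    slope_scale: float = 0.05
    baseline_sd: float = 1.0
    drift_rate: float = 0.01
    drift_ratio: float = 2.0
    shrink_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.prevalence, float):
            self.prevalence = {"6m": self.prevalence}
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.n_fractions < 5:
            raise ConfigurationError("n_fractions must be >= 5")
        if self.n_features <= 0:
            raise ConfigurationError("n_features must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for ep, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"prevalence[{ep!r}]={p} not in (0,1)")
        if not 0.0 <= self.dental_slice_rate <= 1.0:
            raise ConfigurationError("dental_slice_rate must be in [0,1]")
        for idx, _d in self.informative_features:
            if not 0 <= idx < self.n_features:
                raise ConfigurationError(f"informative feature index {idx} out of range")
        if self.informative_endpoint is None:
            self.informative_endpoint = next(iter(self.prevalence))
        elif self.informative_endpoint not in self.prevalence:
            raise ConfigurationError(
                f"informative_endpoint {self.informative_endpoint!r} has no prevalence"
            )

    @property
    def endpoints(self) -> list[str]:
        return list(self.prevalence)

    @property
    def reference_machine(self) -> str:
        return next(iter(self.machine_offsets))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it.

    Exactly one of ``trajectories`` (patients x features x fractions) or
    ``image_series`` is populated, depending on the generator used.
    """

    config: SyntheticConfig
    patient_ids: list[str]
    outcomes: pd.DataFrame            # index patient_id, one column per endpoint
    doses: pd.Series                  # mean contra-lateral dose (Gy)
    machine_ids: list[list[str]]      # per patient, per fraction
    feature_names: list[str] = field(default_factory=list)
    trajectories: np.ndarray | None = None
    image_series: list[ImageSeries] | None = None
    ground_truth: dict = field(default_factory=dict)

    def to_feature_table(self) -> pd.DataFrame:
        """Long-format table (patient_id, fraction, feature, value)."""
        if self.trajectories is None:
            raise ConfigurationError("cohort has no trajectory data")
        n_p, n_f, n_t = self.trajectories.shape
        idx = pd.MultiIndex.from_product(
            [self.patient_ids, self.feature_names, np.arange(1, n_t + 1)],
            names=["patient_id", "feature", "fraction"],
        )
        df = pd.DataFrame({"value": self.trajectories.ravel()}, index=idx).reset_index()
        return df[["patient_id", "fraction", "feature", "value"]]

    def offset_table(self) -> MachineOffsetTable:
        """Machine offsets keyed by (machine, month), constant over months."""
        cfg = self.config
        months = sorted({(fx - 1) // 20 for fx in range(1, cfg.n_fractions + 1)})
        offsets = {
            (m, mo): float(shift)
            for m, shift in cfg.machine_offsets.items()
            for mo in months
        }
        return MachineOffsetTable(reference_machine=cfg.reference_machine, offsets=offsets)


# ---------------------------------------------------------------------------
# outcome model

def _solve_intercept(target_prev: float, linear_sd: float) -> float:
    """Intercept b0 such that E[sigmoid(b0 + s*Z)] = target_prev, Z ~ N(0,1).

    Marginalises the logistic link over the Gaussian linear predictor by
    Gauss-Hermite quadrature.
    """
    if linear_sd == 0.0:
        return float(special.logit(target_prev))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / np.sqrt(2.0 * np.pi)

    def marginal(b0: float) -> float:
        return float(np.sum(weights * special.expit(b0 + linear_sd * nodes)) - target_prev)

    return float(optimize.brentq(marginal, -30.0, 30.0))


def _draw_patients(config: SyntheticConfig, rng: np.random.Generator):
    """Doses, latent frailty and per-endpoint outcomes shared by both
    generator flavours."""
    n = config.n_patients
    doses = rng.normal(config.dose_mean, config.dose_sd, size=n)
    doses = np.clip(doses, 0.0, None)
    dose_sd = doses.std() if doses.std() > 0 else 1.0
    z_dose = (doses - doses.mean()) / dose_sd
    frailty = rng.normal(size=n)
    s = float(np.hypot(config.dose_effect, config.latent_effect))
    outcomes = {}
    for ep, prev in config.prevalence.items():
        b0 = _solve_intercept(prev, s)
        eta = b0 + config.dose_effect * z_dose + config.latent_effect * frailty
        outcomes[ep] = (rng.uniform(size=n) < special.expit(eta)).astype(int)
    pids = [f"P{i:04d}" for i in range(1, n + 1)]
    out_df = pd.DataFrame(outcomes, index=pd.Index(pids, name="patient_id"))
    dose_sr = pd.Series(doses, index=out_df.index, name="mean_dose_gy")
    return pids, out_df, dose_sr, frailty


def _machine_sequence(config: SyntheticConfig) -> list[str]:
    sched = config.machine_schedule
    machines = list(config.machine_offsets)
    if isinstance(sched, list):
        if len(sched) != config.n_fractions:
            raise ConfigurationError("machine_schedule list length != n_fractions")
        return [str(m) for m in sched]
    if sched == "alternate":
        return [machines[(fx - 1) % len(machines)] for fx in range(1, config.n_fractions + 1)]
    if sched.startswith("fixed:"):
        m = sched.split(":", 1)[1]
        if m not in config.machine_offsets:
            raise ConfigurationError(f"unknown machine {m!r} in schedule")
        return [m] * config.n_fractions
    raise ConfigurationError(f"unknown machine_schedule {sched!r}")


# ---------------------------------------------------------------------------
# trajectory-level generator

def generate_trajectory_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate per-feature time series directly.

    Each trajectory is ``baseline + slope * fraction + N(0, noise_sd)``.
    Per-patient slopes are ``slope_scale * (eps + d * y)`` where
    ``eps ~ N(0,1)``, so for an informative feature the class-conditional
    slope means differ by exactly ``d`` within-class SDs.  The recorded
    ground truth holds every true slope, so a noiseless cohort is
    recovered exactly by ordinary least squares.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pat, rng_slope, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    pids, outcomes, doses, frailty = _draw_patients(config, rng_pat)
    n, k, t = config.n_patients, config.n_features, config.n_fractions

    baselines = rng_slope.normal(0.0, config.baseline_sd, size=(n, k))
    slopes = rng_slope.normal(0.0, 1.0, size=(n, k))
    y_inf = outcomes[config.informative_endpoint].to_numpy()
    for idx, d in config.informative_features:
        slopes[:, idx] = slopes[:, idx] + d * y_inf
    slopes = slopes * config.slope_scale

    fractions = np.arange(1, t + 1, dtype=float)
    traj = baselines[:, :, None] + slopes[:, :, None] * fractions[None, None, :]
    if config.noise_sd > 0:
        traj = traj + rng_noise.normal(0.0, config.noise_sd, size=traj.shape)

    machine_seq = _machine_sequence(config)
    feature_names = [f"feature_{i:03d}" for i in range(k)]
    return SyntheticCohort(
        config=config,
        patient_ids=pids,
        outcomes=outcomes,
        doses=doses,
        machine_ids=[list(machine_seq) for _ in range(n)],
        feature_names=feature_names,
        trajectories=traj,
        ground_truth={
            "slopes": slopes,
            "baselines": baselines,
            "frailty": frailty,
            "informative_features": list(config.informative_features),
            "informative_endpoint": config.informative_endpoint,
        },
    )


# ---------------------------------------------------------------------------
# image-level generator

def _ellipsoid_mask(shape, radii_voxels, center=None) -> np.ndarray:
    if center is None:
        center = tuple(s / 2.0 - 0.5 for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rz, ry, rx = radii_voxels
    d2 = (
        ((zz - center[0]) / rz) ** 2
        + ((yy - center[1]) / ry) ** 2
        + ((xx - center[2]) / rx) ** 2
    )
    return d2 <= 1.0


def generate_image_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate textured 3-D HU phantoms, one volume + mask per fraction.

    The phantom mixes two HU populations inside an ellipsoidal mask.  The
    mixing weight grows linearly with fraction number at a rate twice as
    large (``drift_ratio``) in outcome-positive patients, so texture and
    first-order features drift monotonically and class separation is
    guaranteed by construction.  The spatial arrangement comes from a
    patient-fixed smoothed Gaussian field thresholded at the evolving
    mixing quantile, which yields spatially clustered (not salt-and-
    pepper) texture and strictly monotone population growth per patient.
    Machine HU offsets are added whole-volume per the fraction's machine;
    dental-artefact voxel blocks are injected per slice with probability
    ``dental_slice_rate`` and recorded in the ground truth.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pat = np.random.default_rng(ss.spawn(1)[0])
    pids, outcomes, doses, frailty = _draw_patients(config, rng_pat)
    n, t = config.n_patients, config.n_fractions
    machine_seq = _machine_sequence(config)
    months = [(fx - 1) // 20 for fx in range(1, t + 1)]
    y_inf = outcomes[config.informative_endpoint].to_numpy()
    rates = np.where(y_inf == 1, config.drift_rate * config.drift_ratio, config.drift_rate)

    base_radii = np.array([5.0, 10.0, 8.0])
    series_list: list[ImageSeries] = []
    dental_truth: dict[str, dict[int, list[int]]] = {}
    pat_seeds = ss.spawn(n)
    for i, pid in enumerate(pids):
        prng = np.random.default_rng(pat_seeds[i])
        # patient-fixed correlated field; per-fraction draws come after it
        # so the field is identical across fractions of one patient
        field3d = ndimage.gaussian_filter(prng.normal(size=PHANTOM_SHAPE), sigma=1.5)
        volumes, masks = [], []
        dental_truth[pid] = {}
        for fx in range(1, t + 1):
            shrink = max(1.0 - config.shrink_rate * (fx - 1), 0.3)
            mask = _ellipsoid_mask(PHANTOM_SHAPE, base_radii * shrink)
            w = float(np.clip(0.1 + rates[i] * (fx - 1), 0.02, 0.98))
            vals = field3d[mask]
            thr = np.quantile(vals, w)
            pop_b = np.zeros(PHANTOM_SHAPE, dtype=bool)
            pop_b[mask] = field3d[mask] <= thr
            vol = np.full(PHANTOM_SHAPE, HU_BACKGROUND, dtype=float)
            vol[mask] = HU_POP_A
            vol[pop_b] = HU_POP_B
            if config.noise_sd > 0:
                vol = vol + prng.normal(0.0, config.noise_sd, size=PHANTOM_SHAPE)
            # dental artefacts: a small voxel block inside the mask on hit slices
            artefact_slices = []
            if config.dental_slice_rate > 0:
                hits = prng.uniform(size=PHANTOM_SHAPE[0]) < config.dental_slice_rate
                for z in np.nonzero(hits)[0]:
                    inmask = np.nonzero(mask[z])
                    if inmask[0].size == 0:
                        continue
                    j = inmask[0][:3], inmask[1][:3]
                    vol[z][j] = DENTAL_ARTEFACT_HU
                    artefact_slices.append(int(z))
            if artefact_slices:
                dental_truth[pid][fx] = artefact_slices
            vol = vol + config.machine_offsets[machine_seq[fx - 1]]
            volumes.append(vol)
            masks.append(mask)
        series_list.append(
            ImageSeries(
                patient_id=pid,
                volumes=volumes,
                masks=masks,
                spacing=PHANTOM_SPACING_MM,
                machine_ids=list(machine_seq),
                months=list(months),
            )
        )
    return SyntheticCohort(
        config=config,
        patient_ids=pids,
        outcomes=outcomes,
        doses=doses,
        machine_ids=[list(machine_seq) for _ in range(n)],
        image_series=series_list,
        ground_truth={
            "drift_rates": rates,
            "frailty": frailty,
            "dental_slices": dental_truth,
            "mean_hu_slope": (HU_POP_B - HU_POP_A) * rates,
            "informative_endpoint": config.informative_endpoint,
        },
    )


# ---------------------------------------------------------------------------
# writers

def write_patient_table(cohort: SyntheticCohort, path: Path) -> None:
    df = cohort.outcomes.copy()
    df.columns = [f"endpoint_{c}" for c in df.columns]
    df["mean_dose_gy"] = cohort.doses
    df["machine_by_fraction"] = [",".join(m) for m in cohort.machine_ids]
    df.to_csv(path)


def write_trajectories(cohort: SyntheticCohort, path: Path) -> None:
    cohort.to_feature_table().to_csv(path, index=False)


def write_ground_truth(cohort: SyntheticCohort, path: Path) -> None:
    gt = {}
    for key, val in cohort.ground_truth.items():
        if isinstance(val, np.ndarray):
            gt[key] = val.tolist()
        else:
            gt[key] = val
    with open(path, "w") as fh:
        json.dump(gt, fh, sort_keys=True, indent=1, default=str)


def write_image_cohort(cohort: SyntheticCohort, outdir: Path) -> None:
    """Write NIfTI volumes/masks (pt{ID}_fx{FF}_{img|msk}.nii.gz), the
    patient table and the ground-truth JSON into ``outdir``."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort.image_series is None:
        raise ConfigurationError("cohort has no image data")
    for series in cohort.image_series:
        affine = np.diag(list(series.spacing) + [1.0])
        for fx in range(1, series.n_fractions + 1):
            img = nib.Nifti1Image(
                series.volumes[fx - 1].astype(np.float32), affine
            )
            msk = nib.Nifti1Image(
                series.masks[fx - 1].astype(np.uint8), affine
            )
            nib.save(img, outdir / f"pt{series.patient_id}_fx{fx:02d}_img.nii.gz")
            nib.save(msk, outdir / f"pt{series.patient_id}_fx{fx:02d}_msk.nii.gz")
    write_patient_table(cohort, outdir / "patients.csv")
    write_ground_truth(cohort, outdir / "ground_truth.json")


def read_image_series(outdir: Path, patient_id: str, n_fractions: int,
                      machine_ids: list[str]) -> ImageSeries:
    """Reload one patient's written NIfTI series."""
    import nibabel as nib

    outdir = Path(outdir)
    volumes, masks = [], []
    spacing = None
    for fx in range(1, n_fractions + 1):
        img = nib.load(outdir / f"pt{patient_id}_fx{fx:02d}_img.nii.gz")
        msk = nib.load(outdir / f"pt{patient_id}_fx{fx:02d}_msk.nii.gz")
        volumes.append(np.asarray(img.dataobj, dtype=float))
        masks.append(np.asarray(msk.dataobj).astype(bool))
        if spacing is None:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    months = [(fx - 1) // 20 for fx in range(1, n_fractions + 1)]
    return ImageSeries(
        patient_id=patient_id,
        volumes=volumes,
        masks=masks,
        spacing=spacing,
        machine_ids=list(machine_ids),
        months=months,
    )
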