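"""Pre-extraction conditioning of daily image-guidance series.

Patients treated on helical machines alternate between units whose HU
calibration differs, so organ voxels are shifted onto a common reference
scale before any texture is computed.  Axial slices contaminated by
high-HU dental artefacts (beam hardening) are removed from the analysis
mask, and the contra-lateral parotid is identified as the gland with the
lower mean dose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Default HU threshold above which a voxel is treated as a dental artefact.
#: Chosen above dense bone (~1500 HU) and below metal implants (>3000 HU).
DENTAL_HU_THRESHOLD = 2000.0

#: Mask dilation (in voxels) used when searching for artefact voxels near
#: the organ, so that beam-hardening streaks adjacent to the gland also
#: trigger slice exclusion.
DENTAL_DILATION_VOXELS = 3


@dataclass
class ImageSeries:
    """One patient's per-fraction HU volumes with aligned parotid masks.

    Volumes are indexed ``[z, y, x]`` (axial slices along axis 0).
    ``months`` holds the calendar-month index from treatment start for
    each fraction, used to key the machine HU-offset table.
    """

    patient_id: str
    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    spacing: tuple[float, float, float]
    machine_ids: list[str]
    months: list[int]
    normalised: bool = False
    usable: list[bool] = field(default_factory=list)
    excluded_slices: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.masks):
            raise InvalidInputError("volumes and masks must have equal length")
        for fx, (vol, msk) in enumerate(zip(self.volumes, self.masks)):
            if vol.shape != msk.shape:
                raise InvalidInputError(
                    f"fraction {fx + 1}: volume shape {vol.shape} != mask shape {msk.shape}"
                )
        if not self.usable:
            self.usable = [bool(m.any()) for m in self.masks]

    @property
    def n_fractions(self) -> int:
        return len(self.volumes)

    def copy(self) -> "ImageSeries":
        return replace(
            self,
            volumes=[v.copy() for v in self.volumes],
            masks=[m.copy() for m in self.masks],
            machine_ids=list(self.machine_ids),
            months=list(self.months),
            usable=list(self.usable),
            excluded_slices={k: list(v) for k, v in self.excluded_slices.items()},
        )


@dataclass
class MachineOffsetTable:
    """HU shift of each (machine, month) relative to the reference machine.

    The reference machine's shift is zero for every month by construction;
    a non-zero reference entry is rejected.
    """

    reference_machine: str
    offsets: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        for (machine, month), shift in self.offsets.items():
            if machine == self.reference_machine and shift != 0.0:
                raise ConfigurationError(
                    f"reference machine {machine!r} must have zero shift "
                    f"(month {month} has {shift})"
                )

    def shift_for(self, machine: str, month: int) -> float:
        if machine == self.reference_machine:
            return 0.0
        try:
            return self.offsets[(machine, month)]
        except KeyError:
            raise ConfigurationError(
                f"no HU offset for machine {machine!r}, month {month}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"machine_id": m, "month": mo, "hu_shift": s}
            for (m, mo), s in sorted(self.offsets.items())
        ]
        return pd.DataFrame(rows, columns=["machine_id", "month", "hu_shift"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_machine: str) -> "MachineOffsetTable":
        offsets = {
            (str(r.machine_id), int(r.month)): float(r.hu_shift)
            for r in df.itertuples()
        }
        return cls(reference_machine=reference_machine, offsets=offsets)


def normalize_hu(series: ImageSeries, offsets: MachineOffsetTable) -> ImageSeries:
    """Shift organ voxels of non-reference-machine fractions onto the
    reference HU scale.

    Only voxels inside the mask are shifted (the organs of interest are
    normalised; background is untouched).  The returned series carries
    ``normalised=True`` and a second application is rejected, since the
    shift is not idempotent.
    """
    if series.normalised:
        raise ConfigurationError(
            f"series {series.patient_id!r} is already normalised"
        )
    out = series.copy()
    for fx in range(out.n_fractions):
        shift = offsets.shift_for(out.machine_ids[fx], out.months[fx])
        if shift != 0.0:
            msk = out.masks[fx].astype(bool)
            vol = out.volumes[fx].astype(float, copy=True)
            vol[msk] -= shift
            out.volumes[fx] = vol
    out.normalised = True
    return out


def exclude_dental_slices(
    series: ImageSeries,
    hu_threshold: float = DENTAL_HU_THRESHOLD,
    dilation_voxels: int = DENTAL_DILATION_VOXELS,
) -> ImageSeries:
    """Zero the mask on axial slices containing dental-artefact voxels.

    A slice is excluded for a given fraction when any voxel inside the
    mask dilated by ``dilation_voxels`` exceeds ``hu_threshold``.  Voxel
    values are never modified, only masks.  A fraction whose mask is
    emptied entirely is flagged unusable so downstream extraction skips
    it.
    """
    out = series.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    for fx in range(out.n_fractions):
        msk = out.masks[fx].astype(bool)
        if not msk.any():
            continue
        region = ndimage.binary_dilation(msk, structure=struct, iterations=dilation_voxels)
        hot = (out.volumes[fx] > hu_threshold) & region
        bad_slices = sorted(np.unique(np.nonzero(hot)[0]).tolist())
        if not bad_slices:
            continue
        new_mask = msk.copy()
        new_mask[bad_slices, :, :] = False
        out.masks[fx] = new_mask
        out.excluded_slices[fx + 1] = [int(z) for z in bad_slices]
        logger.info(
            "patient %s fraction %d: excluded %d dental-artefact slice(s) %s",
            out.patient_id, fx + 1, len(bad_slices), bad_slices,
        )
        if not new_mask.any():
            out.usable[fx] = False
            warnings.warn(
                f"patient {out.patient_id} fraction {fx + 1}: all slices removed "
                "by dental-artefact exclusion; fraction flagged unusable",
                stacklevel=2,
            )
    return out


def select_contralateral(mean_doses: dict[str, float]) -> str:
    """Return the gland receiving the smaller mean dose.

    The contra-lateral (spared) parotid is defined as the gland with the
    minimum mean dose.  An exact tie deterministically returns ``'left'``
    with a warning.
    """
    if len(mean_doses) != 2:
        raise InvalidInputError(
            f"expected exactly two gland doses, got {sorted(mean_doses)}"
        )
    (g1, d1), (g2, d2) = mean_doses.items()
    if d1 == d2:
        warnings.warn(
            f"equal mean doses ({d1} Gy) for both glands; returning 'left'",
            stacklevel=2,
        )
        return "left"
    return g1 if d1 < d2 else g2
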