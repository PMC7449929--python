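"""FDG PET quantification: spherical VOIs, adaptive segmentation, TLRmax, MTV.

A study consists of a 3-D standardized-uptake-value (SUV) volume with voxel
spacing in mm and two spherical volumes of interest: one enclosing the primary
tumor, one placed on normal liver as a reference region.  The metabolically
active tumor is segmented by an adaptive threshold set between the local
background level and the peak uptake; the maximum tumor SUV divided by the
mean liver SUV gives the scanner-independent TLRmax, and the segmented voxel
volume gives the metabolic tumor volume (MTV).  Studies with small MTV are
excluded downstream because partial-volume effects make their TLRmax
underestimates.

World coordinates are in mm with voxel ``i`` covering ``[i*spacing,
(i+1)*spacing)`` along each axis (so index = floor(mm / spacing)); sphere
membership is evaluated at voxel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, SegmentationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.41
DEFAULT_MIN_VOLUME_CM3 = 5.0
DEFAULT_BACKGROUND_SHELL_VOXELS = 2.0


@dataclass
class Sphere:
    """Spherical VOI in world (mm) coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("sphere radius must be positive")


@dataclass
class PetStudy:
    """One SUV volume plus its tumor and liver VOI spheres."""

    suv: np.ndarray
    spacing: tuple[float, float, float]
    tumor_voi: Sphere
    liver_voi: Sphere

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=float)
        if self.suv.ndim != 3:
            raise ParameterError("SUV volume must be 3-dimensional")
        if np.any(self.suv < 0) or not np.all(np.isfinite(self.suv)):
            raise ParameterError("SUV values must be finite and nonnegative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be three positive voxel edge lengths (mm)")
        extent = np.array(self.suv.shape) * np.array(self.spacing)
        for name, voi in (("tumor", self.tumor_voi), ("liver", self.liver_voi)):
            c = np.asarray(voi.center_mm, dtype=float)
            if np.any(c - voi.radius_mm < 0) or np.any(c + voi.radius_mm > extent):
                raise ParameterError(f"{name} VOI sphere exceeds the volume bounds")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def _center_distance_mm(self, sphere: Sphere) -> np.ndarray:
        """Distance from every voxel center to the sphere center, in mm."""
        axes = [
            (np.arange(n) + 0.5) * s - c
            for n, s, c in zip(self.suv.shape, self.spacing, sphere.center_mm)
        ]
        dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
        return np.sqrt(dx**2 + dy**2 + dz**2)

    def voi_mask(self, sphere: Sphere) -> np.ndarray:
        """Boolean mask of voxels whose centers lie inside the sphere."""
        return self._center_distance_mm(sphere) <= sphere.radius_mm


@dataclass
class SegmentationResult:
    """Adaptive-threshold tumor segmentation of one study."""

    mask: np.ndarray
    threshold: float
    mtv_cm3: float
    tlr_max: float | None = None
    study_id: str | None = field(default=None)


def segment_tumor(
    study: PetStudy,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    background_shell_voxels: float = DEFAULT_BACKGROUND_SHELL_VOXELS,
) -> SegmentationResult:
    """Segment the metabolically active tumor with an adaptive threshold.

    The threshold adapts to both the tumor and its surroundings:
    ``T = B + fraction * (P - B)`` where ``P`` is the peak SUV inside the tumor
    VOI and ``B`` the mean SUV in a thin shell just outside it.  The mask is
    every VOI voxel with SUV >= T.

    Parameters
    ----------
    study
        The PET study to segment.
    fraction
        Position of the threshold between background and peak, in (0, 1).
        0.41 is a common adaptive-threshold choice.
    background_shell_voxels
        Width of the background shell outside the VOI, in voxel widths
        (converted to mm with the largest spacing).

    Raises
    ------
    SegmentationError
        If the mask comes out empty, or if the tumor VOI contains no voxel
        above the background level.
    """
    if not 0 < fraction < 1:
        raise ParameterError("threshold fraction must lie strictly in (0, 1)")
    dist = study._center_distance_mm(study.tumor_voi)
    voi = dist <= study.tumor_voi.radius_mm
    if not voi.any():
        raise SegmentationError("tumor VOI contains no voxel centers")
    shell_mm = background_shell_voxels * max(study.spacing)
    shell = (dist > study.tumor_voi.radius_mm) & (dist <= study.tumor_voi.radius_mm + shell_mm)
    if not shell.any():
        raise SegmentationError("background shell is empty; VOI touches the volume edge")
    background = float(study.suv[shell].mean())
    peak = float(study.suv[voi].max())
    if peak <= background:
        raise SegmentationError("no uptake above background inside the tumor VOI")
    threshold = background + fraction * (peak - background)
    mask = voi & (study.suv >= threshold)
    if not mask.any():
        raise SegmentationError("adaptive threshold produced an empty mask")
    mtv = float(mask.sum()) * study.voxel_volume_cm3
    return SegmentationResult(mask=mask, threshold=threshold, mtv_cm3=mtv)


def tlr_max(study: PetStudy, mask: np.ndarray) -> float:
    """Maximum tumor SUV over the mask divided by the mean liver-VOI SUV.

    The liver normalization removes scanner- and reconstruction-dependent
    scale: multiplying the whole volume by a constant leaves TLRmax unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("tumor mask is empty")
    liver = study.voi_mask(study.liver_voi)
    if not liver.any():
        raise SegmentationError("liver VOI contains no voxel centers")
    liver_mean = float(study.suv[liver].mean())
    if liver_mean == 0:
        raise ParameterError("liver mean SUV is zero; TLRmax undefined")
    return float(study.suv[mask].max()) / liver_mean


def quantify_study(
    study: PetStudy,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    background_shell_voxels: float = DEFAULT_BACKGROUND_SHELL_VOXELS,
    study_id: str | None = None,
) -> SegmentationResult:
    """Segment the tumor and fill in TLRmax in one step."""
    result = segment_tumor(study, fraction=fraction, background_shell_voxels=background_shell_voxels)
    result.tlr_max = tlr_max(study, result.mask)
    result.study_id = study_id
    return result


def filter_small_tumors(
    results: list[SegmentationResult],
    min_volume_cm3: float = DEFAULT_MIN_VOLUME_CM3,
) -> list[SegmentationResult]:
    """Drop studies whose MTV is not strictly greater than ``min_volume_cm3``.

    Small lesions underestimate TLRmax through partial-volume effects, so they
    are excluded from correlation analyses; the boundary itself is excluded.
    """
    kept = [r for r in results if r.mtv_cm3 > min_volume_cm3]
    excluded = len(results) - len(kept)
    if excluded:
        logger.info("excluded %d studies with MTV <= %.1f cm^3", excluded, min_volume_cm3)
    return kept
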