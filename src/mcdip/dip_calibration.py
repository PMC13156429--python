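"""Phase-contrast total-CBF quantification and FD* -> absolute rCBF calibration.

Total cerebral blood flow (tCBF) is the sum of the volumetric flow rates
through the two internal carotid and two vertebral arteries, measured on a
velocity-encoded cine at the mid-C2 level. The vessel lumen is delineated by
pulsatility-based segmentation: pixels whose velocity-vs-cardiac-phase
waveform correlates with the waveform at an arterial seed pixel.

tCBF normalized by brain mass (brain volume × 1.06 g/mL tissue density)
gives the whole-brain perfusion in mL/100 g/min. Assuming rCBF is linear in
the IVIM perfusion surrogate FD*, a conversion factor maps the relative FD*
map to absolute units. We compute it as normalized tCBF divided by the
brain-mean FD* over converged voxels: this distributes the measured total
flow over voxels proportionally to FD*, so the brain-mean of the calibrated
map reproduces the normalized tCBF exactly (a conservation property the
tests assert), and a global gain on the DWI signal chain cancels out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_model import (
    PerfusionCalibration,
    RCBFMap,
    RCBFMethod,
    VelocityCine,
    VesselLabel,
)

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """Raised when pulsatility-based lumen segmentation cannot proceed."""


@dataclass
class VesselROI:
    """Segmented vessel lumen on a cine plane."""

    mask: np.ndarray
    seed_point: Tuple[int, int]
    vessel_label: VesselLabel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask[self.seed_point]:
            raise ValueError("lumen mask must contain the seed point")


def segment_lumen(
    cine: VelocityCine,
    seed_point: Tuple[int, int],
    threshold: float = 0.85,
    vessel_label: VesselLabel = VesselLabel.L_ICA,
) -> VesselROI:
    """Pulsatility-based lumen segmentation.

    The seed pixel's velocity waveform over the cardiac cycle is the
    reference; the lumen is the connected component containing the seed of
    pixels whose waveform Pearson-correlates with the reference at or above
    ``threshold``. Pixels with constant waveforms (no pulsatility) never
    qualify.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    v = cine.velocity
    ref = v[seed_point[0], seed_point[1], :]
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0:
        raise SegmentationError("no pulsatility at seed: constant velocity waveform")
    cent = v - v.mean(axis=2, keepdims=True)
    ss = np.einsum("ijk,ijk->ij", cent, cent)
    num = cent @ ref_c
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(ss * ref_ss)
    candidate = np.nan_to_num(corr, nan=-1.0) >= threshold
    labels, _ = ndimage.label(candidate)
    seed_label = labels[seed_point[0], seed_point[1]]
    if seed_label == 0:
        raise SegmentationError("empty lumen: seed fails its own threshold")
    mask = labels == seed_label
    return VesselROI(mask=mask, seed_point=tuple(seed_point), vessel_label=vessel_label)


def vessel_flow(cine: VelocityCine, roi: VesselROI) -> float:
    """Cycle-mean volumetric flow (mL/min) through a segmented lumen.

    Per cardiac phase the flow is the sum over lumen pixels of
    velocity (cm/s) × pixel area (mm²); cm/s·mm² = 10 mm³/s, i.e.
    0.6 mL/min. Signed velocities are summed as-is, preserving flow
    direction.
    """
    if roi.mask.shape != cine.velocity.shape[:2]:
        raise ValueError("ROI mask does not match the cine plane")
    per_phase = cine.velocity[roi.mask, :].sum(axis=0)  # cm/s summed over pixels
    return float(per_phase.mean() * cine.pixel_area * 0.6)


def total_cbf(flows: Sequence[float]) -> float:
    """Total CBF (mL/min): the sum of the four feeding-artery flows."""
    flows = list(flows)
    if len(flows) != 4:
        raise ValueError("expected exactly four vessel flows")
    for q in flows:
        if q <= 0:
            logger.warning("non-positive vessel flow %.3f mL/min", q)
    return float(sum(flows))


def normalize_tcbf(tcbf: float, brain_volume: float, density: float = 1.06) -> float:
    """Convert tCBF (mL/min) to mL/100 g/min using brain volume and density."""
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    return tcbf / (brain_volume * density) * 100.0


def calibrate_rcbf(
    fd_star_map: np.ndarray,
    mask: np.ndarray,
    tcbf_normalized: float,
    valid: Optional[np.ndarray] = None,
    method: RCBFMethod = RCBFMethod.DIP_2ND_MC,
    vessel_flows: Optional[Dict[VesselLabel, float]] = None,
    brain_volume_ml: float = float("nan"),
    tissue_density: float = 1.06,
) -> Tuple[RCBFMap, PerfusionCalibration]:
    """Scale the relative FD* map to absolute rCBF using normalized tCBF.

    ``conversion_factor = tcbf_normalized / mean(FD*)`` over mask voxels
    whose fit converged (``valid``); the map is emitted for all mask voxels,
    with non-converged ones flagged invalid. Under the IVIM bounds FD* is
    non-negative, so no clamping is needed (asserted).
    """
    fd = np.asarray(fd_star_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fd.shape != mask.shape:
        raise ValueError("fd_star_map and mask shapes differ")
    if valid is None:
        valid = np.isfinite(fd)
    calib_mask = mask & np.asarray(valid, dtype=bool) & np.isfinite(fd)
    n_valid = int(calib_mask.sum())
    if n_valid == 0:
        raise ValueError("calibration mask is empty")
    total_fd = float(fd[calib_mask].sum())
    if total_fd <= 0:
        raise ValueError("total FD* over the calibration mask is not positive")
    mean_fd = total_fd / n_valid
    conversion = tcbf_normalized / mean_fd

    values = np.full(fd.shape, np.nan)
    values[mask] = conversion * fd[mask]
    invalid = mask & ~calib_mask
    assert np.all(values[calib_mask] >= 0), "negative rCBF cannot occur under bounds"

    rcbf = RCBFMap(values=values, mask=mask, method=method, invalid=invalid)
    calibration = PerfusionCalibration(
        vessel_flows=dict(vessel_flows or {}),
        tcbf_ml_min=float(sum((vessel_flows or {}).values())),
        brain_volume_ml=brain_volume_ml,
        tissue_density=tissue_density,
        tcbf_normalized=float(tcbf_normalized),
        total_fd_star=total_fd,
        mean_fd_star=mean_fd,
        conversion_factor=float(conversion),
        n_voxels=n_valid,
    )
    return rcbf, calibration
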