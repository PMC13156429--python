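"""Shared domain types, the IVIM forward model, and unit conventions.

Unit conventions used throughout the package:

* diffusion coefficients (``D``, ``D*``, ``FD*``) in mm²/s, b-values in s/mm²;
* velocities in cm/s, areas in mm², flows in mL/min;
* ASL timing constants in **seconds** (the standard single-compartment scale
  factor of 6000 presumes seconds; acquisition protocols usually print ms);
* regional cerebral blood flow (rCBF) in mL/100 g/min;
* voxel dimensions in mm; a voxel's physical volume is the product of its
  dimensions, and array indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Diffusion weightings (s/mm²) of the multi-b-value protocol the pipeline
#: is designed around: dense low-b sampling for the perfusion compartment and
#: five high-b points (>= 200 s/mm²) for the tissue-diffusion step.
DEFAULT_B_VALUES: Tuple[float, ...] = (
    0.0, 10.0, 20.0, 30.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0
)


class GradientScheme(str, Enum):
    """Diffusion-gradient motion-compensation scheme.

    ``SECOND_ORDER_MC`` nulls both the first (velocity) and second
    (acceleration) gradient moments, ``FIRST_ORDER_MC`` nulls only the first,
    and ``NON_MC`` nulls neither, so coherent bulk motion accrues net phase.
    """

    SECOND_ORDER_MC = "2nd-mc"
    FIRST_ORDER_MC = "1st-mc"
    NON_MC = "non-mc"


#: Residual (velocity, acceleration) moment weights per scheme: second-order
#: compensation nulls both moments, first-order nulls only the velocity
#: moment, and the uncompensated scheme retains both.
DEFAULT_MOMENT_WEIGHTS = {
    GradientScheme.SECOND_ORDER_MC: (0.0, 0.0),
    GradientScheme.FIRST_ORDER_MC: (0.0, 1.0),
    GradientScheme.NON_MC: (1.0, 1.0),
}


class RCBFMethod(str, Enum):
    """Provenance label for an rCBF map."""

    DIP_2ND_MC = "dip-2nd-mc"
    DIP_1ST_MC = "dip-1st-mc"
    DIP_NON_MC = "dip-non-mc"
    ASL = "asl"
    TRUTH = "truth"


#: Mapping from gradient scheme to the rCBF-map label of its DIP output.
SCHEME_TO_METHOD = {
    GradientScheme.SECOND_ORDER_MC: RCBFMethod.DIP_2ND_MC,
    GradientScheme.FIRST_ORDER_MC: RCBFMethod.DIP_1ST_MC,
    GradientScheme.NON_MC: RCBFMethod.DIP_NON_MC,
}


class VesselLabel(str, Enum):
    """The four brain-feeding arteries measured at the mid-C2 level."""

    L_ICA = "l-ica"
    R_ICA = "r-ica"
    L_VA = "l-va"
    R_VA = "r-va"


@dataclass(frozen=True)
class BValueScheme:
    """A b-value table plus the motion-compensation scheme it was acquired with.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm², strictly increasing, starting at 0.
    scheme
        Motion-compensation scheme of the diffusion gradients.
    moment_weights
        Dimensionless residual (first, second) gradient-moment weights
        ``(w1, w2)``.  Used only by the phantom's bulk-motion model; defaults
        follow the scheme (``(0,0)`` for second-order compensation, ``(0,1)``
        for first-order, ``(1,1)`` for uncompensated).
    gradient_separation_ms, gradient_duration_ms
        Optional acquisition metadata (Δ and δ, ms); carried but never used
        numerically.
    """

    b_values: Tuple[float, ...] = DEFAULT_B_VALUES
    scheme: GradientScheme = GradientScheme.SECOND_ORDER_MC
    moment_weights: Optional[Tuple[float, float]] = None
    gradient_separation_ms: Optional[float] = None
    gradient_duration_ms: Optional[float] = None

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("b_values must be a 1-D table with >= 2 entries")
        if b[0] != 0.0:
            raise ValueError("b_values must start at b = 0 s/mm²")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        scheme = GradientScheme(self.scheme)
        object.__setattr__(self, "scheme", scheme)
        if self.moment_weights is None:
            object.__setattr__(
                self, "moment_weights", DEFAULT_MOMENT_WEIGHTS[scheme]
            )
        w1, w2 = self.moment_weights
        if w1 < 0 or w2 < 0:
            raise ValueError("moment_weights must be non-negative")
        if scheme is GradientScheme.SECOND_ORDER_MC and (w1, w2) != (0.0, 0.0):
            raise ValueError("second-order compensation implies weights (0, 0)")
        if scheme is GradientScheme.FIRST_ORDER_MC and w1 != 0.0:
            raise ValueError("first-order compensation implies w1 == 0")

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def n_b(self) -> int:
        return len(self.b_values)


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted series (x, y, z, b) with its b-value scheme.

    Intensities are in arbitrary scanner units and must be non-negative
    (magnitude images). ``n_directions`` records how many orthogonal
    diffusion directions were averaged into the trace.
    """

    signal: np.ndarray
    scheme: BValueScheme
    voxel_dims: Tuple[float, float, float] = (2.0, 2.0, 6.0)
    n_directions: int = 3

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, b)")
        if self.signal.shape[3] != self.scheme.n_b:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but the scheme "
                f"lists {self.scheme.n_b} b-values"
            )
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal intensities must be >= 0")
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def b0(self) -> np.ndarray:
        """The non-diffusion-weighted (b = 0) volume."""
        return self.signal[..., 0]


@dataclass
class IVIMParameterMap:
    """Voxelwise IVIM parameter maps from the stepwise biexponential fit.

    Outside ``mask``, and at voxels where the fit did not converge, map
    values are NaN (flagged invalid, never silently zero-filled).
    """

    s0: np.ndarray
    f: np.ndarray
    d_star: np.ndarray
    d: np.ndarray
    fd_star: np.ndarray
    nrmse: np.ndarray
    mask: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        shape = np.asarray(self.mask).shape
        for name in ("s0", "f", "d_star", "d", "fd_star", "nrmse", "converged"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != mask shape {shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.converged = np.asarray(self.converged, dtype=bool)
        inside = self.valid_mask
        f_in = self.f[inside]
        if f_in.size and (np.any(f_in < 0) or np.any(f_in > 1)):
            raise ValueError("perfusion fraction f must lie in [0, 1] within mask")
        if inside.any() and not np.allclose(
            self.fd_star[inside], self.f[inside] * self.d_star[inside],
            rtol=1e-12, atol=0.0,
        ):
            raise ValueError("fd_star must equal f * d_star elementwise")

    @property
    def valid_mask(self) -> np.ndarray:
        """Voxels inside the brain mask whose fit converged."""
        return self.mask & self.converged

    @property
    def convergence_fraction(self) -> float:
        n = int(self.mask.sum())
        return float(self.converged[self.mask].sum() / n) if n else 0.0


@dataclass
class VelocityCine:
    """Through-plane velocity images over one cardiac cycle for a vessel plane.

    ``velocity`` is (x, y, phase) in cm/s, signed by flow direction;
    ``pixel_area`` in mm²; ``venc`` is the maximum encodable velocity.
    """

    velocity: np.ndarray
    pixel_area: float
    venc: float = 80.0
    heart_rate: float = 60.0

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 3:
            raise ValueError("velocity must be 3-D (x, y, phase)")
        if self.velocity.shape[2] < 2:
            raise ValueError("need at least 2 cardiac phases")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if np.any(np.abs(self.velocity) > self.venc + 1e-12):
            raise ValueError("|velocity| may not exceed venc")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[2]


@dataclass
class PerfusionCalibration:
    """Record of the FD* -> absolute rCBF calibration.

    ``conversion_factor`` is the ratio of phase-contrast-normalized total CBF
    (mL/100 g/min) to the brain-mean FD* (mm²/s) over converged voxels; see
    :func:`mcdip.dip_calibration.calibrate_rcbf` for the adopted reading of
    the calibration.
    """

    vessel_flows: dict
    tcbf_ml_min: float
    brain_volume_ml: float
    tissue_density: float
    tcbf_normalized: float
    total_fd_star: float
    mean_fd_star: float
    conversion_factor: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "vessel_flows_ml_min": {
                (k.value if isinstance(k, VesselLabel) else str(k)): float(v)
                for k, v in self.vessel_flows.items()
            },
            "tcbf_ml_min": float(self.tcbf_ml_min),
            "brain_volume_ml": float(self.brain_volume_ml),
            "tissue_density_g_ml": float(self.tissue_density),
            "tcbf_normalized_ml_100g_min": float(self.tcbf_normalized),
            "total_fd_star_mm2_s": float(self.total_fd_star),
            "mean_fd_star_mm2_s": float(self.mean_fd_star),
            "conversion_factor": float(self.conversion_factor),
            "n_voxels": int(self.n_voxels),
            "conversion_reading": "tcbf_normalized / brain-mean FD* over converged voxels",
        }


@dataclass(frozen=True)
class ASLParams:
    """Constants of the single-compartment pCASL quantification model.

    All times in seconds. Defaults: brain–blood partition coefficient
    λ = 0.9 mL/g, arterial blood T1 = 1.65 s, post-labeling delay 1.525 s,
    label duration 1.8 s, labeling efficiency α = 0.85.
    """

    lambda_partition: float = 0.9
    t1_blood: float = 1.65
    pld: float = 1.525
    tau: float = 1.8
    alpha: float = 0.85

    def __post_init__(self) -> None:
        for name in ("lambda_partition", "t1_blood", "pld", "tau", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency alpha cannot exceed 1")

    @classmethod
    def from_ms(cls, *, lambda_partition: float = 0.9, t1_blood_ms: float = 1650.0,
                pld_ms: float = 1525.0, tau_ms: float = 1800.0,
                alpha: float = 0.85) -> "ASLParams":
        """Build from millisecond timings as printed in acquisition protocols."""
        return cls(
            lambda_partition=lambda_partition,
            t1_blood=t1_blood_ms / 1000.0,
            pld=pld_ms / 1000.0,
            tau=tau_ms / 1000.0,
            alpha=alpha,
        )


@dataclass
class RCBFMap:
    """A regional cerebral blood flow map in mL/100 g/min.

    ``invalid`` flags voxels inside the mask whose value should be excluded
    from statistics (e.g. non-converged fits); NaN outside the mask.
    """

    values: np.ndarray
    mask: np.ndarray
    method: RCBFMethod
    invalid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        self.method = RCBFMethod(self.method)
        if self.invalid is None:
            self.invalid = np.zeros_like(self.mask)
        else:
            self.invalid = np.asarray(self.invalid, dtype=bool)
        good = self.mask & ~self.invalid
        vals = self.values[good]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("valid rCBF values must be finite")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.mask & ~self.invalid

    def valid_values(self, roi: Optional[np.ndarray] = None) -> np.ndarray:
        """Finite, valid values inside the map (optionally intersected with a ROI)."""
        sel = self.valid_mask if roi is None else (self.valid_mask & roi)
        return self.values[sel]


def biexp_signal(s0, f, d_star, d, b):
    """Biexponential (IVIM) diffusion signal.

    ``S(b) = S0 * [F * exp(-b * D*) + (1 - F) * exp(-b * D)]`` with the
    perfusion fraction ``F`` weighting the fast pseudo-diffusion compartment
    ``D*`` against the tissue compartment ``D``.

    All arguments may be scalars or broadcastable arrays. Continuous and
    non-increasing in ``b`` for valid parameters.
    """
    s0 = np.asarray(s0, dtype=float)
    f = np.asarray(f, dtype=float)
    d_star = np.asarray(d_star, dtype=float)
    d = np.asarray(d, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("s0 must be non-negative")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f must lie in [0, 1]")
    if np.any(d <= 0):
        raise ValueError("d must be strictly positive")
    if np.any(d_star < d):
        raise ValueError("d_star must be >= d")
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d))
    return out if out.ndim else float(out)


def compute_trace(
    direction_signals: Sequence[np.ndarray],
    scheme: BValueScheme,
    voxel_dims: Tuple[float, float, float] = (2.0, 2.0, 6.0),
) -> DWISeries:
    """Combine three orthogonal-direction DWI series into a trace series.

    The trace is the voxelwise geometric mean of the three direction images
    at each b-value — equivalent to averaging the per-direction log-signal
    decay rates, so the trace ADC is the mean of the directional ADCs.
    """
    if len(direction_signals) != 3:
        raise ValueError("trace formation requires exactly 3 direction images")
    arrs = [np.asarray(a, dtype=float) for a in direction_signals]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("direction images must share a common shape")
    for i, a in enumerate(arrs):
        if np.any(a < 0):
            raise ValueError(f"direction image {i} has negative intensities")
    prod = arrs[0] * arrs[1] * arrs[2]
    if np.any(prod == 0):
        logger.warning(
            "trace: %d voxel-samples with a zero direction signal map to 0",
            int(np.count_nonzero(prod == 0)),
        )
    trace = np.cbrt(prod)
    return DWISeries(signal=trace, scheme=scheme, voxel_dims=voxel_dims)
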