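"""Brain masking and stepwise biexponential IVIM fitting.

The fit is segmented for robustness: the tissue diffusion coefficient D is
estimated first by log-linear least squares on the high-b portion of the
decay (b >= 200 s/mm², where the perfusion compartment has essentially
decayed away), then the perfusion parameters (S0, F, D*) are estimated by
bounded trust-region nonlinear least squares over all b-values with D held
fixed. Because a residual perfusion tail at b >= 200 biases the one-pass D
slightly high, :func:`fit_ivim_map` optionally iterates: it subtracts the
fitted perfusion component from the high-b signal, re-estimates D, and
repeats the perfusion step, finishing with an Aitken extrapolation of the
D iterates and a cheap fixed-point residual check that triggers extra
cycles only where the contraction is slow (poor D*/D contrast). This
recovers noise-free biexponential truth to a small fraction of a percent
in every parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .core_model import BValueScheme, DWISeries, IVIMParameterMap

logger = logging.getLogger(__name__)


class MaskError(ValueError):
    """Raised when brain masking produces no usable voxels."""


@dataclass(frozen=True)
class FitConfig:
    """Parameters of the masking and stepwise-fitting procedure.

    ``high_b_threshold`` (s/mm²) separates the tissue-diffusion step from
    the perfusion step. Bounds keep the solution physiologic: F in [0,1],
    D in [1e-5, 4e-3] mm²/s, D* in [D, 0.5] mm²/s (enforcing D* > D), S0
    non-negative. ``n_refinements`` is the number of perfusion-corrected
    re-estimations of D after the initial pass (0 = plain two-step fit).
    """

    high_b_threshold: float = 200.0
    f_bounds: Tuple[float, float] = (0.0, 1.0)
    d_bounds: Tuple[float, float] = (1e-5, 4e-3)
    d_star_upper: float = 0.5
    d_star_init: float = 10e-3
    f_init_cap: float = 0.5
    max_iterations: int = 100
    tolerance: float = 1e-12
    n_refinements: int = 3
    mask_threshold_fraction: float = 0.2
    mask_percentile: float = 99.0
    # surface erosion of the mask (iterations of binary erosion), emulating
    # brain-extraction tools that strip the outer CSF rim; 0 keeps the raw
    # intensity mask
    mask_erosion_iterations: int = 0
    min_converged_fraction: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.f_bounds, self.d_bounds):
            if not lo < hi:
                raise ValueError("bounds must satisfy lower < upper")
        if self.d_star_upper <= self.d_bounds[1]:
            raise ValueError("d_star upper bound must exceed the d upper bound")

    def high_b_indices(self, b_values: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(b_values) >= self.high_b_threshold)
        if idx.size < 3:
            raise ValueError(
                f"need >= 3 b-values at or above {self.high_b_threshold} s/mm²"
            )
        return idx


@dataclass
class FitQuality:
    """Per-voxel goodness-of-fit record."""

    nrmse: float
    converged: bool
    n_points: int


def make_brain_mask(b0_volume: np.ndarray, config: Optional[FitConfig] = None) -> np.ndarray:
    """Intensity-threshold brain mask from the b = 0 volume.

    Keeps voxels above ``mask_threshold_fraction`` of the 99th-percentile
    intensity (zero-intensity background always excluded) and retains the
    largest connected component. Optional surface erosion
    (``mask_erosion_iterations``) strips the outer CSF rim the way
    brain-extraction tools do.
    """
    cfg = config or FitConfig()
    b0 = np.asarray(b0_volume, dtype=float)
    if np.any(b0 < 0):
        raise ValueError("b0 volume must be non-negative")
    threshold = cfg.mask_threshold_fraction * np.percentile(b0, cfg.mask_percentile)
    candidate = (b0 > threshold) & (b0 > 0)
    if not candidate.any():
        raise MaskError(
            "empty brain mask; lower mask_threshold_fraction or check intensities"
        )
    labels, n_comp = ndimage.label(candidate)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        candidate = labels == keep
    if cfg.mask_erosion_iterations > 0:
        eroded = ndimage.binary_erosion(
            candidate, iterations=cfg.mask_erosion_iterations
        )
        if eroded.any():
            candidate = eroded
        else:
            logger.warning("mask erosion would empty the mask; skipped")
    return candidate


def brain_volume(mask: np.ndarray, voxel_dims: Tuple[float, float, float]) -> float:
    """Total volume (mL) of a voxel mask: count × voxel volume / 1000."""
    if any(v <= 0 for v in voxel_dims):
        raise ValueError("voxel_dims must be positive")
    return float(np.count_nonzero(mask) * np.prod(voxel_dims) / 1000.0)


def fit_diffusion_step(
    signal: np.ndarray,
    scheme: BValueScheme,
    config: Optional[FitConfig] = None,
) -> Tuple[float, float]:
    """Step 1: log-linear estimate of D from the high-b decay of one voxel.

    Fits ln S = ln S0_high − b·D over b >= ``high_b_threshold`` and returns
    (D clamped to bounds, S0_high). Raises if any included signal is
    non-positive (the caller flags such voxels non-converged).
    """
    cfg = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_array
    if signal.shape != b.shape:
        raise ValueError("signal length must match the b-value table")
    idx = cfg.high_b_indices(b)
    s_high = signal[idx]
    if np.any(s_high <= 0):
        raise ValueError("non-positive signal at a high b-value")
    d, s0_high = _loglinear_d(s_high[None, :], b[idx], cfg)
    return float(d[0]), float(s0_high[0])


def _loglinear_d(
    s_high: np.ndarray, b_high: np.ndarray, cfg: FitConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized log-linear D fit; rows are voxels. Clamps D to bounds."""
    y = np.log(s_high)
    bc = b_high - b_high.mean()
    slope = (y * bc).sum(axis=1) / (bc * bc).sum()
    intercept = y.mean(axis=1) - slope * b_high.mean()
    d = np.clip(-slope, cfg.d_bounds[0], cfg.d_bounds[1])
    return d, np.exp(intercept)


def compute_nrmse(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Root-mean-square residual normalized by the mean observed signal.

    Invariant to common positive rescaling of both vectors; 0 iff the fit
    is perfect.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must be equal-length vectors (n >= 2)")
    mean_obs = observed.mean()
    if mean_obs <= 0:
        raise ValueError("nRMSE undefined for non-positive mean observed signal")
    return float(np.sqrt(np.mean((observed - fitted) ** 2)) / mean_obs)


def _biexp_fixed_d(theta: np.ndarray, b: np.ndarray, d: float) -> np.ndarray:
    s0, f, d_star = theta
    return s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d))


def fit_perfusion_step(
    signal: np.ndarray,
    scheme: BValueScheme,
    d_fixed: float,
    config: Optional[FitConfig] = None,
    s0_high: Optional[float] = None,
    init: Optional[Tuple[float, float, float]] = None,
) -> Tuple[float, float, float, FitQuality]:
    """Step 2: bounded nonlinear fit of (S0, F, D*) with D frozen.

    Uses a trust-region-reflective least-squares solver honoring the bounds
    F in [0,1], D* in [d_fixed, upper], S0 >= 0. Initialization: S0 from the
    b = 0 signal, F from the step-1 extrapolated intercept
    (``1 − S0_high/S0``, capped), D* at its physiologic prior.
    """
    cfg = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_array
    if signal.shape != b.shape:
        raise ValueError("signal length must match the b-value table")
    if not (cfg.d_bounds[0] <= d_fixed <= cfg.d_bounds[1]):
        raise ValueError("d_fixed outside configured bounds")

    s0_init = max(float(signal[0]), 1e-12)
    if init is not None:
        # warm start (used by the refinement loop in fit_ivim_map)
        x0 = np.array(init, dtype=float)
    else:
        if s0_high is None:
            f_init = 0.1
        else:
            f_init = float(np.clip(1.0 - s0_high / s0_init, 0.0, cfg.f_init_cap))
        d_star_init = max(cfg.d_star_init, 2.0 * d_fixed)
        x0 = np.array([s0_init, max(f_init, 1e-6), d_star_init])
    lower = np.array([0.0, cfg.f_bounds[0], d_fixed])
    upper = np.array([np.inf, cfg.f_bounds[1], cfg.d_star_upper])
    x0 = np.clip(x0, lower + 1e-15, np.minimum(upper, 1e300))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _biexp_fixed_d(theta, b, d_fixed) - signal

    def jacobian(theta: np.ndarray) -> np.ndarray:
        s0, f, d_star = theta
        e_star = np.exp(-b * d_star)
        e_d = np.exp(-b * d_fixed)
        jac = np.empty((b.size, 3))
        jac[:, 0] = f * e_star + (1.0 - f) * e_d
        jac[:, 1] = s0 * (e_star - e_d)
        jac[:, 2] = -s0 * f * b * e_star
        return jac

    try:
        res = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=(lower, upper),
            method="trf",
            ftol=cfg.tolerance,
            xtol=cfg.tolerance,
            gtol=cfg.tolerance,
            max_nfev=cfg.max_iterations * 3,
            x_scale=np.array([max(s0_init, 1.0), 0.1, 1e-2]),
        )
        success = bool(res.success) and np.all(np.isfinite(res.x))
        s0_fit, f_fit, d_star_fit = (res.x if success else x0)
    except Exception:  # numerical failure at a pathological voxel
        success = False
        s0_fit, f_fit, d_star_fit = x0

    fitted = _biexp_fixed_d(np.array([s0_fit, f_fit, d_star_fit]), b, d_fixed)
    try:
        nrmse = compute_nrmse(signal, fitted)
    except ValueError:
        nrmse = np.nan
        success = False
    quality = FitQuality(nrmse=nrmse, converged=success, n_points=int(b.size))
    return float(s0_fit), float(f_fit), float(d_star_fit), quality


def fit_ivim_map(
    dwi: DWISeries,
    mask: Optional[np.ndarray] = None,
    config: Optional[FitConfig] = None,
    denoise_hook: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> IVIMParameterMap:
    """Voxelwise stepwise biexponential fit over a brain mask.

    Applies the optional denoising hook (a volume-to-volume transform, e.g.
    an MP-PCA implementation; default identity), then per masked voxel the
    diffusion and perfusion steps, plus ``config.n_refinements`` passes of
    perfusion-corrected D re-estimation. Non-converged voxels keep their
    initialization values and are flagged, so downstream calibration can
    exclude them rather than absorb zeros.
    """
    cfg = config or FitConfig()
    signal = dwi.signal
    if denoise_hook is not None:
        signal = np.asarray(denoise_hook(signal), dtype=float)
        if signal.shape != dwi.signal.shape:
            raise ValueError("denoise hook changed the series shape")
    if mask is None:
        mask = make_brain_mask(signal[..., 0], cfg)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask shape does not match the DWI volume")

    shape = dwi.shape
    nan = np.full(shape, np.nan)
    out = {k: nan.copy() for k in ("s0", "f", "d_star", "d", "fd_star", "nrmse")}
    converged = np.zeros(shape, dtype=bool)

    n_mask = int(mask.sum())
    if n_mask == 0:
        logger.warning("fit_ivim_map: empty mask, returning empty parameter map")
        return IVIMParameterMap(mask=mask, converged=converged, **out)

    b = dwi.scheme.b_array
    hi = cfg.high_b_indices(b)
    bc_hi = b[hi] - b[hi].mean()
    ss_bc = float((bc_hi**2).sum())
    vox = signal[mask]  # (n_vox, n_b)

    usable = np.all(vox[:, hi] > 0, axis=1)
    d_map = np.full(n_mask, cfg.d_bounds[0])
    s0_high_map = np.full(n_mask, np.nan)
    if usable.any():
        d_map[usable], s0_high_map[usable] = _loglinear_d(
            vox[usable][:, hi], b[hi], cfg
        )

    res = {k: np.full(n_mask, np.nan) for k in ("s0", "f", "d_star", "nrmse")}
    ok = np.zeros(n_mask, dtype=bool)
    d_residual = np.zeros(n_mask)
    warm_map: dict = {}

    def run_cycles(i: int, n_cycles: int, d_tol: Optional[float]) -> None:
        """Refinement cycles for one voxel; updates the result arrays.

        Each cycle runs ``n_refinements`` subtract-and-refit iterates of D,
        Aitken-extrapolates the last three toward the fixed point, and
        closes with a perfusion fit; ``d_residual`` records how far the
        closing solution still is from self-consistency.
        """
        y = vox[i]
        d_i = d_map[i]
        warm = warm_map.get(i)
        s0_i = f_i = ds_i = np.nan
        quality = None
        for _ in range(n_cycles):
            d_hist = [d_i]
            aborted = False
            for _ in range(cfg.n_refinements):
                s0_i, f_i, ds_i, quality = fit_perfusion_step(
                    y, dwi.scheme, d_i, cfg, s0_high=s0_high_map[i], init=warm
                )
                if not quality.converged:
                    aborted = True
                    break
                warm = (s0_i, f_i, ds_i)
                corrected = y[hi] - s0_i * f_i * np.exp(-b[hi] * ds_i)
                if np.any(corrected <= 0):
                    aborted = True
                    break
                d_new = float(_loglinear_d(corrected[None, :], b[hi], cfg)[0][0])
                step = abs(d_new - d_i)
                d_i = d_new
                d_hist.append(d_i)
                if step <= 1e-12:
                    break
            if len(d_hist) >= 3:
                d2, d1, d0 = d_hist[-1], d_hist[-2], d_hist[-3]
                denom = (d2 - d1) - (d1 - d0)
                if abs(denom) > 1e-18:
                    d_acc = d2 - (d2 - d1) ** 2 / denom
                    if np.isfinite(d_acc) and cfg.d_bounds[0] <= d_acc <= cfg.d_bounds[1]:
                        d_i = float(d_acc)
            s0_i, f_i, ds_i, quality = fit_perfusion_step(
                y, dwi.scheme, d_i, cfg, s0_high=s0_high_map[i], init=warm
            )
            d_residual[i] = 0.0
            if aborted or not quality.converged or cfg.n_refinements == 0:
                break
            warm = (s0_i, f_i, ds_i)
            corrected = y[hi] - s0_i * f_i * np.exp(-b[hi] * ds_i)
            if np.all(corrected > 0):
                d_check = float(_loglinear_d(corrected[None, :], b[hi], cfg)[0][0])
                d_residual[i] = abs(d_check - d_i)
                if d_tol is not None and d_residual[i] > d_tol * max(d_i, 1e-12):
                    d_i = d_check
                    continue
            break
        d_map[i] = d_i
        warm_map[i] = warm
        res["s0"][i], res["f"][i], res["d_star"][i] = s0_i, f_i, ds_i
        res["nrmse"][i] = quality.nrmse
        ok[i] = quality.converged

    for i in range(n_mask):
        if usable[i]:
            run_cycles(i, 1, None)

    # iterate further only where the fixed-point residual exceeds both the
    # relative target and the population's statistical slope resolution —
    # refining below the noise level would just chase noise
    if cfg.n_refinements > 0 and ok.any():
        rms = np.nanmedian(res["nrmse"][ok]) * np.nanmedian(vox[ok].mean(axis=1))
        sigma2 = rms**2 * b.size / max(b.size - 3, 1)
        slope_se = np.sqrt(
            sigma2 * ((bc_hi / np.maximum(vox[:, hi], 1e-12)) ** 2).sum(axis=1)
        ) / ss_bc
        redo = ok & (d_residual > np.maximum(1e-4 * d_map, 3.0 * slope_se))
        for i in np.flatnonzero(redo):
            run_cycles(i, 3, 1e-4)

    frac = ok.mean() if n_mask else 0.0
    logger.info("fit_ivim_map: %.1f%% of %d voxels converged", 100 * frac, n_mask)
    if frac < cfg.min_converged_fraction:
        raise RuntimeError(
            f"only {100 * frac:.2f}% of voxels converged; check input data"
        )

    out["s0"][mask] = res["s0"]
    out["f"][mask] = res["f"]
    out["d_star"][mask] = res["d_star"]
    out["d"][mask] = d_map
    out["fd_star"][mask] = res["f"] * res["d_star"]
    out["nrmse"][mask] = res["nrmse"]
    converged[mask] = ok
    return IVIMParameterMap(mask=mask, converged=converged, **out)
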