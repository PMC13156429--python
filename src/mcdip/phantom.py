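"""Synthetic brain phantom with known ground truth.

Generates everything the MC-DIP pipeline consumes — multi-b-value DWI under
three motion-compensation schemes, phase-contrast velocity cines of the four
feeding arteries, an ASL control/label/PD triplet, and tissue probability
maps — from a single seeded ground truth, so every downstream estimate can
be checked against the quantity it should recover.

Geometry is a concentric-shell head at desk scale: a CSF rim around a
gray-matter shell around a white-matter core, on a 48x48x24 grid of
2x2x6 mm voxels (~500 mL of "brain"). Bulk motion is modeled as intravoxel
phase dispersion: a voxel with velocity dispersion ``sigma_v`` (cm/s) and
acceleration dispersion ``sigma_a`` (cm/s²) seen by a gradient waveform with
residual moment weights ``(w1, w2)`` loses magnitude by ``exp(-sigma_phi²/2)``
with ``sigma_phi = sqrt(b) * (c1*w1*sigma_v + c2*w2*sigma_a)``. Second-order
compensated gradients (weights ``(0,0)``) are immune; uncompensated gradients
see both terms. Deep (periventricular) tissue pulses harder than cortex, so
``sigma_a`` is larger toward the core — which is what makes the corruption
spatially structured rather than a global gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core_model import (
    ASLParams,
    BValueScheme,
    DWISeries,
    RCBFMap,
    RCBFMethod,
    VelocityCine,
    VesselLabel,
)
from .asl import asl_scale_factor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomConfig:
    """Tunable ground-truth parameters of the synthetic head.

    Defaults are physiologically plausible adult-brain values: tissue
    diffusivities of 0.8/0.7e-3 mm²/s (GM/WM), pseudo-diffusion 10e-3 mm²/s,
    perfusion fractions 0.12/0.06 (GM/WM), and a whole-brain perfusion of
    50 mL/100 g/min split over two ICAs (35% each) and two VAs (15% each).
    """

    voxel_dims: Tuple[float, float, float] = (2.0, 2.0, 6.0)
    # shell boundaries as fractions of the head ellipsoid radius
    wm_radius: float = 0.65
    gm_radius: float = 0.90
    deep_radius: float = 0.35
    # true IVIM parameters per tissue
    d_gm: float = 0.8e-3
    d_wm: float = 0.7e-3
    d_csf: float = 2.0e-3
    d_star: float = 10e-3
    f_gm: float = 0.12
    f_wm: float = 0.06
    f_csf: float = 0.02
    # b=0 signal level per tissue (arbitrary units; CSF bright at b=0)
    s0_gm: float = 100.0
    s0_wm: float = 95.0
    s0_csf: float = 160.0
    # smooth intra-tissue texture (relative sd of the multiplicative field;
    # regional perfusion and diffusivity vary on this order in vivo)
    texture_rel_sd: float = 0.15
    texture_smooth_vox: float = 2.0
    # perfusion / hemodynamics
    tcbf_normalized: float = 50.0  # mL/100 g/min, brain mean
    tissue_density: float = 1.06  # g/mL
    vessel_fractions: Tuple[float, float, float, float] = (0.35, 0.35, 0.15, 0.15)
    # bulk-motion dispersion (cm/s, cm/s²) and phase-coupling constants;
    # magnitudes chosen so uncompensated gradients show pronounced deep-
    # tissue hyperperfusion artifacts while staying short of saturating
    # the fit (diffusion estimates inside bounds over most of the brain)
    sigma_v: float = 0.25
    sigma_a_cortex: float = 1.0
    sigma_a_deep: float = 2.5
    c1: float = 0.1   # rad per (cm/s) per sqrt(s/mm²)
    c2: float = 0.03  # rad per (cm/s²) per sqrt(s/mm²)
    # phase-contrast plane
    pc_grid: int = 64
    # pixel area (mm²). None (default) scales the vessel cross-sections with
    # the desk-scale brain so that lumen velocities stay physiologic
    # (cycle-mean ICA velocity = ica_velocity_target) regardless of grid size.
    pixel_area: Optional[float] = None
    ica_velocity_target: float = 17.0  # cm/s
    venc: float = 80.0        # cm/s
    heart_rate: float = 60.0  # beats/min
    pulsatility: float = 0.6  # raised-cosine modulation amplitude
    lumen_radius_ica: float = 3.5  # pixels
    lumen_radius_va: float = 2.5
    # degenerate single-tissue head (entire head one tissue class), for tests
    uniform_tissue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.uniform_tissue not in (None, "gm", "wm", "csf"):
            raise ValueError("uniform_tissue must be one of gm/wm/csf")
        if not (0 < self.deep_radius < self.wm_radius < self.gm_radius <= 1.0):
            raise ValueError("shell radii must satisfy 0 < deep < wm < gm <= 1")
        if abs(sum(self.vessel_fractions) - 1.0) > 1e-9:
            raise ValueError("vessel_fractions must sum to 1")
        if not (self.f_gm > self.f_wm > 0):
            raise ValueError("require f_gm > f_wm > 0")


@dataclass
class MotionModel:
    """Per-voxel bulk-motion dispersion and its phase-coupling constants."""

    sigma_v: np.ndarray  # cm/s
    sigma_a: np.ndarray  # cm/s²
    c1: float
    c2: float


@dataclass
class VesselPlane:
    """One synthetic phase-contrast acquisition: cine, true lumen, seed pixel."""

    label: VesselLabel
    cine: VelocityCine
    lumen_mask: np.ndarray
    seed_point: Tuple[int, int]


@dataclass
class PhantomGroundTruth:
    """Everything the pipeline should recover, plus the knobs that corrupt it."""

    shape: Tuple[int, int, int]
    voxel_dims: Tuple[float, float, float]
    tissue_probs: Dict[str, np.ndarray]
    brain_mask: np.ndarray
    true_s0: np.ndarray
    true_f: np.ndarray
    true_d_star: np.ndarray
    true_d: np.ndarray
    true_rcbf: RCBFMap
    vessel_true_flows: Dict[VesselLabel, float]
    motion: MotionModel
    config: PhantomConfig
    seed: int

    @property
    def true_fd_star(self) -> np.ndarray:
        return self.true_f * self.true_d_star

    @property
    def brain_volume_ml(self) -> float:
        return float(self.brain_mask.sum() * np.prod(self.voxel_dims) / 1000.0)

    @property
    def tcbf_ml_min(self) -> float:
        """Total CBF (mL/min) consistent with the configured brain-mean rCBF."""
        return (
            self.config.tcbf_normalized
            * self.brain_volume_ml
            * self.config.tissue_density
            / 100.0
        )


def _ellipsoid_radius(shape: Tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoid radius (1.0 at the head surface) per voxel."""
    axes = [np.arange(n, dtype=float) - (n - 1) / 2.0 for n in shape]
    semi = [0.45 * n for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    )


def make_phantom(
    shape: Tuple[int, int, int] = (48, 48, 24),
    seed: int = 0,
    config: Optional[PhantomConfig] = None,
) -> PhantomGroundTruth:
    """Build the seeded ground truth for one synthetic subject.

    The true rCBF map is proportional to FD* (the linearity the calibration
    relies on), scaled so its brain mean equals ``config.tcbf_normalized``;
    the four vessel flows are the consistent split of the implied total CBF.
    """
    if any(n < 8 for n in shape):
        raise ValueError("each phantom dimension must be >= 8")
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    r = _ellipsoid_radius(shape)
    head = r <= 1.0
    wm = r <= cfg.wm_radius
    gm = (r > cfg.wm_radius) & (r <= cfg.gm_radius)
    csf = (r > cfg.gm_radius) & head
    deep = r <= cfg.deep_radius

    if cfg.uniform_tissue is not None:
        gm = head if cfg.uniform_tissue == "gm" else np.zeros_like(head)
        wm = head if cfg.uniform_tissue == "wm" else np.zeros_like(head)
        csf = head if cfg.uniform_tissue == "csf" else np.zeros_like(head)
    probs = {
        "gm": gm.astype(float),
        "wm": wm.astype(float),
        "csf": csf.astype(float),
    }

    def blend(v_gm: float, v_wm: float, v_csf: float) -> np.ndarray:
        return v_gm * probs["gm"] + v_wm * probs["wm"] + v_csf * probs["csf"]

    # smooth multiplicative texture gives intra-tissue spread without
    # breaking tissue ordering
    def texture() -> np.ndarray:
        if cfg.texture_rel_sd == 0:
            return np.ones(shape)
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, cfg.texture_smooth_vox)
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd * cfg.texture_rel_sd
        return np.clip(1.0 + smooth, 0.5, 1.5)

    true_s0 = blend(cfg.s0_gm, cfg.s0_wm, cfg.s0_csf) * texture()
    true_f = blend(cfg.f_gm, cfg.f_wm, cfg.f_csf) * texture()
    true_d = blend(cfg.d_gm, cfg.d_wm, cfg.d_csf) * texture()
    true_d_star = np.full(shape, cfg.d_star) * texture()
    for arr in (true_s0, true_f, true_d, true_d_star):
        arr[~head] = 0.0
    # keep the parameter ordering D < D* everywhere in the head
    np.clip(true_f, 0.0, 0.5, out=true_f)
    true_d_star = np.maximum(true_d_star, 2.0 * true_d)
    true_d_star[~head] = 0.0

    fd = true_f * true_d_star
    mean_fd = fd[head].mean()
    if mean_fd <= 0:
        raise ValueError("degenerate configuration: zero mean FD* in brain")
    rcbf_values = cfg.tcbf_normalized / mean_fd * fd
    rcbf_values[~head] = np.nan
    true_rcbf = RCBFMap(values=rcbf_values, mask=head, method=RCBFMethod.TRUTH)

    brain_volume_ml = float(head.sum() * np.prod(cfg.voxel_dims) / 1000.0)
    tcbf_ml_min = cfg.tcbf_normalized * brain_volume_ml * cfg.tissue_density / 100.0
    labels = [VesselLabel.L_ICA, VesselLabel.R_ICA, VesselLabel.L_VA, VesselLabel.R_VA]
    vessel_true_flows = {
        lab: frac * tcbf_ml_min for lab, frac in zip(labels, cfg.vessel_fractions)
    }

    sigma_v = np.where(head, cfg.sigma_v, 0.0)
    sigma_a = np.where(deep, cfg.sigma_a_deep, cfg.sigma_a_cortex)
    sigma_a = np.where(head, sigma_a * texture(), 0.0)
    motion = MotionModel(sigma_v=sigma_v, sigma_a=sigma_a, c1=cfg.c1, c2=cfg.c2)

    return PhantomGroundTruth(
        shape=tuple(shape),
        voxel_dims=cfg.voxel_dims,
        tissue_probs=probs,
        brain_mask=head,
        true_s0=true_s0,
        true_f=true_f,
        true_d_star=true_d_star,
        true_d=true_d,
        true_rcbf=true_rcbf,
        vessel_true_flows=vessel_true_flows,
        motion=motion,
        config=cfg,
        seed=int(seed),
    )


def motion_attenuation(
    b: float, model: MotionModel, weights: Tuple[float, float]
) -> np.ndarray:
    """Magnitude attenuation factor from bulk-motion phase dispersion.

    ``exp(-sigma_phi²/2)`` with
    ``sigma_phi = sqrt(b) * (c1*w1*sigma_v + c2*w2*sigma_a)``; equals 1 when
    both residual moment weights are zero or at b = 0.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    w1, w2 = weights
    sigma_phi = np.sqrt(b) * (
        model.c1 * w1 * model.sigma_v + model.c2 * w2 * model.sigma_a
    )
    return np.exp(-0.5 * sigma_phi**2)


def synthesize_dwi(
    truth: PhantomGroundTruth,
    scheme: BValueScheme,
    noise_sigma: float = 0.0,
    nsa: int = 2,
    seed: int = 0,
) -> DWISeries:
    """Simulate a trace DWI series under one motion-compensation scheme.

    Per voxel and b-value: the biexponential signal is attenuated by the
    scheme-dependent motion factor, then Rician noise is applied per
    excitation (complex Gaussian channels, magnitude) and the ``nsa``
    magnitudes are averaged — mirroring scanner averaging of magnitude
    reconstructions.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if nsa < 1:
        raise ValueError("nsa must be >= 1")
    if scheme.n_b == 0:
        raise ValueError("scheme has an empty b-value table")
    rng = np.random.default_rng(seed)
    shape = truth.shape
    b_values = scheme.b_array
    out = np.empty(shape + (b_values.size,), dtype=float)
    head = truth.brain_mask
    # evaluate the forward model only in the head; background stays 0
    s0 = truth.true_s0[head]
    f = truth.true_f[head]
    ds = truth.true_d_star[head]
    d = truth.true_d[head]
    for j, b in enumerate(b_values):
        clean = np.zeros(shape)
        decay = f * np.exp(-b * ds) + (1.0 - f) * np.exp(-b * d)
        clean[head] = s0 * decay
        clean *= motion_attenuation(b, truth.motion, scheme.moment_weights)
        if noise_sigma == 0:
            out[..., j] = clean
        else:
            acc = np.zeros(shape)
            for _ in range(nsa):
                re = clean + rng.normal(0.0, noise_sigma, shape)
                im = rng.normal(0.0, noise_sigma, shape)
                acc += np.hypot(re, im)
            out[..., j] = acc / nsa
    return DWISeries(signal=out, scheme=scheme, voxel_dims=truth.voxel_dims)


def _raised_cosine_waveform(mean: float, amplitude: float, n_phases: int) -> np.ndarray:
    """Pulsatile waveform with exact cycle mean ``mean`` on any uniform grid."""
    phases = np.arange(n_phases)
    return mean * (1.0 + amplitude * np.cos(2.0 * np.pi * phases / n_phases))


def synthesize_pc(
    truth: PhantomGroundTruth,
    n_phases: int = 32,
    noise_sigma_v: float = 0.0,
    seed: int = 0,
) -> List[VesselPlane]:
    """Simulate one phase-contrast cine per feeding artery.

    Each plane holds a circular lumen with a spatially uniform raised-cosine
    velocity waveform whose cycle mean reproduces that vessel's true flow;
    the background is zero-mean velocity noise. Velocities are clipped to
    venc (with a warning) as aliasing-free encoding would enforce.
    """
    if n_phases < 4:
        raise ValueError("n_phases must be >= 4")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n = cfg.pc_grid
    pixel_area = cfg.pixel_area
    if pixel_area is None:
        # scale lumen cross-section with the phantom's flow so the ICA
        # cycle-mean velocity lands on its physiologic target
        q_ica = max(
            truth.vessel_true_flows[VesselLabel.L_ICA],
            truth.vessel_true_flows[VesselLabel.R_ICA],
        )
        xx0, yy0 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        c0 = n // 2
        n_pix_ica = int(
            (((xx0 - c0) ** 2 + (yy0 - c0) ** 2) <= cfg.lumen_radius_ica**2).sum()
        )
        pixel_area = q_ica / (0.6 * n_pix_ica * cfg.ica_velocity_target)
    planes: List[VesselPlane] = []
    centers = {
        VesselLabel.L_ICA: (n // 2 - n // 6, n // 2),
        VesselLabel.R_ICA: (n // 2 + n // 6, n // 2),
        VesselLabel.L_VA: (n // 2 - n // 8, n // 2 + n // 5),
        VesselLabel.R_VA: (n // 2 + n // 8, n // 2 + n // 5),
    }
    for label, flow in truth.vessel_true_flows.items():
        radius = (
            cfg.lumen_radius_ica
            if label in (VesselLabel.L_ICA, VesselLabel.R_ICA)
            else cfg.lumen_radius_va
        )
        if 2 * radius >= n:
            raise ValueError("requested lumen larger than the cine field")
        cx, cy = centers[label]
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        lumen = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        n_pix = int(lumen.sum())
        # Q [mL/min] = v[cm/s] * area[mm²] * 0.6  (10 mm³/s -> 60/1000 mL/min)
        v_mean = flow / (0.6 * n_pix * pixel_area)
        waveform = _raised_cosine_waveform(v_mean, cfg.pulsatility, n_phases)
        vel = np.zeros((n, n, n_phases))
        if noise_sigma_v > 0:
            vel += rng.normal(0.0, noise_sigma_v, vel.shape)
        vel[lumen, :] = waveform[None, :] + (
            rng.normal(0.0, noise_sigma_v, (n_pix, n_phases))
            if noise_sigma_v > 0
            else 0.0
        )
        if np.any(np.abs(vel) > cfg.venc):
            logger.warning("%s: velocities clipped to venc=%.1f cm/s", label, cfg.venc)
            vel = np.clip(vel, -cfg.venc, cfg.venc)
        cine = VelocityCine(
            velocity=vel,
            pixel_area=pixel_area,
            venc=cfg.venc,
            heart_rate=cfg.heart_rate,
        )
        planes.append(
            VesselPlane(label=label, cine=cine, lumen_mask=lumen, seed_point=(cx, cy))
        )
    return planes


def synthesize_asl(
    truth: PhantomGroundTruth,
    params: Optional[ASLParams] = None,
    s_pd_level: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate an ASL (control, label, proton-density) triplet.

    Constructed so that the standard kinetic-model quantification inverts it
    exactly in the noise-free limit: ``control - label = rCBF * PD / K`` with
    ``K`` the kinetic scale factor for ``params``.
    """
    if s_pd_level <= 0:
        raise ValueError("s_pd_level must be positive")
    params = params or ASLParams()
    rng = np.random.default_rng(seed)
    k = asl_scale_factor(params)
    head = truth.brain_mask
    pd = np.where(head, s_pd_level, 0.0)
    rcbf = np.where(head, np.nan_to_num(truth.true_rcbf.values), 0.0)
    delta_m = rcbf * pd / k
    label = pd.copy()
    control = label + delta_m
    if noise_sigma > 0:
        control = control + rng.normal(0.0, noise_sigma, control.shape)
        label = label + rng.normal(0.0, noise_sigma, label.shape)
        pd = pd + rng.normal(0.0, noise_sigma, pd.shape)
    return control, label, pd
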