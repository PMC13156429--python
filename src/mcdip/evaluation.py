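"""ROI statistics, distribution similarity and agreement analyses.

Compares rCBF maps from the three DIP variants against a reference (ASL or
ground truth): tissue-ROI means from high-confidence GM/WM probability
masks, Jensen–Shannon divergence between voxel-value histograms, Spearman
rank correlation and Bland–Altman limits of agreement across subjects, and
Friedman/Wilcoxon omnibus testing across the three gradient schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import rel_entr

from .core_model import RCBFMap, RCBFMethod

logger = logging.getLogger(__name__)

#: Default histogram support for rCBF distributions: 64 equal-width bins
#: spanning 0–150 mL/100 g/min (covers the physiological range).
DEFAULT_RCBF_BIN_EDGES = np.linspace(0.0, 150.0, 65)


@dataclass
class ROIResult:
    """Mean/SD of an rCBF map over a tissue ROI."""

    tissue: str
    method: RCBFMethod
    mean: float
    sd: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "method": self.method.value,
            "mean": self.mean,
            "sd": self.sd,
            "n_voxels": self.n_voxels,
        }


@dataclass
class AgreementResult:
    """Bland–Altman bias and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def tissue_roi_mask(tissue_prob: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """High-confidence tissue mask: probability >= threshold (inclusive)."""
    prob = np.asarray(tissue_prob, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("tissue probabilities must lie in [0, 1]")
    mask = prob >= threshold
    if not mask.any():
        logger.warning("tissue ROI empty at threshold %.2f", threshold)
    return mask


def roi_stats(rcbf: RCBFMap, roi: np.ndarray, tissue: str = "") -> Optional[ROIResult]:
    """Mean and SD (n−1 denominator) of valid map voxels inside a ROI.

    Returns None (with a warning) when the ROI and the map's valid voxels
    do not intersect. Invalid-flagged voxels are excluded, and the reported
    ``n_voxels`` makes that exclusion auditable.
    """
    values = rcbf.valid_values(np.asarray(roi, dtype=bool))
    values = values[np.isfinite(values)]
    if values.size == 0:
        logger.warning("roi_stats: empty ROI/map intersection for %s", tissue)
        return None
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ROIResult(
        tissue=tissue,
        method=rcbf.method,
        mean=float(values.mean()),
        sd=sd,
        n_voxels=int(values.size),
    )


def jsd(
    values_a: np.ndarray,
    values_b: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
) -> float:
    """Jensen–Shannon divergence (base 2) between two binned samples.

    Both samples are histogrammed on shared ``bin_edges`` and normalized to
    probability vectors P and Q; JSD = ½KL(P‖M) + ½KL(Q‖M) with
    M = (P+Q)/2, using the 0·log0 = 0 convention. Ranges from 0 (identical
    binned distributions) to 1 (disjoint supports).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_edges is None:
        bin_edges = DEFAULT_RCBF_BIN_EDGES
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    # clip into the covered range so boundary samples land in edge bins
    lo, hi = bin_edges[0], bin_edges[-1]
    p, _ = np.histogram(np.clip(a, lo, hi), bins=bin_edges)
    q, _ = np.histogram(np.clip(b, lo, hi), bins=bin_edges)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    div = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(div / np.log(2.0))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bland–Altman agreement: bias = mean(x−y), limits = bias ± 1.96·SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need paired 1-D samples with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(d.size)
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_schemes(
    per_subject_metric: np.ndarray,
    scheme_names: Sequence[str] = ("2nd-mc", "1st-mc", "non-mc"),
) -> Dict:
    """Friedman omnibus test plus Bonferroni-corrected pairwise Wilcoxon tests.

    ``per_subject_metric`` is subjects × 3 schemes; rows with missing values
    are excluded listwise with a warning.
    """
    m = np.asarray(per_subject_metric, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("expected a subjects x 3-schemes matrix")
    complete = np.all(np.isfinite(m), axis=1)
    if not complete.all():
        logger.warning(
            "compare_schemes: excluding %d incomplete subjects", int((~complete).sum())
        )
    m = m[complete]
    if m.shape[0] < 5:
        raise ValueError("need >= 5 complete subjects")

    if np.allclose(m, m[:, [0]]):
        friedman_stat, friedman_p = 0.0, 1.0
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
    pairwise = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        key = f"{scheme_names[i]}_vs_{scheme_names[j]}"
        diff = m[:, i] - m[:, j]
        if np.all(diff == 0):
            stat_w, p_w = 0.0, 1.0
        else:
            stat_w, p_w = stats.wilcoxon(m[:, i], m[:, j])
        pairwise[key] = {
            "statistic": float(stat_w),
            "p_raw": float(p_w),
            "p_bonferroni": float(min(1.0, 3.0 * p_w)),
        }
    return {
        "friedman_statistic": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "n_subjects": int(m.shape[0]),
        "pairwise_wilcoxon": pairwise,
    }
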