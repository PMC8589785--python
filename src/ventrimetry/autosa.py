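"""Automated splenial-angle landmarking on color-FA volumes.

Emulates what a rater does on a workstation: isolate the red-encoded
commissural fibers, pick the caudal-most axial slice with a complete callosal
body, drop a pivot on the midline, and align straight rays with the centers
of the forceps-major limbs. Every constant is exposed as a keyword and the
chain is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dti import ColorFAVolume
from .geometry import AngleMeasurement, measure_sa, select_sa_slice

__all__ = [
    "CommissuralMask",
    "ForcepsFit",
    "StageError",
    "commissural_mask",
    "callosal_support",
    "detect_midline",
    "fit_forceps_rays",
    "auto_sa",
]


class StageError(ValueError):
    """Error raised by one stage of the automated chain, tagged by stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class CommissuralMask:
    """Red-dominant callosal candidate: FA >= threshold and |e1.x| dominant."""

    mask: np.ndarray  # bool volume, largest midline-crossing red component
    fa_threshold: float
    rule: str = "red-dominant"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ForcepsFit:
    """Result of the pivot/ray grid search on the SA slice."""

    pivot_mm: np.ndarray  # (x, y) in mm
    dir_left: np.ndarray  # unit (x, y), posterior-pointing
    dir_right: np.ndarray
    residual: float  # summed orthogonal distance of limb voxels to their rays
    n_left: int
    n_right: int


def commissural_mask(cfa: ColorFAVolume, fa_threshold: float = 0.2) -> CommissuralMask:
    """Red-dominant voxels (left-right principal direction), reduced to the
    largest connected component that crosses the midline."""
    red = ((cfa.fa >= fa_threshold)
           & (np.abs(cfa.e1[..., 0]) > np.abs(cfa.e1[..., 1]))
           & (np.abs(cfa.e1[..., 0]) > np.abs(cfa.e1[..., 2]))
           & cfa.foreground & ~cfa.e1_undefined)
    if not red.any():
        raise ValueError("no commissural voxels above the FA threshold")
    labels, n = ndimage.label(red)
    mid = (cfa.fa.shape[0] - 1) / 2.0
    best, best_size = 0, 0
    for lab in range(1, n + 1):
        xs = np.nonzero(labels == lab)[0]
        crosses = xs.min() <= mid <= xs.max()
        if crosses and xs.size > best_size:
            best, best_size = lab, xs.size
    if best == 0:
        raise ValueError("no commissural component crosses the midline")
    return CommissuralMask(labels == best, fa_threshold)


def callosal_support(cfa: ColorFAVolume, cmask: CommissuralMask) -> np.ndarray:
    """High-FA voxels connected to the red core.

    The forceps-major limbs run obliquely, so away from the midline their
    principal direction loses left-right dominance; the limb fit therefore
    uses every FA-suprathreshold voxel connected to the commissural core
    rather than the strictly red mask.
    """
    high_fa = (cfa.fa >= cmask.fa_threshold) & cfa.foreground & ~cfa.e1_undefined
    labels, _ = ndimage.label(high_fa)
    seeds = np.unique(labels[cmask.mask])
    seeds = seeds[seeds > 0]
    return np.isin(labels, seeds)


def detect_midline(foreground: np.ndarray, spacing_x: float = 1.0,
                   search_mm: float = 10.0, score_floor: float = 0.5) -> float:
    """Left-right coordinate (mm) of the midsagittal plane by mirror symmetry.

    Scans candidate mirror planes at half-voxel resolution within
    ``search_mm`` of the geometric center and returns the one maximizing the
    Dice overlap between the foreground and its left-right reflection. Falls
    back to the foreground centroid (with a warning) if no candidate scores
    above ``score_floor``.
    """
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        raise ValueError("empty volume: cannot detect a midline")
    profile = fg.reshape(fg.shape[0], -1)
    n = profile.shape[0]
    centroid = float(np.nonzero(fg)[0].mean())
    max_shift = int(np.ceil(2 * search_mm / spacing_x))
    best_score, best_c = -1.0, None
    for s in range(-max_shift, max_shift + 1):
        c = (n - 1 + s) / 2.0  # mirror plane in voxel units
        if abs(c - centroid) * spacing_x > search_mm:
            continue
        # mirrored index of i is (n - 1 + s) - i; clip to the array
        idx = np.arange(n)
        mirr_idx = (n - 1 + s) - idx
        valid = (mirr_idx >= 0) & (mirr_idx < n)
        a = profile[idx[valid]]
        b = profile[mirr_idx[valid]]
        inter = np.logical_and(a, b).sum()
        denom = a.sum() + b.sum()
        score = 2.0 * inter / denom if denom else 0.0
        if score > best_score:
            best_score, best_c = score, c
    if best_c is None or best_score < score_floor:
        warnings.warn("midline symmetry score below floor; falling back to the "
                      "geometric center", stacklevel=2)
        return centroid * spacing_x
    return best_c * spacing_x


def fit_forceps_rays(support_slice: np.ndarray, core_slice: np.ndarray,
                     midline_x_mm: float, spacing: tuple[float, float],
                     annulus_mm: tuple[float, float] = (5.0, 30.0),
                     pivot_step_mm: float = 1.0, min_limb_voxels: int = 10,
                     strip_halfwidth_mm: float = 4.0) -> ForcepsFit:
    """Grid-search the midline pivot and fit one straight ray per limb.

    The pivot is constrained to the midline and swept in ``pivot_step_mm``
    steps over the red core's midline extent on the SA slice. For each
    candidate, limb voxels are the support voxels posterior to the pivot on
    each side of the midline within the radial annulus; each ray direction is
    the principal axis of those voxels anchored at the pivot, and the winning
    pivot minimizes the total orthogonal distance of limb voxels to their rays.
    """
    sx, sy = spacing
    sup = np.asarray(support_slice, dtype=bool)
    core = np.asarray(core_slice, dtype=bool)
    xs, ys = np.nonzero(sup)
    pts = np.column_stack([xs * sx, ys * sy])

    cx, cy = np.nonzero(core)
    near_mid = np.abs(cx * sx - midline_x_mm) <= strip_halfwidth_mm
    if not near_mid.any():
        raise ValueError("limb too sparse: red core absent from the midline strip")
    y_lo, y_hi = cy[near_mid].min() * sy, cy[near_mid].max() * sy
    candidates = np.arange(y_lo, y_hi + pivot_step_mm / 2, pivot_step_mm)

    r_lo, r_hi = annulus_mm
    side = np.sign(pts[:, 0] - midline_x_mm)

    def fit_ray(d: np.ndarray):
        """Principal axis of the limb voxels anchored at the candidate pivot,
        plus the summed orthogonal distance to that ray. The pivot-anchored
        second moment weights voxels by squared radius, which suppresses the
        near-pivot region where narrow limbs merge into the splenium."""
        evals, evecs = np.linalg.eigh(d.T @ d)
        u = evecs[:, -1]
        proj = d @ u
        if proj.mean() < 0:
            u, proj = -u, proj * -1
        resid = np.sqrt(np.clip((d ** 2).sum(axis=1) - proj ** 2, 0.0, None)).sum()
        return u, resid

    best = None
    for y_c in candidates:
        piv = np.array([midline_x_mm, y_c])
        d_all = pts - piv
        r = np.linalg.norm(d_all, axis=1)
        in_ann = (r >= r_lo) & (r <= r_hi) & (d_all[:, 1] < 0)  # posterior only
        left = in_ann & (side < 0)
        right = in_ann & (side > 0)
        if left.sum() < min_limb_voxels or right.sum() < min_limb_voxels:
            continue
        u_l, res_l = fit_ray(d_all[left])
        u_r, res_r = fit_ray(d_all[right])
        # mean (not raw-sum) residual: candidate pivots see different voxel
        # counts, and a raw sum would favor pivots that exclude voxels
        total = (res_l + res_r) / (left.sum() + right.sum())
        if best is None or total < best[0]:
            best = (total, piv, u_l, u_r, int(left.sum()), int(right.sum()))
    if best is None:
        raise ValueError(f"limb too sparse: fewer than {min_limb_voxels} voxels on a side "
                         "for every candidate pivot")
    total, piv, u_l, u_r, n_l, n_r = best
    return ForcepsFit(piv, u_l, u_r, total, n_l, n_r)


def auto_sa(cfa: ColorFAVolume, fa_threshold: float = 0.2,
            annulus_mm: tuple[float, float] = (5.0, 30.0),
            pivot_step_mm: float = 1.0, min_limb_voxels: int = 10,
            strip_halfwidth_mm: float = 4.0, completeness: float = 0.9,
            midline_search_mm: float = 10.0, midline_tolerance_mm: float = 2.0,
            ) -> tuple[AngleMeasurement, dict]:
    """Fully automated splenial angle: mask -> slice -> midline -> rays -> angle.

    Returns the measurement plus an audit dictionary recording every
    intermediate choice (slice, midline, pivot, ray directions, residual).
    """
    audit: dict = {"fa_threshold": fa_threshold, "annulus_mm": list(annulus_mm)}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as e:
            raise StageError(name, str(e)) from e

    cmask = stage("commissural_mask", commissural_mask, cfa, fa_threshold)
    support = stage("callosal_support", callosal_support, cfa, cmask)
    midline = stage("detect_midline", detect_midline, cfa.foreground,
                    cfa.grid.spacing[0], midline_search_mm)
    audit["midline_x_mm"] = float(midline)
    z = stage("select_sa_slice", select_sa_slice, cfa, cmask.mask, midline,
              strip_halfwidth_mm, completeness)
    audit["sa_slice"] = int(z)
    fit = stage("fit_forceps_rays", fit_forceps_rays, support[:, :, z],
                cmask.mask[:, :, z], midline, cfa.grid.spacing[:2], annulus_mm,
                pivot_step_mm, min_limb_voxels, strip_halfwidth_mm)
    audit.update(pivot_mm=[float(v) for v in fit.pivot_mm],
                 dir_left=[float(v) for v in fit.dir_left],
                 dir_right=[float(v) for v in fit.dir_right],
                 residual_mm=float(fit.residual),
                 n_limb_voxels=[fit.n_left, fit.n_right])
    meas = stage("measure_sa", measure_sa, fit.pivot_mm, fit.dir_left, fit.dir_right,
                 z, midline, midline_tolerance_mm, "auto")
    audit["sa_deg"] = float(meas.value)
    return meas, audit
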