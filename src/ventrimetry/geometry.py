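"""Ventriculomegaly index geometry: Evans'/bicaudate indices, callosal angle,
splenial angle, slice selection, and the coronal-plane tilt experiment.

Coordinates are millimetres in a canonical RAS frame (x: left->right,
y: posterior->anterior, z: inferior->superior). Axial slices are planes of
constant z, ordered caudocranially by ascending index; the coronal plane for
the callosal angle is orthogonal to the AC-PC segment and passes through PC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dti import ColorFAVolume

__all__ = [
    "LandmarkAngle",
    "AngleMeasurement",
    "angle_between",
    "evans_index",
    "bicaudate_index",
    "measure_ca",
    "select_sa_slice",
    "measure_sa",
    "extract_roof_rays",
    "ca_tilt_experiment",
]


@dataclass
class LandmarkAngle:
    """Three landmarks defining an angle: a vertex and one point per arm."""

    vertex: np.ndarray
    arm_a: np.ndarray
    arm_b: np.ndarray
    plane: str = "axial"  # 'axial' or 'coronal'
    slice_index: int | None = None
    plane_coord: float | None = None  # mm position of the plane along its normal

    def __post_init__(self) -> None:
        self.vertex = np.asarray(self.vertex, dtype=float)
        self.arm_a = np.asarray(self.arm_a, dtype=float)
        self.arm_b = np.asarray(self.arm_b, dtype=float)
        if self.plane not in ("axial", "coronal"):
            raise ValueError(f"unknown plane tag {self.plane!r}")

    def check_in_plane(self, half_voxel_mm: float) -> None:
        """All three points must lie in the declared plane within half a voxel."""
        if self.plane_coord is None:
            return
        axis = 2 if self.plane == "axial" else 1
        for name, p in (("vertex", self.vertex), ("arm_a", self.arm_a), ("arm_b", self.arm_b)):
            if p.shape == (3,) and abs(p[axis] - self.plane_coord) > half_voxel_mm:
                raise ValueError(
                    f"{name} lies {abs(p[axis] - self.plane_coord):.2f} mm off the "
                    f"declared {self.plane} plane (tolerance {half_voxel_mm:.2f} mm)")


@dataclass
class AngleMeasurement:
    """One index measurement: EI, BCI, CA, or SA."""

    index: str  # 'EI' | 'BCI' | 'CA' | 'SA'
    value: float  # ratio for EI/BCI, degrees for CA/SA
    slice_index: int | None = None
    landmarks: object | None = None
    rater: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.index in ("EI", "BCI") and not 0.0 < self.value <= 1.0:
            raise ValueError(f"{self.index} must lie in (0, 1], got {self.value}")
        if self.index in ("CA", "SA") and not 0.0 < self.value < 180.0:
            raise ValueError(f"{self.index} must lie in (0, 180) degrees, got {self.value}")


def angle_between(vertex: Sequence[float], arm_a: Sequence[float],
                  arm_b: Sequence[float]) -> float:
    """Angle in degrees at ``vertex`` between rays to ``arm_a`` and ``arm_b``.

    Returns a value in [0, 180]; exactly 180 for collinear opposite rays.
    A zero angle (coincident rays) is returned with a warning; coincident
    points raise.
    """
    v = np.asarray(vertex, dtype=float)
    u1 = np.asarray(arm_a, dtype=float) - v
    u2 = np.asarray(arm_b, dtype=float) - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise ValueError("arm point coincides with the vertex")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if ang == 0.0:
        warnings.warn("degenerate angle: arms are coincident", stacklevel=2)
    return ang


def evans_index(frontal_horn_width: float, inner_cranial_diameter: float) -> float:
    """Maximal frontal-horn width over maximal inner cranial diameter (same axial slice)."""
    if inner_cranial_diameter <= 0:
        raise ValueError("inner cranial diameter must be positive")
    if frontal_horn_width <= 0:
        raise ValueError("frontal horn width must be positive")
    if frontal_horn_width > inner_cranial_diameter:
        raise ValueError("implausible geometry: horn width exceeds cranial diameter")
    ratio = frontal_horn_width / inner_cranial_diameter
    if ratio == 1.0:
        warnings.warn("implausible Evans' index of exactly 1.0", stacklevel=2)
    return ratio


def bicaudate_index(intercaudate_width: float, cranial_width_at_level: float) -> float:
    """Intercaudate ventricular width over cranial width at the same level."""
    if cranial_width_at_level <= 0:
        raise ValueError("cranial width must be positive")
    if intercaudate_width < 0:
        raise ValueError("intercaudate width must be non-negative")
    if intercaudate_width > cranial_width_at_level:
        raise ValueError("implausible geometry: intercaudate width exceeds cranial width")
    return intercaudate_width / cranial_width_at_level


def measure_ca(roof_landmarks: LandmarkAngle, pc: Sequence[float] | None = None,
               pc_tolerance_mm: float = 2.0, half_voxel_mm: float = 0.5,
               rater: str = "") -> AngleMeasurement:
    """Callosal angle: angle subtended by the lateral-ventricle roofs on the
    coronal plane through the posterior commissure.

    If ``pc`` is given and the declared plane misses it by more than
    ``pc_tolerance_mm``, a warning is recorded on the measurement.
    """
    if roof_landmarks.plane != "coronal":
        raise ValueError("callosal angle landmarks must lie on a coronal plane")
    roof_landmarks.check_in_plane(half_voxel_mm)
    notes: list[str] = []
    if pc is not None and roof_landmarks.plane_coord is not None:
        off = abs(float(np.asarray(pc, dtype=float)[1]) - roof_landmarks.plane_coord)
        if off > pc_tolerance_mm:
            notes.append(f"coronal plane misses PC by {off:.2f} mm (tolerance {pc_tolerance_mm} mm)")
    value = angle_between(roof_landmarks.vertex, roof_landmarks.arm_a, roof_landmarks.arm_b)
    return AngleMeasurement("CA", value, roof_landmarks.slice_index, roof_landmarks,
                            rater, notes)


def _strip_extents(mask: np.ndarray, midline_col: float, strip_halfwidth_vox: float,
                   spacing_y: float) -> np.ndarray:
    """Anteroposterior extent (mm) of the largest midline-strip component per
    axial slice; 0 where the strip is empty or splits into >1 component.

    Slices whose strip content is not a single connected component are scored
    0: a broken body is by definition not complete.
    """
    nx = mask.shape[0]
    lo = max(0, int(np.ceil(midline_col - strip_halfwidth_vox)))
    hi = min(nx, int(np.floor(midline_col + strip_halfwidth_vox)) + 1)
    nz = mask.shape[2]
    extents = np.zeros(nz)
    for z in range(nz):
        strip = mask[lo:hi, :, z]
        if not strip.any():
            continue
        labels, n = ndimage.label(strip)
        if n != 1:
            continue
        ys = np.nonzero(strip)[1]
        extents[z] = (ys.max() - ys.min() + 1) * spacing_y
    return extents


def select_sa_slice(cfa: ColorFAVolume, callosal_mask: np.ndarray,
                    midline_x_mm: float | None = None,
                    strip_halfwidth_mm: float = 4.0,
                    completeness: float = 0.9) -> int:
    """Caudal-most axial slice showing the complete callosal body.

    Scrolling caudocranially (ascending z), the first slice is returned on
    which the red-dominant callosal mask, restricted to a midline strip of
    half-width ``strip_halfwidth_mm``, forms a single connected component
    whose anteroposterior extent reaches ``completeness`` of the maximum such
    extent over all slices. When consecutive slices qualify, the caudal one
    wins by construction.
    """
    mask = np.asarray(callosal_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no complete callosal body: mask is empty")
    sx, sy, _ = cfa.grid.spacing
    if midline_x_mm is None:
        midline_col = float(np.nonzero(mask)[0].mean())
    else:
        midline_col = midline_x_mm / sx
    extents = _strip_extents(mask, midline_col, strip_halfwidth_mm / sx, sy)
    max_extent = extents.max()
    if max_extent <= 0:
        raise ValueError("no complete callosal body: midline strip never occupied")
    qualifying = np.nonzero(extents >= completeness * max_extent)[0]
    if qualifying.size == 0:
        raise ValueError("no complete callosal body on any slice")
    return int(qualifying[0])


def measure_sa(pivot: Sequence[float], dir_left: Sequence[float],
               dir_right: Sequence[float], slice_index: int | None = None,
               midline_x_mm: float | None = None, midline_tolerance_mm: float = 2.0,
               rater: str = "") -> AngleMeasurement:
    """Splenial angle: angle at a midline pivot between two rays aligned along
    the forceps-major limbs, on the selected axial color-FA slice.

    ``dir_left``/``dir_right`` are in-plane ray directions (posterior-pointing,
    on opposite sides of the midline).
    """
    pivot = np.asarray(pivot, dtype=float)
    dl = np.asarray(dir_left, dtype=float)
    dr = np.asarray(dir_right, dtype=float)
    if midline_x_mm is not None and abs(pivot[0] - midline_x_mm) > midline_tolerance_mm:
        raise ValueError(
            f"pivot is {abs(pivot[0] - midline_x_mm):.2f} mm off the midline "
            f"(tolerance {midline_tolerance_mm} mm)")
    if dl[1] >= 0 or dr[1] >= 0:
        raise ValueError("limb rays must point posteriorly (negative y in RAS)")
    if dl[0] * dr[0] > 0:
        raise ValueError("limb rays lie on the same side of the midline")
    value = angle_between(np.zeros(len(dl)), dl, dr)
    lm = LandmarkAngle(pivot, pivot + dl, pivot + dr, "axial", slice_index,
                       plane_coord=float(pivot[2]) if pivot.shape == (3,) else None)
    return AngleMeasurement("SA", value, slice_index, lm, rater)


def _profile_width(profile: np.ndarray, spacing: float, level: float = 0.5) -> float:
    """Subvoxel width of the >= level support of a 1D profile."""
    idx = np.nonzero(profile >= level)[0]
    if idx.size == 0:
        return 0.0
    lo, hi = idx.min(), idx.max()
    left = float(lo) - 0.5
    if lo > 0 and profile[lo] > profile[lo - 1]:
        left = lo - (profile[lo] - level) / (profile[lo] - profile[lo - 1])
    right = float(hi) + 0.5
    if hi + 1 < profile.size and profile[hi] > profile[hi + 1]:
        right = hi + (profile[hi] - level) / (profile[hi] - profile[hi + 1])
    return (right - left) * spacing


def measure_ei_from_masks(ventricles: np.ndarray, brain: np.ndarray,
                          spacing: tuple[float, float, float],
                          rater: str = "auto") -> AngleMeasurement:
    """Evans' index measured on masks: the axial slice with the widest
    ventricular span provides both the frontal-horn width and the inner
    cranial diameter. A partial-volume (float) ventricular map gives
    subvoxel widths."""
    vent = np.asarray(ventricles, dtype=float)
    br = np.asarray(brain, dtype=float)
    if not (vent > 0).any():
        raise ValueError("empty ventricular mask")
    widths = [
        _profile_width(vent[:, :, z].max(axis=1), spacing[0])
        for z in range(vent.shape[2])
    ]
    z_star = int(np.argmax(widths))
    horn = widths[z_star]
    cranial = _profile_width(br[:, :, z_star].max(axis=1), spacing[0])
    value = evans_index(horn, cranial)
    return AngleMeasurement("EI", value, z_star,
                            {"frontal_horn_width": horn,
                             "inner_cranial_diameter": cranial}, rater)


# ---------------------------------------------------------------------------
# Coronal roof extraction and the plane-tilt experiment
# ---------------------------------------------------------------------------

def extract_roof_rays(plane: np.ndarray, spacing_uv: tuple[float, float],
                      midline_col: float, min_columns: int = 4,
                      roof_fraction: float = 0.6, level: float = 0.5):
    """Fit straight roof rays to a coronal ventricular cross-section.

    ``plane`` is a 2D array (u = left-right, v = inferior-superior), either
    boolean or a partial-volume float map in [0, 1]. For each side of
    ``midline_col`` the roof height per u-column is located as the subvoxel
    ``level`` crossing above the topmost filled voxel, and a line is fitted
    over the upper ``roof_fraction`` of the roof run nearest the midline,
    where the roof is straight before the lateral wall takes over. Returns
    (vertex_uv, dir_left, dir_right) in mm with the directions pointing
    outward-downward, or raises if either roof is too short.
    """
    su, sv = spacing_uv
    plane = np.asarray(plane, dtype=float)
    # only fully filled columns: partially covered edge columns carry
    # partial-volume profiles whose level crossing is biased
    cols = np.nonzero(plane.max(axis=1) >= 0.95)[0]
    if cols.size == 0:
        raise ValueError("empty coronal cross-section")

    def top_of(c: int) -> float:
        prof = plane[c]
        t = np.nonzero(prof >= level)[0].max()
        if t + 1 < prof.size and prof[t] > prof[t + 1]:
            # linear interpolation of the level crossing above the top voxel
            return t + (prof[t] - level) / (prof[t] - prof[t + 1])
        return float(t) + 0.5

    tops = {c: top_of(c) for c in cols}

    def fit_side(side_cols: np.ndarray, sign: int):
        # trim ~0.5 mm at each end of the run (residual edge effects)
        trim = max(1, int(round(0.5 / su)))
        if side_cols.size > min_columns + 2 * trim:
            side_cols = np.sort(side_cols)[trim:-trim]
        if side_cols.size < min_columns:
            raise ValueError("roof too short to fit a ray")
        # keep the portion of the roof nearest the midline (highest part)
        order = np.argsort(sign * side_cols)  # ascending distance from midline
        keep = side_cols[order][: max(min_columns, int(np.ceil(roof_fraction * side_cols.size)))]
        u = keep * su
        v = np.array([tops[c] for c in keep]) * sv
        slope, intercept = np.polyfit(u, v, 1)
        d = np.array([sign * 1.0, sign * slope])  # outward-downward for slope*sign<0
        return slope, intercept, d / np.linalg.norm(d)

    left_cols = cols[cols < midline_col]
    right_cols = cols[cols > midline_col]
    m_l, b_l, d_l = fit_side(left_cols, -1)
    m_r, b_r, d_r = fit_side(right_cols, +1)
    if abs(m_l - m_r) < 1e-12:
        raise ValueError("roof lines are parallel; no vertex")
    u_star = (b_r - b_l) / (m_l - m_r)
    vertex = np.array([u_star, m_l * u_star + b_l])
    return vertex, d_l, d_r


def _sample_coronal_plane(volume: np.ndarray, spacing: tuple[float, float, float],
                          y_plane_mm: float, tilt_deg: float = 0.0,
                          rotation_deg: float = 0.0,
                          step_mm: float = 0.25) -> np.ndarray:
    """Resample a (possibly mal-angulated) coronal plane from a 3D mask.

    ``tilt_deg`` rotates the plane about the left-right axis (acute/obtuse
    angulation); ``rotation_deg`` rotates it about the vertical axis
    (right-left malrotation). Returns a 2D float array (u, v) sampled at
    ``step_mm`` resolution; trilinear interpolation of the mask yields a
    partial-volume map, so downstream roof fits are subvoxel.
    """
    sx, sy, sz = spacing
    nx, ny, nz = volume.shape
    t = np.radians(tilt_deg)
    r = np.radians(rotation_deg)
    u = np.arange(0.0, (nx - 1) * sx + step_mm / 2, step_mm)
    v = np.arange(0.0, (nz - 1) * sz + step_mm / 2, step_mm)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    cx = (nx - 1) * sx / 2.0
    cz = (nz - 1) * sz / 2.0
    du, dv = uu - cx, vv - cz
    x = cx + du * np.cos(r)
    y = y_plane_mm + du * np.sin(r) + dv * np.sin(t)
    z = cz + dv * np.cos(t)
    coords = np.stack([x / sx, y / sy, z / sz])
    return ndimage.map_coordinates(volume.astype(float), coords, order=1, cval=0.0)


def ca_tilt_experiment(ventricle_mask: np.ndarray, spacing: tuple[float, float, float],
                       pc_mm: Sequence[float], true_ca_deg: float,
                       sagittal_tilts: Sequence[float] = (),
                       axial_rotations: Sequence[float] = ()) -> pd.DataFrame:
    """Re-measure the callosal angle on mal-angulated/mal-rotated coronal planes.

    For each perturbation the coronal plane through PC is resampled from the
    ventricular mask, roof rays are re-derived, and the CA recomputed. Rows
    where the ventricles leave the plane (or the roofs cannot be fitted) are
    flagged instead of dropped. Perturbations beyond +-15 deg are rejected.
    """
    for p in list(sagittal_tilts) + list(axial_rotations):
        if abs(p) > 15:
            raise ValueError(f"perturbation {p} deg outside the +-15 deg envelope")
    rows = []
    sched = [("sagittal_tilt", float(t), float(t), 0.0) for t in sagittal_tilts]
    sched += [("axial_rotation", float(r), 0.0, float(r)) for r in axial_rotations]
    if not any(t == 0.0 for _, t, *_ in sched):
        sched.insert(0, ("identity", 0.0, 0.0, 0.0))
    y_pc = float(np.asarray(pc_mm, dtype=float)[1])
    step = 0.25
    vol = np.asarray(ventricle_mask, dtype=float)
    if vol.max() <= 1.0 and np.any((vol > 0) & (vol < 1)):
        field = vol  # partial-volume map: already carries subvoxel boundaries
    else:
        # binary mask: smooth so the 0.5 level set tracks planar boundaries
        # with subvoxel accuracy instead of aliasing against the voxel grid
        field = ndimage.gaussian_filter(vol, sigma=[0.8 / s for s in spacing])
    for kind, amount, tilt, rot in sched:
        plane = _sample_coronal_plane(field, spacing, y_pc, tilt, rot, step)
        try:
            vertex, d_l, d_r = extract_roof_rays(
                plane, (step, step),
                midline_col=(ventricle_mask.shape[0] - 1) * spacing[0] / (2.0 * step))
            ca = angle_between(np.zeros(2), d_l, d_r)
            rows.append({"kind": kind, "perturbation_deg": amount, "ca_deg": ca,
                         "error_deg": ca - true_ca_deg, "flagged": False})
        except ValueError:
            rows.append({"kind": kind, "perturbation_deg": amount, "ca_deg": np.nan,
                         "error_deg": np.nan, "flagged": True})
    return pd.DataFrame(rows)
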