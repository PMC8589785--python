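"""Digital phantoms with known ground-truth indices, and tabular synthetic
cohorts/follow-up tables drawn from published group moments.

The phantom is a parametric head: an ellipsoidal skull, two wedge-shaped
lateral ventricles whose roofs are planes (so the callosal angle is exact by
construction), and a callosal fiber sheet draped over the ventricle roofs
whose forceps-major limbs are straight segments meeting at a midline pivot
with a prescribed opening angle (so the splenial angle is exact too).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dti import ColorFAVolume, DwiSet, Grid, TensorVolume

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "GroupMoments",
    "FollowupDeltas",
    "TABLE1_MOMENTS",
    "FOLLOWUP_DELTAS",
    "SEX_COUNTS",
    "make_phantom",
    "synthesize_dwi",
    "spec_for_ventriculomegaly",
    "simulate_cohort",
    "simulate_followup",
]


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the digital head phantom.

    Macro dimensions (skull, ventricles, limb length, landmark positions) are
    multiplied by ``scale`` so small fast phantoms preserve all angles and
    ratios; sheet/limb thicknesses are kept at physical size so masks stay
    well resolved. ``ventriculomegaly`` >= 1 widens the ventricles (raising
    the Evans' index) and steepens their roofs (narrowing the callosal angle).
    """

    spacing: float = 1.0  # mm, isotropic
    scale: float = 1.0
    skull_semiaxes: tuple[float, float, float] = (70.0, 80.0, 60.0)
    ventricle_inner_x: float = 3.0
    ventricle_width: float = 10.0  # per side at ventriculomegaly 1
    ventriculomegaly: float = 1.0
    ventricle_y: tuple[float, float] = (-45.0, 30.0)
    ventricle_z_bottom: float = -20.0
    ventricle_apex_z: float = 18.0  # roof apex height at the PC plane
    apex_slope: float = 0.3  # roof apex rises anteriorly by this dz/dy
    horn_y: tuple[float, float] = (15.0, 30.0)  # frontal-horn box, anterior
    horn_z: tuple[float, float] = (0.0, 4.0)
    wedge_lateral_fraction: float = 0.9  # wedge body narrower than the horns
    true_sa: float = 75.7  # degrees
    true_ca: float | None = None  # degrees; None -> derived from ventriculomegaly
    pivot_y: float = -20.0
    genu_y: float = 35.0
    limb_length: float = 35.0
    limb_thickness: float = 2.5  # not scaled
    body_halfwidth: float = 14.0
    body_z_extent: float = 3.0  # not scaled
    partial_body_z: float = 4.0  # not scaled
    splenium_length: float = 12.0
    cap_radius: float = 4.0  # not scaled
    acpc_y: tuple[float, float] = (15.0, -15.0)  # AC and PC anterior coordinates
    acpc_z: float = 0.0
    lambda_callosum: tuple[float, float] = (1.7e-3, 0.3e-3)  # parallel, perpendicular
    d_csf: float = 3.0e-3
    d_brain: float = 0.8e-3
    noise_sigma: float = 0.0  # additive Gaussian on synthesized DWI signal

    def __post_init__(self) -> None:
        if self.ventriculomegaly < 1:
            raise ValueError("ventriculomegaly factor must be >= 1")
        if not 0 < self.true_sa < 180:
            raise ValueError("true_sa must lie in (0, 180) degrees")
        ca = self.ca_deg
        if not 0 < ca < 180:
            raise ValueError("true_ca must lie in (0, 180) degrees")

    @property
    def ca_deg(self) -> float:
        """Ground-truth callosal angle; the roof half-angle tangent shrinks
        as 1/ventriculomegaly from a 112 deg baseline."""
        if self.true_ca is not None:
            return self.true_ca
        half = math.atan(math.tan(math.radians(112.0 / 2)) / self.ventriculomegaly)
        return 2.0 * math.degrees(half)

    @property
    def ei(self) -> float:
        """Ground-truth Evans' index from ventricle and skull semi-axes."""
        half_width = (self.ventricle_inner_x
                      + self.ventricle_width * self.ventriculomegaly)
        return half_width / self.skull_semiaxes[0]

    def shape(self) -> tuple[int, int, int]:
        margin = 5.0
        return tuple(int(np.ceil(2 * (ax * self.scale + margin) / self.spacing)) | 1
                     for ax in self.skull_semiaxes)


@dataclass
class PhantomResult:
    tensor: TensorVolume
    masks: dict[str, np.ndarray]
    truth: dict
    spec: PhantomSpec


def spec_for_ventriculomegaly(v: float, base_sa: float = 75.7, **overrides) -> PhantomSpec:
    """Spec whose ground-truth SA narrows with the ventriculomegaly factor:
    tan(SA/2) = tan(base_sa/2) / v, mirroring ventricular compression of the
    forceps major."""
    half = math.atan(math.tan(math.radians(base_sa / 2)) / v)
    return PhantomSpec(ventriculomegaly=v, true_sa=2.0 * math.degrees(half), **overrides)


def _check_inside_skull(point_mm: np.ndarray, semiaxes: np.ndarray, name: str,
                        slack: float = 0.98) -> None:
    q = float(np.sum((point_mm / semiaxes) ** 2))
    if q > slack:
        raise ValueError(f"geometric infeasibility: {name} exits the skull (q={q:.2f})")


def make_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomResult:
    """Rasterize the phantom into a tensor volume plus masks and ground truth.

    All ground-truth values (EI, CA, SA, SA slice, pivot) come from the
    analytic geometry, not from any measurement code. ``seed`` only matters
    when DWI is later synthesized with noise.
    """
    s = spec.scale
    sp = spec.spacing
    shape = spec.shape()
    ax, ay, az = (np.array(spec.skull_semiaxes) * s)
    center = (np.array(shape) - 1) / 2.0 * sp  # mm offset of centered frame

    coords = [(np.arange(n) * sp - c) for n, c in zip(shape, center)]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]

    v = spec.ventriculomegaly
    x_in = spec.ventricle_inner_x * s
    w_v = spec.ventricle_width * s * v
    y0, y1 = (spec.ventricle_y[0] * s, spec.ventricle_y[1] * s)
    z_bot = spec.ventricle_z_bottom * s
    apex_z = spec.ventricle_apex_z * s
    y_pc = spec.acpc_y[1] * s
    phi_ca = math.radians(spec.ca_deg / 2.0)
    phi_sa = math.radians(spec.true_sa / 2.0)
    pivot_y = spec.pivot_y * s
    genu_y = spec.genu_y * s
    limb_len = spec.limb_length * s

    if x_in + w_v > 0.95 * ax:
        raise ValueError("geometric infeasibility: ventricle_width pushes the "
                         "ventricles outside the skull")
    apex_max = apex_z + spec.apex_slope * (y1 - y_pc)
    if apex_max > 0.95 * az:
        raise ValueError("geometric infeasibility: ventricle_apex_z exceeds the skull")

    # SA plane: first voxel plane clear of the ventricle roofs
    z_axis = coords[2]
    z_sa_target = apex_max + 4.0
    z_sa_idx = int(np.searchsorted(z_axis, z_sa_target))
    z_sa = z_axis[z_sa_idx]

    limb_dirs = {+1: np.array([math.sin(phi_sa), -math.cos(phi_sa)]),
                 -1: np.array([-math.sin(phi_sa), -math.cos(phi_sa)])}
    for sgn, d in limb_dirs.items():
        end = np.array([d[0] * limb_len, pivot_y + d[1] * limb_len, z_sa])
        _check_inside_skull(end, np.array([ax, ay, az]), "limb_length")

    brain = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0

    # posterior/body wedge: planar roofs at the CA half-angle, capped slightly
    # narrower than the frontal horns so the horn box alone carries the
    # maximal ventricular width
    w_wedge = spec.wedge_lateral_fraction * w_v
    roof = (apex_z + spec.apex_slope * (Y - y_pc)
            - (np.abs(X) - x_in) / math.tan(phi_ca))
    wedge = ((np.abs(X) >= x_in) & (np.abs(X) <= x_in + w_wedge)
             & (Y >= y0) & (Y <= y1) & (Z >= z_bot) & (Z <= roof) & brain)
    # frontal-horn box: full ventricular width, flat top, straddling z = 0 so
    # the widest axial slice sits at the cranial equator
    hy0, hy1 = spec.horn_y[0] * s, spec.horn_y[1] * s
    hz0, hz1 = spec.horn_z[0] * s, spec.horn_z[1] * s
    horns = ((np.abs(X) >= x_in) & (np.abs(X) <= x_in + w_v)
             & (Y >= hy0) & (Y <= hy1) & (Z >= hz0) & (Z <= hz1) & brain)
    ventricles = wedge | horns
    # anti-aliased (partial-volume) ventricle map: fractional coverage along
    # each boundary so resampled planes carry subvoxel surface positions
    pv_wedge = (np.clip((roof - Z) / sp + 0.5, 0, 1)
                * np.clip((Z - z_bot) / sp + 0.5, 0, 1)
                * np.clip((np.abs(X) - x_in) / sp + 0.5, 0, 1)
                * np.clip((x_in + w_wedge - np.abs(X)) / sp + 0.5, 0, 1)
                * np.clip((Y - y0) / sp + 0.5, 0, 1)
                * np.clip((y1 - Y) / sp + 0.5, 0, 1)
                * brain)
    pv_horns = (np.clip((hz1 - Z) / sp + 0.5, 0, 1)
                * np.clip((Z - hz0) / sp + 0.5, 0, 1)
                * np.clip((np.abs(X) - x_in) / sp + 0.5, 0, 1)
                * np.clip((x_in + w_v - np.abs(X)) / sp + 0.5, 0, 1)
                * np.clip((Y - hy0) / sp + 0.5, 0, 1)
                * np.clip((hy1 - Y) / sp + 0.5, 0, 1)
                * brain)
    pv = np.maximum(pv_wedge, pv_horns)

    body_hw = spec.body_halfwidth * s
    in_body_z = (Z >= z_sa) & (Z <= z_sa + spec.body_z_extent)
    in_partial_z = (Z >= z_sa - spec.partial_body_z) & (Z < z_sa)
    body = in_body_z & (np.abs(X) <= body_hw) & (Y >= pivot_y) & (Y <= genu_y)
    splenium_partial = (in_partial_z & (np.abs(X) <= body_hw)
                        & (Y >= pivot_y) & (Y <= pivot_y + spec.splenium_length * s))
    cap = in_body_z & ((X ** 2 + (Y - pivot_y) ** 2) <= (spec.cap_radius) ** 2)

    # limbs: straight segments from the pivot, thickness limb_thickness
    dx = X - 0.0
    dy = Y - pivot_y
    limbs = np.zeros(shape, dtype=bool)
    limb_e1 = {}
    for sgn, d in limb_dirs.items():
        t = dx * d[0] + dy * d[1]  # along-ray coordinate
        perp = np.abs(dx * d[1] - dy * d[0])
        m = in_body_z & (t >= 0) & (t <= limb_len) & (perp <= spec.limb_thickness)
        limbs |= m
        limb_e1[sgn] = m

    callosum = body | splenium_partial | cap | limbs

    # assemble per-voxel tensors; later assignments take precedence
    lam_par, lam_perp = spec.lambda_callosum
    comp = np.zeros(shape + (6,), dtype=float)
    iso = np.zeros(shape)
    iso[brain] = spec.d_brain
    iso[ventricles] = spec.d_csf
    for k in range(3):
        comp[..., k] = iso
    delta = lam_par - lam_perp
    # red body/splenium/cap fibers run left-right (x axis)
    red = (body | splenium_partial | cap) & ~limbs
    comp[red, 0] = lam_perp + delta
    comp[red, 1] = lam_perp
    comp[red, 2] = lam_perp
    for sgn, m in limb_e1.items():
        u = np.array([limb_dirs[sgn][0], limb_dirs[sgn][1], 0.0])
        dmat = lam_perp * np.eye(3) + delta * np.outer(u, u)
        comp[m, 0] = dmat[0, 0]
        comp[m, 1] = dmat[1, 1]
        comp[m, 2] = dmat[2, 2]
        comp[m, 3] = dmat[0, 1]
        comp[m, 4] = dmat[0, 2]
        comp[m, 5] = dmat[1, 2]
    # keep the cap red: it models the splenium proper at the pivot
    comp[cap, 0] = lam_perp + delta
    comp[cap, 1] = lam_perp
    comp[cap, 2] = lam_perp
    comp[cap, 3] = 0.0
    comp[cap, 4] = 0.0
    comp[cap, 5] = 0.0

    grid = Grid((sp, sp, sp), "RAS")
    tensor = TensorVolume(comp, grid, brain)

    pivot_mm = np.array([center[0], pivot_y + center[1], z_sa + center[2]])
    ac_mm = np.array([center[0], spec.acpc_y[0] * s + center[1], spec.acpc_z + center[2]])
    pc_mm = np.array([center[0], y_pc + center[1], spec.acpc_z + center[2]])
    truth = {
        "ei": spec.ei,
        "ca_deg": spec.ca_deg,
        "sa_deg": spec.true_sa,
        "sa_slice": z_sa_idx,
        "pivot_mm": pivot_mm,
        "limb_dir_left": np.array([limb_dirs[-1][0], limb_dirs[-1][1], 0.0]),
        "limb_dir_right": np.array([limb_dirs[+1][0], limb_dirs[+1][1], 0.0]),
        "midline_x_mm": center[0],
        "ac_mm": ac_mm,
        "pc_mm": pc_mm,
        "seed": seed,
    }
    masks = {"brain": brain, "ventricles": ventricles, "ventricles_pv": pv,
             "callosum": callosum, "limbs": limbs}
    return PhantomResult(tensor, masks, truth, spec)


def _gradient_scheme(n_directions: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """b=0 plus ``n_directions`` unit vectors on a Fibonacci hemisphere."""
    i = np.arange(n_directions)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    zc = (i + 0.5) / n_directions  # upper hemisphere, avoids antipodal pairs
    r = np.sqrt(1 - zc ** 2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), zc])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    bvals = np.concatenate([[0.0], np.full(n_directions, 1000.0)])
    return bvals, bvecs


def synthesize_dwi(phantom: PhantomResult, n_directions: int = 20,
                   b_value: float = 1000.0, s0: float = 100.0,
                   seed: int | None = None) -> DwiSet:
    """Forward-simulate DWI signal S = S0 exp(-b g^T D g) from the phantom
    tensors, with optional additive Gaussian noise (spec.noise_sigma)."""
    bvals, bvecs = _gradient_scheme(n_directions)
    bvals = np.where(bvals > 0, b_value, 0.0)
    mats = phantom.tensor.as_matrices()
    fg = phantom.masks["brain"]
    vols = np.zeros(fg.shape + (len(bvals),))
    quad = np.einsum("gi,...ij,gj->...g", bvecs, mats, bvecs)
    vols = s0 * np.exp(-bvals[None, None, None, :] * quad)
    vols[~fg] = 0.0
    sigma = phantom.spec.noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.normal(0.0, sigma, vols.shape)
        vols = np.clip(vols, 0.0, None)
    return DwiSet(vols, bvals, bvecs, phantom.tensor.grid)


# ---------------------------------------------------------------------------
# Tabular cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupMoments:
    """Marginal mean/SD of EI, CA, SA (plus age) for one diagnostic group."""

    group: str
    n: int
    ei: tuple[float, float]
    ca: tuple[float, float]
    sa: tuple[float, float]
    age: tuple[float, float] = (73.0, 5.8)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name in ("ei", "ca", "sa"):
            # zero is allowed for degenerate (constant-column) configurations
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be non-negative")


# Canonical four-group parameter set shipped with the package (n = 19 each,
# 11 men / 8 women per group).
TABLE1_MOMENTS: tuple[GroupMoments, ...] = (
    GroupMoments("HC", 19, (0.25, 0.02), (112.0, 8.05), (75.7, 13.1), (72.3, 5.38)),
    GroupMoments("PD", 19, (0.29, 0.05), (105.0, 20.0), (67.0, 18.8), (73.6, 5.74)),
    GroupMoments("AD", 19, (0.30, 0.06), (104.0, 20.3), (70.5, 11.9), (73.8, 5.60)),
    GroupMoments("NPH", 19, (0.38, 0.08), (58.3, 15.6), (25.0, 9.74), (73.7, 6.36)),
)
SEX_COUNTS = (11, 8)  # men, women per group of 19

_BOUNDS = {"EI": (0.0, 1.0), "CA": (0.0, 180.0), "SA": (0.0, 180.0)}


def _correlation_matrix(correlation) -> np.ndarray:
    if np.isscalar(correlation):
        c = np.full((3, 3), float(correlation))
        np.fill_diagonal(c, 1.0)
    else:
        c = np.asarray(correlation, dtype=float)
        if c.shape != (3, 3):
            raise ValueError("correlation config must be a scalar or a 3x3 matrix")
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    return c


def simulate_cohort(moments=TABLE1_MOMENTS, seed: int = 0, correlation=0.0,
                    n_per_group: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table from per-group Gaussian marginals.

    (EI, CA, SA) are drawn jointly from a multivariate normal whose marginals
    match the group moments and whose cross-index correlation defaults to 0;
    rows with impossible values (EI outside (0,1), angles outside (0,180))
    are rejected and redrawn. Ages are Gaussian; sexes follow an 11:8 split.
    """
    moments = list(moments)
    if len(moments) < 2:
        raise ValueError("need moments for at least 2 groups")
    corr = _correlation_matrix(correlation)
    rng = np.random.default_rng(seed)
    rows = []
    for gm in moments:
        n = int(n_per_group or gm.n)
        mu = np.array([gm.ei[0], gm.ca[0], gm.sa[0]])
        sd = np.array([gm.ei[1], gm.ca[1], gm.sa[1]])
        cov = corr * np.outer(sd, sd)
        evals, evecs = np.linalg.eigh(cov)
        factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
        draws = np.empty((0, 3))
        for _ in range(1000):
            need = n - len(draws)
            if need <= 0:
                break
            cand = mu + rng.standard_normal((max(need, 8), 3)) @ factor.T
            ok = ((cand[:, 0] > _BOUNDS["EI"][0]) & (cand[:, 0] < _BOUNDS["EI"][1])
                  & (cand[:, 1] > 0) & (cand[:, 1] < 180)
                  & (cand[:, 2] > 0) & (cand[:, 2] < 180))
            draws = np.vstack([draws, cand[ok]])[: n]
        if len(draws) < n:
            raise RuntimeError("rejection sampling failed; check the moment config")
        ages = rng.normal(gm.age[0], gm.age[1], n)
        n_men = int(round(n * SEX_COUNTS[0] / sum(SEX_COUNTS)))
        sexes = np.array(["M"] * n_men + ["F"] * (n - n_men))
        rng.shuffle(sexes)
        for i in range(n):
            rows.append({"subject": f"{gm.group}{i + 1:03d}", "group": gm.group,
                         "age": ages[i], "sex": sexes[i], "EI": draws[i, 0],
                         "CA": draws[i, 1], "SA": draws[i, 2]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FollowupDeltas:
    """Mean +- SD of 1-year changes per measure for one follow-up arm."""

    arm: str  # 'shunt' | 'no_shunt'
    ei: tuple[float, float]
    ca: tuple[float, float]
    sa: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        for name in ("ei", "ca", "sa"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} delta SD must be non-negative")


# Canonical follow-up parameters: angles widen after shunting, EI shrinks.
FOLLOWUP_DELTAS: dict[str, FollowupDeltas] = {
    "shunt": FollowupDeltas("shunt", (-0.03, 0.02), (13.2, 14.3), (13.1, 6.7), 6),
    "no_shunt": FollowupDeltas("no_shunt", (0.00, 0.01), (-2.1, 2.0), (0.2, 5.2), 5),
}


def simulate_followup(baseline: pd.DataFrame,
                      deltas: dict[str, FollowupDeltas] = FOLLOWUP_DELTAS,
                      seed: int = 0) -> pd.DataFrame:
    """Paired baseline/follow-up table for the NPH arm split.

    The first ``n_shunt`` baseline rows get the shunt-arm deltas, the next
    ``n_no_shunt`` the conservative-arm deltas; follow-up = baseline + draw
    from N(delta_mean, delta_SD^2) per measure.
    """
    arms = [deltas["shunt"], deltas["no_shunt"]]
    for d in arms:
        if d.n < 2:
            raise ValueError(f"arm {d.arm!r} needs at least 2 subjects")
    total = sum(d.n for d in arms)
    if len(baseline) < total:
        raise ValueError(f"baseline table has {len(baseline)} rows; need {total}")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for d in arms:
        for _ in range(d.n):
            base = baseline.iloc[idx]
            rec = {"subject": base["subject"], "arm": d.arm}
            for col, par in (("EI", d.ei), ("CA", d.ca), ("SA", d.sa)):
                delta = rng.normal(par[0], par[1]) if par[1] > 0 else par[0]
                rec[f"{col}_baseline"] = base[col]
                rec[f"{col}_followup"] = base[col] + delta
                rec[f"d{col}"] = delta
            rows.append(rec)
            idx += 1
    return pd.DataFrame(rows)
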