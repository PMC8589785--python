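"""Diffusion-tensor maps: tensor fitting, FA, principal eigenvector, RGB encoding.

The directional color map encodes the principal diffusion direction weighted
by fractional anisotropy: red = left-right, green = anterior-posterior,
blue = inferior-superior, in a canonical RAS frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "DwiSet",
    "TensorVolume",
    "ColorFAVolume",
    "fit_tensor",
    "compute_fa_e1",
    "color_encode",
    "fa_from_eigenvalues",
]

B0_THRESHOLD = 50.0  # s/mm^2; gradients at or below are treated as b=0
# Tensor component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_COMPONENT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass(frozen=True)
class Grid:
    """Voxel grid metadata: spacing in mm and an orientation tag.

    Axes are assumed reordered to RAS on load: axis 0 = left->right,
    axis 1 = posterior->anterior, axis 2 = inferior->superior.
    """

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str | None = "RAS"

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid voxel spacing {self.spacing}")


@dataclass
class DwiSet:
    """Diffusion-weighted signal set: 4D volume stack plus gradient scheme."""

    volumes: np.ndarray  # (x, y, z, n_gradients)
    bvals: np.ndarray  # (n_gradients,), s/mm^2
    bvecs: np.ndarray  # (n_gradients, 3), unit for b > 0
    grid: Grid = field(default_factory=Grid)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T  # accept FSL row-major layout
        if self.volumes.ndim != 4:
            raise ValueError("DWI volumes must be 4D (x, y, z, gradient)")
        if self.volumes.shape[3] != len(self.bvals) or self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvals/bvecs length must match the gradient axis")
        if not np.any(self.bvals <= B0_THRESHOLD):
            raise ValueError("DwiSet requires at least one b=0 volume")
        dw = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("b-vectors for b > 0 must be unit length (tol 1e-6)")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, 6 unique components in mm^2/s."""

    components: np.ndarray  # (x, y, z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    grid: Grid = field(default_factory=Grid)
    foreground: np.ndarray | None = None  # bool (x, y, z); None = all

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError("tensor components must have shape (x, y, z, 6)")
        if self.foreground is None:
            self.foreground = np.ones(self.components.shape[:3], dtype=bool)

    def as_matrices(self) -> np.ndarray:
        """Expand components to full (x, y, z, 3, 3) symmetric matrices."""
        out = np.empty(self.components.shape[:3] + (3, 3), dtype=float)
        for k, (i, j) in enumerate(_COMPONENT_IDX):
            out[..., i, j] = self.components[..., k]
            out[..., j, i] = self.components[..., k]
        return out

    @classmethod
    def from_matrices(cls, mats: np.ndarray, grid: Grid | None = None,
                      foreground: np.ndarray | None = None) -> "TensorVolume":
        mats = np.asarray(mats, dtype=float)
        comp = np.stack([mats[..., i, j] for (i, j) in _COMPONENT_IDX], axis=-1)
        return cls(comp, grid or Grid(), foreground)


@dataclass
class ColorFAVolume:
    """FA map with principal eigenvector and optional RGB directional encoding."""

    fa: np.ndarray  # (x, y, z) in [0, 1]
    e1: np.ndarray  # (x, y, z, 3) unit where defined
    grid: Grid = field(default_factory=Grid)
    rgb: np.ndarray | None = None  # (x, y, z, 3) = fa * |e1|
    foreground: np.ndarray | None = None
    e1_undefined: np.ndarray | None = None  # bool; True where tensor was degenerate

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.e1 = np.asarray(self.e1, dtype=float)
        if self.e1.shape != self.fa.shape + (3,):
            raise ValueError("e1 must have shape fa.shape + (3,)")
        if self.foreground is None:
            self.foreground = np.ones(self.fa.shape, dtype=bool)
        if self.e1_undefined is None:
            self.e1_undefined = np.zeros(self.fa.shape, dtype=bool)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    b = bvals[:, None]
    return -b * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def fit_tensor(dwi: DwiSet, background_fraction: float = 0.01) -> TensorVolume:
    """Fit a diffusion tensor per voxel by log-linear least squares.

    The model is log(S/S0) = -b g^T D g solved unweighted over all b>0
    gradients; negative eigenvalues are clamped to zero after the fit.
    Voxels whose mean b=0 signal falls below ``background_fraction`` of the
    volume's robust maximum are flagged background and left as zero tensors.
    """
    dw = ~dwi.b0_mask
    design = _design_matrix(dwi.bvals[dw], dwi.bvecs[dw])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("insufficient gradient scheme: need >= 6 non-collinear directions")

    s0 = dwi.volumes[..., dwi.b0_mask].mean(axis=-1)
    robust_max = np.percentile(s0, 99.9)
    foreground = s0 > background_fraction * robust_max

    shape = dwi.volumes.shape[:3]
    comp = np.zeros(shape + (6,), dtype=float)
    fg = foreground.reshape(-1)
    if fg.any():
        sig = dwi.volumes[..., dw].reshape(-1, dw.sum())[fg]
        s0f = s0.reshape(-1)[fg]
        eps = np.finfo(float).tiny
        y = np.log(np.maximum(sig, eps) / np.maximum(s0f[:, None], eps))
        coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        comp.reshape(-1, 6)[fg] = coef.T

    tv = TensorVolume(comp, dwi.grid, foreground)
    # clamp negative eigenvalues (noise can push the LLS fit non-PSD)
    mats = tv.as_matrices()
    vals, vecs = np.linalg.eigh(mats.reshape(-1, 3, 3))
    if (vals < 0).any():
        vals = np.clip(vals, 0.0, None)
        mats = (vecs * vals[:, None, :]) @ np.swapaxes(vecs, -1, -2)
        tv = TensorVolume.from_matrices(mats.reshape(shape + (3, 3)), dwi.grid, foreground)
    return tv


def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam|| along the last axis."""
    lam = np.asarray(lam, dtype=float)
    dev = lam - lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((dev ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa_e1(tensor: TensorVolume) -> ColorFAVolume:
    """Compute FA and the sign-normalized principal eigenvector per voxel.

    The eigenvector sign is fixed so that its largest-magnitude component is
    non-negative. Voxels with an all-zero tensor get FA = 0 and are flagged
    in ``e1_undefined``.
    """
    shape = tensor.components.shape[:3]
    comp = tensor.components.reshape(-1, 6)
    nonzero = np.any(comp != 0, axis=1)
    mats = tensor.as_matrices().reshape(-1, 3, 3)[nonzero]
    vals, vecs = np.linalg.eigh(mats)  # ascending eigenvalues
    fa = np.zeros(comp.shape[0])
    fa[nonzero] = fa_from_eigenvalues(vals)
    e1_nz = vecs[:, :, 2]  # eigenvector of the largest eigenvalue
    # sign normalization: largest-|component| non-negative
    lead = np.take_along_axis(e1_nz, np.abs(e1_nz).argmax(axis=1)[:, None], axis=1)[:, 0]
    e1_nz = np.where(lead[:, None] < 0, -e1_nz, e1_nz)
    e1 = np.zeros((comp.shape[0], 3))
    e1[nonzero] = e1_nz
    undefined = (~nonzero).reshape(shape)
    return ColorFAVolume(fa.reshape(shape), e1.reshape(shape + (3,)), tensor.grid,
                         None, tensor.foreground, undefined)


def color_encode(cfa: ColorFAVolume) -> ColorFAVolume:
    """Fill the RGB channels: rgb = FA * (|e1.x|, |e1.y|, |e1.z|).

    Requires orientation metadata on the grid so the red channel can be tied
    to the left-right axis. Idempotent; returns the same object.
    """
    if cfa.grid.orientation is None:
        raise ValueError("missing orientation metadata: cannot assign the red (left-right) axis")
    cfa.rgb = cfa.fa[..., None] * np.abs(cfa.e1)
    return cfa
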