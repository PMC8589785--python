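"""NIfTI and sidecar I/O. Volumes are reoriented to canonical RAS on load."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dti import ColorFAVolume, DwiSet, Grid, TensorVolume

__all__ = ["load_volume", "load_dwi", "save_volume", "save_color_fa", "save_tensor"]


def _grid_from_img(img: nib.Nifti1Image) -> Grid:
    zooms = img.header.get_zooms()[:3]
    ax = "".join(nib.aff2axcodes(img.affine))
    return Grid(tuple(float(z) for z in zooms), ax)


def load_volume(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Load a NIfTI volume reoriented to RAS; returns (data, grid)."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asarray(img.dataobj, dtype=float), _grid_from_img(img)


def load_dwi(dwi_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path) -> DwiSet:
    """Load a 4D DWI NIfTI with FSL-style plain-text bval/bvec sidecars."""
    img = nib.as_closest_canonical(nib.load(str(dwi_path)))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return DwiSet(data, bvals, bvecs, _grid_from_img(img))


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    return aff


def save_volume(data: np.ndarray, grid: Grid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(grid)),
             str(path))


def save_color_fa(cfa: ColorFAVolume, outdir: str | Path, stem: str = "dti") -> dict:
    """Write FA, e1, and (if present) RGB maps; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fa": outdir / f"{stem}_fa.nii.gz", "e1": outdir / f"{stem}_e1.nii.gz"}
    save_volume(cfa.fa, cfa.grid, paths["fa"])
    save_volume(cfa.e1, cfa.grid, paths["e1"])
    if cfa.rgb is not None:
        paths["rgb"] = outdir / f"{stem}_rgb.nii.gz"
        save_volume(cfa.rgb, cfa.grid, paths["rgb"])
    return {k: str(v) for k, v in paths.items()}


def save_tensor(tensor: TensorVolume, path: str | Path) -> None:
    save_volume(tensor.components, tensor.grid, path)
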