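"""Reading and writing 3D volumes (NRRD, NIfTI, multipage TIFF).

Binary segmentation masks come in as :class:`~chondromorph.thickness.BinaryVolume`
(boolean, z-y-x order) and thickness maps go out in the same container
format as their input, as floating point micrometre values.

Header spacings in NRRD/NIfTI are conventionally millimetres and are
converted to micrometres on read; TIFF stacks carry no reliable spacing, so
a spacing override (in um) is required for them.  An explicit override
always wins.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .thickness import BinaryVolume, ThicknessMap

__all__ = ["read_volume", "write_volume", "write_thickness_map"]

_NRRD_EXT = (".nrrd", ".nhdr")
_NIFTI_EXT = (".nii", ".nii.gz")
_TIFF_EXT = (".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _isotropic(spacings, path: Path) -> float:
    spacings = np.asarray(spacings, dtype=float)
    if not np.allclose(spacings, spacings[0], rtol=1e-3):
        raise ValueError(f"{path.name}: anisotropic voxels {spacings} are not "
                         "supported; resample first")
    return float(spacings[0])


def read_volume(path: str | Path, spacing_um: float | None = None,
                provenance: dict | None = None) -> BinaryVolume:
    """Read a binary mask volume; nonzero voxels are foreground.

    ``spacing_um`` overrides (or, for TIFF, supplies) the voxel edge length
    in micrometres.
    """
    path = Path(path)
    ext = _suffix(path)
    if ext in _NRRD_EXT:
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        header_um = _isotropic(img.GetSpacing(), path) * 1000.0
    elif ext in _NIFTI_EXT:
        import nibabel as nib
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj).T  # (x, y, z) -> (z, y, x)
        header_um = _isotropic(img.header.get_zooms()[:3], path) * 1000.0
    elif ext in _TIFF_EXT:
        import tifffile
        arr = tifffile.imread(str(path))
        header_um = None
    else:
        raise ValueError(f"unsupported volume format {ext!r}")

    if spacing_um is None:
        if header_um is None:
            raise ValueError(
                f"{path.name}: no spacing metadata; pass spacing_um (um)")
        spacing_um = header_um
    prov = {"source": str(path)}
    if provenance:
        prov.update(provenance)
    return BinaryVolume(occupancy=arr != 0, spacing=spacing_um,
                        provenance=prov)


def write_volume(array: np.ndarray, spacing_um: float,
                 path: str | Path) -> Path:
    """Write a (z, y, x) array to NRRD / NIfTI / TIFF chosen by extension."""
    path = Path(path)
    ext = _suffix(path)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    spacing_mm = spacing_um / 1000.0
    if ext in _NRRD_EXT:
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((spacing_mm,) * 3)
        sitk.WriteImage(img, str(path), useCompression=False)
    elif ext in _NIFTI_EXT:
        import nibabel as nib
        affine = np.diag([spacing_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(arr.T, affine), str(path))
    elif ext in _TIFF_EXT:
        import tifffile
        tifffile.imwrite(str(path), arr)
    else:
        raise ValueError(f"unsupported volume format {ext!r}")
    return path


def write_thickness_map(tmap: ThicknessMap, like: str | Path,
                        out_dir: str | Path) -> Path:
    """Write a thickness map next to its source volume's format (float um)."""
    like = Path(like)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = _suffix(like)
    stem = like.name[:-len(ext)]
    out = out_dir / f"{stem}_thickness{ext}"
    return write_volume(tmap.values.astype(np.float32), tmap.spacing, out)
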