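"""Reading and writing NIfTI / MetaImage volumes via SimpleITK.

SimpleITK stores arrays as ``(z, y, x)``; this module transposes so that the
in-memory :class:`~ctvi.volume.ImageVolume` convention ``(x, y, z)`` holds.
Vector images (3-component displacement fields) round-trip with component
order preserved as ``(u_x, u_y, u_z)``.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .volume import ImageVolume

__all__ = [
    "UnsupportedFormatError",
    "CorruptVolumeError",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


class UnsupportedFormatError(ValueError):
    """File extension is not NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""


class CorruptVolumeError(IOError):
    """File exists but cannot be parsed as a volume."""


def _check_extension(path: str) -> None:
    low = str(path).lower()
    if not any(low.endswith(ext) for ext in _EXTENSIONS):
        raise UnsupportedFormatError(
            f"unsupported extension for {path!r}; expected one of {_EXTENSIONS}"
        )


def _read_image(path) -> sitk.Image:
    path = os.fspath(path)
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        return sitk.ReadImage(path)
    except RuntimeError as exc:  # ITK wraps parse failures in RuntimeError
        raise CorruptVolumeError(f"cannot read {path!r}: {exc}") from exc


def read_volume(path) -> ImageVolume:
    """Read a scalar 3D volume from NIfTI or MetaImage."""
    img = _read_image(path)
    if img.GetDimension() != 3:
        raise ValueError(
            f"{path!r} is {img.GetDimension()}D; expected a 3D scalar volume"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"{path!r} has {img.GetNumberOfComponentsPerPixel()} components; "
            "use read_displacement_field for vector images"
        )
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(vol: ImageVolume, path) -> None:
    """Write a scalar volume; format chosen by extension."""
    path = os.fspath(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing_mm)
    img.SetOrigin(vol.origin_mm)
    sitk.WriteImage(img, path)


def read_displacement_field(path):
    """Read a 3-component vector image as a DisplacementField."""
    from .jacobian import DisplacementField

    img = _read_image(path)
    if img.GetDimension() != 3:
        raise ValueError(f"{path!r} is {img.GetDimension()}D; expected 3D")
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(
            f"{path!r} has {img.GetNumberOfComponentsPerPixel()} components; expected 3"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    arr = arr.transpose(2, 1, 0, 3)
    return DisplacementField(
        u_x=arr[..., 0],
        u_y=arr[..., 1],
        u_z=arr[..., 2],
        spacing_mm=tuple(img.GetSpacing()),
        origin_mm=tuple(img.GetOrigin()),
    )


def write_displacement_field(dvf, path) -> None:
    """Write a DisplacementField as a 3-component vector image."""
    path = os.fspath(path)
    _check_extension(path)
    arr = np.stack([dvf.u_x, dvf.u_y, dvf.u_z], axis=-1)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(arr.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing(dvf.spacing_mm)
    img.SetOrigin(dvf.origin_mm)
    sitk.WriteImage(img, path)
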