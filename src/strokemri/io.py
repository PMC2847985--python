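"""NIfTI-1 and JSON input/output helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .geometry import AcquisitionGeometry

__all__ = ["save_nifti", "load_nifti", "save_json", "load_json"]


def save_nifti(volume: np.ndarray, geometry: AcquisitionGeometry, path,
               dtype=None, description: str = "") -> Path:
    """Write a volume as NIfTI-1 on the geometry's grid.

    Masks/labels should pass an integer ``dtype`` (uint8/int16); map units
    go into the header description field.
    """
    path = Path(path)
    data = np.asarray(volume)
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, geometry.affine())
    if description:
        img.header["descrip"] = description.encode()[:79]
    img.header.set_zooms(tuple(geometry.spacing_mm) + (1.0,) * (data.ndim - 3))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> Tuple[np.ndarray, np.ndarray, str]:
    """Read a NIfTI volume; returns (data, affine, header description)."""
    img = nib.load(str(path))
    desc = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    return np.asarray(img.dataobj), img.affine, desc


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
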