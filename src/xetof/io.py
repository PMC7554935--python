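"""NIfTI and sidecar round-tripping.

Dynamic series are stored as one NIfTI volume with axes (x, y, dynamic) and
a JSON sidecar (same basename, ``.json``) carrying the TOF delays, seed and
acquisition metadata; parametric maps are single 2-D NIfTI images with the
units recorded in the header description.  Pixel data are written at full
float64/complex128 precision so a write/read round trip is bit-identical.

Axis convention: x runs left -> right and y posterior -> anterior in the
anatomical view; :func:`to_anatomical` is the documented left-right flip
from the radiological convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ValidationError


def sidecar_path(path) -> Path:
    """`series.nii` / `series.nii.gz` -> `series.json`."""
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".json")


def _affine(fov: tuple[float, float], shape_xy: tuple[int, int]) -> np.ndarray:
    nx, ny = shape_xy
    fx, fy = fov
    return np.diag([fx / nx, fy / ny, 1.0, 1.0])


def save_series(
    path,
    data: np.ndarray,
    tof_delays,
    fov: tuple[float, float] = (250.0, 250.0),
    meta: dict | None = None,
) -> None:
    """Write a (dynamics, y, x) stack as NIfTI (x, y, dynamic) + sidecar."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValidationError("series data must be (dynamics, y, x)")
    delays = [float(t) for t in np.atleast_1d(tof_delays)]
    if len(delays) != data.shape[0]:
        raise ValidationError("one TOF delay per dynamic is required")
    dtype = np.complex128 if np.iscomplexobj(data) else np.float64
    vol = np.transpose(data.astype(dtype), (2, 1, 0))
    img = nib.Nifti1Image(vol, _affine(fov, vol.shape[:2]))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
    sidecar = {"tof_delays_s": delays, "fov_mm": [float(f) for f in fov]}
    sidecar.update(meta or {})
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_series(path) -> tuple[np.ndarray, tuple[float, ...], dict]:
    """Read a series written by :func:`save_series`.

    Returns (data (dynamics, y, x), tof_delays, sidecar_meta).  A missing
    sidecar or one without delays raises :class:`ValidationError`.
    """
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise ValidationError(f"expected a 3-D series, got shape {vol.shape}")
    sc = sidecar_path(path)
    if not sc.exists():
        raise ValidationError(f"missing sidecar {sc}")
    meta = json.loads(sc.read_text())
    if "tof_delays_s" not in meta:
        raise ValidationError(f"sidecar {sc} lacks 'tof_delays_s'")
    delays = tuple(float(t) for t in meta["tof_delays_s"])
    data = np.transpose(vol, (2, 1, 0))
    if data.shape[0] != len(delays):
        raise ValidationError(
            f"{data.shape[0]} dynamics but {len(delays)} sidecar delays"
        )
    return data, delays, meta


def save_map(
    path,
    arr: np.ndarray,
    fov: tuple[float, float] = (250.0, 250.0),
    units: str = "",
    meta: dict | None = None,
) -> None:
    """Write a 2-D parametric map; ``units`` lands in the header descrip."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("map must be 2-D")
    vol = arr.T  # (y, x) -> (x, y)
    img = nib.Nifti1Image(vol, _affine(fov, vol.shape))
    img.header.set_data_dtype(np.float64)
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, str(path))
    if meta is not None:
        sidecar_path(path).write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


def load_map(path) -> np.ndarray:
    """Read a 2-D map written by :func:`save_map`, returned as (y, x)."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim == 3 and vol.shape[2] == 1:
        vol = vol[:, :, 0]
    if vol.ndim != 2:
        raise ValidationError(f"expected a 2-D map, got shape {vol.shape}")
    return np.asarray(vol).T


def to_anatomical(arr: np.ndarray) -> np.ndarray:
    """Flip the x (left-right) axis: radiological -> anatomical view."""
    return np.flip(np.asarray(arr), axis=-1)
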