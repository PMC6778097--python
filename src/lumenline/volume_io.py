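"""Reading, writing and in-memory representation of 3D image volumes.

Volumes are held in ``(x, y, z)`` axis order with the stack-slice index
mapping to ``z``.  Voxel indices are 0-based and a voxel's center sits at
its integer coordinate; continuous positions throughout the package are
expressed in voxel units and converted to physical units (µm / mm) only
when results are reported.  The voxel length is a single isotropic edge
length in µm — anisotropic volumes are rejected on input unless the
caller overrides the spacing explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "VoxelVolume",
    "LumenMask",
    "read_volume",
    "write_volume",
    "binarize",
]

_ISO_RTOL = 1e-6


def _check_grid(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all grid dimensions must be >= 1, got shape {data.shape}")


@dataclass
class VoxelVolume:
    """A 3D scalar field with an isotropic physical voxel length.

    Parameters
    ----------
    data:
        3D array indexed ``(x, y, z)``.
    voxel_length:
        Edge length of one (cubic) voxel in µm.
    name:
        Free-text label carried through the pipeline.
    """

    data: np.ndarray
    voxel_length: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data)
        if not self.voxel_length > 0:
            raise ValueError(f"voxel_length must be > 0, got {self.voxel_length}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LumenMask:
    """Binary segmentation of the vessel lumen (foreground = lumen)."""

    data: np.ndarray
    voxel_length: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_grid(data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be exactly {0, 1}")
            data = data.astype(bool)
        self.data = data
        if not self.voxel_length > 0:
            raise ValueError(f"voxel_length must be > 0, got {self.voxel_length}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


def _numeric_key(p: Path):
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else 0, p.name)


def _infer_fmt(path: Path) -> str:
    if path.is_dir():
        return "tiff-stack"
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    if suffix == ".nrrd":
        return "nrrd"
    if suffix in (".mha", ".mhd"):
        return "mha"
    raise ValueError(f"cannot infer volume format from {path}")


def _read_tiff(path: Path) -> np.ndarray:
    """Read a multipage TIFF or a directory of per-slice TIFFs as (x, y, z)."""
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(str(f)) for f in files]
        zyx = np.stack(slices, axis=0)
    else:
        zyx = tifffile.imread(str(path))
        if zyx.ndim == 2:
            zyx = zyx[None]
    # pages are stored (row=y, col=x); reorder to (x, y, z)
    return np.ascontiguousarray(zyx.transpose(2, 1, 0))


def _read_itk(path: Path, voxel_length: float | None) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if voxel_length is None:
        if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL):
            raise ValueError(
                f"anisotropic spacing {tuple(spacing)} in {path.name}; "
                "pass an explicit voxel_length to override"
            )
        voxel_length = float(spacing[0])
    zyx = sitk.GetArrayFromImage(img)
    return np.ascontiguousarray(zyx.transpose(2, 1, 0)), voxel_length


def read_volume(
    path: str | Path,
    fmt: str | None = None,
    voxel_length: float | None = None,
    name: str | None = None,
) -> VoxelVolume:
    """Read a volume from a TIFF stack, NRRD or MetaImage file.

    TIFF carries no reliable spacing metadata, so ``voxel_length`` is
    required for TIFF input.  For NRRD/MHA the spacing is taken from the
    file; anisotropic metadata is rejected unless ``voxel_length``
    overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    fmt = fmt or _infer_fmt(path)
    if fmt == "tiff-stack":
        if voxel_length is None:
            raise ValueError("voxel_length is required for TIFF input (no spacing metadata)")
        data = _read_tiff(path)
    elif fmt in ("nrrd", "mha"):
        data, voxel_length = _read_itk(path, voxel_length)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return VoxelVolume(data, voxel_length, name=name if name is not None else path.stem)


def write_volume(v: VoxelVolume | LumenMask, path: str | Path, fmt: str | None = None) -> Path:
    """Write a volume; re-readable by :func:`read_volume` with identical data.

    Masks are written as 8-bit ``{0, 255}`` TIFF for viewer compatibility
    and read back as ``{0, 1}``.  Float data written to TIFF is stored as
    32-bit float.
    """
    path = Path(path)
    fmt = fmt or _infer_fmt(path)
    data = v.data
    if isinstance(v, LumenMask):
        out = (data.astype(np.uint8) * 255) if fmt == "tiff-stack" else data.astype(np.uint8)
    elif data.dtype.kind == "f":
        out = data.astype(np.float32)
    else:
        out = data
    if fmt == "tiff-stack":
        zyx = out.transpose(2, 1, 0)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), zyx, photometric="minisblack")
    elif fmt in ("nrrd", "mha"):
        img = sitk.GetImageFromArray(out.transpose(2, 1, 0))
        img.SetSpacing((v.voxel_length,) * 3)
        path.parent.mkdir(parents=True, exist_ok=True)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def read_mask(path: str | Path, voxel_length: float = 1.0, fmt: str | None = None) -> LumenMask:
    """Read a binary mask; any nonzero voxel is foreground."""
    v = read_volume(path, fmt=fmt, voxel_length=voxel_length)
    return LumenMask(v.data > 0, v.voxel_length, name=v.name)


def binarize(v: VoxelVolume, threshold: float) -> LumenMask:
    """Threshold a volume: foreground where ``data >= threshold``."""
    return LumenMask(v.data >= threshold, v.voxel_length, name=v.name)
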