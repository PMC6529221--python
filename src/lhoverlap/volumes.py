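"""Registered 3D volumes and binary masks on a common template grid.

All quantitative comparisons in this package presuppose that every volume has
been registered to a single template space (e.g. JFRC2013) beforehand, so a
volume here is just a scalar grid plus its voxel spacing, world origin and the
identifier of the space it lives in.  Arrays are indexed ``[x, y, z]`` with
``spacing`` and ``origin`` given per axis in micrometres; the world coordinate
of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.

Masks additionally carry the biological annotations used downstream: cell
type, compartment (axon / dendrite / membrane / whole), polarity class (LHON,
LHLN, LHIN, MBON, DAN, PN), neurotransmitter and sensory modality.  Volume
comparisons throughout the package use voxel counts, not physical volume: all
masks share one grid, so the two differ only by a constant factor.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

COMPARTMENTS = ("axon", "dendrite", "membrane", "whole")
POLARITY_CLASSES = ("LHON", "LHLN", "LHIN", "MBON", "DAN", "PN", "other")
TRANSMITTERS = ("ACh", "GABA", "Glu", "mixed", "unknown")
MODALITIES = ("olfactory", "mechanosensory", "temperature", "visual", "taste", "none")

DEFAULT_SPACE = "JFRC2013"
#: 20x confocal voxel size of the template stacks, micrometres per axis.
DEFAULT_SPACING = (0.56, 0.56, 1.0)

_REL_TOL = 1e-6


class GridMismatchError(ValueError):
    """Two volumes do not live on the same registered grid."""


@dataclass
class LabelVolume:
    """A single-channel registered image stack.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Voxel edge length per axis in micrometres, strictly positive.
    origin : tuple of float
        World-space offset of voxel (0, 0, 0) in micrometres.
    space_id : str
        Identifier of the registration template (e.g. ``"JFRC2013"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    space_id: str = DEFAULT_SPACE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """A boolean volume tagged with the cell-type annotations used downstream."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    space_id: str = DEFAULT_SPACE
    cell_type: str | None = None
    compartment: str | None = None
    polarity_class: str | None = None
    transmitter: str | None = None
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            if not np.isin(self.data, (0, 1)).all():
                raise ValueError("mask data must be boolean or 0/1")
            self.data = self.data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        labels = (
            self.cell_type,
            self.compartment,
            self.polarity_class,
            self.transmitter,
            self.modality,
        )
        if all(v is None for v in labels):
            raise ValueError("a BinaryMask needs at least one metadata label")
        _check_choice("compartment", self.compartment, COMPARTMENTS)
        _check_choice("polarity_class", self.polarity_class, POLARITY_CLASSES)
        _check_choice("transmitter", self.transmitter, TRANSMITTERS)
        _check_choice("modality", self.modality, MODALITIES)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        """Number of true voxels."""
        return int(self.data.sum())

    @property
    def label(self) -> str:
        """Row/column label: ``cell_type.compartment`` where both are set."""
        parts = [p for p in (self.cell_type, self.compartment) if p]
        return ".".join(parts) if parts else "mask"

    def metadata_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "compartment": self.compartment,
            "polarity_class": self.polarity_class,
            "transmitter": self.transmitter,
            "modality": self.modality,
        }

    def copy_with(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=data)


def _check_choice(name: str, value: str | None, allowed: tuple[str, ...]) -> None:
    if value is not None and value not in allowed:
        raise ValueError(f"{name}={value!r} not in {allowed}")


def assert_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless two volumes share one grid.

    Shapes must match exactly, spacings to 1e-6 relative tolerance, and the
    template ``space_id`` strings must be identical — comparing voxels across
    different template brains is meaningless.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    if not np.allclose(sa, sb, rtol=_REL_TOL, atol=0.0):
        raise GridMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if a.space_id != b.space_id:
        raise GridMismatchError(f"space_id mismatch: {a.space_id!r} vs {b.space_id!r}")


def restrict_to_region(v, region: BinaryMask):
    """Zero (or falsify) everything outside ``region``; inside is unchanged.

    The idiom behind "only pixels in the LH were displayed": any volume or
    mask can be restricted to a neuropil mask on the same grid.  Restriction
    is idempotent and never increases the true-voxel count.
    """
    assert_same_grid(v, region)
    if isinstance(v, BinaryMask):
        return v.copy_with(v.data & region.data)
    return v.copy_with(np.where(region.data, v.data, 0))


# ---------------------------------------------------------------------------
# NRRD (canonical on-disk format: carries spacing natively)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "int16": np.int16,
    "uint16": np.uint16,
    "int32": np.int32,
    "uint32": np.uint32,
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
}
_NP_TO_NRRD = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def _parse_vector(text: str) -> tuple[float, ...]:
    return tuple(float(t) for t in text.strip().lstrip("(").rstrip(")").split(","))


def write_nrrd(path, volume, encoding: str = "gzip") -> None:
    """Write a :class:`LabelVolume` or :class:`BinaryMask` as detached NRRD.

    Data are stored little-endian in Fortran index order (x fastest), the
    convention NRRD readers expect.  Mask annotations go into NRRD key-value
    fields and are mirrored in a JSON sidecar next to the file.
    """
    path = Path(path)
    if encoding not in ("raw", "gzip"):
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    data = volume.data
    is_mask = isinstance(volume, BinaryMask)
    if is_mask:
        data = data.astype(np.uint8)
    if data.dtype not in _NP_TO_NRRD:
        data = data.astype(np.float32)
    sx, sy, sz = volume.spacing
    header = [
        "NRRD0004",
        "# written by lhoverlap",
        f"type: {_NP_TO_NRRD[data.dtype]}",
        "dimension: 3",
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"encoding: {'gzip' if encoding == 'gzip' else 'raw'}",
        "endian: little",
        "space dimension: 3",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        f"space origin: ({volume.origin[0]},{volume.origin[1]},{volume.origin[2]})",
        f"lhoverlap:space_id:={volume.space_id}",
    ]
    if is_mask:
        for key, value in volume.metadata_dict().items():
            if value is not None:
                header.append(f"lhoverlap:{key}:={value}")
    payload = np.ravel(data, order="F").astype(data.dtype.newbyteorder("<")).tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode("ascii"))
        fh.write(payload)
    if is_mask:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(volume.metadata_dict(), indent=2))


def read_nrrd(path):
    """Read an NRRD written by :func:`write_nrrd` (or compatible).

    Returns a :class:`BinaryMask` when mask annotations are present in the
    key-value fields, otherwise a :class:`LabelVolume`.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    try:
        head_end = blob.index(b"\n\n")
    except ValueError as exc:
        raise ValueError(f"corrupt NRRD header in {path} (no blank line)") from exc
    lines = blob[:head_end].decode("ascii", errors="replace").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path} is not an NRRD file (bad magic)")
    fields: dict[str, str] = {}
    kv: dict[str, str] = {}
    for line in lines[1:]:
        if line.startswith("#") or not line.strip():
            continue
        if ":=" in line:
            k, v = line.split(":=", 1)
            kv[k.strip()] = v.strip()
        elif ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip().lower()] = v.strip()
    for required in ("type", "sizes", "encoding"):
        if required not in fields:
            raise ValueError(f"corrupt NRRD header in {path}: missing '{required}' field")
    dtype = _NRRD_TYPES.get(fields["type"])
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {fields['type']!r} in {path}")
    shape = tuple(int(t) for t in fields["sizes"].split())
    payload = blob[head_end + 2 :]
    if fields["encoding"] == "gzip":
        payload = gzip.decompress(payload)
    elif fields["encoding"] != "raw":
        raise ValueError(f"unsupported NRRD encoding {fields['encoding']!r} in {path}")
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    if arr.size != int(np.prod(shape)):
        raise ValueError(f"corrupt NRRD payload in {path}: size mismatch")
    arr = arr.reshape(shape, order="F")
    if "space directions" in fields:
        vecs = [_parse_vector(v) for v in fields["space directions"].split(") ")]
        spacing = tuple(float(np.linalg.norm(v)) for v in vecs)
    elif "spacings" in fields:
        spacing = tuple(float(t) for t in fields["spacings"].split())
    else:
        spacing = DEFAULT_SPACING
    origin = (
        _parse_vector(fields["space origin"]) if "space origin" in fields else (0.0, 0.0, 0.0)
    )
    space_id = kv.get("lhoverlap:space_id", DEFAULT_SPACE)
    mask_meta = {
        key: kv[f"lhoverlap:{key}"]
        for key in ("cell_type", "compartment", "polarity_class", "transmitter", "modality")
        if f"lhoverlap:{key}" in kv
    }
    if mask_meta:
        return BinaryMask(
            arr.astype(bool), spacing=spacing, origin=origin, space_id=space_id, **mask_meta
        )
    return LabelVolume(
        np.array(arr), spacing=spacing, origin=origin, space_id=space_id
    )


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------


def write_tiff(path, volume) -> None:
    """Write a volume as a multi-page TIFF with ImageJ spacing metadata."""
    data = volume.data
    if isinstance(volume, BinaryMask):
        data = data.astype(np.uint8)
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    # TIFF pages are z-slices: transpose (x, y, z) -> (z, y, x)
    pages = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    sx, sy, sz = volume.spacing
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def read_tiff(path, spacing=None, space_id: str = DEFAULT_SPACE) -> LabelVolume:
    """Read a multi-page TIFF stack into a :class:`LabelVolume`.

    TIFF carries no mandatory voxel-size field; ImageJ metadata is used when
    present, otherwise ``spacing`` must be supplied (e.g. from a run config).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            meta_spacing = _tiff_spacing(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"cannot read TIFF file {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 1, 0))
    if meta_spacing is not None:
        spacing = meta_spacing
    elif spacing is None:
        raise ValueError(
            f"{path} carries no voxel-spacing metadata; pass spacing=(sx, sy, sz)"
        )
    return LabelVolume(data, spacing=tuple(spacing), space_id=space_id)


def _tiff_spacing(tif) -> tuple[float, float, float] | None:
    try:
        ij = tif.imagej_metadata
        if not ij or "spacing" not in ij:
            return None
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
        return (float(sx), float(sy), float(ij["spacing"]))
    except (KeyError, ZeroDivisionError, TypeError):
        return None


def read_volume(path, format: str | None = None, spacing=None, space_id=DEFAULT_SPACE):
    """Read a volume, dispatching on ``format`` or the file extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("nrrd",):
        return read_nrrd(path)
    if fmt in ("tif", "tiff"):
        return read_tiff(path, spacing=spacing, space_id=space_id)
    raise ValueError(f"unsupported volume format {fmt!r} for {path}")


def write_volume(path, volume, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "nrrd":
        write_nrrd(path, volume)
    elif fmt in ("tif", "tiff"):
        write_tiff(path, volume)
    else:
        raise ValueError(f"unsupported volume format {fmt!r} for {path}")
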