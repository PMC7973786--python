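"""Annotation and modality volumes.

A :class:`LabeledVolume` is the annotation volume (AV): a 3D integer array
in which each voxel carries the id of a brain structure, 0 meaning outside
the brain.  A :class:`ScalarVolume` is a modality volume on the same grid
(gene-expression energy or axonal projection density).  Hemisphere logic
is driven by an explicit left–right axis declaration rather than header
orientation strings, so the same code handles AIBS (PIR) and RAS data.

NIfTI files are read and written through nibabel.  NRRD support (the
format AIBS distributes) is a minimal built-in codec covering the subset
those files use: 3D arrays, little-endian, ``raw`` or ``gzip`` encodings.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConsistencyError

__all__ = [
    "LabeledVolume",
    "ScalarVolume",
    "read_volume",
    "write_volume",
    "label_sizes",
    "remap_labels",
    "hemisphere_masks",
    "mirror",
    "label_size_table",
]


@dataclass
class LabeledVolume:
    """3D integer annotation volume.

    ``lr_axis`` is the array axis running left–right; ``left_is_low`` says
    whether low indices along that axis are the animal's left.  At 100 µm
    isotropic resolution one voxel is exactly 1 nL, so voxel counts double
    as node sizes in nL.
    """

    data: np.ndarray
    voxel_size_um: float = 100.0
    lr_axis: int = 2
    left_is_low: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"annotation volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"annotation volume must be integer-typed, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("annotation labels must be non-negative")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def voxel_nl(self) -> float:
        return (self.voxel_size_um / 100.0) ** 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabeledVolume":
        return replace(self, data=data)


@dataclass
class ScalarVolume:
    """3D non-negative float volume on the grid of a reference atlas."""

    data: np.ndarray
    voxel_size_um: float = 100.0
    lr_axis: int = 2
    left_is_low: bool = True
    kind: str = "gene_energy"  # or "projection_density"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3D, got shape {self.data.shape}")
        if self.kind not in ("gene_energy", "projection_density"):
            raise ValueError(f"unknown scalar kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# minimal NRRD codec (NRRD0004, 3D, little-endian, raw/gzip)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "signed char": np.int8, "int8": np.int8, "uchar": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "uint": np.uint32, "uint32": np.uint32,
    "long long": np.int64, "int64": np.int64,
    "unsigned long long": np.uint64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in _NRRD_TYPES.items() if k in
               ("int8", "uint8", "int16", "uint16", "int32", "uint32",
                "int64", "uint64", "float", "double")}


def _read_nrrd(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        blob = fh.read()
    try:
        header_end = blob.index(b"\n\n") + 2
    except ValueError:
        raise ValueError(f"{path}: no NRRD header terminator found") from None
    header = blob[:header_end].decode("ascii", errors="replace").splitlines()
    if not header or not header[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in header[1:]:
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.lstrip("=").strip()
    dim = int(fields.get("dimension", "0"))
    if dim != 3:
        raise ValueError(f"{path}: expected 3D NRRD, got dimension {dim}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path}: only little-endian NRRD is supported")
    enc = fields.get("encoding", "raw")
    payload = blob[header_end:]
    if enc in ("gzip", "gz"):
        payload = _gzip.decompress(payload)
    elif enc != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {enc!r}")
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    if arr.size != int(np.prod(sizes)):
        raise ValueError(f"{path}: payload size {arr.size} != product of sizes {sizes}")
    # NRRD lists sizes fastest-first; use Fortran order so axis k of the
    # array matches the k-th entry of `sizes`.
    return arr.reshape(sizes, order="F").copy()


def _write_nrrd(path: Path, data: np.ndarray) -> None:
    dt = np.dtype(data.dtype).newbyteorder("<")
    name = _NRRD_NAMES.get(np.dtype(data.dtype.base).newbyteorder("="))
    if name is None:
        raise ValueError(f"cannot write dtype {data.dtype} to NRRD")
    header = (
        "NRRD0004\n"
        f"type: {name}\n"
        "dimension: 3\n"
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        "endian: little\n"
        "encoding: gzip\n"
        "\n"
    )
    payload = _gzip.compress(np.asfortranarray(data.astype(dt)).tobytes(order="F"), 6)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("nrrd", "nifti"):
            raise ValueError(f"unknown volume format {fmt!r}")
        return f
    name = path.name.lower()
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def read_volume(
    path,
    format: str | None = None,
    *,
    voxel_size_um: float = 100.0,
    lr_axis: int = 2,
    left_is_low: bool = True,
    kind: str = "gene_energy",
):
    """Read a 3D volume; integer data yields a :class:`LabeledVolume`,
    floating-point data a :class:`ScalarVolume`.

    The left–right axis and handedness are caller declarations (they are
    not trusted from headers); ``kind`` applies only to scalar data.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "nrrd":
        data = _read_nrrd(path)
    else:
        import nibabel as nib

        img = nib.load(str(path))
        if img.ndim != 3:
            raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
        data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        return LabeledVolume(data, voxel_size_um, lr_axis, left_is_low)
    return ScalarVolume(data, voxel_size_um, lr_axis, left_is_low, kind)


def write_volume(vol, path, format: str | None = None) -> None:
    """Write a volume to NRRD or NIfTI; integer labels round-trip exactly."""
    path = Path(path)
    fmt = _detect_format(path, format)
    data = vol.data
    if isinstance(vol, LabeledVolume):
        # store with the narrowest standard integer type that fits
        hi = int(data.max()) if data.size else 0
        for cand in (np.uint8, np.uint16, np.uint32, np.uint64):
            if hi <= np.iinfo(cand).max:
                data = data.astype(cand)
                break
    if fmt == "nrrd":
        _write_nrrd(path, data)
    else:
        import nibabel as nib

        affine = np.diag([vol.voxel_size_um / 1000.0] * 3 + [1.0])
        img = nib.Nifti1Image(data, affine)
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# label bookkeeping
# ---------------------------------------------------------------------------

def label_sizes(vol: LabeledVolume) -> dict[int, int]:
    """Voxel count per nonzero label; the background label 0 is excluded."""
    ids, counts = np.unique(vol.data, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}


def remap_labels(
    vol: LabeledVolume, mapping: dict[int, int], pass_through: bool = True
) -> LabeledVolume:
    """Relabel voxels according to ``mapping`` (old id → new id).

    Label 0 is never remapped and may not be a target.  With
    ``pass_through=False`` every nonzero label present in the volume must
    be covered by the mapping.
    """
    for old, new in mapping.items():
        if old == 0:
            raise ValueError("label 0 (background) cannot be remapped")
        if new == 0:
            raise ValueError(f"mapping {old}→0 would delete voxels; 0 is reserved")
        if new < 0 or old < 0:
            raise ValueError("labels must be positive")
    uniq, inverse = np.unique(vol.data, return_inverse=True)
    if not pass_through:
        missing = [int(u) for u in uniq if u != 0 and int(u) not in mapping]
        if missing:
            raise ConsistencyError(f"labels without a mapping entry: {missing}")
    lut = np.array([mapping.get(int(u), int(u)) for u in uniq], dtype=np.int64)
    return vol.with_data(lut[inverse].reshape(vol.data.shape))


def hemisphere_masks(vol) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (left, right) masks partitioning the grid along ``lr_axis``.

    For an odd extent the midline slice is assigned to the left side (a
    documented convention; the choice only matters for midline voxels).
    """
    n = vol.data.shape[vol.lr_axis]
    idx = np.arange(n)
    if vol.left_is_low:
        left_1d = idx < (n + 1) // 2
    else:
        left_1d = idx >= n // 2
    shape = [1, 1, 1]
    shape[vol.lr_axis] = n
    left = np.broadcast_to(left_1d.reshape(shape), vol.data.shape).copy()
    return left, ~left


def mirror(vol):
    """Flip a volume along its left–right axis (an involution)."""
    return vol.with_data(np.flip(vol.data, axis=vol.lr_axis).copy())


def label_size_table(vol: LabeledVolume, onto=None):
    """Label-size table as a DataFrame (columns: id, acronym, voxels, nL)."""
    import pandas as pd

    sizes = label_sizes(vol)
    rows = []
    for i in sorted(sizes):
        acr = onto.nodes[i].acronym if (onto is not None and i in onto.nodes) else ""
        rows.append({"id": i, "acronym": acr, "voxels": sizes[i], "nL": sizes[i] * vol.voxel_nl})
    return pd.DataFrame(rows, columns=["id", "acronym", "voxels", "nL"])
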