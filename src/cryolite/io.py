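"""Reading and writing of MRC2014 maps/stacks and STAR metadata tables.

The MRC2014 format stores a 1024-byte binary header followed by the raw
voxel data in column/row/section order (fastest to slowest), which maps
onto numpy arrays indexed ``(z, y, x)`` for volumes and ``(n, y, x)`` for
image stacks.  Only mode 2 (float32) is written; modes 0, 1, 2 and 6 are
accepted on read.  STAR tables are parsed into :class:`pandas.DataFrame`
objects wrapped in :class:`MetaTable`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MapVolume",
    "ImageStack",
    "MetaTable",
    "FormatError",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
    "read_config",
    "write_config",
    "star_to_index",
    "index_to_star",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk data."""


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------


@dataclass
class MapVolume:
    """A 3D density map.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Real-valued density, dimensionless.
    voxel_size : float
        Angstrom per voxel (isotropic).
    origin : ndarray, shape (3,)
        Map origin in Angstrom, ``(x, y, z)`` order.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"MapVolume needs 3D data, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MapVolume data contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def is_cubic(self) -> bool:
        nz, ny, nx = self.data.shape
        return nz == ny == nx

    def require_cubic(self) -> None:
        if not self.is_cubic:
            raise ValueError(f"expected a cubic map, got shape {self.data.shape}")


@dataclass
class ImageStack:
    """A stack of N square 2D images sharing one pixel size."""

    data: np.ndarray
    pixel_size: float = 1.0
    ids: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("ImageStack needs data of shape (N, H, W), N >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.ids is None:
            self.ids = list(range(self.data.shape[0]))

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class MetaTable:
    """A named STAR table: one row per particle/coordinate, named columns."""

    df: pd.DataFrame
    name: str = "particles"

    def __len__(self) -> int:
        return len(self.df)

    def require_columns(self, columns) -> None:
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise ValueError(f"table '{self.name}' is missing columns {missing}")


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

HEADER_SIZE = 1024

_HEADER_DTYPE = np.dtype(
    [
        ("nx", "<i4"), ("ny", "<i4"), ("nz", "<i4"),
        ("mode", "<i4"),
        ("nxstart", "<i4"), ("nystart", "<i4"), ("nzstart", "<i4"),
        ("mx", "<i4"), ("my", "<i4"), ("mz", "<i4"),
        ("cella", "<f4", 3),
        ("cellb", "<f4", 3),
        ("mapc", "<i4"), ("mapr", "<i4"), ("maps", "<i4"),
        ("dmin", "<f4"), ("dmax", "<f4"), ("dmean", "<f4"),
        ("ispg", "<i4"),
        ("nsymbt", "<i4"),
        ("extra", "V100"),
        ("origin", "<f4", 3),
        ("map", "S4"),
        ("machst", "V4"),
        ("rms", "<f4"),
        ("nlabl", "<i4"),
        ("label", "V800"),
    ]
)
assert _HEADER_DTYPE.itemsize == HEADER_SIZE

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_header(raw: bytes):
    if len(raw) < HEADER_SIZE:
        raise FormatError("file too short for an MRC header")
    hdr = np.frombuffer(raw[:HEADER_SIZE], dtype=_HEADER_DTYPE)[0]
    if hdr["map"] not in (b"MAP ", b"MAP\x00"):
        raise FormatError("missing 'MAP ' signature; not an MRC2014 file")
    if min(hdr["nx"], hdr["ny"], hdr["nz"]) <= 0:
        raise FormatError("non-positive dimensions in MRC header")
    mode = int(hdr["mode"])
    if mode not in _MODE_DTYPES:
        raise FormatError(f"unsupported MRC mode {mode} (accepted: 0, 1, 2, 6)")
    return hdr


def read_mrc(path) -> "MapVolume | ImageStack":
    """Read an MRC/MRCS file into a :class:`MapVolume` or :class:`ImageStack`.

    ``.mrcs`` files and single-section images are returned as stacks;
    everything else is treated as a volume.  The voxel size is derived from
    the header cell dimensions.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    hdr = _read_header(raw)
    nx, ny, nz = int(hdr["nx"]), int(hdr["ny"]), int(hdr["nz"])
    nsymbt = int(hdr["nsymbt"])
    dtype = _MODE_DTYPES[int(hdr["mode"])]
    start = HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw[start:], dtype=dtype, count=count)
    if data.size != count:
        raise FormatError("file truncated: data block shorter than header promises")
    data = data.reshape(nz, ny, nx).astype(np.float32)

    mx = int(hdr["mx"]) or nx
    voxel = float(hdr["cella"][0]) / mx if hdr["cella"][0] > 0 else 1.0

    is_stack = str(path).endswith(".mrcs") or (int(hdr["ispg"]) == 0 and nz != ny)
    if is_stack or nz == 1:
        return ImageStack(data=data, pixel_size=voxel)
    return MapVolume(data=data, voxel_size=voxel, origin=np.array(hdr["origin"], float))


def write_mrc(obj, path) -> None:
    """Write a :class:`MapVolume` or :class:`ImageStack` as MRC2014 mode 2."""
    if isinstance(obj, MapVolume):
        data, voxel, origin, ispg = obj.data, obj.voxel_size, obj.origin, 1
    elif isinstance(obj, ImageStack):
        data, voxel, origin, ispg = obj.data, obj.pixel_size, np.zeros(3), 0
    else:  # raw array convenience
        data, voxel, origin, ispg = np.asarray(obj), 1.0, np.zeros(3), 0
        if data.ndim == 2:
            data = data[None]
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite data")
    if data.ndim != 3 or min(data.shape) <= 0:
        raise ValueError(f"need positive 3D data shape, got {data.shape}")
    data = np.ascontiguousarray(data, dtype=np.float32)
    nz, ny, nx = data.shape

    hdr = np.zeros(1, dtype=_HEADER_DTYPE)[0]
    hdr["nx"], hdr["ny"], hdr["nz"] = nx, ny, nz
    hdr["mode"] = 2
    hdr["mx"], hdr["my"], hdr["mz"] = nx, ny, nz
    hdr["cella"] = np.array([nx, ny, nz], float) * voxel
    hdr["cellb"] = (90.0, 90.0, 90.0)
    hdr["mapc"], hdr["mapr"], hdr["maps"] = 1, 2, 3
    hdr["dmin"], hdr["dmax"], hdr["dmean"] = (
        float(data.min()), float(data.max()), float(data.mean()))
    hdr["ispg"] = ispg
    hdr["origin"] = np.asarray(origin, dtype=np.float32)
    hdr["map"] = b"MAP "
    hdr["machst"] = np.void(bytes([0x44, 0x44, 0x00, 0x00]))
    hdr["rms"] = float(data.std())
    hdr["nlabl"] = 0
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------


def read_star(path) -> MetaTable:
    """Parse the first ``loop_`` block of a STAR file into a :class:`MetaTable`.

    Column labels keep their ``_rln`` prefixes stripped of the leading
    underscore-free index; numeric columns are converted to numbers, other
    columns stay as strings.  A duplicated column label is a format error.
    """
    name = "data"
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                if columns:
                    break  # only the first block
                name = line[len("data_"):] or "data"
                continue
            if line == "loop_":
                in_loop = True
                columns, rows = [], []
                continue
            if in_loop and line.startswith("_"):
                label = line.split()[0].lstrip("_")
                if label in columns:
                    raise FormatError(f"duplicated STAR column label '{label}'")
                columns.append(label)
                continue
            if in_loop and columns:
                values = line.split()
                if len(values) != len(columns):
                    raise FormatError(
                        f"row has {len(values)} fields, expected {len(columns)}")
                rows.append(values)
    if not columns:
        raise FormatError(f"no loop_ block found in {path}")
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return MetaTable(df=df, name=name)


def write_star(table: MetaTable | pd.DataFrame, path) -> None:
    """Write a table as a single-block STAR file with a ``loop_`` section."""
    if isinstance(table, pd.DataFrame):
        table = MetaTable(df=table)
    df = table.df
    lines = [f"data_{table.name}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in df.iterrows():
        fields = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                fields.append(f"{v:.6f}")
            else:
                fields.append(str(v))
        lines.append(" ".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Parse a plain-text ``key = value`` job-parameter file.

    Blank lines and ``#`` comments are ignored; values are converted to
    int/float where possible, otherwise kept as strings.
    """
    params: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            value = value.strip()
            for cast in (int, float):
                try:
                    value = cast(value)
                    break
                except ValueError:
                    continue
            params[key.strip()] = value
    return params


def write_config(params: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v}\n")


def star_to_index(coord):
    """1-based STAR pixel-center coordinates -> 0-based array indices."""
    return np.asarray(coord, dtype=float) - 1.0


def index_to_star(index):
    """0-based array indices -> 1-based STAR pixel-center coordinates."""
    return np.asarray(index, dtype=float) + 1.0
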