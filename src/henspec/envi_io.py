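"""ENVI-style hyperspectral cube I/O.

Hyperspectral imagers conventionally serialize a data cube (Y lines ×
X samples × L bands) as a raw binary file accompanied by a small text
header. The binary file stores the scalars in one of three interleave
orders:

- **BIL** (band interleaved by line): ``[line][band][sample]``
- **BIP** (band interleaved by pixel): ``[line][sample][band]``
- **BSQ** (band sequential): ``[band][line][sample]``

This module parses the de-facto ENVI header dialect (``samples``,
``lines``, ``bands``, ``interleave``, ``data type``, ``byte order``,
``wavelength``), decodes any of the three interleaves into an in-memory
:class:`HyperCube` indexed ``[y][x][l]``, and writes cubes back out.
Plain two-column (wavelength, reflectance) text spectra are also
supported, since single comb spectra travel through the pipeline as
delimited text.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Optional, Union

import numpy as np

__all__ = [
    "EnviHeader",
    "HyperCube",
    "HeaderFormatError",
    "UnsupportedDialectError",
    "TruncationError",
    "parse_header",
    "format_header",
    "read_cube",
    "write_cube",
    "load_cube",
    "save_cube",
    "read_spectrum_text",
    "write_spectrum_text",
]


class HeaderFormatError(ValueError):
    """A required header key is missing or malformed."""


class UnsupportedDialectError(ValueError):
    """Interleave or scalar encoding outside the supported set."""


class TruncationError(ValueError):
    """Binary stream length disagrees with the header geometry."""


INTERLEAVES = ("bil", "bip", "bsq")

# ENVI numeric "data type" codes for the scalar encodings we support.
DATA_TYPE_CODES = {
    1: np.dtype("u1"),
    2: np.dtype("i2"),
    3: np.dtype("i4"),
    4: np.dtype("f4"),
    5: np.dtype("f8"),
    12: np.dtype("u2"),
}
_DTYPE_TO_CODE = {v: k for k, v in DATA_TYPE_CODES.items()}


@dataclass
class EnviHeader:
    """Validated cube geometry and encoding metadata.

    Attributes
    ----------
    samples, lines, bands
        Spatial width X, spatial height Y, and spectral depth L.
    interleave
        One of ``bil``, ``bip``, ``bsq``.
    data_type
        ENVI numeric scalar-encoding code (see :data:`DATA_TYPE_CODES`).
    byte_order
        0 = little-endian (default, the dominant instrument convention),
        1 = big-endian.
    wavelengths
        Optional per-band center wavelengths in nanometres, strictly
        increasing, length ``bands``.
    """

    samples: int
    lines: int
    bands: int
    interleave: str = "bil"
    data_type: int = 4
    byte_order: int = 0
    wavelengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("samples", "lines", "bands"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise HeaderFormatError(f"{name} must be a positive integer, got {v!r}")
        self.interleave = str(self.interleave).lower()
        if self.interleave not in INTERLEAVES:
            raise UnsupportedDialectError(
                f"interleave must be one of {INTERLEAVES}, got {self.interleave!r}"
            )
        if self.data_type not in DATA_TYPE_CODES:
            raise UnsupportedDialectError(
                f"data type code {self.data_type} unsupported "
                f"(supported: {sorted(DATA_TYPE_CODES)})"
            )
        if self.byte_order not in (0, 1):
            raise HeaderFormatError(f"byte order must be 0 or 1, got {self.byte_order!r}")
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.shape != (self.bands,):
                raise HeaderFormatError(
                    f"wavelength list has {wl.size} entries, expected bands={self.bands}"
                )
            if not np.all(np.diff(wl) > 0):
                raise HeaderFormatError("wavelengths must be strictly increasing")
            self.wavelengths = wl

    @property
    def dtype(self) -> np.dtype:
        dt = DATA_TYPE_CODES[self.data_type]
        return dt.newbyteorder("<" if self.byte_order == 0 else ">")

    @property
    def nbytes(self) -> int:
        return self.samples * self.lines * self.bands * self.dtype.itemsize


@dataclass
class HyperCube:
    """In-memory reflectance cube, ``values[y][x][l]`` plus a wavelength axis."""

    values: np.ndarray
    wavelengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D (Y, X, L), got shape {self.values.shape}")
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.shape != (self.values.shape[2],):
                raise ValueError(
                    f"wavelength axis length {wl.size} != bands {self.values.shape[2]}"
                )
            if not np.all(np.diff(wl) > 0):
                raise ValueError("wavelengths must be strictly increasing")
            self.wavelengths = wl

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (Y, X, L)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type")


def _tokenize_header(text: str) -> dict[str, str]:
    """Split ENVI header text into a key -> raw-value map.

    Values in ``{ ... }`` braces may span lines; unknown keys are kept
    (and ignored downstream), comment lines starting with ``;`` dropped.
    """
    body = re.sub(r"^\s*ENVI\s*", "", text, count=1)
    fields: dict[str, str] = {}
    # Collapse brace blocks onto one logical line.
    pattern = re.compile(r"^\s*([^=\n;]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def parse_header(text: str) -> EnviHeader:
    """Parse ENVI header text into a validated :class:`EnviHeader`.

    Raises
    ------
    HeaderFormatError
        If a required key (samples, lines, bands, interleave, data type)
        is missing or a value cannot be parsed.
    UnsupportedDialectError
        If the interleave or data-type code is outside the supported set.
    """
    fields = _tokenize_header(text)
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise HeaderFormatError(f"header missing required key {key!r}")

    def _int(key: str) -> int:
        try:
            return int(fields[key])
        except ValueError as exc:
            raise HeaderFormatError(f"header key {key!r} is not an integer: {fields[key]!r}") from exc

    wavelengths = None
    if "wavelength" in fields:
        raw = fields["wavelength"].strip("{} \n")
        if raw:
            try:
                wavelengths = np.array(
                    [float(tok) for tok in re.split(r"[,\s]+", raw) if tok], dtype=float
                )
            except ValueError as exc:
                raise HeaderFormatError("wavelength list contains non-numeric entries") from exc

    return EnviHeader(
        samples=_int("samples"),
        lines=_int("lines"),
        bands=_int("bands"),
        interleave=fields["interleave"].strip().lower(),
        data_type=_int("data type"),
        byte_order=_int("byte order") if "byte order" in fields else 0,
        wavelengths=wavelengths,
    )


def format_header(header: EnviHeader) -> str:
    """Render a header back to ENVI text (inverse of :func:`parse_header`)."""
    lines = [
        "ENVI",
        f"samples = {header.samples}",
        f"lines = {header.lines}",
        f"bands = {header.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {header.data_type}",
        f"interleave = {header.interleave}",
        f"byte order = {header.byte_order}",
    ]
    if header.wavelengths is not None:
        wl = ", ".join(f"{w:.12g}" for w in header.wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{ {wl} }}")
    return "\n".join(lines) + "\n"


# Axis order of the serialized stream for each interleave, in terms of
# the in-memory (line y, sample x, band l) = axes (0, 1, 2).
_INTERLEAVE_AXES = {
    "bil": (0, 2, 1),  # [line][band][sample]
    "bip": (0, 1, 2),  # [line][sample][band]
    "bsq": (2, 0, 1),  # [band][line][sample]
}


def read_cube(data: Union[bytes, BinaryIO], header: EnviHeader) -> HyperCube:
    """De-interleave a raw binary stream into a :class:`HyperCube`.

    Raises
    ------
    TruncationError
        If the stream byte count disagrees with the header geometry.
    """
    if not isinstance(data, (bytes, bytearray)):
        data = data.read()
    expected = header.nbytes
    if len(data) != expected:
        raise TruncationError(
            f"cube stream has {len(data)} bytes, header implies {expected} "
            f"({header.lines}x{header.samples}x{header.bands} @ {header.dtype.itemsize} B)"
        )
    flat = np.frombuffer(data, dtype=header.dtype)
    axes = _INTERLEAVE_AXES[header.interleave]
    dims = {0: header.lines, 1: header.samples, 2: header.bands}
    arr = flat.reshape(tuple(dims[a] for a in axes))
    # Invert the axis permutation back to (y, x, l).
    inv = np.argsort(axes)
    values = np.ascontiguousarray(arr.transpose(inv))
    return HyperCube(values=values, wavelengths=header.wavelengths)


def write_cube(
    cube: HyperCube,
    interleave: str = "bil",
    data_type: Optional[int] = None,
    byte_order: int = 0,
) -> tuple[bytes, EnviHeader]:
    """Serialize a cube to a raw binary stream plus its matching header.

    ``data_type`` defaults to the ENVI code matching the array dtype, or
    32-bit float when the dtype has no ENVI code (e.g. float64 promoted
    arithmetic results are kept as code 5).
    """
    interleave = str(interleave).lower()
    if interleave not in INTERLEAVES:
        raise UnsupportedDialectError(
            f"interleave must be one of {INTERLEAVES}, got {interleave!r}"
        )
    native = cube.values.dtype.newbyteorder("=")
    if data_type is None:
        data_type = _DTYPE_TO_CODE.get(np.dtype(native.str.lstrip("<>=|")), 4)
    header = EnviHeader(
        samples=cube.n_samples,
        lines=cube.n_lines,
        bands=cube.n_bands,
        interleave=interleave,
        data_type=data_type,
        byte_order=byte_order,
        wavelengths=cube.wavelengths,
    )
    axes = _INTERLEAVE_AXES[interleave]
    stream = np.ascontiguousarray(
        cube.values.transpose(axes).astype(header.dtype)
    ).tobytes()
    return stream, header


def load_cube(data_path: Union[str, Path], header_path: Union[str, Path, None] = None) -> HyperCube:
    """Read a cube from ``<name>`` + ``<name>.hdr`` on disk."""
    data_path = Path(data_path)
    if header_path is None:
        header_path = data_path.with_suffix(data_path.suffix + ".hdr")
    header = parse_header(Path(header_path).read_text())
    return read_cube(data_path.read_bytes(), header)


def save_cube(
    cube: HyperCube,
    data_path: Union[str, Path],
    interleave: str = "bil",
    data_type: Optional[int] = None,
) -> Path:
    """Write ``<name>`` + ``<name>.hdr``; returns the header path."""
    data_path = Path(data_path)
    stream, header = write_cube(cube, interleave=interleave, data_type=data_type)
    data_path.write_bytes(stream)
    header_path = data_path.with_suffix(data_path.suffix + ".hdr")
    header_path.write_text(format_header(header))
    return header_path


def read_spectrum_text(path_or_buf) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength_nm, reflectance) delimited text file."""
    if isinstance(path_or_buf, (str, Path)):
        raw = Path(path_or_buf).read_text()
    else:
        raw = path_or_buf.read()
    try:
        arr = np.loadtxt(io.StringIO(raw), comments="#", delimiter=None, ndmin=2)
    except ValueError:
        # Tolerate a single column-name header row.
        arr = np.loadtxt(io.StringIO(raw), comments="#", delimiter=None, ndmin=2, skiprows=1)
    if arr.shape[1] < 2:
        raise ValueError("spectrum file must have wavelength and reflectance columns")
    return arr[:, 0], arr[:, 1]


def write_spectrum_text(path, wavelengths: np.ndarray, reflectance: np.ndarray) -> None:
    """Write a two-column (wavelength_nm, reflectance) tab-delimited file."""
    wl = np.asarray(wavelengths, float)
    rf = np.asarray(reflectance, float)
    if wl.shape != rf.shape:
        raise ValueError("wavelength and reflectance lengths differ")
    header = "wavelength_nm\treflectance"
    np.savetxt(path, np.column_stack([wl, rf]), delimiter="\t", header=header, comments="")
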