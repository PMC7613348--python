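"""ENVI raster reader/writer (header text file + flat binary payload).

Supported dialect
-----------------
* read: data types 4 (float32) and 5 (float64); interleaves bsq, bil, bip;
  byte order 0 (little-endian) or 1 (big-endian);
* write: always float32, bsq, byte order 0, wavelengths at 4+ decimals.

The header is the ``<stem>.hdr`` file; the payload lives next to it as
``<stem>.dat`` (``.img``, ``.bin`` and a bare ``<stem>`` are also accepted on
read). Parsing is tolerant of ``\\r\\n`` line endings and of ``key = {...}``
blocks spanning several lines.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .datamodel import BandGrid, RadianceCube, SIFCube
from .errors import ConsistencyError, FormatError, UnsupportedDialectError

_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}

_MANDATORY = ("samples", "lines", "bands", "data type", "interleave", "byte order")


def _parse_header(text: str) -> dict:
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # fold {...} blocks onto one line so a simple key = value scan works
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.split("\n"):
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_list(value: str) -> list[str]:
    value = value.strip()
    if not (value.startswith("{") and value.endswith("}")):
        raise FormatError(f"expected a {{...}} block, got: {value[:40]!r}")
    return [v.strip() for v in value[1:-1].split(",") if v.strip()]


def _payload_path(header_path: Path) -> Path:
    stem = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    for cand in (stem.with_suffix(".dat"), stem.with_suffix(".img"),
                 stem.with_suffix(".bin"), stem):
        if cand.exists() and cand != header_path:
            return cand
    raise FormatError(f"no binary payload found next to header {header_path}")


def read_envi_cube(header_path: str | os.PathLike) -> RadianceCube:
    """Read an ENVI cube; values come back as [rows, cols, bands] float32/64."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for key in _MANDATORY:
        if key not in fields:
            raise FormatError(f"ENVI header missing mandatory key '{key}'")
    samples = int(fields["samples"])  # cols
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _DTYPES:
        raise UnsupportedDialectError(f"unsupported ENVI data type {dtype_code}")
    dtype = _DTYPES[dtype_code]
    if int(fields["byte order"]) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise UnsupportedDialectError(f"unsupported interleave '{interleave}'")
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing mandatory key 'wavelength'")
    wavelengths = [float(w) for w in _parse_list(fields["wavelength"])]
    if len(wavelengths) != bands:
        raise ConsistencyError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    raw = np.fromfile(_payload_path(header_path), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ConsistencyError(
            f"payload holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(lines, samples, bands)

    grid = BandGrid(np.asarray(wavelengths))
    metadata = {k: v for k, v in fields.items() if k not in _MANDATORY}
    return RadianceCube(np.ascontiguousarray(values), grid, metadata=metadata)


def write_envi_cube(cube: RadianceCube | SIFCube, path: str | os.PathLike,
                    description: str = "") -> None:
    """Write ``<path>.hdr`` + ``<path>.dat`` (float32, BSQ, little-endian).

    ``path`` may end in ``.hdr`` or ``.dat``; the pair is derived either way.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".hdr", ".dat") else path
    hdr, dat = stem.with_suffix(".hdr"), stem.with_suffix(".dat")
    rows, cols, bands = cube.values.shape
    wl_block = ",\n ".join(f"{w:.4f}" for w in cube.grid.wavelengths)
    desc = description or getattr(cube, "metadata", {}).get("description", "") or "sifemu cube"
    header = (
        "ENVI\n"
        f"description = {{{desc}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl_block}}}\n"
    )
    hdr.write_text(header)
    payload = np.ascontiguousarray(
        cube.values.transpose(2, 0, 1), dtype=np.dtype("<f4")
    )
    payload.tofile(dat)
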