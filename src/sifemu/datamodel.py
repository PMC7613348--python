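"""Core spectral containers.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, row-major; in ENVI terms
  ``lines`` = rows and ``samples`` = cols;
* image cubes are ``[rows, cols, bands]``;
* sample matrices are ``[n_samples, bands]``;
* radiance and SIF are in mW m-2 sr-1 nm-1;
* class label -1 means "unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError, ShapeError


@dataclass(frozen=True)
class BandGrid:
    """An ordered set of band-center wavelengths in nanometres."""

    wavelengths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise ArgumentError("band grid needs a 1-D, non-empty wavelength list")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ArgumentError("wavelengths must be finite and positive")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ArgumentError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def index_nearest(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm``; ties go to the lower band."""
        d = np.abs(self.wavelengths - float(wavelength_nm))
        # argmin returns the first (lowest-wavelength) index on ties
        return int(np.argmin(d))


def _check_cube(values: np.ndarray, grid: BandGrid) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ShapeError(f"cube must be 3-D [rows, cols, bands], got shape {values.shape}")
    if values.shape[2] != len(grid):
        raise ConsistencyError(
            f"cube has {values.shape[2]} bands but grid has {len(grid)}"
        )
    if not np.all(np.isfinite(values)):
        raise ArgumentError("cube values must be finite")
    return values


@dataclass
class RadianceCube:
    """At-sensor radiance image, [rows, cols, bands]."""

    values: np.ndarray
    grid: BandGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _check_cube(self.values, self.grid)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


@dataclass
class SIFCube:
    """Sun-induced fluorescence image, [rows, cols, bands]; negatives permitted."""

    values: np.ndarray
    grid: BandGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _check_cube(self.values, self.grid)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectralMatrix:
    """A stack of spectra, [n_samples, bands], on a common grid."""

    values: np.ndarray
    grid: BandGrid

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ShapeError("spectral matrix must be 2-D")
        if self.values.shape[1] != len(self.grid):
            raise ShapeError(
                f"matrix has {self.values.shape[1]} columns but grid has {len(self.grid)} bands"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SampleTable:
    """Paired radiance / reference-SIF samples with pixel provenance.

    ``scene``, ``row``, ``col`` and ``label`` are parallel 1-D arrays; ``X``
    holds the input (radiance) spectra and ``Y`` the output (SIF) spectra.
    Label -1 marks unclassified pixels.
    """

    scene: np.ndarray
    row: np.ndarray
    col: np.ndarray
    label: np.ndarray
    X: SpectralMatrix
    Y: SpectralMatrix

    def __post_init__(self) -> None:
        self.scene = np.asarray(self.scene, dtype=object)
        self.row = np.asarray(self.row, dtype=int)
        self.col = np.asarray(self.col, dtype=int)
        self.label = np.asarray(self.label, dtype=int)
        n = self.scene.size
        for name in ("row", "col", "label"):
            if getattr(self, name).size != n:
                raise ShapeError(f"column '{name}' has wrong length")
        if self.X.n != n or self.Y.n != n:
            raise ShapeError("spectra row counts do not match provenance columns")
        key = pd.MultiIndex.from_arrays([self.scene, self.row, self.col])
        if key.duplicated().any():
            raise ConsistencyError("duplicate (scene, row, col) records in sample table")

    def __len__(self) -> int:
        return int(self.scene.size)

    def take(self, indices) -> "SampleTable":
        """Row subset preserving order."""
        idx = np.asarray(indices, dtype=int)
        return SampleTable(
            scene=self.scene[idx],
            row=self.row[idx],
            col=self.col[idx],
            label=self.label[idx],
            X=SpectralMatrix(self.X.values[idx], self.X.grid),
            Y=SpectralMatrix(self.Y.values[idx], self.Y.grid),
        )


def extract_pixels(cube: RadianceCube | SIFCube, coords) -> SpectralMatrix:
    """Spectra at a list of ``(row, col)`` coordinates, order preserved."""
    coords = list(coords)
    if not coords:
        raise ArgumentError("no coordinates given")
    rows = np.asarray([c[0] for c in coords], dtype=int)
    cols = np.asarray([c[1] for c in coords], dtype=int)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= cube.values.shape[0]
        or cols.max() >= cube.values.shape[1]
    ):
        raise IndexError("pixel coordinate outside the cube")
    return SpectralMatrix(np.asarray(cube.values[rows, cols, :], dtype=float), cube.grid)
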