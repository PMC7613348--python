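"""Goodness-of-fit statistics for emulated vs. reference SIF.

NRMSE is the RMSE divided by one global normalization constant — the max
minus min over *all* entries of the reference matrix — expressed in percent.
The per-band NRMSE_lambda reuses that same denominator, so a spectrally flat
error gives a flat NRMSE curve. R-squared is the coefficient-of-determination
form ``1 - SS_res / SS_tot`` (it can go negative). Signed errors are always
``emulated - reference``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .datamodel import SIFCube, SpectralMatrix
from .errors import ArgumentError, ShapeError

SIF_UNITS = "mW m-2 sr-1 nm-1"
_REPORT_BAND_NM = 760.0


@dataclass
class EvaluationReport:
    n: int
    rmse_per_band: list[float]
    nrmse_per_band_pct: list[float]
    rmse: float
    nrmse_pct: float
    r2: float
    r2_at_760nm: float
    f_max: float
    f_min: float
    units: str = SIF_UNITS

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class ErrorSummary:
    median: float
    p25: float
    p75: float
    p02: float
    p98: float


def _paired(ref, est) -> tuple[np.ndarray, np.ndarray]:
    r = ref.values if isinstance(ref, SpectralMatrix) else np.atleast_2d(np.asarray(ref, float))
    e = est.values if isinstance(est, SpectralMatrix) else np.atleast_2d(np.asarray(est, float))
    if r.shape != e.shape:
        raise ShapeError(f"shapes differ: {r.shape} vs {e.shape}")
    if isinstance(ref, SpectralMatrix) and isinstance(est, SpectralMatrix):
        if ref.grid != est.grid:
            raise ShapeError("reference and estimate are on different band grids")
    return np.asarray(r, float), np.asarray(e, float)


def rmse_per_band(ref, est) -> np.ndarray:
    """Per-wavelength root-mean-square error over samples."""
    r, e = _paired(ref, est)
    return np.sqrt(np.mean((e - r) ** 2, axis=0))


def nrmse(ref, est) -> tuple[float, np.ndarray]:
    """(overall NRMSE %, per-band NRMSE %), normalized by the global
    max - min of the reference matrix."""
    r, e = _paired(ref, est)
    f_max, f_min = float(r.max()), float(r.min())
    if f_max <= f_min:
        raise ArgumentError("reference range is zero; NRMSE undefined")
    span = f_max - f_min
    overall = 100.0 * float(np.sqrt(np.mean((e - r) ** 2))) / span
    per_band = 100.0 * rmse_per_band(r, e) / span
    return overall, per_band


def r_squared(ref: np.ndarray, est: np.ndarray) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    r = np.asarray(ref, dtype=float).ravel()
    e = np.asarray(est, dtype=float).ravel()
    if r.size != e.size:
        raise ShapeError("length mismatch")
    if r.size < 2:
        raise ArgumentError("need at least 2 values")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0:
        raise ArgumentError("constant reference; R^2 undefined")
    return 1.0 - float(np.sum((r - e) ** 2)) / ss_tot


def evaluate_pairs(ref: SpectralMatrix, est: SpectralMatrix) -> EvaluationReport:
    """Full report for a matched pair of spectral matrices."""
    r, e = _paired(ref, est)
    grid = ref.grid if isinstance(ref, SpectralMatrix) else None
    band_rmse = rmse_per_band(r, e)
    overall_nrmse, band_nrmse = nrmse(r, e)
    band_760 = grid.index_nearest(_REPORT_BAND_NM) if grid is not None else r.shape[1] // 2
    return EvaluationReport(
        n=int(r.shape[0]),
        rmse_per_band=[float(v) for v in band_rmse],
        nrmse_per_band_pct=[float(v) for v in band_nrmse],
        rmse=float(np.sqrt(np.mean((e - r) ** 2))),
        nrmse_pct=float(overall_nrmse),
        r2=r_squared(r, e),
        r2_at_760nm=r_squared(r[:, band_760], e[:, band_760]),
        f_max=float(r.max()),
        f_min=float(r.min()),
    )


def absolute_error_map(ref: SIFCube, est: SIFCube, band_nm: float) -> np.ndarray:
    """Signed ``emulated - reference`` map at the band nearest ``band_nm``."""
    if ref.grid != est.grid:
        raise ShapeError("cubes are on different band grids")
    if ref.values.shape != est.values.shape:
        raise ShapeError("cube shapes differ")
    wl = ref.grid.wavelengths
    if not (wl[0] <= band_nm <= wl[-1]):
        raise ArgumentError(f"band {band_nm} nm outside grid range "
                            f"[{wl[0]}, {wl[-1]}] nm")
    b = ref.grid.index_nearest(band_nm)
    return np.asarray(est.values[:, :, b], float) - np.asarray(ref.values[:, :, b], float)


def error_summary(error_map: np.ndarray) -> ErrorSummary:
    """Median, quartiles and 2/98 percentiles of a signed-error map."""
    p02, p25, med, p75, p98 = np.percentile(
        np.asarray(error_map, float).ravel(), [2, 25, 50, 75, 98],
        method="linear",
    )
    return ErrorSummary(median=float(med), p25=float(p25), p75=float(p75),
                        p02=float(p02), p98=float(p98))
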