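"""End-to-end spectrum-to-spectrum emulation.

Training compresses the radiance inputs and the SIF outputs with separate
PCAs (fit on the training split only), regresses output scores on input
scores, and scores the held-out split through the full
project -> predict -> reconstruct chain. The deployable artifact bundles
both PCA models and the regressor; applying it to an image cube is a
chunked pixel-wise run of the same chain.

Defaults follow the optimum of the sensitivity analysis: 20 input
components, 5 output components, 70/30 train/validation split.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import pca
from .datamodel import BandGrid, RadianceCube, SampleTable, SIFCube, SpectralMatrix
from .errors import (
    ArgumentError,
    IntegrityError,
    ShapeError,
    UnsupportedVersionError,
)
from .evaluation import EvaluationReport, evaluate_pairs
from .regressors import PerOutputLoop, RegressorSpec, get_regressor
from .sampling import split_train_val

FORMAT_VERSION = 1

# fixed pixel-block size used end to end so results never depend on how a
# caller chunks the cube (all BLAS calls see identical shapes)
_BLOCK = 256


@dataclass
class EmulatorConfig:
    p_in: int = 20
    p_out: int = 5
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_in < 1 or self.p_out < 1:
            raise ArgumentError("p_in and p_out must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ArgumentError("train_fraction must be in (0, 1)")


@dataclass
class EmulatorModel:
    input_pca: pca.PCAModel
    output_pca: pca.PCAModel
    regressor: object                      # registry adapter, fitted
    config: EmulatorConfig
    provenance: dict = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    @property
    def input_grid(self) -> BandGrid:
        return self.input_pca.grid

    @property
    def output_grid(self) -> BandGrid:
        return self.output_pca.grid


def train_emulator(samples: SampleTable, config: EmulatorConfig | None = None
                   ) -> tuple[EmulatorModel, EvaluationReport]:
    """Train on a 70/30 split of ``samples``; report scores the held-out 30%."""
    config = config or EmulatorConfig()
    n = len(samples)
    needed = max(config.p_in, config.p_out) + config.regressor.folds
    if n < needed:
        raise ArgumentError(f"need at least {needed} samples, got {n}")

    train_idx, val_idx = split_train_val(list(range(n)), config.train_fraction,
                                         seed=config.seed)
    train, val = samples.take(train_idx), samples.take(val_idx)

    for side, mat in (("input", train.X), ("output", train.Y)):
        if float(np.ptp(mat.values)) == 0.0:
            raise ArgumentError(f"zero-variance {side} spectra; nothing to learn")

    p_in = min(config.p_in, len(train.X.grid), len(train_idx) - 1)
    p_out = min(config.p_out, len(train.Y.grid), len(train_idx) - 1)
    input_pca = pca.fit_pca(train.X, p_in)
    output_pca = pca.fit_pca(train.Y, p_out)

    W_in = pca.project(input_pca, train.X).values
    W_out = pca.project(output_pca, train.Y).values

    reg = get_regressor(config.regressor)
    if not getattr(reg, "multi_output", True):
        reg = PerOutputLoop(config.regressor)  # single-output loop fallback
    reg.fit(W_in, W_out)

    model = EmulatorModel(
        input_pca=input_pca, output_pca=output_pca, regressor=reg, config=config,
        provenance={
            "n_samples": n,
            "n_train": len(train_idx),
            "scenes": sorted({str(s) for s in samples.scene}),
            "seed": config.seed,
        },
    )
    report = evaluate_pairs(val.Y, emulate_spectra(model, val.X))
    return model, report


def emulate_spectra(model: EmulatorModel, X: SpectralMatrix) -> SpectralMatrix:
    """Radiance spectra -> SIF spectra on the model's output grid."""
    if X.grid != model.input_grid:
        raise ShapeError("spectra are not on the model's input grid")
    values = X.values
    out = np.empty((values.shape[0], len(model.output_grid)))
    for start in range(0, values.shape[0], _BLOCK):
        block = values[start:start + _BLOCK]
        nb = block.shape[0]
        if nb < _BLOCK:  # pad so every matmul sees the same shape
            block = np.vstack([block, np.tile(block[-1:], (_BLOCK - nb, 1))])
        W_in = pca.project(model.input_pca, SpectralMatrix(block, X.grid)).values
        W_out = model.regressor.predict(W_in)
        out[start:start + nb] = pca.reconstruct(model.output_pca, W_out).values[:nb]
    return SpectralMatrix(out, model.output_grid)


def emulate_cube(model: EmulatorModel, cube: RadianceCube,
                 chunk_rows: int = 64) -> SIFCube:
    """Pixel-wise emulation of a whole cube, processed in row chunks.

    Chunk size trades memory for nothing else: results are identical for
    any ``chunk_rows``.
    """
    if cube.grid != model.input_grid:
        raise ShapeError("cube is not on the model's input grid")
    if chunk_rows < 1:
        raise ArgumentError("chunk_rows must be >= 1")
    rows, cols, _ = cube.values.shape
    b_out = len(model.output_grid)
    out = np.empty((rows, cols, b_out), dtype=np.float32)
    for r0 in range(0, rows, chunk_rows):
        r1 = min(r0 + chunk_rows, rows)
        flat = np.asarray(cube.values[r0:r1], dtype=float).reshape(-1, len(cube.grid))
        sif = emulate_spectra(model, SpectralMatrix(flat, cube.grid))
        out[r0:r1] = sif.values.reshape(r1 - r0, cols, b_out).astype(np.float32)
    return SIFCube(out, model.output_grid,
                   metadata={"description": "sifemu emulated SIF"})


def save_model(model: EmulatorModel, path: str | os.PathLike) -> None:
    """Write the emulator container: JSON metadata + named numeric arrays."""
    reg_arrays = model.regressor.to_arrays()
    meta = {
        "format_version": model.format_version,
        "config": {
            "p_in": model.config.p_in,
            "p_out": model.config.p_out,
            "train_fraction": model.config.train_fraction,
            "seed": model.config.seed,
            "regressor": {
                "method": model.config.regressor.method,
                "kernel": model.config.regressor.kernel,
                "lambda_grid": [float(v) for v in model.config.regressor.lambda_grid],
                "sigma_grid": (None if model.config.regressor.sigma_grid is None
                               else [float(v) for v in model.config.regressor.sigma_grid]),
                "sigma_multipliers": [float(v) for v in
                                      model.config.regressor.sigma_multipliers],
                "folds": model.config.regressor.folds,
                "seed": model.config.regressor.seed,
            },
        },
        "provenance": model.provenance,
        "regressor_container": ("loop" if isinstance(model.regressor, PerOutputLoop)
                                else "plain"),
        "input_grid_label": model.input_grid.label,
        "output_grid_label": model.output_grid.label,
        "regressor_arrays": sorted(reg_arrays),
    }
    arrays = {
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "in_mean": model.input_pca.mean, "in_U": model.input_pca.U,
        "in_eigenvalues": model.input_pca.eigenvalues,
        "in_total_variance": np.array(model.input_pca.total_variance),
        "in_wavelengths": model.input_pca.grid.wavelengths,
        "out_mean": model.output_pca.mean, "out_U": model.output_pca.U,
        "out_eigenvalues": model.output_pca.eigenvalues,
        "out_total_variance": np.array(model.output_pca.total_variance),
        "out_wavelengths": model.output_pca.grid.wavelengths,
    }
    for name, arr in reg_arrays.items():
        arrays[f"reg_{name}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | os.PathLike) -> EmulatorModel:
    path = Path(path)
    try:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise IntegrityError(f"cannot read emulator container {path}: {exc}") from exc
    try:
        meta = json.loads(bytes(arrays["meta_json"]).decode())
    except Exception as exc:
        raise IntegrityError(f"corrupted metadata block in {path}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"container format version {version!r}; this build reads {FORMAT_VERSION}"
        )
    cfg = meta["config"]
    spec = RegressorSpec(
        method=cfg["regressor"]["method"], kernel=cfg["regressor"]["kernel"],
        lambda_grid=tuple(cfg["regressor"]["lambda_grid"]),
        sigma_grid=(None if cfg["regressor"]["sigma_grid"] is None
                    else tuple(cfg["regressor"]["sigma_grid"])),
        sigma_multipliers=tuple(cfg["regressor"]["sigma_multipliers"]),
        folds=cfg["regressor"]["folds"], seed=cfg["regressor"]["seed"],
    )
    config = EmulatorConfig(p_in=cfg["p_in"], p_out=cfg["p_out"], regressor=spec,
                            train_fraction=cfg["train_fraction"], seed=cfg["seed"])
    try:
        input_pca = pca.PCAModel(
            mean=arrays["in_mean"], U=arrays["in_U"],
            eigenvalues=arrays["in_eigenvalues"],
            total_variance=float(arrays["in_total_variance"]),
            grid=BandGrid(arrays["in_wavelengths"], label=meta["input_grid_label"]),
        )
        output_pca = pca.PCAModel(
            mean=arrays["out_mean"], U=arrays["out_U"],
            eigenvalues=arrays["out_eigenvalues"],
            total_variance=float(arrays["out_total_variance"]),
            grid=BandGrid(arrays["out_wavelengths"], label=meta["output_grid_label"]),
        )
        reg_arrays = {name: arrays[f"reg_{name}"] for name in meta["regressor_arrays"]}
    except KeyError as exc:
        raise IntegrityError(f"missing array {exc} in {path}") from exc
    if meta.get("regressor_container") == "loop":
        reg = PerOutputLoop.from_arrays(reg_arrays, spec)
    else:
        reg = get_regressor(spec).__class__.from_arrays(reg_arrays, spec)
    return EmulatorModel(input_pca=input_pca, output_pca=output_pca, regressor=reg,
                         config=config, provenance=meta.get("provenance", {}),
                         format_version=version)
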