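"""Scaled synthetic sensitivity study of the emulator.

This module reruns, on generated scenes, the optimization experiments that
motivate the default settings: train at the optimal configuration (20 input
PCs, 5 output PCs, 3000 samples, absolute-per-class sampling over a k=40
segmentation), transfer the emulator to a second scene with a different
land-cover mix and a few-percent illumination shift, and sweep the training
sample size and the output PC count.

Two design choices keep the scaled-down curves interpretable:

* sweep points train on *nested* subsets of one random pixel pool and are
  all scored against one common held-out pixel set, so successive points
  differ by added information rather than by split noise;
* the (lambda, sigma) pair is tuned once, at the optimal configuration, and
  then held fixed across sweep points, isolating the swept variable.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import pca
from .datamodel import RadianceCube, SampleTable, SIFCube, SpectralMatrix, extract_pixels
from .emulator import EmulatorConfig, EmulatorModel, emulate_cube, emulate_spectra, train_emulator
from .evaluation import evaluate_pairs
from .regressors import KernelRidgeRegressor, RegressorSpec
from .sampling import SamplingPlan, build_training_set
from .synth import SceneConfig, simulate_scene

SAMPLE_SIZES = (200, 500, 1000, 1500, 2000, 3000, 5000, 7000)
P_OUT_RANGE = tuple(range(1, 11))

OPTIMAL_P_IN = 20
OPTIMAL_P_OUT = 5
OPTIMAL_N_SAMPLES = 3000
OPTIMAL_K_CLASSES = 40


def _seeded(seed: int, n: int) -> list[int]:
    """n sub-seeds (< 2^31) derived deterministically from one seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _flatten_cube(cube: RadianceCube | SIFCube) -> SpectralMatrix:
    v = np.asarray(cube.values, dtype=float)
    return SpectralMatrix(v.reshape(-1, v.shape[2]), cube.grid)


def _fit_fixed_emulator(table: SampleTable, p_in: int, p_out: int,
                        lam: float, sigma: float) -> EmulatorModel:
    """Emulator trained on *all* rows of ``table`` with fixed hyperparameters."""
    p_in = min(p_in, len(table.X.grid), len(table) - 1)
    p_out = min(p_out, len(table.Y.grid), len(table) - 1)
    input_pca = pca.fit_pca(table.X, p_in)
    output_pca = pca.fit_pca(table.Y, p_out)
    spec = RegressorSpec(lambda_grid=(lam,), sigma_grid=(sigma,))
    reg = KernelRidgeRegressor(spec).fit(
        pca.project(input_pca, table.X).values,
        pca.project(output_pca, table.Y).values,
    )
    return EmulatorModel(input_pca=input_pca, output_pca=output_pca, regressor=reg,
                         config=EmulatorConfig(p_in=p_in, p_out=p_out, regressor=spec),
                         provenance={"n_samples": len(table), "fixed_hyperparameters": True})


def _pixel_pools(rows: int, cols: int, n_pool: int, n_val: int, seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (training pool, validation) pixel index sets."""
    rng = np.random.default_rng(seed)
    flat = rng.choice(rows * cols, n_pool + n_val, replace=False)
    return flat[:n_pool], flat[n_pool:]


def _table_from_flat(cube: RadianceCube, ref: SIFCube, flat: np.ndarray,
                     scene_id: str) -> SampleTable:
    coords = list(map(tuple, np.column_stack(
        np.unravel_index(flat, (cube.rows, cube.cols)))))
    return SampleTable(
        scene=np.full(len(coords), scene_id, dtype=object),
        row=np.array([r for r, _ in coords]),
        col=np.array([c for _, c in coords]),
        label=np.full(len(coords), -1),
        X=extract_pixels(cube, coords),
        Y=extract_pixels(ref, coords),
    )


def noiseless_recovery_nrmse(seed: int = 0, rows: int = 100, cols: int = 100,
                             n_samples: int = 1000) -> float:
    """Held-out NRMSE (%) on a zero-noise scene with default emulator settings.

    With no sensor noise, no retrieval noise and a noiseless linear
    radiance-SIF link, the emulator should recover the reference SIF almost
    exactly; this is the end-to-end correctness check of the whole chain.
    """
    s_scene, s_plan, s_emu = _seeded(seed, 3)
    config = SceneConfig(rows=rows, cols=cols, radiance_noise_sd=0.0,
                         reference_sif_noise_sd=0.0, seed=s_scene)
    cube, truth = simulate_scene(config)
    plan = SamplingPlan(strategy="random", n_samples=n_samples, seed=s_plan)
    table = build_training_set([(cube, truth.reference_sif, "noiseless")], plan)
    emu_config = EmulatorConfig(seed=s_emu,
                                regressor=RegressorSpec(seed=s_emu))
    _, report = train_emulator(table, emu_config)
    return report.nrmse_pct


def run_full_study(seed: int = 0, rows: int = 300, cols: int = 300,
                   n_classes: int = 8) -> dict:
    """The full scaled study; returns a flat dict of results.

    Keys: held-out and transfer NRMSE/R2 for the optimally configured
    emulator, the absolute-vs-random strategy comparison on the transfer
    scene, the sample-size learning curve and the output-PC sweep.
    """
    (s_scene_a, s_scene_b, s_plan, s_emu, s_pool, s_rand) = _seeded(seed, 6)

    scene_cfg_a = SceneConfig(rows=rows, cols=cols, n_classes=n_classes, seed=s_scene_a)
    # transfer scene: different land-cover composition, illumination a few
    # percent off — the flight-line-to-flight-line situation
    scene_cfg_b = replace(scene_cfg_a, seed=s_scene_b, vegetation_fraction=0.5,
                          illumination_factor=1.04)
    cube_a, truth_a = simulate_scene(scene_cfg_a)
    cube_b, truth_b = simulate_scene(scene_cfg_b)
    ref_b_flat = _flatten_cube(truth_b.reference_sif)

    results: dict[str, float | dict] = {}

    # --- optimally configured emulator: absolute sampling, k = 40 ---
    plan_abs = SamplingPlan(strategy="absolute", n_samples=OPTIMAL_N_SAMPLES,
                            k=OPTIMAL_K_CLASSES, seed=s_plan)
    table_abs = build_training_set([(cube_a, truth_a.reference_sif, "A")], plan_abs)
    emu_config = EmulatorConfig(p_in=OPTIMAL_P_IN, p_out=OPTIMAL_P_OUT, seed=s_emu,
                                regressor=RegressorSpec(seed=s_emu))
    model, holdout = train_emulator(table_abs, emu_config)
    results["holdout_nrmse_pct"] = holdout.nrmse_pct
    results["holdout_r2_760"] = holdout.r2_at_760nm
    lam = model.regressor.model.lam
    sigma = model.regressor.model.sigma
    results["lambda"] = lam
    results["sigma"] = sigma

    transfer = evaluate_pairs(ref_b_flat,
                              _flatten_cube(emulate_cube(model, cube_b)))
    results["transfer_nrmse_pct"] = transfer.nrmse_pct
    results["transfer_r2_760"] = transfer.r2_at_760nm

    # --- sampling-strategy comparison on the shifted scene ---
    plan_rand = SamplingPlan(strategy="random", n_samples=OPTIMAL_N_SAMPLES,
                             seed=s_rand)
    table_rand = build_training_set([(cube_a, truth_a.reference_sif, "A")], plan_rand)
    model_rand, _ = train_emulator(table_rand, emu_config)
    transfer_rand = evaluate_pairs(ref_b_flat,
                                   _flatten_cube(emulate_cube(model_rand, cube_b)))
    results["random_transfer_nrmse_pct"] = transfer_rand.nrmse_pct
    results["absolute_minus_random_pp"] = (results["transfer_nrmse_pct"]
                                           - transfer_rand.nrmse_pct)

    # --- nested sample-size sweep against one common validation set ---
    pool, val = _pixel_pools(rows, cols, max(SAMPLE_SIZES), 3000, s_pool)
    val_table = _table_from_flat(cube_a, truth_a.reference_sif, val, "A-val")
    curve: dict[int, float] = {}
    for size in SAMPLE_SIZES:
        sub = _table_from_flat(cube_a, truth_a.reference_sif, pool[:size], "A-pool")
        emu = _fit_fixed_emulator(sub, OPTIMAL_P_IN, OPTIMAL_P_OUT, lam, sigma)
        rep = evaluate_pairs(val_table.Y, emulate_spectra(emu, val_table.X))
        curve[size] = rep.nrmse_pct
    results["learning_curve_nrmse_pct"] = curve

    # --- output-PC sweep at 1000 samples, 20 input PCs ---
    base = _table_from_flat(cube_a, truth_a.reference_sif, pool[:1000], "A-pool")
    pout_curve: dict[int, float] = {}
    for p_out in P_OUT_RANGE:
        emu = _fit_fixed_emulator(base, OPTIMAL_P_IN, p_out, lam, sigma)
        rep = evaluate_pairs(val_table.Y, emulate_spectra(emu, val_table.X))
        pout_curve[p_out] = rep.nrmse_pct
    results["pout_curve_nrmse_pct"] = pout_curve
    results["pout_spread_pp"] = max(pout_curve.values()) - min(pout_curve.values())

    return results
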