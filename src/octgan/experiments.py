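"""Canned desk-scale experiments: dataset -> training -> evaluation.

These functions bundle the full pipeline at the reduced problem sizes the
package uses for quantitative self-checks on a single CPU: 64 x 64 pixel
B-scans, a U-Net with 4 levels starting at 16 features, and a 5-hidden-layer
discriminator starting at 16 features. All randomness derives from the one
``seed`` argument.

* :func:`run_quality_experiment` — mixed-phantom training and the
  SSIM / PSNR / FID table for input and prediction cohorts vs ground truth.
* :func:`run_resolution_experiment` — bead-phantom training and the
  Gaussian-fit axial-FWHM improvement factor FWHM(input)/FWHM(prediction).
* :func:`run_phase_ablation` — the same training with and without the phase
  input channel, seed-averaged FID comparison.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import spectra as sp
from .evaluation import bead_resolution_analysis, evaluate_run
from .gan import DiscriminatorSpec, GeneratorSpec, LossConfig
from .phantoms import (AcquisitionConfig, generate_dataset, load_pair,
                       scatterer_pixel_locations)
from .processing import channels_to_linear_amplitude, to_channels
from .training import TrainConfig, fit, load_checkpoint

__all__ = [
    "desk_generator_spec", "desk_discriminator_spec", "expected_fwhms",
    "run_quality_experiment", "run_resolution_experiment",
    "run_phase_ablation",
]

#: Phantom-kind mix for quality experiments, proportioned like the study's
#: training corpus (tape : beads : tissue = 3 : 3 : 2).
MIXED_COUNTS = {"tape": 94, "beads": 94, "tissue": 62}


def desk_generator_spec(use_phase: bool = True) -> GeneratorSpec:
    return GeneratorSpec(in_channels=2 if use_phase else 1, out_channels=1,
                         n_levels=4, base_width=16, max_width=128)


def desk_discriminator_spec() -> DiscriminatorSpec:
    return DiscriminatorSpec(base_width=16, max_width=128)


def expected_fwhms() -> dict:
    """Model-PSF Gaussian-fit FWHMs (um) of the two sources.

    Used to size the per-cohort bead fit windows (+-3 expected FWHM).
    """
    axis = sp.SpectralAxis.uniform()
    broadband = sp.make_broadband_spectrum(axis)
    gapped = sp.apply_window(broadband, sp.make_gapped_window(axis))
    return {"input": sp.expected_axial_fwhm_um(gapped),
            "truth": sp.expected_axial_fwhm_um(broadband)}


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0]
               % (2**31 - 1))


def _train(data_dir, run_dir, seed, epochs, use_phase=True):
    cfg = TrainConfig(epochs=epochs, seed=seed, use_phase_channel=use_phase)
    return fit(data_dir, run_dir, cfg, desk_generator_spec(use_phase),
               desk_discriminator_spec(), LossConfig())


def _test_pairs(data_dir):
    manifest = pd.read_csv(Path(data_dir) / "manifest.csv")
    rows = manifest[manifest["split"] == "test"]
    return [load_pair(Path(data_dir) / f) for f in rows["file"]]


def run_quality_experiment(workdir, seed: int, counts: dict | None = None,
                           epochs: int = 8, test_fraction: float = 0.2) -> dict:
    """Mixed-phantom training and the Table-1-shaped metric summary.

    With the default counts, 250 pairs are simulated (200 train+val, 50
    held-out test) and the cGAN is trained for ``epochs`` epochs; the
    returned dict carries mean ± std SSIM and PSNR and the cohort FID for
    the input and prediction cohorts versus ground truth.
    """
    workdir = Path(workdir)
    data_dir = workdir / "data"
    counts = counts or dict(MIXED_COUNTS)
    if not (data_dir / "manifest.csv").exists():
        generate_dataset(data_dir, counts, seed=_subseed(seed, 1),
                         test_fraction=test_fraction)
    result = _train(data_dir, workdir / "run", _subseed(seed, 2), epochs)
    gen, _, _ = load_checkpoint(result.checkpoint_path)
    report = evaluate_run(_test_pairs(data_dir), gen)
    summary = dict(report.summary)
    summary["best_val_l1"] = result.best_val_l1
    return summary


def run_resolution_experiment(workdir, seed: int, n_pairs: int = 250,
                              epochs: int = 30,
                              test_fraction: float = 0.2) -> dict:
    """Bead-phantom training and the axial-resolution improvement factor.

    Held-out bead pairs are analyzed with per-cohort Gaussian fits on
    linear-amplitude axial profiles through each bead (+-3 expected-FWHM
    windows); the factor is mean FWHM(input) / mean FWHM(prediction).
    """
    workdir = Path(workdir)
    data_dir = workdir / "data"
    if not (data_dir / "manifest.csv").exists():
        generate_dataset(data_dir, {"beads": n_pairs},
                         seed=_subseed(seed, 1),
                         test_fraction=test_fraction)
    result = _train(data_dir, workdir / "run", _subseed(seed, 2), epochs)
    gen, _, _ = load_checkpoint(result.checkpoint_path)
    pairs = _test_pairs(data_dir)
    exp = expected_fwhms()
    depth_pitch = pairs[0].truth_bscan.depth_pitch_um
    images = {"input": [], "prediction": []}
    locations = []
    for pair in pairs:
        ch_in = to_channels(pair.input_bscan)
        pred = gen(np.asarray(ch_in.stacked(), np.float32))[0, 0]
        lin_in = np.abs(pair.input_bscan.pixels)
        images["input"].append(lin_in / lin_in.max())
        images["prediction"].append(channels_to_linear_amplitude(pred))
        locations.append(scatterer_pixel_locations(pair))
    table, factor = bead_resolution_analysis(
        images, locations, depth_pitch,
        fit_window_um={"input": 6.0 * exp["input"],
                       "prediction": 6.0 * exp["truth"]})
    ok = table[table["ok"]]
    return {
        "improvement_factor": factor,
        "fwhm_input_um": float(ok[ok.cohort == "input"].fwhm_um.mean()),
        "fwhm_prediction_um": float(
            ok[ok.cohort == "prediction"].fwhm_um.mean()),
        "n_beads_fit": int(len(ok)),
        "best_val_l1": result.best_val_l1,
    }


def run_phase_ablation(workdir, seed: int, counts: dict | None = None,
                       epochs: int = 8, n_seeds: int = 3,
                       test_fraction: float = 0.2) -> dict:
    """Amplitude+phase vs amplitude-only training, seed-averaged FID.

    Repeats the identical run ``n_seeds`` times per arm (same data, same
    training seeds; only the generator's input channels differ) and
    averages the prediction-cohort FID.
    """
    workdir = Path(workdir)
    data_dir = workdir / "data"
    counts = counts or {"tape": 38, "beads": 38, "tissue": 24}
    if not (data_dir / "manifest.csv").exists():
        generate_dataset(data_dir, counts, seed=_subseed(seed, 1),
                         test_fraction=test_fraction)
    pairs = _test_pairs(data_dir)
    fids = {True: [], False: []}
    for i in range(n_seeds):
        run_seed = _subseed(seed, 10 + i)
        for use_phase in (True, False):
            tag = "phase" if use_phase else "nophase"
            result = _train(data_dir, workdir / f"run_{tag}_{i}", run_seed,
                            epochs, use_phase)
            gen, _, _ = load_checkpoint(result.checkpoint_path)
            report = evaluate_run(pairs, gen, use_phase=use_phase)
            fids[use_phase].append(report.summary["fid_pred"])
    return {
        "fid_with_phase": float(np.mean(fids[True])),
        "fid_without_phase": float(np.mean(fids[False])),
        "fid_with_phase_per_seed": [float(v) for v in fids[True]],
        "fid_without_phase_per_seed": [float(v) for v in fids[False]],
    }
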