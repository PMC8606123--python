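"""Quantitative evaluation: SSIM, PSNR, Fréchet distance, bead FWHM analysis.

The reporting layout follows the study's table: each metric is computed for
the input-vs-truth cohort (I) and the prediction-vs-truth cohort (P), mean
± std across test images, plus a cohort-level Fréchet distance and — for
bead phantoms — a Gaussian-fit axial-FWHM table whose mean ratio
FWHM(input) / FWHM(prediction) is the resolution improvement factor.

The Fréchet distance is computed between Gaussian fits of feature-space
distributions. The default feature extractor is a documented fixed-seed
random convolutional network, so evaluation runs offline and is fully
reproducible; any other extractor (e.g. a pretrained Inception) can be
plugged in, and the matrix-square-root Fréchet formula is shared by both
paths. Relative comparisons (input vs prediction) are meaningful under any
fixed extractor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from skimage.metrics import structural_similarity

from . import nn
from .processing import to_channels
from .spectra import GaussianFitError, fit_gaussian_fwhm

__all__ = [
    "psnr", "ssim", "frechet_distance", "FeatureExtractor", "fid_cohort",
    "bead_resolution_analysis", "evaluate_run", "MetricsReport",
    "plot_metric_violins",
]


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; infinite (flagged) for identical images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Single-scale SSIM with the standard Gaussian window (sigma 1.5)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def _as_moments(mu, cov):
    mu = np.atleast_1d(np.asarray(mu, dtype=np.float64))
    cov = np.atleast_2d(np.asarray(cov, dtype=np.float64))
    return mu, cov


def frechet_distance(mu1, cov1, mu2, cov2) -> float:
    """Squared Fréchet distance between two Gaussians.

    d^2 = ||mu1 - mu2||^2 + Tr(C1 + C2 - 2 (C1 C2)^{1/2}); symmetric, zero
    iff the moments coincide. A numerically non-PSD cross term is repaired
    to its nearest PSD counterpart with a warning.
    """
    mu1, cov1 = _as_moments(mu1, cov1)
    mu2, cov2 = _as_moments(mu2, cov2)
    diff = mu1 - mu2
    prod = cov1 @ cov2
    sqrt_prod = np.asarray(linalg.sqrtm(prod))
    if np.iscomplexobj(sqrt_prod):
        imag_max = float(np.abs(sqrt_prod.imag).max())
        if imag_max > 1e-6 * max(1.0, float(np.abs(sqrt_prod.real).max())):
            warnings.warn(
                "covariance product not PSD; using nearest PSD square root",
                RuntimeWarning, stacklevel=2)
        sqrt_prod = sqrt_prod.real
    d2 = float(diff @ diff + np.trace(cov1) + np.trace(cov2)
               - 2.0 * np.trace(sqrt_prod))
    return max(d2, 0.0)


class FeatureExtractor:
    """Fixed-seed random convolutional feature embedding for cohort FID.

    Three strided 4x4 convolution + LeakyReLU stages with frozen
    He-initialized weights, followed by global average pooling — a
    reproducible, offline stand-in for a pretrained embedding. The
    embedding is deterministic for a fixed seed.
    """

    def __init__(self, seed: int = 0, widths: tuple = (16, 32, 64)):
        rng = np.random.default_rng(seed)
        self.layers = []
        cin = 1
        for w in widths:
            conv = nn.Conv2d(cin, w, rng=rng)
            fan_in = cin * 16
            conv.weight.data = rng.normal(
                0.0, np.sqrt(2.0 / fan_in),
                size=conv.weight.data.shape).astype(np.float32)
            self.layers.append(conv)
            cin = w
        self.act = nn.LeakyReLU(0.2)
        self.n_features = widths[-1]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        h = np.asarray(image, dtype=np.float32)[None, None]
        for conv in self.layers:
            h, _ = conv.forward(h)
            h, _ = self.act.forward(h)
        return h.mean(axis=(2, 3))[0].astype(np.float64)


def fid_cohort(images_a, images_b,
               extractor: FeatureExtractor | None = None) -> float:
    """Fréchet distance between feature distributions of two image cohorts."""
    extractor = extractor or FeatureExtractor()
    fa = np.stack([extractor(im) for im in images_a])
    fb = np.stack([extractor(im) for im in images_b])
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least two images per cohort")
    reg = 1e-6 * np.eye(extractor.n_features)
    return frechet_distance(fa.mean(0), np.cov(fa, rowvar=False) + reg,
                            fb.mean(0), np.cov(fb, rowvar=False) + reg)


def bead_resolution_analysis(
    images: dict,
    bead_locations: list,
    depth_pitch_um: float,
    fit_window_um: dict | float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Gaussian-fit axial FWHM of bead profiles per cohort.

    Parameters
    ----------
    images:
        Mapping cohort name -> list of linear-amplitude images (depth x
        lateral), e.g. {"input": [...], "prediction": [...]}. All cohorts
        index the same underlying scenes.
    bead_locations:
        Per image, a list of (depth_px, lateral_px) bead peak positions.
    fit_window_um:
        Full fit-window width per cohort (default three times the profile's
        own coarse width estimate). Profiles are fit on the linear
        amplitude with a Gaussian + constant offset.

    Returns
    -------
    (table, improvement_factor)
        Per-bead rows (cohort, image, bead, fwhm_um, r_squared); failed
        fits are excluded and counted. improvement_factor is
        mean FWHM(input) / mean FWHM(prediction) when both cohorts are
        present, else NaN.

    Notes
    -----
    A fit is accepted only if it is physically meaningful for a bead
    profile: r^2 >= 0.3, FWHM no wider than the fit window (a Gaussian
    wider than the window is unconstrained) and at least half a pixel, and
    a fitted center within half the window of the nominal bead position.
    Rejected fits appear with ok = False.
    """
    rows = []
    for cohort, imgs in images.items():
        for i_img, (img, beads) in enumerate(zip(imgs, bead_locations)):
            img = np.asarray(img, dtype=np.float64)
            depth = np.arange(img.shape[0]) * depth_pitch_um
            for i_bead, (zpx, xpx) in enumerate(beads):
                profile = img[:, int(xpx)]
                if isinstance(fit_window_um, dict):
                    window = fit_window_um.get(cohort)
                else:
                    window = fit_window_um
                center = float(zpx) * depth_pitch_um
                try:
                    fit = fit_gaussian_fwhm(depth, profile, window_um=window,
                                            center_um=center)
                    w_eff = window if window is not None else \
                        depth[-1] - depth[0]
                    ok = (fit.r_squared >= 0.3
                          and 0.5 * depth_pitch_um <= fit.fwhm <= w_eff
                          and abs(fit.center - center) <= 0.5 * w_eff)
                    rows.append({"cohort": cohort, "image": i_img,
                                 "bead": i_bead, "fwhm_um": fit.fwhm,
                                 "r_squared": fit.r_squared, "ok": bool(ok)})
                except GaussianFitError:
                    rows.append({"cohort": cohort, "image": i_img,
                                 "bead": i_bead, "fwhm_um": np.nan,
                                 "r_squared": np.nan, "ok": False})
    table = pd.DataFrame(rows)
    factor = float("nan")
    good = table[table["ok"]]
    if {"input", "prediction"} <= set(images):
        f_in = good[good["cohort"] == "input"]["fwhm_um"].mean()
        f_pr = good[good["cohort"] == "prediction"]["fwhm_um"].mean()
        if np.isfinite(f_in) and np.isfinite(f_pr) and f_pr > 0:
            factor = float(f_in / f_pr)
    return table, factor


@dataclass
class MetricsReport:
    """Per-image metrics plus the six-quantity cohort summary."""

    per_image: pd.DataFrame
    summary: dict

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(out_dir / "metrics.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1, sort_keys=True)


def evaluate_run(
    pairs: list,
    generator,
    dyn_range_db: float = 40.0,
    use_phase: bool = True,
    extractor: FeatureExtractor | None = None,
) -> MetricsReport:
    """SSIM / PSNR / FID for input and prediction cohorts vs ground truth.

    ``pairs`` are held-out :class:`~octgan.phantoms.PairedBScan` objects
    (never seen in training); ``generator`` maps a channel stack to a
    predicted amplitude image.
    """
    if not pairs:
        raise ValueError("empty test set")
    rows, amps_i, amps_p, amps_t = [], [], [], []
    for i, pair in enumerate(pairs):
        ch_in = to_channels(pair.input_bscan, dyn_range_db)
        ch_tr = to_channels(pair.truth_bscan, dyn_range_db)
        x = ch_in.stacked() if use_phase else ch_in.amplitude[None]
        pred = generator(np.asarray(x, dtype=np.float32))[0, 0].astype(np.float64)
        a_i, a_t = ch_in.amplitude, ch_tr.amplitude
        rows.append({
            "pair": i, "phantom_kind": pair.phantom_kind,
            "ssim_input": ssim(a_i, a_t), "ssim_pred": ssim(pred, a_t),
            "psnr_input": psnr(a_i, a_t), "psnr_pred": psnr(pred, a_t),
        })
        amps_i.append(a_i)
        amps_p.append(pred)
        amps_t.append(a_t)
    per_image = pd.DataFrame(rows)
    fid_i = fid_cohort(amps_i, amps_t, extractor)
    fid_p = fid_cohort(amps_p, amps_t, extractor)
    summary = {
        "n_pairs": len(pairs),
        "ssim_input_mean": float(per_image["ssim_input"].mean()),
        "ssim_input_std": float(per_image["ssim_input"].std()),
        "ssim_pred_mean": float(per_image["ssim_pred"].mean()),
        "ssim_pred_std": float(per_image["ssim_pred"].std()),
        "psnr_input_mean": float(per_image["psnr_input"].mean()),
        "psnr_input_std": float(per_image["psnr_input"].std()),
        "psnr_pred_mean": float(per_image["psnr_pred"].mean()),
        "psnr_pred_std": float(per_image["psnr_pred"].std()),
        "fid_input": fid_i,
        "fid_pred": fid_p,
    }
    return MetricsReport(per_image, summary)


def plot_metric_violins(report: MetricsReport, path) -> None:
    """Optional violin plots of per-image SSIM and PSNR, input vs prediction.

    Requires matplotlib (``pip install octgan[plot]``).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_image
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, metric in zip(axes, ("ssim", "psnr")):
        data = [df[f"{metric}_input"], df[f"{metric}_pred"]]
        parts = ax.violinplot(data, showmeans=True)
        for body, color in zip(parts["bodies"], ("tab:blue", "tab:orange")):
            body.set_facecolor(color)
        ax.set_xticks([1, 2], ["input", "prediction"])
        ax.set_ylabel(metric.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
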