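"""Synthetic-data generator: phantoms, fringe synthesis, co-registered pairs.

Emulates the study's three sample classes — a layered scotch-tape-like
phantom, isolated micro-beads, and a three-layer tissue-like scatterer field
(epidermis / dermis / cartilage) — and the two ways a low-resolution
discontinuous acquisition can be paired with a broadband ground truth:

``synthetic-gap``
    The broadband spectral fringes are multiplied per-wavelength with the
    two-band Gaussian window and reconstructed; input and truth share the
    identical fringe (and noise) realization, so the pair is co-registered
    by construction. This mirrors the synthetically gapped training data.
``two-source``
    The gapped member is synthesized independently from the windowed
    spectrum with the same scatterers and the same noise seed, emulating a
    physically separate SLED acquisition.

The forward model is the standard Fourier-domain OCT cross term: for each
A-scan, fringe(k) = sum_i w_i * r_i * S(k) * cos(2 k z_i) with a Gaussian
lateral beam weight w_i (transverse resolution 2.0 um FWHM by default) and
additive white Gaussian noise on the spectral fringes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .container import read_container, write_container
from .processing import ComplexBScan, reconstruct_bscan
from .spectra import (
    SourceSpectrum,
    SpectralAxis,
    SpectralWindow,
    apply_window,
    make_broadband_spectrum,
    make_gapped_window,
)

__all__ = [
    "Phantom",
    "AcquisitionConfig",
    "PairedBScan",
    "make_bead_phantom",
    "make_tape_phantom",
    "make_tissue_phantom",
    "synthesize_fringes",
    "make_pair",
    "generate_dataset",
    "load_pair",
    "scatterer_pixel_locations",
    "NOMINAL_BROADBAND_FWHM_UM",
]

#: Nominal axial FWHM (um) of the broadband 425-685 nm source; sets the
#: default bead separation so individual bead fits stay uncontaminated.
NOMINAL_BROADBAND_FWHM_UM = 1.2

PHANTOM_KINDS = ("tape", "beads", "tissue")


@dataclass(frozen=True)
class Phantom:
    """Discrete scatterer field: columns (x um lateral, z um depth, reflectivity)."""

    scatterers: np.ndarray
    kind: str
    extent_um: tuple  # (width, depth)

    def __post_init__(self):
        sc = np.asarray(self.scatterers, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "scatterers", sc)
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        w, d = self.extent_um
        if sc.size:
            if np.any(sc[:, 2] < 0):
                raise ValueError("reflectivities must be non-negative")
            if (np.any(sc[:, 0] < 0) or np.any(sc[:, 0] > w)
                    or np.any(sc[:, 1] < 0) or np.any(sc[:, 1] > d)):
                raise ValueError("scatterers outside extent")

    @property
    def n_scatterers(self) -> int:
        return self.scatterers.shape[0]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan geometry, spectral sampling and noise for one B-scan.

    Desk-scale default: 64 A-scans x 128 spectral samples -> 64 x 64 pixel
    images. The full-scale study geometry (500 x 4096 over a 400 um field)
    is reachable by configuration.
    """

    n_ascans: int = 64
    n_k: int = 256
    fov_um: float = 128.0
    noise_sigma: float = 0.2
    seed: int = 0
    lambda_lo_nm: float = 400.0
    lambda_hi_nm: float = 710.0
    transverse_fwhm_um: float = 2.0
    #: Image depth in pixels; only the shallow part of the FFT half-space is
    #: kept, so the blue-end Nyquist depth of the wavelength-sampled fringes
    #: stays below every imaged reflector (spectrometer OCT images shallow
    #: content for the same reason).
    keep_depth_px: int = 64

    def __post_init__(self):
        if self.n_ascans < 8:
            raise ValueError("need at least 8 A-scans")
        if self.n_k < 128:
            raise ValueError("need at least 128 spectral samples")
        if self.keep_depth_px > self.n_k // 2:
            raise ValueError("keep_depth_px exceeds the FFT half-space")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def axis(self) -> SpectralAxis:
        return SpectralAxis(np.linspace(self.lambda_lo_nm, self.lambda_hi_nm,
                                        self.n_k))

    @property
    def lateral_pitch_um(self) -> float:
        return self.fov_um / self.n_ascans

    @property
    def depth_pitch_um(self) -> float:
        k_hi = 2.0 * np.pi / self.lambda_lo_nm
        k_lo = 2.0 * np.pi / self.lambda_hi_nm
        return float(np.pi / (k_hi - k_lo) / 1e3)

    @property
    def depth_extent_um(self) -> float:
        return self.depth_pitch_um * min(self.keep_depth_px, self.n_k // 2)


@dataclass(frozen=True)
class PairedBScan:
    """Co-registered (gapped input, broadband truth) complex B-scans."""

    input_bscan: ComplexBScan
    truth_bscan: ComplexBScan
    provenance: str           # "synthetic-gapped" | "measured-style"
    phantom_kind: str
    phantom_id: str
    seed: int
    #: (n, 3) scatterer ground truth (x um, z um, reflectivity), when known.
    scatterers_um: np.ndarray | None = None

    def __post_init__(self):
        if self.input_bscan.pixels.shape != self.truth_bscan.pixels.shape:
            raise ValueError("pair members must share a pixel grid")

    def save(self, path) -> Path:
        arrays = {
            "input_complex_real": self.input_bscan.pixels.real,
            "input_complex_imag": self.input_bscan.pixels.imag,
            "truth_complex_real": self.truth_bscan.pixels.real,
            "truth_complex_imag": self.truth_bscan.pixels.imag,
        }
        if self.scatterers_um is not None:
            arrays["scatterers_um"] = np.asarray(self.scatterers_um)
        meta = {
            "provenance": self.provenance,
            "phantom_kind": self.phantom_kind,
            "phantom_id": self.phantom_id,
            "seed": self.seed,
            "depth_pitch_um": self.input_bscan.depth_pitch_um,
            "lateral_pitch_um": self.input_bscan.lateral_pitch_um,
        }
        return write_container(path, arrays, meta)


def load_pair(path) -> PairedBScan:
    arrays, meta = read_container(
        path,
        required=("input_complex_real", "input_complex_imag",
                  "truth_complex_real", "truth_complex_imag"),
    )
    dz, dx = meta["depth_pitch_um"], meta["lateral_pitch_um"]
    inp = ComplexBScan(arrays["input_complex_real"]
                       + 1j * arrays["input_complex_imag"], dz, dx)
    tru = ComplexBScan(arrays["truth_complex_real"]
                       + 1j * arrays["truth_complex_imag"], dz, dx)
    return PairedBScan(inp, tru, meta["provenance"], meta["phantom_kind"],
                       meta["phantom_id"], meta["seed"],
                       scatterers_um=arrays.get("scatterers_um"))


# ---------------------------------------------------------------------------
# Phantom builders
# ---------------------------------------------------------------------------

_EDGE_MARGIN_UM = 4.0


def make_bead_phantom(
    n_beads: int,
    extent_um: tuple = (128.0, 29.0),
    reflectivity_range: tuple = (0.5, 1.5),
    seed: int = 0,
    min_separation_um: float | None = None,
) -> Phantom:
    """Isolated point scatterers with a guaranteed minimum pairwise spacing.

    The default spacing, five broadband PSF widths, keeps each bead's axial
    profile free of contamination from its neighbours so Gaussian FWHM fits
    measure the PSF alone.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    sep = (min_separation_um if min_separation_um is not None
           else 5.0 * NOMINAL_BROADBAND_FWHM_UM)
    w, d = extent_um
    lo_x, hi_x = _EDGE_MARGIN_UM, w - _EDGE_MARGIN_UM
    lo_z, hi_z = _EDGE_MARGIN_UM, d - 3.0
    if hi_x <= lo_x or hi_z <= lo_z:
        raise ValueError("extent too small for edge margins")
    # capacity check: disks of radius sep/2 must fit loosely in the area
    if n_beads * np.pi * (sep / 2.0) ** 2 > 0.5 * (hi_x - lo_x) * (hi_z - lo_z):
        raise ValueError("extent too small for the separation constraint")
    rng = np.random.default_rng(seed)
    pts: list = []
    tries = 0
    while len(pts) < n_beads:
        tries += 1
        if tries > 2000 * n_beads:
            raise ValueError("could not satisfy the separation constraint")
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_z, hi_z)])
        if all(np.hypot(*(cand - p)) >= sep for p in pts):
            pts.append(cand)
    refl = rng.uniform(*reflectivity_range, size=n_beads)
    sc = np.column_stack([np.array(pts), refl])
    return Phantom(sc, "beads", extent_um)


def make_tape_phantom(
    n_layers: int = 6,
    layer_spacing_um: float = 4.0,
    scatterers_per_layer: int = 60,
    extent_um: tuple = (128.0, 29.0),
    seed: int = 0,
) -> Phantom:
    """Thin scattering bands at regular depth spacing (tape-like sample)."""
    if n_layers < 2:
        raise ValueError("need at least two layers")
    w, d = extent_um
    z0 = _EDGE_MARGIN_UM
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_layers):
        zc = z0 + i * layer_spacing_um
        if zc > d - 2.0:
            break
        x = rng.uniform(1.0, w - 1.0, size=scatterers_per_layer)
        z = np.clip(zc + rng.normal(0.0, 0.15, size=scatterers_per_layer),
                    0.0, d)
        r = rng.uniform(0.8, 1.2, size=scatterers_per_layer)
        rows.append(np.column_stack([x, z, r]))
    return Phantom(np.vstack(rows), "tape", extent_um)


def make_tissue_phantom(
    layer_boundaries_um: tuple = (3.0, 9.0, 19.0, 28.0),
    densities_per_um2: tuple = (2.5, 1.0, 0.4),
    extent_um: tuple = (128.0, 29.0),
    seed: int = 0,
) -> Phantom:
    """Piecewise-constant random scatterer density vs depth (tissue-like).

    Consecutive boundary pairs delimit the layers (defaults mimic an
    epidermis / dermis / cartilage stack); scatterer counts are Poisson with
    mean density * layer area, producing fully developed speckle in the
    reconstructed amplitude.
    """
    bounds = np.asarray(layer_boundaries_um, dtype=float)
    if bounds.size != len(densities_per_um2) + 1:
        raise ValueError("need len(densities) + 1 boundaries")
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("boundaries must be ascending")
    if np.any(np.asarray(densities_per_um2) <= 0):
        raise ValueError("densities must be positive")
    w, d = extent_um
    if bounds[-1] > d:
        raise ValueError("boundaries exceed phantom depth")
    rng = np.random.default_rng(seed)
    rows = []
    for (z_lo, z_hi), dens in zip(zip(bounds[:-1], bounds[1:]),
                                  densities_per_um2):
        n = rng.poisson(dens * w * (z_hi - z_lo))
        if n == 0:
            continue
        x = rng.uniform(0.0, w, size=n)
        z = rng.uniform(z_lo, z_hi, size=n)
        r = rng.uniform(0.3, 1.0, size=n)
        rows.append(np.column_stack([x, z, r]))
    if not rows:
        raise ValueError("empty tissue phantom; increase densities")
    return Phantom(np.vstack(rows), "tissue", extent_um)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def synthesize_fringes(
    phantom: Phantom,
    spectrum: SourceSpectrum,
    acq: AcquisitionConfig,
) -> np.ndarray:
    """Spectral interferogram B-scan (n_ascans, n_k) for one acquisition.

    Cross-term fringes only (reference and sample autocorrelation terms are
    removed by background subtraction downstream and are not modeled):
    fringe_a(k) = sum_i w(x_a - x_i) * r_i * S(k) * cos(2 k z_i), plus white
    Gaussian noise whose std is ``noise_sigma`` times the RMS of the
    noiseless fringes (times 1.0 for an empty phantom). Deterministic for a
    fixed ``acq.seed``.
    """
    lam_acq = acq.axis.wavelengths_nm
    s_acq = np.interp(lam_acq, spectrum.axis.wavelengths_nm, spectrum.density,
                      left=0.0, right=0.0)
    k = 2.0 * np.pi / lam_acq  # rad/nm, descending with wavelength
    x_scan = (np.arange(acq.n_ascans) + 0.5) * acq.lateral_pitch_um
    sigma_b = acq.transverse_fwhm_um / 2.354820045
    fringes = np.zeros((acq.n_ascans, acq.n_k))
    if phantom.n_scatterers:
        xs, zs, rs = phantom.scatterers.T
        z_nm = zs * 1e3
        reach = 4.0 * sigma_b
        order = np.argsort(xs)
        xs_s, z_s, r_s = xs[order], z_nm[order], rs[order]
        for a, xa in enumerate(x_scan):
            i0, i1 = np.searchsorted(xs_s, (xa - reach, xa + reach))
            if i1 <= i0:
                continue
            w = np.exp(-((xs_s[i0:i1] - xa) ** 2) / (2.0 * sigma_b**2))
            amp = w * r_s[i0:i1]
            fringes[a] = amp @ np.cos(2.0 * np.outer(z_s[i0:i1], k))
        fringes *= s_acq[None, :]
    rms = float(np.sqrt(np.mean(fringes**2)))
    scale = rms if rms > 0 else 1.0
    rng = np.random.default_rng(acq.seed)
    fringes = fringes + rng.standard_normal(fringes.shape) * (
        acq.noise_sigma * scale)
    return fringes


def make_pair(
    phantom: Phantom,
    acq: AcquisitionConfig,
    mode: str = "synthetic-gap",
    window: SpectralWindow | None = None,
    edge_smoothing_nm: float = 25.0,
    phantom_id: str = "phantom-0000",
) -> PairedBScan:
    """Build a co-registered (gapped input, broadband truth) pair.

    ``synthetic-gap`` multiplies the broadband fringes per wavelength with
    the two-band window before reconstruction; ``two-source`` synthesizes
    the gapped member independently from the windowed spectrum with the
    same scatterers and noise seed.
    """
    if mode not in ("synthetic-gap", "two-source"):
        raise ValueError(f"unknown pair mode {mode!r}")
    axis = acq.axis
    broadband = make_broadband_spectrum(axis, edge_smoothing_nm=edge_smoothing_nm)
    gap_window = make_gapped_window(axis, window)
    truth_fringes = synthesize_fringes(phantom, broadband, acq)
    if mode == "synthetic-gap":
        input_fringes = truth_fringes * gap_window.density[None, :]
        provenance = "synthetic-gapped"
    else:
        gapped = apply_window(broadband, gap_window)
        input_fringes = synthesize_fringes(phantom, gapped, acq)
        provenance = "measured-style"
    lam = axis.wavelengths_nm
    truth = reconstruct_bscan(truth_fringes, lam, acq.lateral_pitch_um)
    inp = reconstruct_bscan(input_fringes, lam, acq.lateral_pitch_um)
    keep = acq.keep_depth_px
    truth = ComplexBScan(truth.pixels[:keep], truth.depth_pitch_um,
                         truth.lateral_pitch_um)
    inp = ComplexBScan(inp.pixels[:keep], inp.depth_pitch_um,
                       inp.lateral_pitch_um)
    return PairedBScan(inp, truth, provenance, phantom.kind, phantom_id,
                       acq.seed, scatterers_um=phantom.scatterers.copy())


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _build_phantom(kind: str, extent: tuple, seed: int) -> Phantom:
    if kind == "beads":
        return make_bead_phantom(12, extent_um=extent, seed=seed)
    if kind == "tape":
        return make_tape_phantom(extent_um=extent, seed=seed)
    if kind == "tissue":
        return make_tissue_phantom(extent_um=extent, seed=seed)
    raise ValueError(f"unknown phantom kind {kind!r}")


def generate_dataset(
    out_dir,
    counts: dict,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
    mode: str = "synthetic-gap",
    test_fraction: float = 0.0,
) -> pd.DataFrame:
    """Write a paired dataset plus manifest.csv and a config snapshot.

    ``counts`` maps phantom kind ("tape" | "beads" | "tissue") to the number
    of pairs. Every pair gets its own phantom realization (fresh scatterers
    drawn from a per-pair subseed), so any train/test partition labelled
    here is disjoint at the phantom level by construction; the last
    ``test_fraction`` of each kind is labelled "test".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acq = acq or AcquisitionConfig()
    extent = (acq.fov_um, acq.depth_extent_um)
    master = np.random.SeedSequence(seed)
    rows = []
    idx = 0
    for kind in PHANTOM_KINDS:
        n = int(counts.get(kind, 0))
        if n < 0:
            raise ValueError("counts must be >= 0")
        n_test = int(round(n * test_fraction))
        for j in range(n):
            child = master.spawn(1)[0]
            sub = int(child.generate_state(2)[0] % (2**31 - 1))
            acq_j = AcquisitionConfig(
                n_ascans=acq.n_ascans, n_k=acq.n_k, fov_um=acq.fov_um,
                noise_sigma=acq.noise_sigma, seed=sub,
                lambda_lo_nm=acq.lambda_lo_nm, lambda_hi_nm=acq.lambda_hi_nm,
                transverse_fwhm_um=acq.transverse_fwhm_um)
            phantom_id = f"{kind}-{j:04d}"
            phantom = _build_phantom(kind, extent, sub)
            pair = make_pair(phantom, acq_j, mode=mode, phantom_id=phantom_id)
            fname = f"pair_{idx:04d}.octz"
            pair.save(out_dir / fname)
            rows.append({
                "file": fname,
                "phantom_kind": kind,
                "phantom_id": phantom_id,
                "seed": sub,
                "provenance": pair.provenance,
                "split": "test" if j >= n - n_test else "train",
            })
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    snapshot = {"master_seed": seed, "mode": mode, "counts": dict(counts),
                "test_fraction": test_fraction,
                "acquisition": asdict(acq)}
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    return manifest


def scatterer_pixel_locations(pair: PairedBScan, acq: AcquisitionConfig | None = None):
    """Ground-truth scatterer positions as (depth_px, lateral_px) integer pairs.

    Positions outside the reconstructed pixel grid (or within 3 px of the
    depth edges, where fit windows would be truncated asymmetrically) are
    dropped.
    """
    if pair.scatterers_um is None:
        raise ValueError("pair carries no scatterer ground truth")
    dz = pair.input_bscan.depth_pitch_um
    dx = pair.input_bscan.lateral_pitch_um
    n_z, n_x = pair.input_bscan.pixels.shape
    out = []
    for x_um, z_um, _ in pair.scatterers_um:
        zp, xp = int(round(z_um / dz)), int(round(x_um / dx - 0.5))
        if 3 <= zp < n_z - 3 and 0 <= xp < n_x:
            out.append((zp, xp))
    return out
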