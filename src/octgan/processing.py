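"""Spectral fringes -> complex B-scans -> (amplitude, phase) channel stacks.

Standard spectrometer-based Fourier-domain OCT processing: per-B-scan mean
spectrum (background/DC) subtraction, resampling from the uniform-wavelength
spectrometer grid to uniform wavenumber (k-linearization), FFT along k, and
retention of the positive-depth half-space. The network consumes the result
as two channels in [0, 1]: log-compressed amplitude and the wrapped phase
angle map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["ComplexBScan", "ChannelStack", "reconstruct_bscan", "to_channels",
           "channels_to_linear_amplitude", "export_tiff"]


@dataclass(frozen=True)
class ComplexBScan:
    """Complex-valued B-scan, depth x lateral, with physical pixel pitches."""

    pixels: np.ndarray          # complex, (n_depth, n_lateral)
    depth_pitch_um: float
    lateral_pitch_um: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("B-scan must be 2-D (depth x lateral)")
        if not np.all(np.isfinite(px)):
            raise ValueError("B-scan contains non-finite values")
        object.__setattr__(self, "pixels", px.astype(np.complex128, copy=False))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.pixels)

    @property
    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.pixels.shape[0]) * self.depth_pitch_um


@dataclass(frozen=True)
class ChannelStack:
    """Normalized network input channels, both in [0, 1]."""

    amplitude: np.ndarray
    phase: np.ndarray
    dyn_range_db: float = 40.0

    def __post_init__(self):
        for name in ("amplitude", "phase"):
            ch = np.asarray(getattr(self, name), dtype=np.float64)
            if ch.min() < 0.0 or ch.max() > 1.0:
                raise ValueError(f"{name} channel outside [0, 1]")
            object.__setattr__(self, name, ch)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("channels must share a shape")

    def stacked(self) -> np.ndarray:
        """(2, H, W) array: amplitude then phase."""
        return np.stack([self.amplitude, self.phase])


def reconstruct_bscan(
    fringes: np.ndarray,
    wavelengths_nm: np.ndarray,
    lateral_pitch_um: float = 2.0,
) -> ComplexBScan:
    """Reconstruct a complex B-scan from real spectral fringes.

    Parameters
    ----------
    fringes:
        Real array (n_ascans, n_k), one spectral interferogram per A-scan,
        sampled uniformly in wavelength on ``wavelengths_nm``.
    wavelengths_nm:
        Ascending spectrometer wavelength grid of length n_k.

    Returns
    -------
    ComplexBScan
        (n_k // 2, n_ascans) complex image; depth pitch pi / (k-range).
    """
    fringes = np.asarray(fringes, dtype=np.float64)
    lam = np.asarray(wavelengths_nm, dtype=np.float64)
    if fringes.ndim != 2 or fringes.shape[1] != lam.size:
        raise ValueError("fringes must be (n_ascans, n_k) matching the axis")
    n_k = lam.size
    # Background removal: the mean spectrum over the B-scan estimates the
    # depth-independent reference/DC term.
    fr = fringes - fringes.mean(axis=0, keepdims=True)
    # k-linearization (lambda grid descending in k -> reverse).
    k_desc = 2.0 * np.pi / lam[::-1]
    k_uniform = np.linspace(k_desc[0], k_desc[-1], n_k)
    if np.allclose(k_desc, k_uniform):
        fr_k = fr[:, ::-1]
    else:
        fr_k = CubicSpline(k_desc, fr[:, ::-1], axis=1)(k_uniform)
    spectrum_img = np.fft.fft(fr_k, axis=1)
    half = spectrum_img[:, : n_k // 2]
    depth_pitch_um = np.pi / (k_uniform[-1] - k_uniform[0]) / 1e3
    return ComplexBScan(half.T, depth_pitch_um, lateral_pitch_um)


def to_channels(bscan: ComplexBScan, dyn_range_db: float = 40.0) -> ChannelStack:
    """Log-compress amplitude and normalize phase to [0, 1].

    The amplitude channel maps the top ``dyn_range_db`` decibels below the
    per-image maximum linearly onto [0, 1] (clipped below). The phase channel
    is the wrapped angle mapped by (angle + pi) / (2*pi); it is not
    unwrapped. A zero image yields amplitude 0 everywhere and phase 0.5
    (angle of +0 is 0 by convention).
    """
    if dyn_range_db <= 0:
        raise ValueError("dyn_range_db must be positive")
    mag = bscan.amplitude
    peak = mag.max()
    if peak <= 0:
        amp = np.zeros_like(mag)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.where(mag > 0, mag / peak, 1e-300))
        amp = np.clip(1.0 + db / dyn_range_db, 0.0, 1.0)
    phase = (np.angle(bscan.pixels) + np.pi) / (2.0 * np.pi)
    # angle returns (-pi, pi]; fold the closed endpoint onto 1.0 max.
    phase = np.clip(phase, 0.0, 1.0)
    return ChannelStack(amp, phase, dyn_range_db=dyn_range_db)


def channels_to_linear_amplitude(amplitude_channel: np.ndarray,
                                 dyn_range_db: float = 40.0) -> np.ndarray:
    """Invert the log compression of :func:`to_channels`.

    Returns linear amplitude relative to the per-image maximum (peak 1.0);
    channel value 0 maps to the bottom of the dynamic range, 10^(-R/20).
    """
    a = np.asarray(amplitude_channel, dtype=np.float64)
    return 10.0 ** ((a - 1.0) * dyn_range_db / 20.0)


def export_tiff(path, stack: ChannelStack) -> None:
    """Write a channel stack as a 16-bit two-page TIFF (amplitude, phase).

    Lossy by documentation: complex data cannot be recovered from the
    log-compressed export; use the array container for lossless storage.
    """
    import tifffile

    pages = np.stack([stack.amplitude, stack.phase])
    tifffile.imwrite(path, (pages * 65535.0 + 0.5).astype(np.uint16))
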