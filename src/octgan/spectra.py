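"""Source spectra and the axial point-spread function they induce.

In Fourier-domain OCT the axial resolution is set entirely by the power
spectrum of the light source: the coherence function — the Fourier transform
of the spectral density over wavenumber k = 2*pi/lambda, with the round-trip
phase convention exp(i*2*k*z) — is the axial PSF. A broad continuous band
gives a narrow single-lobed PSF; concentrating the power in two separated
bands (here 510 nm and 635 nm) keeps the individual band widths and adds a
beat between the two carriers, producing the sidelobe/ghost-replica
artifacts this package's reconstruction network is trained to remove.

All wavelengths are in nm, depths in optical-path micrometres in air.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import erf

__all__ = [
    "SpectralAxis",
    "SourceSpectrum",
    "SpectralWindow",
    "AxialPSF",
    "GaussianFitResult",
    "GaussianFitError",
    "FWHM_SIGMA",
    "DEFAULT_GAPPED_PEAKS",
    "BLUE_PEAK",
    "make_broadband_spectrum",
    "make_gapped_window",
    "apply_window",
    "spectrum_to_psf",
    "coherence_from_k_density",
    "psf_energy_ratio",
    "resample_to_wavenumber",
    "fit_gaussian_fwhm",
    "gaussian_band_fwhm_um",
    "expected_axial_fwhm_um",
    "sidelobe_peak_indices",
]

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # = 2.354820045...

#: The two SLED bands used for imaging: (center_nm, fwhm_nm, relative amplitude).
#: The green band is 510 nm / 10 nm, the red band 635 nm / 6 nm.
DEFAULT_GAPPED_PEAKS = ((510.0, 10.0, 1.0), (635.0, 6.0, 1.0))

#: The blue SLED band (450 nm / 5 nm). Available but excluded from the
#: default window: at the camera's low blue quantum efficiency it was not
#: used for imaging.
BLUE_PEAK = (450.0, 5.0, 1.0)


class GaussianFitError(RuntimeError):
    """Raised when an axial profile has no fittable dominant peak."""


@dataclass(frozen=True)
class SpectralAxis:
    """Uniformly sampled, ascending wavelength grid in nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        if lam.ndim != 1 or lam.size < 64:
            raise ValueError("spectral axis needs at least 64 samples")
        d = np.diff(lam)
        if not np.all(d > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("wavelengths must be uniformly sampled")
        if lam[0] < 300.0 or lam[-1] > 900.0:
            raise ValueError("axis must lie within 300-900 nm")

    @classmethod
    def uniform(cls, lo_nm: float = 400.0, hi_nm: float = 710.0, n: int = 1024):
        return cls(np.linspace(lo_nm, hi_nm, n))

    @property
    def n_samples(self) -> int:
        return self.wavelengths_nm.size

    @property
    def pitch_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])


@dataclass(frozen=True)
class SourceSpectrum:
    """Power spectral density (arbitrary units) on a wavelength grid."""

    axis: SpectralAxis
    density: np.ndarray
    #: True for window-shaped objects whose values are multipliers, not power.
    is_window: bool = False

    def __post_init__(self):
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", dens)
        if dens.shape != self.axis.wavelengths_nm.shape:
            raise ValueError("density shape must match axis")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        if not self.is_window and dens.sum() <= 0:
            raise ValueError("total power must be positive")

    @property
    def total_power(self) -> float:
        """Integral of the density over wavelength (trapezoidal)."""
        return float(np.trapezoid(self.density, self.axis.wavelengths_nm))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.axis.wavelengths_nm, self.density])
        np.savetxt(path, arr, delimiter=",", header="wavelength_nm,density", comments="")

    @classmethod
    def from_csv(cls, path) -> "SourceSpectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(SpectralAxis(arr[:, 0]), arr[:, 1])


@dataclass(frozen=True)
class SpectralWindow:
    """A set of Gaussian peaks: (center_nm, fwhm_nm, relative_amplitude)."""

    peaks: tuple = DEFAULT_GAPPED_PEAKS

    def __post_init__(self):
        if len(self.peaks) < 1:
            raise ValueError("window needs at least one peak")
        for c, fw, a in self.peaks:
            if fw <= 0 or a <= 0:
                raise ValueError("peak fwhm and amplitude must be positive")


@dataclass(frozen=True)
class AxialPSF:
    """Complex coherence function vs depth and its magnitude envelope."""

    depth_um: np.ndarray
    complex_amplitude: np.ndarray
    #: False when the envelope has not decayed below half max at the window
    #: edges, i.e. the requested span does not contain the main lobe.
    main_lobe_contained: bool = True

    @property
    def intensity_envelope(self) -> np.ndarray:
        return np.abs(self.complex_amplitude)


@dataclass(frozen=True)
class GaussianFitResult:
    """Gaussian + constant-offset least-squares fit of an axial profile."""

    center: float
    sigma: float
    offset: float
    amplitude: float
    r_squared: float

    @property
    def fwhm(self) -> float:
        return FWHM_SIGMA * self.sigma


def _erf_step(x: np.ndarray, edge: float, smoothing_nm: float) -> np.ndarray:
    """Smooth 0->1 step at ``edge`` whose 10-90% transition ~ smoothing_nm."""
    s = max(smoothing_nm, 1e-6) / FWHM_SIGMA
    return 0.5 * (1.0 + erf((x - edge) / (s * math.sqrt(2.0))))


def make_broadband_spectrum(
    axis: SpectralAxis,
    lo_nm: float = 425.0,
    hi_nm: float = 685.0,
    edge_smoothing_nm: float = 25.0,
    shape: str = "raised-cosine",
) -> SourceSpectrum:
    """Broadband source spectrum over [lo, hi], normalized to unit power.

    Models the supercontinuum source band-filtered to the visible
    425-685 nm range. Two shapes are available:

    ``raised-cosine`` (default)
        A smooth unimodal band (Hann profile). Its axial PSF is free of
        ringing and has a Gaussian-fit FWHM of ~1.1 um over the default
        band — the class of axial resolution the real filtered
        supercontinuum system measures in air — which is why it is the
        simulator default: ground-truth B-scans then show no sidelobe
        artifacts, as real broadband acquisitions do.
    ``tophat``
        A flat plateau with erf edges rolled off over
        ``edge_smoothing_nm``. The idealized filter model; note that any
        near-flat band rings (a sharp top-hat's first PSF sidelobe is 22%),
        so isolated reflectors acquire visible secondary lobes.
    """
    lam = axis.wavelengths_nm
    if not (lam[0] <= lo_nm < hi_nm <= lam[-1]):
        raise ValueError(f"band [{lo_nm}, {hi_nm}] outside axis range "
                         f"[{lam[0]}, {lam[-1]}]")
    if shape == "raised-cosine":
        phase = (lam - lo_nm) / (hi_nm - lo_nm)
        dens = np.where((lam > lo_nm) & (lam < hi_nm),
                        0.5 * (1.0 - np.cos(2.0 * np.pi * phase)), 0.0)
    elif shape == "tophat":
        dens = _erf_step(lam, lo_nm, edge_smoothing_nm) * (
            1.0 - _erf_step(lam, hi_nm, edge_smoothing_nm)
        )
    else:
        raise ValueError(f"unknown spectral shape {shape!r}")
    power = np.trapezoid(dens, lam)
    if power <= 0:
        raise ValueError("degenerate band")
    return SourceSpectrum(axis, dens / power)


def make_gapped_window(
    axis: SpectralAxis, window: SpectralWindow | None = None
) -> SourceSpectrum:
    """Multiplier spectrum: a sum of Gaussian peaks on ``axis``.

    With the default two-peak window (510 nm / 10 nm and 635 nm / 6 nm) this
    is the synthetic discontinuous-source filter that is multiplied onto
    broadband fringes in post-processing. Values equal each peak's relative
    amplitude at its own center; the object is a multiplier, so it is not
    normalized.
    """
    window = window or SpectralWindow()
    lam = axis.wavelengths_nm
    vals = np.zeros_like(lam)
    for c, fw, a in window.peaks:
        if not (lam[0] <= c <= lam[-1]):
            raise ValueError(f"peak center {c} nm outside axis")
        s = fw / FWHM_SIGMA
        vals += a * np.exp(-((lam - c) ** 2) / (2.0 * s * s))
    return SourceSpectrum(axis, vals, is_window=True)


def apply_window(spectrum: SourceSpectrum, window: SourceSpectrum) -> SourceSpectrum:
    """Pointwise product of a spectrum with a spectral window.

    The product is deliberately NOT re-normalized: the power removed by the
    window is physically lost, exactly as when the discontinuous source
    replaces the broadband one.
    """
    if spectrum.axis.n_samples != window.axis.n_samples or not np.allclose(
        spectrum.axis.wavelengths_nm, window.axis.wavelengths_nm
    ):
        raise ValueError("spectrum and window must share the same axis")
    return SourceSpectrum(spectrum.axis, spectrum.density * window.density)


def resample_to_wavenumber(spectrum: SourceSpectrum, n_k: int | None = None):
    """Resample a wavelength-sampled density onto a uniform-k grid.

    Returns ``(k, S_k)`` with k ascending in rad/nm. Cubic interpolation
    mirrors the k-linearization step of spectrometer-based OCT processing.
    """
    lam = spectrum.axis.wavelengths_nm
    k_desc = 2.0 * np.pi / lam[::-1]
    dens = spectrum.density[::-1]
    n_k = n_k or lam.size
    k_uniform = np.linspace(k_desc[0], k_desc[-1], n_k)
    s_k = CubicSpline(k_desc, dens)(k_uniform)
    return k_uniform, np.clip(s_k, 0.0, None)


def coherence_from_k_density(k: np.ndarray, s_k: np.ndarray,
                             z_um: np.ndarray) -> np.ndarray:
    """Coherence function of a wavenumber-sampled density.

    gamma(z) = sum_k S(k) exp(i*2*k*z) dk with the round-trip phase
    convention; ``k`` in rad/nm, depths in um of optical path in air.
    """
    z_nm = np.asarray(z_um, dtype=float) * 1e3
    dk = k[1] - k[0]
    # Direct transform: modest sizes make the dense kernel affordable and
    # exact on an arbitrary depth grid.
    kernel = np.exp(2j * np.outer(z_nm, k))
    return kernel @ s_k * dk


def spectrum_to_psf(
    spectrum: SourceSpectrum,
    n_depth: int = 4001,
    depth_span_um: float = 120.0,
) -> AxialPSF:
    """Coherence function (axial PSF) of a source spectrum.

    The density is resampled to uniform wavenumber and transformed with the
    round-trip kernel exp(i*2*k*z) onto a symmetric depth grid spanning
    ``depth_span_um``. Depths are optical path in air (group index 1).
    """
    k, s_k = resample_to_wavenumber(spectrum)
    z_um = np.linspace(-depth_span_um / 2.0, depth_span_um / 2.0, n_depth)
    gamma = coherence_from_k_density(k, s_k, z_um)
    env = np.abs(gamma)
    # Containment check on the smoothed envelope level: the mean magnitude
    # over the outer 5% margins must have decayed below half the peak
    # (single edge samples can fool the check when a beat-fringe node
    # happens to sit at the boundary).
    margin = max(env.size // 20, 2)
    edge_level = 0.5 * (env[:margin].mean() + env[-margin:].mean())
    contained = bool(edge_level < 0.5 * env.max())
    if not contained:
        warnings.warn(
            "depth span does not contain the PSF main lobe", RuntimeWarning,
            stacklevel=2,
        )
    return AxialPSF(z_um, gamma, main_lobe_contained=contained)


def psf_energy_ratio(psf: AxialPSF, spectrum: SourceSpectrum) -> float:
    """Numerical check of the Parseval relation for the PSF transform.

    For the kernel exp(i*2*k*z), integral |gamma|^2 dz = pi * integral S^2 dk
    once the envelope has decayed inside the depth window. Returns the ratio
    of the two sides (1.0 when the relation holds).
    """
    k, s_k = resample_to_wavenumber(spectrum)
    lhs = np.trapezoid(psf.intensity_envelope**2, psf.depth_um * 1e3)
    rhs = np.pi * np.trapezoid(s_k**2, k)
    return float(lhs / rhs)


def gaussian_band_fwhm_um(center_nm: float, fwhm_nm: float) -> float:
    """Closed-form axial FWHM (um) of a single Gaussian band.

    The coherence-length formula (2*ln2/pi) * lambda^2 / delta_lambda for a
    Gaussian power spectrum of FWHM ``fwhm_nm`` centred at ``center_nm``.
    """
    return (2.0 * math.log(2.0) / math.pi) * center_nm**2 / fwhm_nm / 1e3


def fit_gaussian_fwhm(
    depth_um: np.ndarray,
    profile: np.ndarray,
    window_um: float | None = None,
    center_um: float | None = None,
) -> GaussianFitResult:
    """Least-squares Gaussian + constant-offset fit of an axial profile.

    The fit is performed on the linear-scale amplitude. ``window_um``
    restricts the fit to +-window_um/2 around the profile maximum (or around
    ``center_um`` when given). Deterministic for fixed input.

    Raises
    ------
    GaussianFitError
        If the profile is flat, has no interior maximum, or the optimizer
        fails to converge.
    """
    depth_um = np.asarray(depth_um, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if depth_um.shape != profile.shape or depth_um.ndim != 1:
        raise ValueError("depth and profile must be 1-D and aligned")
    span = profile.max() - profile.min()
    if not np.isfinite(span) or span <= 0:
        raise GaussianFitError("flat profile")
    c0 = center_um if center_um is not None else depth_um[int(np.argmax(profile))]
    if window_um is not None:
        half = window_um / 2.0
        sel = (depth_um >= c0 - half) & (depth_um <= c0 + half)
        if sel.sum() < 5:
            raise GaussianFitError("fit window contains fewer than 5 samples")
        depth_um, profile = depth_um[sel], profile[sel]
    i_max = int(np.argmax(profile))
    pitch = np.median(np.diff(depth_um))
    p0 = [profile[i_max] - profile.min(), depth_um[i_max],
          max(2.0 * pitch, 1e-3), profile.min()]

    def model(z, a, c, s, b):
        return a * np.exp(-((z - c) ** 2) / (2.0 * s * s)) + b

    try:
        popt, _ = curve_fit(model, depth_um, profile, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # no convergence
        raise GaussianFitError(str(exc)) from exc
    a, c, s, b = popt
    if a <= 0 or not np.isfinite(s):
        raise GaussianFitError("degenerate fit (non-positive amplitude)")
    resid = profile - model(depth_um, *popt)
    ss_tot = float(((profile - profile.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return GaussianFitResult(center=float(c), sigma=float(abs(s)),
                             offset=float(b), amplitude=float(a), r_squared=r2)


def expected_axial_fwhm_um(spectrum: SourceSpectrum) -> float:
    """Gaussian-fit FWHM of a spectrum's model PSF on a dense depth grid.

    Used to size fit windows for bead-resolution analysis: the expected
    axial width an isolated point reflector shows under this source.
    """
    psf = spectrum_to_psf(spectrum, n_depth=4001, depth_span_um=160.0)
    fit = fit_gaussian_fwhm(psf.depth_um, psf.intensity_envelope)
    return fit.fwhm


def sidelobe_peak_indices(profile: np.ndarray, rel_height: float = 0.1) -> np.ndarray:
    """Indices of secondary local maxima above ``rel_height`` of the global max.

    The global maximum itself (the main lobe) is excluded; everything else
    above the threshold counts as a sidelobe/ghost peak.
    """
    profile = np.asarray(profile, dtype=float)
    peaks, _ = find_peaks(profile, height=rel_height * profile.max())
    return peaks[peaks != int(np.argmax(profile))]
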