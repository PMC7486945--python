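"""Nuclei orientation from 2D images via the Fourier angular amplitude.

Elongated cardiomyocyte nuclei imprint an oriented texture on each image
slice.  The 2D power spectrum |F(kx, ky)|² of such a texture concentrates
along the direction perpendicular to the stripes, so summing spectral
power under a fan of wedge masks — one per orientation θi on a 0–180° grid
— yields an angular amplitude

    A(θi) = Σ_ky Σ_kx |F(kx, ky)|² · h_θi(kx, ky),

which, after a 90° spectral→spatial rotation, peaks at the dominant
*spatial* orientation.  A(θi) is normalized so its minimum is zero and its
trapezoidal area over θ (radians) is one, then summarized by the axial
circular mean (amplitude-weighted) and a least-squares bimodal von Mises
concentration fit.

Orientation convention: angles are measured in image coordinates from the
+x (column) axis toward the +y (row) axis, axially on [0°, 180°).  A Hann
window is applied before the transform to suppress the ±45° cross artifact
that hard image borders would otherwise leak into the wedge sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular_stats import (
    AngularSample,
    axial_mean,
    fit_kappa,
    standard_uncertainty,
)
from .io_core import DepthProfile, ImageStack, logger

__all__ = [
    "AngularSpectrum",
    "NucleiSlice",
    "NoSignalError",
    "angular_amplitude",
    "normalize_spectrum",
    "spectrum_mean",
    "nuclei_depth_profile",
]

MIN_IMAGE_SIZE = 64


class NoSignalError(ValueError):
    """The image carries no angular signal (e.g. constant intensity)."""


@dataclass
class NucleiSlice:
    """One grayscale nuclei image with its physical pixel size and depth."""

    image: np.ndarray       # 2D
    pixel_size_um: float
    depth_um: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, float)
        if self.image.ndim != 2:
            raise ValueError("nuclei slice must be a 2D image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


@dataclass
class AngularSpectrum:
    """Angular amplitude A(θi) on a 0–180° grid."""

    theta_deg: np.ndarray
    amplitude: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, float)
        self.amplitude = np.asarray(self.amplitude, float)
        if self.theta_deg.shape != self.amplitude.shape:
            raise ValueError("theta grid and amplitude must match")


def _wedge_index(theta_deg: np.ndarray, increment: float) -> np.ndarray:
    """Assign orientations to the wedge centred at the nearest grid angle.

    Wedges have half-width increment/2 and partition the half-plane; an
    orientation exactly on a wedge boundary goes to the lower θi.
    """
    n = int(round(180.0 / increment))
    # boundary θ = (k + 1/2)·inc belongs to wedge k (the lower center)
    idx = np.ceil(theta_deg / increment - 0.5 - 1e-12).astype(int)
    return np.mod(idx, n)


def angular_amplitude(slice_: NucleiSlice, increment_deg: float = 5.0) -> AngularSpectrum:
    """Wedge-mask angular amplitude of one image's power spectrum.

    The image is mean-subtracted and Hann-windowed, transformed with the
    2D FFT, and the power in every non-DC frequency bin is summed into the
    wedge (and its antipode) containing that bin's orientation.  Spectral
    orientations are rotated by 90° so the returned grid is in *spatial*
    orientation.  The result is normalized (min 0, unit trapezoidal area
    over θ in radians).
    """
    img = slice_.image
    if min(img.shape) < MIN_IMAGE_SIZE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIZE} px per side")
    if 180.0 % increment_deg != 0:
        raise ValueError("increment must divide 180")

    ny, nx = img.shape
    win = np.outer(np.hanning(ny), np.hanning(nx))
    f = np.fft.fft2((img - img.mean()) * win)
    power = np.abs(f) ** 2

    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    spectral_theta = np.degrees(np.arctan2(np.broadcast_to(ky, power.shape),
                                           np.broadcast_to(kx, power.shape)))
    # stripes at spatial angle θ put power at θ+90° in frequency space
    spatial_theta = np.mod(spectral_theta + 90.0, 180.0)

    # isotropic support: keep the inscribed frequency disc (and drop DC) so
    # every wedge integrates over the same spectral area — otherwise the
    # square corners systematically favour diagonal orientations
    k2 = kx**2 + ky**2
    keep = (k2 > 0) & (k2 <= 0.25)
    total = power[keep].sum()
    if total <= 0 or np.ptp(img) == 0:
        raise NoSignalError("constant image: no spectral power outside DC")

    n = int(round(180.0 / increment_deg))
    idx = _wedge_index(spatial_theta[keep].ravel(), increment_deg)
    amplitude = np.bincount(idx, weights=power[keep].ravel(), minlength=n)
    theta = np.arange(n) * increment_deg
    return normalize_spectrum(AngularSpectrum(theta_deg=theta, amplitude=amplitude))


def normalize_spectrum(spectrum: AngularSpectrum) -> AngularSpectrum:
    """Shift to zero minimum and scale to unit trapezoidal area over θ (rad).

    The grid is periodic, so the trapezoid is closed with A(180°) = A(0°).
    Idempotent: normalizing twice equals normalizing once.
    """
    a = spectrum.amplitude - spectrum.amplitude.min()
    theta = np.deg2rad(np.append(spectrum.theta_deg, 180.0))
    area = np.trapezoid(np.append(a, a[0]), theta)
    if area <= 0:
        raise NoSignalError("spectrum is flat; cannot normalize")
    return AngularSpectrum(spectrum.theta_deg.copy(), a / area, normalized=True)


def spectrum_mean(spectrum: AngularSpectrum) -> tuple[float, float, float]:
    """Mean orientation, concentration and uncertainty of a spectrum.

    The mean is the axial circular mean of the grid angles weighted by
    A(θi); κ is the least-squares bimodal von Mises fit to the normalized
    amplitude; u is the standard uncertainty of that fitted distribution.
    Antipodal spectra (resultant length ≈ 0) have no defined mean and are
    flagged with NaN.
    """
    if not spectrum.normalized:
        spectrum = normalize_spectrum(spectrum)
    mean, r = axial_mean(AngularSample(spectrum.theta_deg, weights=spectrum.amplitude))
    if not np.isfinite(mean):
        return float("nan"), float("nan"), float("nan")
    kappa, _ = fit_kappa(spectrum.theta_deg, spectrum.amplitude, mean)
    return mean, kappa, standard_uncertainty(kappa)


def nuclei_depth_profile(
    stack: ImageStack, increment_deg: float = 5.0
) -> DepthProfile:
    """Per-slice orientation summary of a nuclei z-stack.

    Each slice is analyzed independently (nuclei orientation is a 2D
    quantity) and the per-slice means assembled into a depth profile over
    the slice z positions.  Slices with no signal are kept as NaN rows; if
    every slice is flagged, the profile is empty and an error is raised.
    """
    nz = stack.shape[0]
    if nz == 0:
        raise ValueError("empty stack")
    px = stack.voxel_size[0]
    depths, means, kappas, us = [], [], [], []
    n_ok = 0
    for k in range(nz):
        depths.append(stack.slice_depth_um(k))
        try:
            spec = angular_amplitude(
                NucleiSlice(stack.data[k], px, depths[-1]), increment_deg
            )
            mu, kappa, u = spectrum_mean(spec)
            n_ok += int(np.isfinite(mu))
        except NoSignalError:
            mu = kappa = u = float("nan")
            logger.warning("slice %d flagged no-signal", k)
        means.append(mu)
        kappas.append(kappa)
        us.append(u)
    if n_ok == 0:
        raise NoSignalError("every slice flagged no-signal; empty profile")
    return DepthProfile(
        depth=np.asarray(depths),
        mean_deg=np.asarray(means),
        kappa=np.asarray(kappas),
        u_deg=np.asarray(us),
        n=np.isfinite(np.asarray(means)).astype(int),
    )
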