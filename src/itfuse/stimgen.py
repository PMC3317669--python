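"""Weighted mean phase mixing of grayscale images.

Stimulus informativeness is manipulated by mixing an image's Fourier phase
spectrum with the phase spectrum of a Gaussian noise image while keeping
the amplitude spectrum untouched.  The mixed phase is the circular
(vector-resultant) weighted mean

    phi_final = arg( w * exp(i phi_orig) + (1 - w) * exp(i phi_noise) )

with the signal-to-noise weighting coefficient w in [0, 1]: w = 1 returns
the original image, w = 0 a fully phase-scrambled image with the same
amplitude spectrum.  The noise phase is taken from the FFT of a real
Gaussian noise image, so it carries conjugate (Hermitian) symmetry and the
mixed spectrum always corresponds to a real image; the DC phase is held at
the original's, preserving mean luminance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._streams import substream

__all__ = ["StimulusMixSpec", "weighted_phase_mix", "to_uint8", "mix_series"]


@dataclass(frozen=True)
class StimulusMixSpec:
    """An image (square, even-sized, grayscale) with mixing weight and noise seed."""

    image: np.ndarray
    w: float
    seed: int = 0

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError(f"image must be square 2-d, got shape {img.shape}")
        if img.shape[0] % 2:
            raise ValueError(f"image size must be even, got {img.shape[0]}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"weighting coefficient w={self.w} outside [0, 1]")
        object.__setattr__(self, "image", img)


def weighted_phase_mix(spec: StimulusMixSpec) -> np.ndarray:
    """Mix image phase with noise phase at weight ``spec.w``; float output.

    The returned array is the real part of the inverse transform of
    (original amplitude, circularly mixed phase); apply :func:`to_uint8`
    for an 8-bit image.
    """
    img = spec.image
    rng = substream(spec.seed, "phase_noise")
    F = np.fft.fft2(img)
    amplitude = np.abs(F)
    phi_orig = np.angle(F)
    noise = rng.standard_normal(img.shape)
    phi_noise = np.angle(np.fft.fft2(noise))

    resultant = spec.w * np.exp(1j * phi_orig) + (1.0 - spec.w) * np.exp(1j * phi_noise)
    phi_final = np.angle(resultant)
    phi_final[0, 0] = phi_orig[0, 0]  # keep DC -> mean luminance preserved
    mixed = amplitude * np.exp(1j * phi_final)
    return np.fft.ifft2(mixed).real


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a float image to 8 bit by rounding and clipping to [0, 255]."""
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def mix_series(image: np.ndarray, ws, seed: int = 0) -> dict[float, np.ndarray]:
    """Phase-mix ``image`` at several weights with a shared noise draw."""
    return {float(w): weighted_phase_mix(StimulusMixSpec(image, float(w), seed)) for w in ws}
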