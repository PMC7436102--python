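"""Procedural albedo textures.

Textures are deterministic functions of world coordinates keyed by an
integer id, so the same surface point receives the same colour in every
view — exactly what block matching needs. Wavelengths are kept above ~6 mm
so the synthetic renderer does not alias at the default pixel footprint
(~1.2 mm on the table).
"""

from __future__ import annotations

import colorsys

import numpy as np

_N_WAVES = 6


def class_base_color(index: int, n_classes: int = 16) -> np.ndarray:
    """Distinct, saturated base colour for a food class (hue wheel)."""
    hue = (index % n_classes) / float(n_classes)
    r, g, b = colorsys.hsv_to_rgb(hue, 0.65, 0.75)
    return np.array([r, g, b])


class ProceduralTexture:
    """Sum-of-sinusoids albedo pattern around a base colour."""

    def __init__(
        self,
        tex_id: int,
        base_rgb,
        amplitude: float = 0.15,
        min_wavelength_mm: float = 6.0,
        max_wavelength_mm: float = 18.0,
    ):
        self.tex_id = int(tex_id)
        self.base_rgb = np.asarray(base_rgb, dtype=float)
        self.amplitude = float(amplitude)
        rng = np.random.default_rng(0xD1E7 + self.tex_id)
        wavelengths = rng.uniform(min_wavelength_mm, max_wavelength_mm, _N_WAVES)
        angles = rng.uniform(0.0, np.pi, _N_WAVES)
        self._freq = (
            2.0 * np.pi / wavelengths[:, None]
            * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        )
        self._phase = rng.uniform(0.0, 2.0 * np.pi, _N_WAVES)
        self._weights = rng.uniform(0.5, 1.0, _N_WAVES)
        self._weights /= self._weights.sum()
        # per-channel gains decorrelate the channels a little
        self._gains = rng.uniform(0.6, 1.0, 3)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate albedo at world coordinates (mm); returns (..., 3)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pattern = np.zeros(x.shape)
        for k in range(_N_WAVES):
            pattern += self._weights[k] * np.sin(
                self._freq[k, 0] * x + self._freq[k, 1] * y + self._phase[k]
            )
        rgb = (
            self.base_rgb
            + self.amplitude * pattern[..., None] * self._gains
        )
        return np.clip(rgb, 0.0, 1.0)
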