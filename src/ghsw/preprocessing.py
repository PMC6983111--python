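"""Per-pixel spectrum normalization.

Normalization removes unwanted intensity variation — chiefly optical
path-length differences from root thickness (samples are 15–20 mm) — while
keeping spectral shape.  Three methods operate on each foreground pixel's
spectrum ``x`` independently:

=======  ==========================================
range    ``(x - min x) / (max x - min x)`` -> [0, 1]
max      ``x / max x``                      -> max 1
mean     ``x / mean x``                     -> mean 1
=======  ==========================================

Range normalization is the default.  Degenerate spectra (zero range, or a
non-positive max/mean) are set to all-zeros and counted rather than raised,
so a few dead pixels cannot abort a run; more than 5% degenerate foreground
pixels indicates a systematic problem and is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ghsw.hypercube_io import HyperCube, SampleMask, GeometryError

_METHODS = ("range", "max", "mean")


@dataclass
class NormalizationConfig:
    """Choice of per-pixel-spectrum normalization method."""

    method: str = "range"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got '{self.method}'")


def normalize(
    cube: HyperCube,
    mask: SampleMask,
    config: NormalizationConfig | None = None,
    max_degenerate_fraction: float = 0.05,
) -> HyperCube:
    """Normalize every foreground pixel spectrum; background is untouched.

    Returns a new cube with ``meta['normalization']`` set to the method and
    ``meta['n_degenerate']`` counting zeroed degenerate spectra.  Raises if
    more than ``max_degenerate_fraction`` of foreground pixels are
    degenerate.
    """
    config = config or NormalizationConfig()
    if mask.mask.shape != cube.spatial_shape:
        raise GeometryError(
            f"mask shape {mask.mask.shape} != cube spatial shape {cube.spatial_shape}"
        )
    if mask.n_foreground == 0:
        raise ValueError("mask has no foreground pixels")

    spectra = cube.values[mask.mask].astype(float)  # (n_fg, bands)
    if config.method == "range":
        lo = spectra.min(axis=1, keepdims=True)
        hi = spectra.max(axis=1, keepdims=True)
        span = hi - lo
        degenerate = span[:, 0] == 0
        span[degenerate] = 1.0
        out = (spectra - lo) / span
    elif config.method == "max":
        hi = spectra.max(axis=1, keepdims=True)
        degenerate = hi[:, 0] <= 0
        hi[degenerate] = 1.0
        out = spectra / hi
    else:  # mean
        mu = spectra.mean(axis=1, keepdims=True)
        degenerate = mu[:, 0] <= 0
        mu[degenerate] = 1.0
        out = spectra / mu
    out[degenerate] = 0.0

    # a lone dead pixel is always tolerated; the budget guards against
    # systematic degeneracy, not small masks
    n_deg = int(degenerate.sum())
    if n_deg > max(1.0, max_degenerate_fraction * mask.n_foreground):
        raise ValueError(
            f"{n_deg} of {mask.n_foreground} foreground spectra are degenerate "
            f"(> {100 * max_degenerate_fraction:.0f}% budget) under "
            f"{config.method} normalization"
        )

    values = cube.values.astype(float).copy()
    values[mask.mask] = out
    meta = dict(cube.meta)
    meta.update(normalization=config.method, n_degenerate=n_deg)
    return HyperCube(values=values, wavelengths=cube.wavelengths.copy(), meta=meta)
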