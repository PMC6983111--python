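"""Two-band ratio imaging, threshold binarization, percent-whitening score.

Whitened central tissue is optically denser than healthy tissue and
attenuates transmittance far more strongly near 1326 nm than near 950 nm,
so the pixelwise band ratio

    R(x, y) = T(x, y; 950 nm) / T(x, y; 1326 nm)

lights up whitened regions while cancelling path-length (root thickness)
effects — scaling a pixel's whole spectrum leaves R unchanged.  The ratio
image is binarized at a fixed threshold T (default 5, inclusive ``>=``),
chosen in the source workflow from a 3-D mesh plot of pixel intensity, and
the severity of whitening per root is the percentage of whitening pixels
among all root pixels:

    Tp = Wp + Hp,      Pwp = 100 * Wp / Tp.

The ratio is computed on *calibrated* transmittance, not on per-spectrum
normalized data: range normalization rescales every spectrum into [0, 1]
and would destroy the absolute contrast that a fixed threshold of 5 relies
on.  Normalization belongs to the PCA path only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ghsw.hypercube_io import HyperCube, SampleMask, GeometryError


@dataclass
class DetectionConfig:
    """Parameters of ratio-image whitening detection.

    lambda_num / lambda_den
        Numerator and denominator wavelengths in nm (defaults 950 / 1326,
        the two most differentiating wavebands); the nearest band center
        on the cube's grid is used and recorded in the report.
    threshold
        Ratio cutoff T; a pixel is whitening iff its ratio >= T.
    min_region_pixels
        Connected whitening components smaller than this are removed as
        speckle (4-connectivity); 0 disables the filter.
    epsilon
        Denominator transmittance below this excludes the pixel.
    """

    lambda_num: float = 950.0
    lambda_den: float = 1326.0
    threshold: float = 5.0
    min_region_pixels: int = 5
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_num == self.lambda_den:
            raise ValueError("numerator and denominator wavelengths must differ")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_region_pixels < 0:
            raise ValueError("min_region_pixels must be >= 0")


@dataclass
class WhiteningReport:
    """Pixel counts and percent whitening for one root.

    Invariants ``Tp = Wp + Hp`` and ``Pwp = 100 * Wp / Tp`` hold exactly.
    """

    Wp: int
    Hp: int
    Tp: int
    Pwp: float
    outlier_flag: bool = False
    band_num_nm: float | None = None
    band_den_nm: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.Tp != self.Wp + self.Hp:
            raise ValueError(f"Tp={self.Tp} != Wp+Hp={self.Wp + self.Hp}")
        expected = 100.0 * self.Wp / self.Tp
        if abs(self.Pwp - expected) > 1e-9:
            raise ValueError(f"Pwp={self.Pwp} != 100*Wp/Tp={expected}")


def ratio_image(
    cube: HyperCube, mask: SampleMask, config: DetectionConfig | None = None
) -> np.ndarray:
    """Pixelwise two-band ratio over the foreground; background is NaN.

    Foreground pixels whose denominator transmittance is below
    ``config.epsilon`` are excluded (set to NaN) and counted in
    ``cube.meta['n_ratio_excluded']``.
    """
    config = config or DetectionConfig()
    if mask.mask.shape != cube.spatial_shape:
        raise GeometryError("mask/cube spatial shape mismatch")
    b_num = cube.band_index(config.lambda_num)
    b_den = cube.band_index(config.lambda_den)
    num = cube.values[:, :, b_num].astype(float)
    den = cube.values[:, :, b_den].astype(float)

    out = np.full(cube.spatial_shape, np.nan)
    fg = mask.mask
    bad = fg & (np.abs(den) < config.epsilon)
    ok = fg & ~bad
    out[ok] = num[ok] / den[ok]
    cube.meta["n_ratio_excluded"] = int(bad.sum())
    cube.meta["ratio_bands_nm"] = (
        float(cube.wavelengths[b_num]),
        float(cube.wavelengths[b_den]),
    )
    return out


def threshold_binary(
    image: np.ndarray, mask: SampleMask, config: DetectionConfig | None = None
) -> np.ndarray:
    """Binarize a ratio image at T (inclusive) and remove small speckle.

    A foreground pixel maps to True iff its ratio >= T; connected
    components (4-connectivity) smaller than ``min_region_pixels`` are
    dropped.  Background and excluded (NaN) pixels map to False.
    """
    config = config or DetectionConfig()
    if image.shape != mask.mask.shape:
        raise GeometryError("ratio image and mask are not aligned")
    with np.errstate(invalid="ignore"):
        binary = mask.mask & (image >= config.threshold)
    if config.min_region_pixels > 0 and binary.any():
        labels, n = ndimage.label(binary)  # 4-connectivity default
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= config.min_region_pixels) + 1
        binary = np.isin(labels, keep)
    return binary


def whitening_percentage(
    binary: np.ndarray, mask: SampleMask, config: DetectionConfig | None = None
) -> WhiteningReport:
    """Count whitening vs healthy pixels and compute percent whitening.

    ``binary`` must be a subset of the foreground mask.  Counts use exact
    integer arithmetic.
    """
    if mask.n_foreground == 0:
        raise ValueError("empty mask: no foreground pixels to score")
    if binary.shape != mask.mask.shape:
        raise GeometryError("binary map and mask are not aligned")
    if np.any(binary & ~mask.mask):
        raise ValueError("binary whitening map extends outside the foreground mask")
    wp = int(np.count_nonzero(binary))
    tp = int(mask.n_foreground)
    hp = tp - wp
    kwargs = {}
    if config is not None:
        kwargs = dict(
            band_num_nm=config.lambda_num,
            band_den_nm=config.lambda_den,
            threshold=config.threshold,
        )
    return WhiteningReport(Wp=wp, Hp=hp, Tp=tp, Pwp=100.0 * wp / tp, **kwargs)


def sigma3_screen(values) -> np.ndarray:
    """Three-sigma outlier screen over per-sample percent-whitening values.

    A value is flagged iff |value - mean| > 3 * sd, with mean and sd
    (population sd) computed once over all values — a single pass with no
    re-iteration after removing flagged points.  Requires at least three
    values; zero sd flags nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"3-sigma screen needs >= 3 values, got {values.size}")
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - mu) > 3.0 * sd


def mesh_plot_data(image: np.ndarray, mask: SampleMask) -> pd.DataFrame:
    """Tabulate a ratio image as (x, y, intensity) records for surface plots.

    One record per pixel: ``x`` = column, ``y`` = row, ``intensity`` = the
    ratio value, NaN for background/masked pixels.  Feed to any 3-D mesh
    or surface plotting routine to eyeball where the whitened-pixel
    intensity mode sits relative to the threshold.
    """
    if image.shape != mask.mask.shape:
        raise GeometryError("image and mask are not aligned")
    rows, cols = image.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    intensity = np.where(mask.mask, image, np.nan)
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "intensity": intensity.ravel()}
    )
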