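"""Synthetic ginseng phantom hypercubes with planted whitening ground truth.

No public hyperspectral dataset of ginseng inner whitening exists, so this
module generates raw transmittance hypercubes plus dark/white references
that emulate the real acquisition geometry: an elliptical root silhouette
on a bright glass-plate background, smooth transmittance spectra with
ginsenoside-associated absorption dips near 950, 1110 and 1326 nm, and —
in abnormal phantoms — a central whitened region of known area fraction
whose transmittance is attenuated inside the 900–1050 nm and 1150–1400 nm
windows where whitened tissue is optically denser.

The spectral model is phenomenological, not radiative transfer:

* baseline: transmittance falling roughly linearly from 900 to 1700 nm
  with a per-pixel convex curvature term (tissue-scattering spread, the
  dominant common-mode variation and hence the first principal
  component);
* absorption: Gaussian dips at the three characteristic centers, each
  depth varying pixel-to-pixel (ginsenoside concentration), strongest at
  1110 nm;
* whitening: multiplicative attenuation inside the two windows, shaped
  as smooth bumps whose realized contrast — after calibration and range
  normalization — peaks at the 950 and 1326 nm characteristic bands: a
  mild factor (~0.8) in the 900–1050 nm window and a strong one (~0.24)
  in the 1150–1400 nm window, so the 950/1326 band ratio of whitened
  tissue rises well above the detection threshold of 5 while normal
  tissue stays near 2;
* thickness: a smooth elliptical dome scaling each pixel's whole spectrum
  (thicker center transmits less), plus mild per-pixel scatter — both
  cancel in the band ratio and under range normalization;
* noise: multiplicative Gaussian on sample-pixel transmittance
  (default sd 1%, shot-noise-like); a constant dark-current offset per
  band; references are returned noiseless.

Identical seeds give byte-identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ghsw.hypercube_io import HyperCube, ReferencePair, SampleMask


@dataclass
class SpectralModel:
    """Parameters of the phantom transmittance spectrum.

    The baseline falls roughly linearly from ``baseline_start`` at 900 nm
    to ``baseline_end`` at 1700 nm (water absorption rises towards the
    long-wave end), with a per-pixel convex curvature term standing in
    for tissue-scattering differences.  Gaussian dips sit at the three
    characteristic centers; whitening multiplies the spectrum by
    ``1 - depth * bump`` inside each window, with a mild bump at 950 nm
    and a strong one at 1326 nm — whitened tissue darkens far more in the
    1150–1400 nm window, which is what the 950/1326 band ratio exploits.
    """

    baseline_start: float = 0.60  # transmittance at 900 nm
    baseline_end: float = 0.05  # transmittance at 1700 nm
    curvature_mean: float = 0.05  # convex bowing, transmittance units
    curvature_sd: float = 0.06  # per-pixel spread of the bowing
    curvature_center_nm: float = 1300.0
    dip_centers_nm: tuple[float, ...] = (950.0, 1110.0, 1326.0)
    dip_depths: tuple[float, ...] = (0.04, 0.06, 0.04)
    dip_sigmas_nm: tuple[float, ...] = (25.0, 30.0, 25.0)
    # whitening attenuation: smooth bumps inside the two windows
    whitening_windows_nm: tuple[tuple[float, float], ...] = (
        (900.0, 1050.0),
        (1150.0, 1400.0),
    )
    whitening_bump_centers_nm: tuple[float, ...] = (950.0, 1330.0)
    whitening_bump_depths: tuple[float, ...] = (0.20, 0.76)
    whitening_bump_sigmas_nm: tuple[float, ...] = (30.0, 30.0)

    def __post_init__(self) -> None:
        for d in self.whitening_bump_depths:
            if not (0.0 <= d < 1.0):
                raise ValueError(
                    f"whitening attenuation factor 1-{d} outside (0, 1]"
                )


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic ginseng sample.

    Defaults are half the instrument resolution (160 x 250 of 320 x 500)
    with the full 168-band 900–1700 nm axis; ``whitening_fraction`` is the
    target fraction of sample pixels inside the planted whitened ellipse
    (0 for a normal root).  The whitening ellipse is concentric with the
    sample ellipse and sized by bisection so the realized pixel fraction
    matches the target to within pixelation.
    """

    spatial_shape: tuple[int, int] = (160, 250)
    n_bands: int = 168
    wavelength_range_nm: tuple[float, float] = (900.0, 1700.0)
    sample_axes_fraction: tuple[float, float] = (0.40, 0.44)  # of rows, cols
    whitening_fraction: float = 0.0
    spectral: SpectralModel = field(default_factory=SpectralModel)
    thickness_dome: float = 0.35  # edge-to-center transmittance swing
    dip1110_depth_sd: float = 0.35  # relative sd of the 1110 nm dip depth
    dip_other_depth_sd: float = 0.08
    noise_sd: float = 0.01
    dark_level: float = 100.0
    white_level: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.whitening_fraction < 1.0):
            raise ValueError("whitening_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.white_level <= self.dark_level:
            raise ValueError("white_level must exceed dark_level")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.linspace(lo, hi, self.n_bands)


@dataclass
class GroundTruth:
    """Planted geometry of a phantom: what the pipeline should recover."""

    sample_mask: SampleMask
    whitening_mask: np.ndarray  # boolean, subset of sample_mask
    target_fraction: float
    actual_fraction: float


def _ellipse_mask(shape: tuple[int, int], semi_axes: tuple[float, float]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = semi_axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _normalized_radius2(shape: tuple[int, int], semi_axes: tuple[float, float]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = semi_axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2


def _baseline(spec: PhantomSpec, curvature) -> np.ndarray:
    """Baseline transmittance for scalar or per-pixel curvature values."""
    wl = spec.wavelengths
    m = spec.spectral
    u = (wl - spec.wavelength_range_nm[0]) / (
        spec.wavelength_range_nm[1] - spec.wavelength_range_nm[0]
    )
    linear = m.baseline_start + (m.baseline_end - m.baseline_start) * u
    quad = ((wl - m.curvature_center_nm) / 400.0) ** 2
    curvature = np.asarray(curvature, dtype=float)
    if curvature.ndim == 0:
        return linear + float(curvature) * quad
    return linear[None, :] + curvature[:, None] * quad[None, :]


def _whitening_attenuation(spec: PhantomSpec) -> np.ndarray:
    """Per-band multiplicative attenuation of whitened tissue, in (0, 1]."""
    wl = spec.wavelengths
    m = spec.spectral
    att = np.ones_like(wl)
    for (lo, hi), c, d, s in zip(
        m.whitening_windows_nm,
        m.whitening_bump_centers_nm,
        m.whitening_bump_depths,
        m.whitening_bump_sigmas_nm,
    ):
        window = (wl >= lo) & (wl <= hi)
        bump = d * np.exp(-0.5 * ((wl - c) / s) ** 2)
        att = att * np.where(window, 1.0 - bump, 1.0)
    return att


def generate_spectrum(spec: PhantomSpec, whitened: bool = False) -> np.ndarray:
    """Mean (noiseless) transmittance spectrum of normal or whitened tissue.

    Baseline minus Gaussian absorption dips; whitened tissue is further
    attenuated inside the two whitening windows.  Values are clipped to
    (0, 1].
    """
    wl = spec.wavelengths
    m = spec.spectral
    t = _baseline(spec, m.curvature_mean)
    for c, d, s in zip(m.dip_centers_nm, m.dip_depths, m.dip_sigmas_nm):
        t = t - d * np.exp(-0.5 * ((wl - c) / s) ** 2)
    if whitened:
        t = t * _whitening_attenuation(spec)
    return np.clip(t, 1e-4, 1.0)


def _fit_whitening_axes(
    sample_mask: np.ndarray,
    sample_axes: tuple[float, float],
    shape: tuple[int, int],
    target_fraction: float,
) -> tuple[np.ndarray, float]:
    """Concentric ellipse sized by bisection to the target pixel fraction."""
    n_sample = int(sample_mask.sum())
    target_pixels = target_fraction * n_sample
    lo, hi = 0.0, 1.0
    best_mask = np.zeros_like(sample_mask)
    for _ in range(40):
        s = 0.5 * (lo + hi)
        mask = _ellipse_mask(shape, (s * sample_axes[0], s * sample_axes[1]))
        count = int(mask.sum())
        if count < target_pixels:
            lo = s
        else:
            hi = s
            best_mask = mask
    # hi is the smallest scale reaching the target; compare with lo side
    mask_lo = _ellipse_mask(shape, (lo * sample_axes[0], lo * sample_axes[1]))
    if abs(int(mask_lo.sum()) - target_pixels) < abs(int(best_mask.sum()) - target_pixels):
        best_mask = mask_lo
    best_mask = best_mask & sample_mask
    return best_mask, best_mask.sum() / n_sample


def generate_cube(spec: PhantomSpec) -> tuple[HyperCube, ReferencePair, GroundTruth]:
    """Generate one raw phantom hypercube with references and ground truth.

    Background pixels hold the white-reference counts exactly (glass
    plate); sample pixels hold ``t * (white - dark) + dark`` where ``t``
    is the pixel's noisy transmittance spectrum.  References are
    per-line frames (col x band, noiseless) with a smooth illumination
    profile across columns, matching line-scan acquisition.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.spatial_shape
    wl = spec.wavelengths
    n_bands = spec.n_bands

    sample_axes = (
        spec.sample_axes_fraction[0] * rows,
        spec.sample_axes_fraction[1] * cols,
    )
    sample_mask = _ellipse_mask(spec.spatial_shape, sample_axes)
    if spec.whitening_fraction > 0:
        whitening_mask, actual = _fit_whitening_axes(
            sample_mask, sample_axes, spec.spatial_shape, spec.whitening_fraction
        )
        if not np.all(sample_mask[whitening_mask]):
            raise ValueError("whitening ellipse exceeds the sample ellipse")
    else:
        whitening_mask = np.zeros_like(sample_mask)
        actual = 0.0

    # references: smooth illumination profile across the scan line
    col_profile = 1.0 - 0.15 * (np.linspace(-1, 1, cols) ** 2)
    white = spec.white_level * col_profile[:, None] * np.ones((cols, n_bands))
    dark = np.full((cols, n_bands), spec.dark_level)
    refs = ReferencePair(dark=dark, white=white)

    # per-pixel transmittance of the sample
    fg = np.nonzero(sample_mask)
    n_fg = len(fg[0])
    m = spec.spectral
    curvature = np.clip(
        rng.normal(m.curvature_mean, m.curvature_sd, size=n_fg), 0.0, 0.12
    )
    spectra = _baseline(spec, curvature)
    depth_sds = (spec.dip_other_depth_sd, spec.dip1110_depth_sd, spec.dip_other_depth_sd)
    for (c, d, s), rel_sd in zip(
        zip(m.dip_centers_nm, m.dip_depths, m.dip_sigmas_nm), depth_sds
    ):
        g = np.clip(rng.normal(1.0, rel_sd, size=n_fg), 0.2, 1.8)
        spectra -= (d * g)[:, None] * np.exp(-0.5 * ((wl - c) / s) ** 2)

    whitened_rows = whitening_mask[fg]
    if whitened_rows.any():
        spectra[whitened_rows] *= _whitening_attenuation(spec)

    # thickness dome + mild per-pixel scatter: whole-spectrum scaling
    e2 = _normalized_radius2(spec.spatial_shape, sample_axes)[fg]
    thickness = (1.0 - spec.thickness_dome * (1.0 - e2)) * np.clip(
        rng.normal(1.0, 0.05, size=n_fg), 0.75, 1.25
    )
    spectra *= thickness[:, None]

    if spec.noise_sd > 0:
        spectra *= 1.0 + spec.noise_sd * rng.standard_normal(spectra.shape)
    spectra = np.clip(spectra, 1e-4, 1.0)

    # assemble raw counts: background = white reference, sample = t*(w-d)+d
    values = np.broadcast_to(white, (rows, cols, n_bands)).copy()
    gain = white[fg[1], :] - dark[fg[1], :]
    values[fg] = spectra * gain + dark[fg[1], :]

    cube = HyperCube(
        values=values,
        wavelengths=wl,
        meta={
            "phantom": True,
            "seed": spec.seed,
            "target_whitening_fraction": spec.whitening_fraction,
            "actual_whitening_fraction": float(actual),
        },
    )
    truth = GroundTruth(
        sample_mask=SampleMask(mask=sample_mask),
        whitening_mask=whitening_mask,
        target_fraction=spec.whitening_fraction,
        actual_fraction=float(actual),
    )
    return cube, refs, truth


def fixture_library() -> dict[str, PhantomSpec]:
    """Named phantom fixtures with frozen seeds and planted fractions.

    S1/S3/S4 carry the reference whitened-area fractions (48.18%, 53.14%,
    37.66%); two normal phantoms have no whitening; a sweep covers 10, 25
    and 50%.  Every fixture regenerates byte-identically from its stored
    seed.
    """
    return {
        "S1": PhantomSpec(whitening_fraction=0.4818, seed=101),
        "S3": PhantomSpec(whitening_fraction=0.5314, seed=103),
        "S4": PhantomSpec(whitening_fraction=0.3766, seed=104),
        "normal_1": PhantomSpec(whitening_fraction=0.0, seed=201),
        "normal_2": PhantomSpec(whitening_fraction=0.0, seed=202),
        "sweep_10": PhantomSpec(whitening_fraction=0.10, seed=301),
        "sweep_25": PhantomSpec(whitening_fraction=0.25, seed=302),
        "sweep_50": PhantomSpec(whitening_fraction=0.50, seed=303),
    }


def phantom_ensemble(
    n_normal: int = 6,
    n_abnormal: int = 6,
    base_seed: int = 1,
    spatial_shape: tuple[int, int] = (80, 125),
) -> list[tuple[str, PhantomSpec]]:
    """Normal + abnormal phantom set for PCA waveband-selection studies.

    Seeds run ``base_seed .. base_seed + n_normal + n_abnormal - 1``;
    abnormal whitened fractions cycle through moderate-to-heavy values.
    The reduced default spatial size keeps ensemble PCA fast; the
    spectral model is the library default.
    """
    fractions = [0.35, 0.40, 0.45, 0.48, 0.50, 0.53]
    out: list[tuple[str, PhantomSpec]] = []
    seed = base_seed
    for i in range(n_normal):
        out.append(
            (f"normal_{i + 1}", PhantomSpec(spatial_shape=spatial_shape, seed=seed))
        )
        seed += 1
    for i in range(n_abnormal):
        out.append(
            (
                f"abnormal_{i + 1}",
                PhantomSpec(
                    spatial_shape=spatial_shape,
                    whitening_fraction=fractions[i % len(fractions)],
                    seed=seed,
                ),
            )
        )
        seed += 1
    return out
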