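# Methods

## Processing model

`ghsw` analyses NIR transmittance hypercubes `(row, col, band)` with a
strictly increasing wavelength axis (defaults mirror a line-scan
instrument: 168 bands over 900–1700 nm, ~4.79 nm spacing; the scan axis
is rows, pixel indexing is 0-based row/col).

**Calibration.** `T = (R − D)/(B − D)` per element. References may be
full cubes or per-line `(col, band)` frames broadcast along the scan
axis, matching pushbroom acquisition. The formula gives no guidance at
dead detector elements, so pixels with `|B − D| < ε` (default `ε` =
1e−6 of the white reference's dynamic range) are set to 0 and counted in
the cube's metadata rather than propagating infinities. Outputs satisfy
`calibrate(B) = 1` and `calibrate(D) = 0` exactly, and are invariant to a
common positive gain applied to raw and references.

**Background segmentation.** Foreground is `mean_band(T) < threshold`
(default 0.85 — the source workflow used a binary threshold but did not
state its value, so it is a configurable parameter here). Only the
largest 4-connected component is kept; everything else is speckle.

**Normalization.** Applied per foreground pixel spectrum, never
globally: the dominant nuisance is optical path length (root thickness,
15–20 mm), which is a per-pixel effect. Range `(x−min)/(max−min)`,
max `x/max`, and mean `x/mean` are provided; range is the default.
Degenerate spectra (zero range, non-positive max/mean) are zeroed and
counted; a single degenerate pixel is always tolerated, and more than 5%
of the foreground aborts the run as evidence of a systematic problem,
not dead pixels.

**PCA waveband selection.** Masked cubes are unfolded to a pixels × bands
matrix (rows stacked sample-by-sample, row-major within a sample, with
an invertible pixel index). PCA is mean-centered with no variance
scaling, the standard choice for spectra on a common scale; the
decomposition is delegated to scikit-learn's full-SVD PCA and checked in
the test suite against an independent dense eigendecomposition of the
covariance matrix (1e−8 agreement on eigenvalues and |loadings|, and
exact-rank reconstruction). Loading-column signs are fixed by making
each column's largest-|value| element positive, so score images are
reproducible (whitened region bright, not randomly bright-or-dark).
Characteristic wavebands are the `n` local extrema of a loading vector
with the largest |loading|; a local extremum must strictly exceed both
neighbours (endpoints compare to their single neighbour, plateaus are
represented by their first index, and |loading| ties break toward the
lower wavelength). Which component discriminates whitening is a
configurable 1-based component number (default 2); `rank_components`
orders components by the standardized score difference between abnormal
and normal samples as a data-driven helper, and the pipeline uses it
when group labels are available.

**Band ANOVA.** One observation per root (the per-sample mean foreground
spectrum), never per pixel — pixels within one root are strongly
correlated, and pixel-level ANOVA would overstate significance. `F` is
computed from the between/within sums of squares with df `(k−1, N−k)`;
only the F-distribution tail probability comes from scipy. Zero
within-group variance yields the `(inf, 0)` sentinel for separated means
and `(0, 1)` for identical constant groups.

**Detection.** The two-band ratio (default 950 nm over 1326 nm, nearest
band centers used and recorded) is computed on *calibrated*
transmittance, not normalized spectra: range normalization rescales each
spectrum into [0, 1] and would destroy the absolute contrast a fixed
threshold relies on. The ratio itself already removes thickness effects
— it is invariant under per-pixel scaling of the spectrum. Binarization
uses the inclusive rule `g = 1 iff ratio ≥ T` with `T = 5` by default;
4-connected whitening components smaller than `min_region_pixels`
(default 5, settable to 0) are removed, a concrete remedy for the stray
unidentifiable pixels that appear at low whitening severity. Counts are
exact integers with `Tp = Wp + Hp` and `Pwp = 100·Wp/Tp` by
construction. The 3σ screen flags `|x − mean| > 3·sd` with mean and
population sd computed once over all values (no re-iteration after
removal). `mesh_plot_data` exports (x, y, intensity) records — the
diagnostic used to justify the threshold by eye: healthy tissue clusters
near ratio ≈ 2, whitened tissue well above 5.

## Synthetic phantoms

The generator exists because no hyperspectral dataset of ginseng inner
whitening is publicly deposited; it defines the study conditions under
which the package's claims are tested.

Geometry: an elliptical root silhouette (default semi-axes 0.40/0.44 of
a 160 × 250 frame — half the instrument resolution, keeping the default
test suite fast; any size is configurable) on a background that holds
the white-reference counts exactly. The whitened region is a concentric
ellipse sized by bisection so its realized pixel fraction matches the
requested area fraction to within pixelation (< 0.5 pp). Real whitening
is likely irregular and graded rather than elliptical and binary; the
binary ellipse matches what a binary threshold map can recover, which is
the quantity under test.

Spectra (phenomenological, not radiative transfer):

* baseline transmittance falling linearly 0.60 → 0.05 across
  900–1700 nm, plus a per-pixel convex curvature term
  (mean 0.05, sd 0.06, clipped to [0, 0.12]) standing in for
  tissue-scattering variability — deliberately the largest common-mode
  variation, so it occupies PC-1 and the whitening contrast lands on
  PC-2, reproducing the PC ordering reported for the real instrument
  data;
* Gaussian absorption dips at 950/1110/1326 nm (depths 0.04/0.06/0.04,
  σ 25/30/25 nm), ginsenoside-associated bands, with per-pixel depth
  jitter (relative sd 0.08/0.35/0.08);
* whitening as multiplicative attenuation inside the 900–1050 and
  1150–1400 nm windows, shaped as Gaussian bumps (depths 0.20 and 0.76,
  σ 30 nm, internal centers 950 and 1330 nm). The 1330 nm center
  compensates the leftward pull of the falling baseline so the
  *realized* whitening contrast — after calibration and range
  normalization — peaks exactly at the band centers nearest 950 and
  1326 nm (947.90 and 1326.35 nm on the default grid). These depths put
  whitened-pixel ratios near 6 (minimum ≈ 5.3–6.0 across fixtures) and
  healthy pixels near 2.1 (maximum ≈ 2.5), so the fixed threshold 5
  separates the populations with margin at the default noise level;
* a smooth elliptical thickness dome (edge-to-center swing 0.35) and
  mild per-pixel scatter scaling whole spectra — nuisances that the
  ratio and range normalization must (and do) cancel;
* multiplicative Gaussian noise on sample transmittance (sd 1%,
  shot-noise-like) and a constant dark-current offset (dark 100, white
  3000 counts); references are returned noiseless, and identical seeds
  give byte-identical cubes.

The fixture library freezes these parameters with stored seeds: S1/S3/S4
at 48.18/53.14/37.66% planted whitening (the reference severities), two
normal phantoms, and a 10/25/50% sweep. `phantom_ensemble` builds the
6 normal + 6 abnormal set (seeds counted up from a base, abnormal
fractions cycling 0.35–0.53, 80 × 125 frames) used for the PCA study;
at that size the 66k × 168 decomposition runs in seconds.

**What passing on phantoms does and does not show.** It demonstrates
that every algorithmic stage is implemented correctly and that the
chain, end to end, recovers planted whitened fractions within
±2 percentage points and planted characteristic bands exactly (nearest
band center), robustly across seeds. It does not validate the biology:
real whitening boundaries are gradual, spectra are richer than three
dips, stray light and wavelength miscalibration are not modelled, and
the detection threshold of 5 is meaningful only relative to the
phantoms' calibrated contrast, as it was relative to the real
instrument's.

## Numerical and design notes

* Nearest-band lookup for requested wavelengths; requests outside the
  axis raise with the available range listed.
* ENVI I/O is implemented in-package (ASCII header + raw binary,
  BSQ/BIL/BIP, dtype codes 1–5/12/13) and round-trips bit-exactly; the
  wavelength list is required on read, since downstream stages are
  meaningless without an axis.
* The ANOVA observation unit (per-sample means) makes phantom F values
  incomparable to pixel-level analyses by design.
* Pipeline runs serialize their full configuration to YAML; re-running a
  saved config with the same seed reproduces `report.csv` byte-for-byte.
  The summary label "abnormal (inner whitening)" uses a configurable
  Pwp cutoff (default 5%) — a pragmatic rule, since the visual grading
  it stands in for has no numeric definition.
* The acceptance script derives every phantom seed from its `--seed`
  argument; the recovered quantities are properties of the generative
  design, not of a particular seed.
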