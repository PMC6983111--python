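"""PCA waveband selection: unfold, fit, refold scores, pick characteristic bands.

The masked hypercube is unfolded into a 2-D matrix with one row per
foreground pixel (each row a spectrum, each column a band) and decomposed
by principal component analysis of the mean-centered rows,

    X_centered = S @ L.T + E,

with ``S`` the pixel x component score matrix, ``L`` the band x component
loading matrix (orthonormal columns) and ``E`` the residual of discarded
components.  Scores refold onto pixel coordinates as score images; loading
extrema mark the characteristic wavebands that drive a component.  A
one-way ANOVA between normal and abnormal per-sample mean spectra ranks
bands by group separation.

Component numbers are 1-based throughout ("PC-2" is ``component=2``),
matching how principal components are named in practice.

Sign convention: each loading column is flipped so its largest-|value|
element is positive, removing eigenvector sign ambiguity — a whitened
region is then reproducibly *bright* in the discriminating score image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ghsw.hypercube_io import HyperCube, SampleMask


@dataclass
class UnfoldedMatrix:
    """Pixel-spectra matrix with an invertible pixel index.

    ``rows`` has one row per foreground pixel across all included samples,
    stacked sample-by-sample and, within a sample, in row-major spatial
    order.  ``index[i] = (sample_id, row, col)`` locates row ``i``.
    """

    rows: np.ndarray
    index: list[tuple[object, int, int]]
    wavelengths: np.ndarray
    shapes: dict = field(default_factory=dict)  # sample_id -> spatial shape

    @property
    def n_bands(self) -> int:
        return self.rows.shape[1]

    def __post_init__(self) -> None:
        if self.rows.ndim != 2:
            raise ValueError("rows must be 2-D (pixels x bands)")
        if len(self.index) != self.rows.shape[0]:
            raise ValueError("index length must equal the number of rows")
        if len(set(self.index)) != len(self.index):
            raise ValueError("index contains duplicate (sample, row, col) entries")


@dataclass
class PCAModel:
    """Scores/loadings/explained-variance triple of a fitted PCA.

    ``loadings`` is bands x components with orthonormal columns;
    ``scores`` is pixels x components; ``mean_spectrum`` is the band-wise
    mean removed before decomposition.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    mean_spectrum: np.ndarray
    wavelengths: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def _component_column(self, component: int) -> int:
        if not (1 <= component <= self.n_components):
            raise ValueError(
                f"component must be in 1..{self.n_components} (1-based PC number); "
                f"got {component}"
            )
        return component - 1


def unfold(
    cubes: Sequence[tuple[HyperCube, SampleMask]] | Sequence[tuple[HyperCube, SampleMask, object]],
) -> UnfoldedMatrix:
    """Stack the foreground spectra of one or more masked cubes.

    Each element is ``(cube, mask)`` or ``(cube, mask, sample_id)``;
    omitted ids default to the position in the sequence.  All cubes must
    share the wavelength axis.
    """
    if not cubes:
        raise ValueError("no cubes to unfold")
    blocks: list[np.ndarray] = []
    index: list[tuple[object, int, int]] = []
    shapes: dict = {}
    wavelengths: np.ndarray | None = None
    for pos, entry in enumerate(cubes):
        cube, mask = entry[0], entry[1]
        sample_id = entry[2] if len(entry) > 2 else pos
        if wavelengths is None:
            wavelengths = cube.wavelengths
        elif not np.array_equal(cube.wavelengths, wavelengths):
            raise ValueError(
                f"sample '{sample_id}': wavelength axis differs from the first sample"
            )
        if mask.mask.shape != cube.spatial_shape:
            raise ValueError(f"sample '{sample_id}': mask/cube spatial shape mismatch")
        rr, cc = np.nonzero(mask.mask)  # row-major order
        blocks.append(cube.values[rr, cc, :].astype(float))
        index.extend((sample_id, int(r), int(c)) for r, c in zip(rr, cc))
        shapes[sample_id] = cube.spatial_shape
    return UnfoldedMatrix(
        rows=np.vstack(blocks), index=index, wavelengths=np.asarray(wavelengths), shapes=shapes
    )


def fit_pca(matrix: UnfoldedMatrix, n_components: int) -> PCAModel:
    """Fit a mean-centered PCA of the unfolded pixel spectra.

    Uses a full SVD; loading-column signs are fixed so each column's
    largest-|value| element is positive.
    """
    n, b = matrix.rows.shape
    if not (1 <= n_components <= min(n, b)):
        raise ValueError(
            f"n_components={n_components} exceeds min(pixels, bands)={min(n, b)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.rows)
    loadings = pca.components_.T.copy()  # bands x k
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        mean_spectrum=pca.mean_.copy(),
        wavelengths=matrix.wavelengths.copy(),
    )


def refold_scores(
    model: PCAModel,
    matrix: UnfoldedMatrix,
    component: int,
    sample_id: object | None = None,
):
    """Map one component's score vector back onto pixel coordinates.

    Returns a 2-D score image (background = NaN) for ``sample_id``, or a
    ``{sample_id: image}`` dict over all samples when ``sample_id`` is
    None.  ``component`` is the 1-based PC number.
    """
    j = model._component_column(component)
    ids = [sid for sid, _, _ in matrix.index]
    wanted = set(matrix.shapes) if sample_id is None else {sample_id}
    unknown = wanted - set(matrix.shapes)
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(map(str, unknown))}")
    images = {sid: np.full(matrix.shapes[sid], np.nan) for sid in wanted}
    idx = np.array([(r, c) for _, r, c in matrix.index])
    for sid in wanted:
        sel = np.array([x == sid for x in ids])
        if not sel.any():
            raise ValueError(f"sample id {sid!r} has no foreground pixels")
        images[sid][idx[sel, 0], idx[sel, 1]] = model.scores[sel, j]
    return images[sample_id] if sample_id is not None else images


def select_wavebands(model: PCAModel, component: int, n_bands: int = 2) -> list[float]:
    """Characteristic wavebands of a component: top local extrema of its loading.

    A band is a candidate if its |loading| is strictly greater than both
    neighbors (endpoints compare to their single neighbor; a plateau is
    represented by its first index).  Candidates are ranked by |loading|
    descending, ties broken toward the lower wavelength, and the top
    ``n_bands`` wavelengths are returned in ascending order.  If fewer
    extrema exist, all are returned with a warning.
    """
    j = model._component_column(component)
    a = np.abs(model.loadings[:, j])
    n = len(a)
    candidates: list[int] = []
    i = 0
    while i < n:
        k = i
        while k + 1 < n and a[k + 1] == a[i]:
            k += 1  # plateau [i, k]
        left_ok = i == 0 or a[i] > a[i - 1]
        right_ok = k == n - 1 or a[k] > a[k + 1]
        if left_ok and right_ok:
            candidates.append(i)  # first index of the plateau
        i = k + 1
    candidates.sort(key=lambda b: (-a[b], model.wavelengths[b]))
    if len(candidates) < n_bands:
        warnings.warn(
            f"only {len(candidates)} loading extrema found; requested {n_bands}",
            stacklevel=2,
        )
    chosen = candidates[:n_bands]
    return sorted(float(model.wavelengths[b]) for b in chosen)


def band_anova(
    group_a: np.ndarray | Sequence[float],
    group_b: np.ndarray | Sequence[float],
    band: int | None = None,
) -> tuple[float, float]:
    """One-way ANOVA F and p between two groups at one band.

    Groups are per-sample mean spectra (samples x bands; ``band`` selects
    the column) or plain 1-D value sequences.  One observation per root —
    pixels within a root are not independent.  F is the between-group mean
    square over the within-group mean square with df ``(k-1, N-k)``; p is
    the upper tail of the F distribution.

    Degenerate cases: zero within-group variance with unequal means gives
    ``(inf, 0.0)``; identical constant groups give ``(0.0, 1.0)``.
    """
    groups = []
    for g in (group_a, group_b):
        g = np.asarray(g, dtype=float)
        if g.ndim == 2:
            if band is None:
                raise ValueError("band index required for 2-D (samples x bands) input")
            g = g[:, band]
        if g.size < 2:
            raise ValueError("each group needs at least 2 samples")
        groups.append(g)

    k = len(groups)
    all_vals = np.concatenate(groups)
    n_total = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n_total - k

    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def band_ranking(
    spectra_a: np.ndarray,
    spectra_b: np.ndarray,
    wavelengths: np.ndarray,
    model: PCAModel | None = None,
) -> pd.DataFrame:
    """Per-band ANOVA table between two groups of per-sample mean spectra.

    Returns a DataFrame with ``wavelength_nm``, ``F``, ``p`` per band,
    plus one loading column per component when a fitted ``model`` is
    supplied, sorted by F descending.
    """
    spectra_a = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    spectra_b = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    rows = []
    for b, wl in enumerate(wavelengths):
        f_stat, p = band_anova(spectra_a, spectra_b, band=b)
        rows.append({"band": b, "wavelength_nm": float(wl), "F": f_stat, "p": p})
    df = pd.DataFrame(rows)
    if model is not None:
        for j in range(model.n_components):
            df[f"loading_pc{j + 1}"] = model.loadings[:, j]
    return df.sort_values("F", ascending=False, ignore_index=True)


def rank_components(model: PCAModel, matrix: UnfoldedMatrix, abnormal_ids) -> list[int]:
    """Rank components by how strongly their scores separate two sample groups.

    ``abnormal_ids`` is the set of sample ids in the abnormal group.  For
    each component the standardized difference of pixel scores between
    abnormal and normal samples (|mean difference| / pooled sd) is
    computed; components are returned as 1-based numbers, most
    discriminating first.  This is a helper for choosing which PC carries
    the whitening contrast; the pipeline default remains configurable.
    """
    abnormal_ids = set(abnormal_ids)
    sel = np.array([sid in abnormal_ids for sid, _, _ in matrix.index])
    if not sel.any() or sel.all():
        raise ValueError("both groups need at least one sample's pixels")
    sep = []
    for j in range(model.n_components):
        s = model.scores[:, j]
        pooled = np.sqrt(0.5 * (s[sel].var() + s[~sel].var()))
        sep.append(abs(s[sel].mean() - s[~sel].mean()) / pooled if pooled > 0 else 0.0)
    order = np.argsort(sep)[::-1]
    return [int(j) + 1 for j in order]
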