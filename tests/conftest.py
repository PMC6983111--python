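"""Shared fixtures: tiny hand-built cubes and session-scoped phantom runs."""

from __future__ import annotations

import time

import numpy as np
import pytest

from ghsw import (
    DetectionConfig,
    NormalizationConfig,
    calibrate,
    fit_pca,
    fixture_library,
    generate_cube,
    normalize,
    phantom_ensemble,
    ratio_image,
    segment_background,
    threshold_binary,
    unfold,
    whitening_percentage,
)
from ghsw.band_selection import UnfoldedMatrix, rank_components, select_wavebands
from ghsw.hypercube_io import HyperCube


def make_cube(values, wavelengths=None, **meta) -> HyperCube:
    """Small HyperCube with an evenly spaced default wavelength axis."""
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.linspace(900.0, 1700.0, values.shape[2])
    return HyperCube(values=values, wavelengths=np.asarray(wavelengths, float), meta=meta)


def matrix_from_array(x: np.ndarray) -> UnfoldedMatrix:
    """Wrap a plain 2-D array as an UnfoldedMatrix (one fake sample)."""
    x = np.asarray(x, dtype=float)
    n, b = x.shape
    return UnfoldedMatrix(
        rows=x,
        index=[(0, i, 0) for i in range(n)],
        wavelengths=np.linspace(900.0, 1700.0, b),
        shapes={0: (n, 1)},
    )


@pytest.fixture(scope="session")
def s1_products():
    """Full-resolution S1 phantom pushed through the detection path."""
    spec = fixture_library()["S1"]
    t0 = time.perf_counter()
    raw, refs, truth = generate_cube(spec)
    cal = calibrate(raw, refs)
    mask = segment_background(cal)
    cfg = DetectionConfig()
    ratio = ratio_image(cal, mask, cfg)
    binary = threshold_binary(ratio, mask, cfg)
    report = whitening_percentage(binary, mask, cfg)
    elapsed = time.perf_counter() - t0
    return {
        "spec": spec,
        "raw": raw,
        "refs": refs,
        "truth": truth,
        "cal": cal,
        "mask": mask,
        "ratio": ratio,
        "binary": binary,
        "report": report,
        "elapsed": elapsed,
    }


@pytest.fixture(scope="session")
def ensemble_products():
    """6 normal + 6 abnormal phantoms through calibration, normalization, PCA."""
    t0 = time.perf_counter()
    inputs = []
    groups = {}
    for name, spec in phantom_ensemble(base_seed=1):
        raw, refs, truth = generate_cube(spec)
        cal = calibrate(raw, refs)
        mask = segment_background(cal)
        norm = normalize(cal, mask, NormalizationConfig("range"))
        inputs.append((norm, mask, name))
        groups[name] = "abnormal" if spec.whitening_fraction > 0 else "normal"
    matrix = unfold(inputs)
    model = fit_pca(matrix, 3)
    abnormal = {n for n, g in groups.items() if g == "abnormal"}
    order = rank_components(model, matrix, abnormal)
    selected = select_wavebands(model, order[0], n_bands=2)
    elapsed = time.perf_counter() - t0
    return {
        "matrix": matrix,
        "model": model,
        "order": order,
        "selected": selected,
        "groups": groups,
        "elapsed": elapsed,
    }
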