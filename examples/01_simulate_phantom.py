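"""Generate a synthetic ginseng phantom and inspect its planted ground truth.

The generator emulates a line-scan NIR transmittance acquisition: an
elliptical root on a bright glass plate, 168 bands over 900-1700 nm, and —
for abnormal phantoms — a central whitened region of known area fraction.
"""

import numpy as np

from ghsw import fixture_library, generate_cube, generate_spectrum

lib = fixture_library()
spec = lib["S1"]  # heavy whitening, planted at 48.18% of the root area
raw, refs, truth = generate_cube(spec)

print(f"cube shape (rows, cols, bands): {raw.values.shape}")
print(f"wavelengths: {raw.wavelengths[0]:.1f} .. {raw.wavelengths[-1]:.1f} nm")
print(f"sample pixels: {truth.sample_mask.n_foreground}")
print(f"planted whitened fraction: target {truth.target_fraction:.4f}, "
      f"realized {truth.actual_fraction:.4f}")

normal = generate_spectrum(spec, whitened=False)
whitened = generate_spectrum(spec, whitened=True)
wl = spec.wavelengths
for lo, hi in spec.spectral.whitening_windows_nm:
    w = (wl >= lo) & (wl <= hi)
    print(f"mean transmittance {lo:.0f}-{hi:.0f} nm: "
          f"normal {normal[w].mean():.3f}, whitened {whitened[w].mean():.3f}")
# The whitened tissue is optically denser inside both windows — the
# contrast every downstream stage relies on.
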