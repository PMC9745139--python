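"""Generate a labelled synthetic hyperspectral scene and inspect it.

The generator builds per-class endmember spectra (vegetation with a red
edge, water decaying into the NIR), lays out irregular class regions,
and renders a noisy reflectance cube.
"""

import numpy as np

from hsiseg import SceneSpec, generate_scene

spec = SceneSpec(height=128, width=128, n_bands=32, n_classes=4, seed=0)
cube, labels, endmembers = generate_scene(spec)

print(f"cube: {cube.data.shape}, reflectance in "
      f"[{cube.data.min():.3f}, {cube.data.max():.3f}]")
print(f"wavelengths: {cube.wavelengths[0]:.0f}-{cube.wavelengths[-1]:.0f} nm "
      f"({len(cube.wavelengths)} bands)")
for m in endmembers:
    count = int((labels.labels == m.class_id).sum())
    print(f"class {m.class_id} ({m.kind:10s}): {count:6d} px, "
          f"mean reflectance {m.spectrum.mean():.3f}")

# adjacent spectral bands are strongly correlated, the redundancy that
# makes PCA band reduction effective
flat = cube.data.reshape(-1, spec.n_bands).astype(np.float64)
corr = np.diag(np.corrcoef(flat.T), k=1)
print(f"adjacent-band correlation: min {corr.min():.3f}, "
      f"median {np.median(corr):.3f}")
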