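"""Split an RGB image into intensity and chrominance and put it back.

The 3x3 orthogonal matrix C sends a pixel p = (r, g, b) to p' = p·C whose
first coordinate is (r+g+b)/sqrt(3) — the brightness — and whose other two
coordinates carry the color. Because C is orthogonal the split is lossless.
"""

import numpy as np

from nirseed import build_decoupling_matrix, couple_intensity, decouple_intensity

C = build_decoupling_matrix().entries
print("decoupling matrix C (rounded):")
print(np.round(C, 3))
print("orthogonality error ||C C^T - I||_max =", np.abs(C @ C.T - np.eye(3)).max())

rng = np.random.default_rng(0)
img = rng.uniform(-1, 1, (4, 4, 3))
intensity, chroma = decouple_intensity(img)
back = couple_intensity(intensity, chroma)

print("\nintensity of a pure-red pixel:", decouple_intensity(np.ones((1, 1, 3)) * [1, 0, 0])[0][0, 0])
print("round-trip error:", np.abs(back - img).max())
print("(0.577 is 1/sqrt(3): red contributes a third of the brightness axis;")
print(" the round-trip error is at machine precision because C is orthogonal.)")
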