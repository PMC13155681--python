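"""The sinusoidal dose embedding: what a single concentration becomes.

A dose d is first mapped into [0, 1] by a log-min-max transform over the
training dose range, then expanded into [sin(2 pi f_i d'), cos(2 pi f_i d')]
pairs over log-spaced frequencies. Nearby doses get similar vectors; the
high-frequency pairs resolve small dose differences, the low-frequency
pairs encode the coarse position in the range.
"""

import numpy as np

from pairdose.encoders import DoseEmbedderConfig, embed_dose

cfg = DoseEmbedderConfig(n_frequencies=4).fit([0.01, 1.0])

for dose in (0.01, 0.1, 0.32, 1.0):
    v = embed_dose(dose, cfg)
    print(f"dose {dose:5.2f} -> d' = {cfg.transform_dose(dose):.3f} -> {np.round(v, 3)}")

v = embed_dose(0.1, cfg)
print(f"\nper-frequency sin^2+cos^2: {np.round(v[0::2]**2 + v[1::2]**2, 12)}")
print("(each pair lies on the unit circle, so the embedding norm is sqrt(c))")
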