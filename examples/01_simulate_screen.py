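"""Generate a synthetic drug-combination screen and look at its structure.

The generator emits four mutually consistent tables: combination responses
(full 5x5 dose matrices per drug pair and cell line, Bliss-null surfaces
plus a localized synergy/antagonism bump plus noise), monotherapy Hill
curves, a SMILES library, and latent-factor expression profiles whose
factors also shift each drug's EC50 — so expression is informative.
"""

import numpy as np

from pairdose.synthetic import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_drugs=6, n_cells=3, seed=7)
ds = generate_dataset(cfg)

print(f"combo rows : {len(ds.combo)}  (15 pairs x 3 cells x 25 grid points)")
print(f"mono rows  : {len(ds.mono)}  (6 drugs x 3 cells x 5 doses)")
print(f"drugs      : {[d.drug_id for d in ds.drugs]}")
print(f"doses      : {np.round(cfg.doses, 3)}  (log-spaced)")

key = next(iter(ds.truth.surface))
surf = ds.truth.surface[key]
print(f"\nnoise-free surface for {key} (rows = drug1 dose, cols = drug2 dose):")
print(np.round(surf, 3))
amp, mu1, mu2, w = ds.truth.bump[key]
print(
    f"\nbump amplitude {amp:+.3f} at log-doses ({mu1:.2f}, {mu2:.2f}), width {w:.2f} — "
    "positive amplitude means synergy above the Bliss product, negative antagonism."
)
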