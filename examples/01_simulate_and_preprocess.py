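"""Simulate a serum FTIR cohort and run the preprocessing chain.

Builds a small synthetic case/reference cohort, applies water-displacement
correction, spectral masking and L2 normalization, and shows how well the
per-sample water-correction coefficient recovers the simulated deficit.
"""

import numpy as np

from oncospectra import SimConfig, apply_pipeline, generate_cohort

cfg = SimConfig(n_cases=60, n_refs=80, seed=42)
cohort, truth = generate_cohort(cfg)
print(f"cohort: {cohort.X.shape[0]} samples x {cohort.X.shape[1]} wavenumbers "
      f"({cohort.wavenumbers[0]:.0f}-{cohort.wavenumbers[-1]:.0f} cm^-1)")

feats = apply_pipeline(cohort)
print(f"preprocessed: {feats.X.shape[1]} retained wavenumbers "
      "(1000-1750 and 2800-3000 cm^-1), unit-norm rows")

alphas = feats.provenance["water_alpha"]
err = np.array([alphas[sid] - truth.beta[sid] for sid in cohort.sample_ids])
print(f"water-correction coefficient error: mean {err.mean():+.4f}, "
      f"sd {err.std():.4f}")
print("-> alpha tracks the simulated water deficit; the residual reflects "
      "biological absorption bleeding into the 2000-2300 cm^-1 window.")
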