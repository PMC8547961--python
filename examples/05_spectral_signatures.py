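"""Per-wavenumber statistics and stage dependence of the spectral signature.

Computes the differential fingerprint (mean case minus mean reference
spectrum), per-wavenumber t-test p-values and Mann-Whitney AUCs, then shows
that detection performance and the integrated |differential fingerprint|
grow with the simulated tumour T class.
"""

import numpy as np

from oncospectra import (SimConfig, StudyConfig, apply_pipeline, compare_groups,
                         generate_cohort, run_stage_comparison)
from oncospectra.stats import area_abs_diff

cfg = SimConfig(n_cases=300, n_refs=300, seed=8,
                stage_probs=(0.25, 0.25, 0.25, 0.25))
cohort, _ = generate_cohort(cfg)
feats = apply_pipeline(cohort)
y = (feats.meta["group"] == "case").to_numpy()

ws = compare_groups(feats.X[y], feats.X[~y], feats.wavenumbers)
peak = np.argmax(np.abs(ws.effect))
print(f"strongest signature at {ws.wavenumbers[peak]:.0f} cm^-1: "
      f"effect size {ws.effect[peak]:+.2f}, AUC {ws.auc_w[peak]:.2f}, "
      f"p = {ws.p_t[peak]:.1e}")
print(f"area under |differential fingerprint|: "
      f"{area_abs_diff(ws.delta, ws.wavenumbers):.3f} AU*cm^-1")

study = StudyConfig(sim=SimConfig(n_cases=400, n_refs=450, seed=8,
                                  stage_probs=(0.25, 0.25, 0.25, 0.25)),
                    folds=10, repeats=2, seed=8)
table = run_stage_comparison(study, by="t_class")
print("\nAUC by tumour T class (re-matched sub-cohorts):")
print(table[["stratum", "n_cases", "auc_mean", "auc_sd"]]
      .round(3).to_string(index=False))
print("-> detection performance rises with the simulated tumour load, "
      "mirroring a stage-dependent blood signature.")
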