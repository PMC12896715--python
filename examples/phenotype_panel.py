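"""Classify simulated Western-blot densitometry into E/hybrid/M phenotypes.

Simulates a 95-patient panel with the default epithelial/hybrid/
mesenchymal mixture (14%/63%/23%), normalizes band intensities against
the β-actin channel, classifies each patient by the Vimentin/E-cadherin
ratio (<1 epithelial, 1–10 hybrid, >10 mesenchymal), and reports the
marker correlation matrix entry for VIM–CDH1.
"""

import numpy as np

import emtsig as es

panel, _ = es.simulate_densitometry_panel(es.DensitometrySimParams(rng_seed=42))
panel = es.normalize_panel(panel)

calls, counts = es.classify_phenotypes(panel, numerator="VIM", denominator="CDH1")
print("phenotype counts of 95 patients:")
for k in ("epithelial", "hybrid", "mesenchymal", "unclassified"):
    print(f"  {k:13s} {counts[k]:3d}  ({100 * counts[k] / 95:.0f}%)")

corr = es.pearson_with_p(
    np.log(panel.normalized["VIM"]), np.log(panel.normalized["CDH1"])
)
print(
    f"VIM-CDH1 log-intensity correlation: r = {corr.r:.2f}, "
    f"p = {corr.p_value:.1e} ({corr.n_pairs} complete pairs)"
)
# Most patients sit in the hybrid band, and the epithelial and mesenchymal
# markers correlate positively — co-expression, not mutual exclusion.
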