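"""Optimal-cutpoint survival screen on one simulated gene.

Simulates a 500-patient cohort in which one gene carries a log hazard
ratio of ln 2 per SD of expression, scans every candidate cutoff between
the expression quartiles, and contrasts the nominal minimum log-rank p
with its permutation-adjusted value.
"""

import numpy as np
import pandas as pd

import emtsig as es

rng = np.random.default_rng(7)
expression = pd.DataFrame({"MKI67like": rng.normal(size=500)})
cohort = es.simulate_survival_cohort(
    es.SurvivalSimParams(
        n_patients=500, log_hr_per_sd={"MKI67like": np.log(2)},
        censor_rate=0.3, max_follow_up=40.0, endpoint="OS", rng_seed=7,
    ),
    expression,
)
config = es.AnalysisConfig(n_permutations=999, rng_seed=7)
res = es.best_cutoff_scan("MKI67like", cohort, config)

print(f"candidates evaluated between Q1 and Q3: {res.candidates_evaluated}")
print(f"best cutoff: {res.best_cutoff:.3f} (low n={res.n_low}, high n={res.n_high})")
print(f"minimum log-rank p: {res.logrank_p_min:.3e}")
print(f"permutation-adjusted p (B=999): {res.adjusted_p:.4f}")
print(f"hazard ratio high vs low (Pike O/E): {res.hazard_ratio:.2f}")
# The adjusted p accounts for the minimum being taken over all candidate
# splits; the HR > 1 marks high expression of this gene as hazardous.
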