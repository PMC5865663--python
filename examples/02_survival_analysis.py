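"""Relapse-free survival by signature status.

Generates a cohort whose relapse hazard is 4.9-fold higher in
signature-mutant tumours, then runs the full survival toolkit:
Kaplan-Meier curves per status group, the log-rank test, univariate and
multivariate Cox fits, and Harrell's concordance index comparing the
continuous risk score with a random competitor.
"""

import numpy as np
import pandas as pd

from tp53sig import (
    SyntheticConfig,
    compare_signatures,
    cox_fit,
    default_signature,
    generate_cohort,
    km_estimate,
    logrank_test,
    score_cohort,
)

sig = default_signature()
bundle = generate_cohort(SyntheticConfig(seed=2, n_mutant=200, n_wildtype=300), sig)
status = bundle.true_status

curves = km_estimate(bundle.outcomes, status)
for label, curve in curves.items():
    print(f"KM {label}: survival at last follow-up = {curve['survival'].iloc[-1]:.3f}")

stat, p = logrank_test(bundle.outcomes, status)
print(f"log-rank: chi2={stat:.2f}, p={p:.2e}  (MT relapses earlier)")

cov = bundle.clinical[["er_positive", "node_positive"]].copy()
cov["signature_mt"] = (status == "MT").astype(int)
print("\nCox proportional hazards (univariate):")
for r in cox_fit(cov, bundle.outcomes, "univariate"):
    print(f"  {r.variable:<14} HR={r.hazard_ratio:5.2f}  "
          f"95% CI {r.ci_low:.2f}-{r.ci_high:.2f}  p={r.p_value:.3g}")
print("Cox (multivariate, univariate p<0.05 entry rule):")
for r in cox_fit(cov, bundle.outcomes, "multivariate"):
    print(f"  {r.variable:<14} HR={r.hazard_ratio:5.2f}  "
          f"95% CI {r.ci_low:.2f}-{r.ci_high:.2f}  p={r.p_value:.3g}")

risk = pd.DataFrame({
    "tp53_signature": score_cohort(bundle.expression, sig)["risk_score"],
    "noise": np.random.default_rng(0).normal(size=len(status)),
})
print("\nConcordance index for relapse-free survival (0.5 = uninformative):")
for res in compare_signatures(risk, bundle.outcomes):
    print(f"  {res.name:<14} c={res.c_index:.3f}  ({res.n_usable_pairs} usable pairs)")
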