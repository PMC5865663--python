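"""Score a cohort and calibrate the mutant/wild-type cutoff.

Builds a synthetic nCounter-style cohort (64 signature-mutant, 110
wild-type tumours), computes each sample's risk score — the ratio of
summed counts of the 22 up-regulated to the 9 down-regulated signature
genes — and calibrates the MT/WT cutoff against TP53 structural-mutation
labels.  Also runs the same calibration on the frozen 30-sample learning
fixture, which reproduces the published operating characteristics.
"""

from tp53sig import (
    SyntheticConfig,
    assign_status,
    canonical_learning_fixture,
    default_signature,
    generate_cohort,
    score_cohort,
    select_cutoff,
)

sig = default_signature()
bundle = generate_cohort(SyntheticConfig(seed=1), sig)
scores = score_cohort(bundle.expression, sig)

cal = select_cutoff(scores["risk_score"].to_numpy(), bundle.tp53_mutation.to_numpy())
assigned = assign_status(scores, cal.cutoff)

print(f"cohort: {len(scores)} samples, "
      f"{(assigned['status'] == 'MT').sum()} called MT at cutoff {cal.cutoff:.3f}")
print(f"  AUC={cal.auc:.3f}  sensitivity={cal.sensitivity:.3f} "
      f"specificity={cal.specificity:.3f} accuracy={cal.accuracy:.3f}")
print("  (sensitivity/specificity are measured against the structural-mutation label,")
print("   which intentionally disagrees with the expression phenotype for some samples)")

fx = canonical_learning_fixture()
cal_fx = select_cutoff(fx["risk_score"].to_numpy(), fx["tp53_mutation"].to_numpy())
print(f"\ncanonical 30-sample learning fixture: cutoff={cal_fx.cutoff:.2f} "
      f"AUC={cal_fx.auc:.4f}")
print(f"  confusion={cal_fx.confusion} -> sensitivity {cal_fx.sensitivity:.2f}, "
      f"specificity {cal_fx.specificity:.3f}, accuracy {cal_fx.accuracy:.2f}")
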