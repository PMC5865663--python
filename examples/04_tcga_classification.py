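"""Status assignment without a calibrated cutoff, and variant filtering.

For cohorts where no learning set exists to calibrate a score cutoff,
status is assigned directly from the 31 signature genes: unsupervised
two-way Ward clustering (the mutant-dominated cluster becomes MT) or a
linear SVM trained on a balanced 100-sample subset and applied to the
held-out remainder.  Both are demonstrated on a strongly separated
synthetic cohort.  Finally, the somatic-variant filter keeps calls that
are rare in both population SNP databases (<1%) and well covered
(DP > 20).
"""

from tp53sig import (
    SyntheticConfig,
    VariantRecord,
    cluster_classify,
    default_signature,
    filter_somatic_variants,
    generate_cohort,
    svm_classify,
)

sig = default_signature()
cfg = SyntheticConfig(seed=4, n_mutant=150, n_wildtype=150,
                      tp53_mut_fraction_mt=1.0, tp53_mut_fraction_wt=0.0)
bundle = generate_cohort(cfg, sig)
expr = bundle.expression.restrict(sig.signature_genes)

status_cl = cluster_classify(expr, bundle.tp53_mutation)
acc_cl = (status_cl == bundle.true_status).mean()
print(f"clustering: {(status_cl == 'MT').sum()} samples called MT; "
      f"agreement with truth {acc_cl:.1%}")

status_svm, model = svm_classify(expr, bundle.tp53_mutation, train_per_class=50, seed=4)
acc_svm = (status_svm == bundle.true_status.loc[status_svm.index]).mean()
print(f"linear SVM: trained on {len(model.training_samples)} samples, "
      f"predicted {len(status_svm)} held-out samples; agreement {acc_svm:.1%}")
top = model.weights.abs().sort_values(ascending=False).head(3)
print(f"  heaviest weights: {', '.join(f'{g} ({model.weights[g]:+.2f})' for g in top.index)}")

variants = [
    VariantRecord("S1", "TP53", "v1", 0.005, 0.002, 45),   # rare + covered -> kept
    VariantRecord("S1", "BRCA1", "v2", 0.02, 0.001, 80),   # common in one DB -> dropped
    VariantRecord("S2", "RB1", "v3", None, None, 30),      # unannotated -> treated as novel
    VariantRecord("S2", "KIF1A", "v4", 0.001, 0.001, 20),  # DP not > 20 -> dropped
]
kept = filter_somatic_variants(variants)
print(f"\nvariant filter kept {len(kept)}/{len(variants)}: "
      f"{', '.join(v.gene for v in kept)}")
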