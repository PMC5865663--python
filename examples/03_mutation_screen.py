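"""Molecular-burden comparisons and the mutated-gene screen.

Generates a TCGA-like bundle in which signature-mutant tumours carry
higher background mutation rates, CNV burden and immune-marker (PD-L1,
CD8B) expression, then: (1) screens for genes mutated in at least six
MT samples with Fisher's exact test, also in the subgroup without TP53
structural mutation; (2) compares CNV, somatic mutation number and
immune expression between status groups with the rank-sum test; and (3)
tests clinical covariates for association with status.
"""

from tp53sig import (
    SyntheticConfig,
    association_table,
    compare_continuous,
    default_signature,
    generate_tcga_like,
    mutated_gene_screen,
)

sig = default_signature()
cfg = SyntheticConfig(seed=3, n_mutant=150, n_wildtype=250,
                      mutation_rate_mt=0.06, mutation_rate_wt=0.02)
bundle = generate_tcga_like(cfg, sig)
status = bundle.true_status

rows = mutated_gene_screen(bundle.mutations, status, min_mt_samples=6)
enriched = [r for r in rows if r.p_value < 0.05 and r.enriched_in == "MT"]
print(f"screen: {len(rows)} genes mutated in >=6 MT samples; "
      f"{len(enriched)} MT-enriched at p<0.05")
for r in rows[:3]:
    print(f"  {r.gene:<8} MT {r.n_mut_in_mt}/{r.n_mt}  WT {r.n_mut_in_wt}/{r.n_wt}  "
          f"p={r.p_value:.2e}  enriched in {r.enriched_in}")

sub = mutated_gene_screen(bundle.mutations, status, min_mt_samples=6,
                          exclude_tp53_mutants=True)
print(f"subgroup without TP53 structural mutation: {len(sub)} genes retained")

print("\nburden comparisons (two-sided Mann-Whitney):")
for name, values in [("CNV burden", bundle.cnv_burden),
                     ("somatic mutation number", bundle.smn),
                     ("PD-L1 expression", bundle.immune_expression["PDL1"]),
                     ("CD8B expression", bundle.immune_expression["CD8B"])]:
    _, p = compare_continuous(values, status)
    mt, wt = values[status == "MT"].median(), values[status == "WT"].median()
    print(f"  {name:<24} median MT={mt:7.1f}  WT={wt:7.1f}  p={p:.2e}")

print("\nclinicopathological associations with signature status:")
for col in ("er_positive", "her2_positive", "grade", "age"):
    res = association_table(bundle.clinical[col], status, variable=col,
                            continuous=(col == "age"))
    print(f"  {col:<14} {res.test_used:<14} p={res.p_value:.3g}")
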