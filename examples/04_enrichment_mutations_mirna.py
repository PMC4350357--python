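"""Gene-set enrichment, mutation intersection and miRNA-mRNA inverse links.

The significant signature is tested against annotation sets (Fisher's exact
test, BH across sets) with the baseline-filtered probes as universe; mutated
genes that are also up-regulated are nominated as co-driver candidates; and
(miRNA, target) pairs from a prediction map are linked when both are
significant with opposite directions.
"""

from accsig import (SimConfig, chipseq_overlap_fraction, derive_signature,
                    fisher_enrichment, generate_cohort, integrate_mutations,
                    mirna_mrna_links)

cohort = generate_cohort(SimConfig(seed=1))
sig = derive_signature(cohort.mrna, cohort.sheet)
mi_sig = derive_signature(cohort.mirna, cohort.sheet, min_intensity=800.0)

universe = list(sig.index[sig["passed_baseline"]])
signature = list(sig.index[sig["significant"]])
enr = fisher_enrichment(signature, cohort.gene_sets, universe)
print("enrichment (universe = baseline-filtered probes):")
print(enr[["set_name", "overlap", "set_size", "odds_ratio", "q"]]
      .round(4).to_string(index=False))

chip = cohort.gene_sets["MYB_CHIP_TARGETS"]
print(f"\nChIP target overlap: {chipseq_overlap_fraction(signature, chip):.0%} "
      "of the signature are candidate MYB-related genes")

muts = integrate_mutations(sig, cohort.mutations)
print("\nmutated AND up-regulated (candidate co-drivers):")
print(muts.round(2).to_string(index=False))

links = mirna_mrna_links(mi_sig, sig, cohort.mirna_map)
print("\ninverse miRNA -> target links:")
print(links.round(3).to_string(index=False))
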