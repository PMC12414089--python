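"""Cohort screening and classification of the shipped variant table.

Reproduces the population arithmetic for the 11 private homozygous
protein-changing variants found in the three white-coat cases: allele
frequencies, non-case homozygote counts, breed specificity, and the
evidence-based classification labels.
"""

import triomap as tm

counts = tm.load_case_variant_counts()

grid1 = tm.screen_cohorts("28:40526902:G:T", counts, breed="Simmental",
                          include_case=True)
print(f"GRID1 missense, Simmental (WGS + array, case included): "
      f"allele frequency {grid1.allele_frequency:.4f} over "
      f"{grid1.n_genotyped} genotypes; breed-specific: {grid1.breed_specific}")

tyr = tm.screen_cohorts("29:6343738:G:A", counts,
                        populations=["Simmental_array"])
print(f"TYR missense: {tyr.n_refref} array-genotyped Simmental, none "
      f"carrying the variant allele")

nsmf_hom = tm.count_homozygotes("NSMF:case3", counts, breed="Simmental",
                                exclude_case=True)
print(f"NSMF variant: {nsmf_hom} normal-colored Simmental homozygotes "
      "(unaffected homozygotes argue against pathogenicity)")

tab = tm.classify_case_variant_table()
print("\nclassification of all 11 variants (default rule table):")
print(tab[["gene", "case", "votes", "control_hom", "breed_specific",
           "classification"]].to_string(index=False))
split = tab["classification"].value_counts()
print(f"\nsplit: {split.get('likely_pathogenic', 0)} likely pathogenic / "
      f"{split.get('uncertain_significance', 0)} uncertain / "
      f"{split.get('likely_benign', 0)} likely benign")
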