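"""Generate a synthetic two-species dataset and look at its structure.

Two dioecious species, "A" and "B", with independently evolved XY
chromosomes: a gene sex-linked in one species is autosomal in the other,
and ortholog pairs share their ancestral expression profile.
"""

import haplosel as h

cfg = h.SimConfig(n_genes=2000, seed=1)
ds = h.simulate_dataset(cfg)

print("gene classes per species:")
print(ds.catalog.groupby("species")["true_class"].value_counts().unstack())
print()
print(f"counts matrix: {ds.counts.shape[0]} genes x {ds.counts.shape[1]} samples")
print(f"mean library size: {ds.counts.sum(axis=0).mean():,.0f} reads")
print(f"genotype panel A: {ds.panels['A'].genotypes.shape[0]} sites x "
      f"{ds.panels['A'].genotypes.shape[1]} individuals")
print(f"allelic count records: {len(ds.allelic):,}")
print()
print("Each species carries ~15% sex-linked genes, half hemizygous under the")
print("flat default retention model; fixed X-Y SNP differences (3 per")
print("sex-linked gene) plus X-polymorphism decoys feed the linkage caller.")
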