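"""Classify reference genes as haplotype-consistent or mosaic.

A collapsed diploid assembly can splice the two parental alleles together
within one locus. Each gene's reference sequence is aligned to its haplotype A
and B counterparts; sites where A and B differ diagnose which parent the
reference copied. A gene matching A at some sites and B at others is mosaic.
"""

from collections import Counter

from pollenphase import classify_triplet, mosaic_report, simulate_gene_triplets

triplets, truth = simulate_gene_triplets(n_genes=80, seed=3)
calls = [classify_triplet(t) for t in triplets]
report = mosaic_report(calls)

print("class counts:")
for klass, n in sorted(report.counts.items()):
    print(f"  {klass:16s} {n}")
print(f"mosaic genes:             {report.n_mosaic} ({report.mosaic_pct}%)")
agree = sum(1 for c in calls if c.klass == truth[c.gene_id])
print(f"agreement with truth:     {agree}/{len(calls)}")

example = next(c for c in calls if c.klass.startswith("mosaic"))
print(f"example {example.gene_id}: {example.n_sites_a} sites match A, "
      f"{example.n_sites_b} match B, switch at {example.switch_positions}")

# mosaic_exon means at least one minority-haplotype site falls in an exon —
# these are the assembly errors that corrupt gene models.
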