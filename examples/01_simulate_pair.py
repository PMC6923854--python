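"""Simulate a clonal genome pair with a recorded truth set.

Generates a 100 kb high-GC ancestor (dense CDSs with Shine-Dalgarno motifs
upstream of start codons) and a derived genome separated from it by point
mutations, homopolymer sequencing-style indels and one large deletion.
"""

from clonalpair import AncestorParams, DivergenceParams, generate_ancestor, simulate_divergence

ancestor = generate_ancestor(AncestorParams(replicon_lengths=[100_000], seed=1))
derived, truth = simulate_divergence(
    ancestor,
    DivergenceParams(seed=2, large_indel_rate=1, homopolymer_indel_rate=0.02),
)

print(f"ancestor: {ancestor.length:,} bp, GC {ancestor.gc_fraction():.3f}, "
      f"{len(ancestor.cds())} CDSs")
print(f"derived:  {derived.length:,} bp")
print(f"truth: {len(truth.snps)} SNPs, {len(truth.indels)} indels")
silent = sum(1 for s in truth.snps if s.effect == "silent")
coding = sum(1 for s in truth.snps if s.effect is not None)
print(f"of {coding} CDS SNPs, {silent} are silent "
      f"(syn:nonsyn = {silent / (coding - silent):.2f})")
# The silent excess reflects the acceptance bias against non-synonymous
# changes, emulating purifying selection within a clonal complex.
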