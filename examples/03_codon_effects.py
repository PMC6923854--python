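"""Classify CDS SNPs by codon effect and tally synonymous/non-synonymous changes.

Each CDS SNP is read in coding orientation and labelled silent, missense,
nonsense or stop-loss under the bacterial translation table; the summary
reports the raw syn:nonsyn count ratio and per-site dS/dN with equal-weight
(Nei-Gojobori style) site counting.
"""

from clonalpair import (
    AncestorParams, DivergenceParams, align_genomes, call_variants,
    classify_variants, ds_dn, generate_ancestor, simulate_divergence,
)

ancestor = generate_ancestor(AncestorParams(replicon_lengths=[100_000], seed=1))
derived, _ = simulate_divergence(ancestor, DivergenceParams(seed=2))
alignment = align_genomes(ancestor, derived)
variants = call_variants(alignment, ancestor.sequences, derived.sequences)

effects = classify_variants(variants, ancestor)
summary = ds_dn(effects, [ancestor.cds_sequence(f) for f in ancestor.cds()])

print(f"classified CDS SNPs: {summary.n_classified}")
print(f"effect counts: {summary.counts}")
print(f"raw syn:nonsyn ratio: {summary.raw_ratio:.2f}")
print(f"per-site dS={summary.dS:.4f}, dN={summary.dN:.4f}, "
      f"dS/dN={summary.ds_dn_per_site:.2f}")
print(f"conservative missense fraction: {summary.conservative_fraction:.2f}")
top = sorted(summary.codon_transitions.items(), key=lambda kv: -kv[1])[:5]
print("most frequent codon transitions:", top)
# A raw ratio near 1.8 with a per-site dS/dN well above 1 is the signature of
# weak purifying selection within a recently diverged clonal complex.
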