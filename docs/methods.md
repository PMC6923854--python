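# Methods

This note documents the models and procedures implemented in `clonalpair`,
the defaults that matter, and what the synthetic-data validation does and
does not demonstrate.

## Scope and assumptions

The package targets pairs of assembled bacterial genomes from the same
clonal complex: divergence is assumed to be dominated by point mutation and
block gain/loss, not recombination or rearrangement. Alignment is therefore
collinear and forward-strand only — inverted or transposed segments surface
as unaligned gap intervals, which is the honest behavior for this model
rather than a limitation in disguise. Annotations (CDS, rRNA, tRNA,
optional BGC intervals) are inputs; the package does not predict genes.
Internally all coordinates are 0-based half-open; GFF3 and VCF emitters use
those formats' 1-based conventions.

## Collinear alignment (seed–chain–close)

1. **Anchors**: exact matches of length *k* (default 21) that are unique in
   both genomes. Uniqueness in both is required so that repeat families
   (e.g. rRNA operon copies) cannot seed misjoins. Adjacent same-diagonal
   anchors are merged into maximal exact runs.
2. **Chaining**: the highest-scoring chain of runs with strictly
   co-increasing starts, scored by anchored bases; a successor overlapping
   its predecessor (a k-mer straddling an indel junction can do this) is
   trimmed from the left. Ties prefer the leftmost chain, making the output
   deterministic.
3. **Closing**: each inter-anchor segment is globally aligned when it is
   shorter than `join_threshold` (default 10 kb) and its length imbalance is
   within `band` (default 50) gap columns — checked again on the realized
   alignment. Unit-cost alignment can represent two adjacent substitutions
   as an insertion+deletion pair at equal cost; segments whose alignment
   mixes both gap directions are therefore refined with an affine scorer
   (match +1, mismatch −1, gap open 5, extend 2) that prefers substitution
   columns. Segments failing the band test become gap intervals attributed
   to the genome holding the extra sequence; unalignable sequence at
   replicon ends is reported as tails. Aligned + gap + tail bases account
   for every base of each replicon exactly once, an invariant the test
   suite enforces.

Variant calling walks the block alignments column-wise: one record per
mismatch (SNP) and one per gap run up to `band` columns (insertion/
deletion), with indels shifted left while the preceding aligned column
repeats the indel's trailing base (canonical homopolymer placement) and
annotated with the homopolymer run length at the site. Aligned identity is
matches / (matches + mismatches); gap columns are excluded. The large-event
report keeps unaligned intervals **strictly longer** than 100 bp (the
threshold is a flag) and expresses them as a fraction of genome length;
whole replicons present in one genome only (plasmid gain/loss) count in
full.

## Codon effects and dS/dN

CDS SNPs are read in coding orientation (alleles complemented on
reverse-strand genes) and classified under translation table 11. Default
semantics are per-SNP — the partner codon is the reference codon with that
single base substituted — matching one-arc-per-SNP transition tallies; a
joint per-codon mode applies co-occurring SNPs together. The chemistry
partition is acidic {D,E}, basic {K,R,H}, hydrophilic {S,T,N,Q,C,G,Y},
hydrophobic {A,V,L,I,P,M,F,W}, stop; it is configurable because no single
partition is canonical.

Two syn/nonsyn statistics are reported side by side: the **raw count
ratio** n_syn/n_nonsyn, which is the customary headline for clonal pairs,
and per-site dS/dN with synonymous site counts from equal-weight
enumeration of all nine single-base changes per codon (Nei–Gojobori style;
terminal stop codons excluded from site counting, changes to or from stops
counted as non-synonymous). The raw ratio is flagged undefined rather than
divided when there are no non-synonymous changes. No maximum-likelihood
codon model is attempted; an optional Jukes–Cantor correction of the
per-site proportions is the only multiple-hit adjustment.

## Positional enrichment

The upstream profile counts SNPs at each offset −60..−1 from the start
codon (strand-aware), dividing each position's count by the number of CDSs
contributing a valid position there — positions inside a neighboring CDS or
off the replicon are excluded from the denominator, which makes profiles
comparable between genomes with different gene spacing. Smoothing is a
centered width-3 window with truncated edges. The null band is the mean ±
SD of per-position densities over −60..−21, far enough upstream to avoid
both the Shine-Dalgarno window (default −15..−5, configurable — the window
is only approximately localizable) and the spacer next to the start codon.

The relative-CDS profile assigns each CDS SNP to bin ⌊pos/length·100⌋ and
takes the null mean/SD over bins at relative position ≥ 0.10, i.e. the last
90% of the CDS; only CDSs at least as long as the bin count participate.
`enrichment_zscore` is (region mean − null mean)/null SD and raises on a
degenerate null. SNPs under overlapping CDSs count once per CDS context by
default (a single-count mode exists); the generator never produces
overlapping genes, so this only matters for real annotations.

## Frameshift adjudication

Each disagreement locus yields two windows of ±150 b (truncated at replicon
ends) differing by exactly the variant. Windows are translated in all six
frames (stops kept as `*`; local alignment may span them, as a translated
database search would) and aligned against every reference protein with
BLOSUM62, gap open 11 / extend 1 — BLASTx-like scoring, but ranked by raw
score instead of E-value: with a fixed reference set the raw score is
monotone in the same quantity and fully reproducible offline. The best
hit is informative only if it clears `min_score` (50) and its query span
covers the variant position with ≥ 10 residues on each side — a hit
touching only a window edge says nothing about the variant. Verdicts:
A (or B) when the score difference reaches `margin` (5) **and** the winner's
hit is centered; tie below the margin; uninformative when neither window
has a centered hit (non-coding locus or no homolog in the reference set).
Swapping the windows swaps A and B exactly.

## Relatedness and replicon statistics

Markers are extracted as the lowest-edit-distance infix hit of each
reference sequence over both strands of every replicon, kept when the
approximate identity (1 − edits/|reference|) reaches `min_identity` (0.75)
and flagged incomplete otherwise — incomplete markers drop out of the
concatenation, supporting four-gene fallbacks. Percent identity globally
aligns each shared marker and pools matches over non-gap columns (gap
columns excluded — pairwise deletion; the choice matters only at higher
divergence). Distances are 1 − identity; the neighbor-joining tree is
provided as plumbing for inspection, not as a substitute for a
likelihood phylogeny. The marker regions are defined by whatever reference
sequences the user supplies; identity values on real data depend on those
extents.

BGC overlap is interval-and-class based: a cluster is shared when ≥ 50%
(configurable) of its span maps through aligned columns into same-class
clusters of the partner genome. Clusters on a replicon the partner lacks
are unshared by construction. This deliberately does not compare protein
content.

Replicon statistics report GC fraction, whole-replicon skew
(G−C)/(G+C), and tiled window profiles at 10 kb and 1 Mb (partial final
window); windows without G or C get skew 0. Feature counts come from the
annotation as given.

## The synthetic-genome simulator

**What it emulates.** High-GC (default 72%) replicons with ~85% CDS
density; every CDS in-frame with ATG start, a sampled stop, and no internal
stops; an IUPAC Shine-Dalgarno motif (default `AGGAGG`) planted 5–10 bases
upstream of every start codon, strand-aware; homopolymer-enriched
intergenic sequence via a Markov chain whose repeat probability is
multiplied by `homopolymer_boost` (default 2) — the input base weights are
solved so the chain's stationary distribution still hits the GC target, and
at boost 1 run lengths are exactly geometric. Divergence applies per-base
Bernoulli substitutions at `snp_rate` (default 5×10⁻³, the order of a
closely related clonal pair at ~40 k SNPs per 8 Mb), suppressed by
`sd_suppression` inside the SD window and `cds5_suppression` in the first
10% of each CDS; single-base homopolymer indels in sequencing-error mode;
large (>100 bp) insertions in intergenic DNA and deletions snapped to
whole-gene spans (so annotations stay valid — block gain/loss, the
dominant observed mode); and plasmid gain/loss directives. Every event is
recorded in a truth set that reconstructs the derived genome exactly
(SNPs, then indels in descending position, then replicon events), and
identical seeds give byte-identical output.

**Silent bias.** A proposed CDS substitution that is non-synonymous is
accepted with probability `silent_bias` relative to a synonymous proposal
(site-level acceptance–rejection). Allele-level re-weighting cannot produce
a silent majority — only about a third of CDS sites have any synonymous
alternative — so rejection is the right mechanism; to keep the realized
rate equal to `snp_rate`, the CDS proposal rate is inflated by the inverse
of the expected acceptance, computed exactly from the genome's codon
composition. The default `silent_bias = 0.25` yields a silent fraction of
~0.64 (syn:nonsyn ≈ 1.8) on the default high-GC ancestor, whose GC-rich
codon usage makes ~31% of random proposals synonymous.

**What it does not emulate**, and hence what passing tests do not show
about real data: no recombination or HGT mosaicism beyond block gain/loss,
no rearrangements or inversions, no read-level error model (errors are
applied to assembled sequence), no operon structure or expression-coupled
mutation biases, uniform mutation rates outside the modeled suppression
windows, and no overlap between genes. Real pairs also differ in ways the
marker module is sensitive to (rRNA operon copy variation, marker-specific
conservation), so synthetic multilocus identities track genome-wide
divergence more tightly than real ones do.

## Problem sizes and statistical choices in the validation

Desk-scale runs use 100–200 kb replicons (~90 CDSs per 100 kb): large
enough that GC and rate contracts concentrate (binomial SD of GC at 50 kb
is ~0.002 against a ±0.01 tolerance) while the whole suite stays fast. The
suppression-recovery sweep uses `snp_rate = 0.1` rather than the clonal
default: the SD-window z separates adjacent sweep levels by
(Δsup)·√(n_CDS·r/(1−r)) ≈ 1.3 at r = 0.1 with ~90 CDSs, giving >99%
probability of a perfect 4-level ordering per replicate set, whereas at
r = 0.05 the separation (~0.9) makes a 10-set experiment flaky. The
forced CDS-5′ case uses r = 0.02 so that null bins average >4 SNPs and the
2-SD band sits above zero. Adjudication validation uses a 60 kb genome
(~55 proteins) and 200 homopolymer loci ≥ 60 b inside CDSs, with the
ancestral proteome as the reference set. Acceptance-script conditions are
stated in its docstring; all randomness derives from the `--seed` argument.

## Numerical and degenerate-input choices

Zero aligned columns, a zero null SD, an empty protein set, a window
shorter than a codon, no shared complete markers, and fewer than two
genomes all raise typed errors rather than returning NaN. Bernoulli
probabilities are clipped at 1 after suppression/compensation multipliers.
Large-indel placement re-draws on overlap and fails with a simulation error
after 100 attempts rather than looping. Chain ties and aligner ties are
broken deterministically (leftmost; first-maximum). The VCF emitted is
minimal (CHROM/POS/REF/ALT plus mate coordinate and homopolymer length in
INFO) and round-trips through the package's reader.
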