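"""Codon-effect classification of CDS SNPs and synonymous/non-synonymous accounting.

Each SNP falling inside a CDS is read in coding orientation (alleles are
complemented on reverse-strand genes), classified as silent, missense,
nonsense or stop-loss under the bacterial translation table, and labelled
with the amino-acid chemistry transition. Aggregates include the ordered
codon-pair tally, the raw synonymous:non-synonymous count ratio (the
headline number for clonal pairs), and per-site dS/dN with Nei-Gojobori
equal-weight site counting over the reference CDSs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .align import VariantRecord
from .codons import CODON_TO_AA, SYNONYMOUS_ALT_COUNTS, synonymous_sites
from .errors import AnnotationError, InputError, UndefinedResultError
from .genome import AnnotatedGenome, Feature

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default amino-acid chemistry partition (configurable via ``chemistry=``)
DEFAULT_CHEMISTRY: dict[str, str] = {}
for _aa in "AVLIPMFW":
    DEFAULT_CHEMISTRY[_aa] = "hydrophobic"
for _aa in "STNQCGY":
    DEFAULT_CHEMISTRY[_aa] = "hydrophilic"
for _aa in "KRH":
    DEFAULT_CHEMISTRY[_aa] = "basic"
for _aa in "DE":
    DEFAULT_CHEMISTRY[_aa] = "acidic"
DEFAULT_CHEMISTRY["*"] = "stop"


def chemistry_class(residue: str, chemistry: dict[str, str] | None = None) -> str:
    """Chemistry class of a residue (or stop): hydrophobic/hydrophilic/basic/acidic/stop."""
    table = chemistry or DEFAULT_CHEMISTRY
    try:
        return table[residue.upper()]
    except KeyError:
        raise InputError(f"unknown residue {residue!r}") from None


@dataclass(frozen=True)
class CodonEffect:
    """A classified CDS SNP: codon pair, effect class, chemistry transition."""

    variant: VariantRecord
    cds_id: str
    codon_index: int  # 0-based within the CDS
    codon_a: str
    codon_b: str
    aa_a: str
    aa_b: str
    effect: str  # silent / missense / nonsense / stop_loss
    chem_a: str
    chem_b: str


@dataclass
class EffectSummary:
    """Aggregate counts over classified CDS SNPs.

    ``raw_ratio`` is n_syn/n_nonsyn (None when n_nonsyn == 0); dS/dN are the
    per-site variants with equal-weight enumeration site counts. The raw
    count ratio is the headline statistic for clonal genome pairs.
    """

    counts: dict[str, int] = field(default_factory=dict)
    codon_transitions: dict[tuple[str, str], int] = field(default_factory=dict)
    chemistry_transitions: dict[tuple[str, str], int] = field(default_factory=dict)
    n_syn: int = 0
    n_nonsyn: int = 0
    raw_ratio: float | None = None
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    dS: float | None = None
    dN: float | None = None
    ds_dn_per_site: float | None = None

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def conservative_fraction(self) -> float | None:
        """Fraction of missense changes preserving the chemistry class.

        Chemistry transitions with a changed non-stop class are exactly the
        non-conservative missense records (silent records never change the
        class; nonsense/stop-loss transitions involve the stop class).
        """
        n_missense = self.counts.get("missense", 0)
        if n_missense == 0:
            return None
        changed = sum(
            v
            for (ca, cb), v in self.chemistry_transitions.items()
            if ca != cb and "stop" not in (ca, cb)
        )
        return (n_missense - changed) / n_missense


def build_cds_index(genome: AnnotatedGenome) -> dict[str, IntervalTree]:
    """Per-replicon interval tree over CDS features."""
    trees: dict[str, IntervalTree] = {}
    for feat in genome.cds():
        trees.setdefault(feat.replicon, IntervalTree()).addi(feat.start, feat.end, feat)
    return trees


def classify_snp(
    variant: VariantRecord,
    genome: AnnotatedGenome,
    cds_index: dict[str, IntervalTree] | None = None,
    chemistry: dict[str, str] | None = None,
) -> CodonEffect | None:
    """Classify a SNP by codon effect; returns None for non-CDS (intergenic) SNPs.

    Default semantics are per-SNP: the partner codon is the reference codon
    with this SNP's alternate base substituted, holding other positions at
    reference (one record per SNP, as in arc-per-SNP tallies). Use
    :func:`classify_variants` with ``mode="per_codon"`` for the joint mode.
    """
    if variant.kind != "snp":
        raise InputError("classify_snp expects a SNP record")
    if cds_index is None:
        cds_index = build_cds_index(genome)
    tree = cds_index.get(variant.replicon_a)
    hits = sorted(tree[variant.a_position], key=lambda iv: iv.begin) if tree else []
    if not hits:
        return None
    feat: Feature = hits[0].data
    return _classify_in_cds(variant, variant.alt, feat, genome, chemistry)


def _classify_in_cds(
    variant: VariantRecord,
    alt: str,
    feat: Feature,
    genome: AnnotatedGenome,
    chemistry: dict[str, str] | None,
    extra_subs: dict[int, str] | None = None,
) -> CodonEffect:
    if feat.length % 3 != 0:
        raise AnnotationError(
            f"CDS {feat.feature_id} length {feat.length} is not a multiple of 3"
        )
    pos = variant.a_position
    if feat.strand == "+":
        i = pos - feat.start
    else:
        i = feat.end - 1 - pos
    ci, off = divmod(i, 3)
    cds_seq = genome.cds_sequence(feat)
    codon_a = cds_seq[3 * ci : 3 * ci + 3]
    alt_c = alt if feat.strand == "+" else _COMPLEMENT[alt]
    codon_b = list(codon_a)
    codon_b[off] = alt_c
    if extra_subs:
        for o2, b2 in extra_subs.items():
            codon_b[o2] = b2
    codon_b = "".join(codon_b)
    aa_a, aa_b = CODON_TO_AA[codon_a], CODON_TO_AA[codon_b]
    if aa_a == aa_b:
        effect = "silent"
    elif aa_b == "*":
        effect = "nonsense"
    elif aa_a == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    return CodonEffect(
        variant=variant,
        cds_id=feat.feature_id,
        codon_index=ci,
        codon_a=codon_a,
        codon_b=codon_b,
        aa_a=aa_a,
        aa_b=aa_b,
        effect=effect,
        chem_a=chemistry_class(aa_a, chemistry),
        chem_b=chemistry_class(aa_b, chemistry),
    )


def classify_variants(
    variants,
    genome: AnnotatedGenome,
    mode: str = "per_snp",
    chemistry: dict[str, str] | None = None,
) -> list[CodonEffect]:
    """Classify all SNPs in a variant set (list or VariantSet) against genome A.

    ``mode="per_snp"`` (default) emits one record per SNP with other codon
    positions held at reference; ``mode="per_codon"`` applies all SNPs
    hitting the same codon jointly to the partner codon of each record.
    """
    records = getattr(variants, "records", variants)
    index = build_cds_index(genome)
    snps = [r for r in records if r.kind == "snp"]
    if mode == "per_snp":
        out = []
        for r in snps:
            eff = classify_snp(r, genome, index, chemistry)
            if eff is not None:
                out.append(eff)
        return out
    if mode != "per_codon":
        raise InputError("mode must be per_snp or per_codon")
    # group SNPs by (cds, codon_index)
    staged: dict[tuple[str, int], list[tuple[VariantRecord, Feature, int, str]]] = {}
    for r in snps:
        tree = index.get(r.replicon_a)
        hits = sorted(tree[r.a_position], key=lambda iv: iv.begin) if tree else []
        if not hits:
            continue
        feat = hits[0].data
        i = r.a_position - feat.start if feat.strand == "+" else feat.end - 1 - r.a_position
        alt_c = r.alt if feat.strand == "+" else _COMPLEMENT[r.alt]
        staged.setdefault((feat.feature_id, i // 3), []).append((r, feat, i % 3, alt_c))
    out = []
    for (_, _), group in sorted(staged.items(), key=lambda kv: kv[0]):
        subs = {off: alt for _, _, off, alt in group}
        for r, feat, off, _ in group:
            extra = {o: b for o, b in subs.items() if o != off}
            out.append(_classify_in_cds(r, r.alt, feat, genome, chemistry, extra_subs=extra))
    return out


def codon_transition_tally(effects: list[CodonEffect]) -> EffectSummary:
    """Tally ordered codon pairs, chemistry transitions, and effect classes."""
    summary = EffectSummary()
    counts: Counter = Counter()
    ctrans: Counter = Counter()
    chem: Counter = Counter()
    for e in effects:
        counts[e.effect] += 1
        ctrans[(e.codon_a, e.codon_b)] += 1
        chem[(e.chem_a, e.chem_b)] += 1
    summary.counts = dict(counts)
    summary.codon_transitions = dict(ctrans)
    summary.chemistry_transitions = dict(chem)
    summary.n_syn = counts.get("silent", 0)
    summary.n_nonsyn = (
        counts.get("missense", 0) + counts.get("nonsense", 0) + counts.get("stop_loss", 0)
    )
    summary.raw_ratio = (
        summary.n_syn / summary.n_nonsyn if summary.n_nonsyn > 0 else None
    )
    return summary


def ds_dn(
    effects: list[CodonEffect],
    cds_sequences: list[str],
    jukes_cantor: bool = False,
) -> EffectSummary:
    """Raw syn:non-syn count ratio plus per-site dS/dN.

    ``cds_sequences`` are the reference CDS nucleotide sequences in coding
    orientation; synonymous/non-synonymous site counts are computed per sense
    codon by equal-weight enumeration of all nine single-base changes
    (terminal stop codons are excluded from site counting). The raw count
    ratio is reported as the headline; ``raw_ratio`` is None (undefined
    flag) when there are no non-synonymous changes.
    """
    if not effects:
        raise InputError("ds_dn needs at least one classified CDS SNP")
    summary = codon_transition_tally(effects)
    syn_sites = 0.0
    n_codons = 0
    for cds in cds_sequences:
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci : 3 * ci + 3]
            if CODON_TO_AA.get(codon, "*") == "*":
                continue
            syn_sites += synonymous_sites(codon)
            n_codons += 1
    summary.syn_sites = syn_sites
    summary.nonsyn_sites = 3.0 * n_codons - syn_sites
    if summary.syn_sites > 0:
        ps = summary.n_syn / summary.syn_sites
        summary.dS = _jc(ps) if jukes_cantor else ps
    if summary.nonsyn_sites > 0:
        pn = summary.n_nonsyn / summary.nonsyn_sites
        summary.dN = _jc(pn) if jukes_cantor else pn
    if summary.dS is not None and summary.dN not in (None, 0.0):
        summary.ds_dn_per_site = summary.dS / summary.dN
    return summary


def _jc(p: float) -> float:
    """Jukes-Cantor correction of a per-site proportion."""
    if p >= 0.75:
        raise UndefinedResultError("Jukes-Cantor correction undefined for p >= 0.75")
    return -0.75 * np.log1p(-4.0 * p / 3.0)
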