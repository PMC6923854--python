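"""Bacterial genetic code (translation table 11) lookup tables.

Stops are represented as ``"*"``. Synonymous-site arithmetic follows the
equal-weight single-substitution enumeration (Nei-Gojobori style): for every
codon position, the synonymous fraction is the share of the three possible
single-base changes that preserve the encoded residue; changes to or from a
stop codon count as non-synonymous.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

_T11 = CodonTable.unambiguous_dna_by_id[11]

CODON_TO_AA: dict[str, str] = dict(_T11.forward_table)
for _stop in _T11.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = tuple(_T11.stop_codons)
SENSE_CODONS = tuple(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")


def translate_codon(codon: str) -> str:
    """Amino acid (or ``*``) for a codon; raises KeyError on non-ACGT."""
    return CODON_TO_AA[codon]


def effect_of_codon_change(codon_a: str, codon_b: str) -> str:
    """Effect class of a codon substitution: silent/missense/nonsense/stop_loss."""
    aa_a, aa_b = CODON_TO_AA[codon_a], CODON_TO_AA[codon_b]
    if aa_a == aa_b:
        return "silent"
    if aa_b == "*":
        return "nonsense"
    if aa_a == "*":
        return "stop_loss"
    return "missense"


def _synonymous_alt_counts() -> dict[str, tuple[int, int, int]]:
    out = {}
    for codon in CODON_TO_AA:
        counts = []
        for pos in range(3):
            k = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if (
                    CODON_TO_AA[codon] != "*"
                    and CODON_TO_AA[alt] != "*"
                    and CODON_TO_AA[alt] == CODON_TO_AA[codon]
                ):
                    k += 1
                elif CODON_TO_AA[codon] == "*" and CODON_TO_AA[alt] == "*":
                    k += 1  # stop-preserving change, treated as synonymous
            counts.append(k)
        out[codon] = tuple(counts)
    return out


#: codon -> per-position count (0..3) of synonymous single-base alternatives
SYNONYMOUS_ALT_COUNTS: dict[str, tuple[int, int, int]] = _synonymous_alt_counts()


def synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3); non-syn sites = 3 - this."""
    return sum(SYNONYMOUS_ALT_COUNTS[codon]) / 3.0
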