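"""Frameshift-aware adjudication of assembly disagreements.

When two assemblies of the same genome disagree at a locus (typically a
single-base indel in a homopolymer run, the characteristic long-read error),
the variant-containing window of each assembly is translated in all six
frames and locally aligned against a protein reference set. A frameshift
truncates the translated match, so the erroneous variant scores worse. The
verdict also requires the best hit to cover the variant position away from
the window edges, mirroring the caveats of database-search adjudication.

Scores are raw affine-gap substitution-matrix alignment scores (BLOSUM62,
gap open 11 / extend 1 by default): fully reproducible offline and monotone
in the same quantity an E-value ranking would order for a fixed reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .codons import CODON_TO_AA
from .errors import InputError
from .genome import revcomp


@dataclass(frozen=True)
class DisagreementLocus:
    """A locus where assemblies A and B disagree, with its sequence windows."""

    replicon: str
    position_a: int
    position_b: int
    description: str  # e.g. 'snp', 'insertion:G', 'deletion:C'
    window_a: str
    window_b: str
    variant_offset_a: int  # variant position within window_a
    variant_offset_b: int


@dataclass(frozen=True)
class AdjudicationResult:
    locus: DisagreementLocus
    score_a: float
    score_b: float
    center_ok_a: bool
    center_ok_b: bool
    verdict: str  # 'A', 'B', 'tie', 'uninformative'


@dataclass
class AdjudicationSummary:
    counts: dict[str, int] = field(default_factory=dict)
    ratio_a_to_b: float | None = None
    mean_score_difference: float = 0.0


@dataclass
class ScoringParams:
    """Translated-alignment scoring knobs (BLASTx-like defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    margin: float = 5.0  # score-units margin between verdicts
    center_margin: int = 10  # residues of query coverage required on each side
    min_score: float = 50.0  # below this the hit is not considered informative


def extract_windows(
    assembly_a: dict[str, str],
    assembly_b: dict[str, str],
    loci,
    flank: int = 150,
) -> list[DisagreementLocus]:
    """Cut +/- flank windows around each disagreement locus.

    ``loci`` is an iterable of variant-like records with ``replicon_a``,
    ``a_position``, ``b_position``, ``kind``, ``ref`` and ``alt`` attributes
    (a VariantSet works directly). Windows are truncated at replicon ends.
    """
    out: list[DisagreementLocus] = []
    for r in getattr(loci, "records", loci):
        rep = r.replicon_a
        if rep not in assembly_a or rep not in assembly_b:
            raise InputError(f"locus replicon {rep} missing from an assembly")
        sa, sb = assembly_a[rep], assembly_b[rep]
        if not (0 <= r.a_position <= len(sa)) or not (0 <= r.b_position <= len(sb)):
            raise InputError(f"locus {rep}:{r.a_position} outside replicon")
        len_a = len(r.ref) if r.ref != "." else 0
        len_b = len(r.alt) if r.alt != "." else 0
        a0 = max(0, r.a_position - flank)
        b0 = max(0, r.b_position - flank)
        wa = sa[a0 : min(len(sa), r.a_position + len_a + flank)]
        wb = sb[b0 : min(len(sb), r.b_position + len_b + flank)]
        desc = r.kind if r.kind == "snp" else f"{r.kind}:{r.alt if r.kind == 'insertion' else r.ref}"
        out.append(
            DisagreementLocus(
                replicon=rep,
                position_a=r.a_position,
                position_b=r.b_position,
                description=desc,
                window_a=wa,
                window_b=wb,
                variant_offset_a=r.a_position - a0,
                variant_offset_b=r.b_position - b0,
            )
        )
    return out


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs open + k * extend
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    aln.mode = "local"
    return aln


def six_frame_translations(window: str) -> list[tuple[str, int, str]]:
    """(frame label, frame offset, peptide) for all six frames.

    Stops are kept as '*' (local alignment may span them, as a translated
    database search would); ambiguous codons translate to 'X'.
    """
    out = []
    for strand, seq in (("+", window), ("-", revcomp(window))):
        for f in range(3):
            pep = "".join(
                CODON_TO_AA.get(seq[i : i + 3], "X")
                for i in range(f, len(seq) - 2, 3)
            )
            if pep:
                out.append((f"{strand}{f}", f, pep))
    return out


def _variant_residue(frame_label: str, frame: int, offset: int, window_len: int) -> int:
    """Residue index covering a window nucleotide offset in the given frame."""
    if frame_label.startswith("-"):
        offset = window_len - 1 - offset
    return max(0, (offset - frame) // 3)


def score_window(
    window: str,
    proteins: dict[str, str],
    variant_offset: int,
    params: ScoringParams | None = None,
) -> tuple[float, bool]:
    """Best translated local-alignment score of a window against a protein set.

    Translates the window in all six frames, locally aligns each frame
    against each protein with an affine-gap substitution-matrix scorer, and
    returns the maximum score plus whether that best alignment's query span
    covers ``variant_offset`` with at least ``center_margin`` residues on
    each side (and clears ``min_score``).
    """
    if not proteins:
        raise InputError("protein reference set is empty")
    if len(window) < 3:
        raise InputError("window shorter than one codon")
    p = params or ScoringParams()
    aligner = _aligner(p.matrix, p.gap_open, p.gap_extend)
    best = (float("-inf"), None, None, None)  # score, frame_label, frame, (pep, prot)
    frames = six_frame_translations(window)
    for label, frame, pep in frames:
        for pname, prot in proteins.items():
            s = aligner.score(pep, prot)
            if s > best[0]:
                best = (s, label, frame, (pep, prot))
    score, label, frame, seqs = best
    if score <= 0 or seqs is None:
        return 0.0, False
    if score < p.min_score:
        return float(score), False
    pep, prot = seqs
    alignment = aligner.align(pep, prot)[0]
    q_spans = alignment.aligned[0]
    q_start, q_end = int(q_spans[0][0]), int(q_spans[-1][-1])  # [start, end)
    var_res = _variant_residue(label, frame, variant_offset, len(window))
    center_ok = (
        q_start + p.center_margin <= var_res <= q_end - 1 - p.center_margin
    )
    return float(score), bool(center_ok)


def adjudicate(
    locus: DisagreementLocus,
    proteins: dict[str, str],
    params: ScoringParams | None = None,
) -> AdjudicationResult:
    """Decide which assembly variant is correct at one locus.

    Verdict 'A' requires score_a - score_b >= margin with a centered,
    informative A hit (symmetrically for 'B'); |difference| < margin is a
    tie; and the locus is 'uninformative' when neither window has a centered
    hit (no coding context or no homolog in the reference set).
    """
    p = params or ScoringParams()
    score_a, ok_a = score_window(locus.window_a, proteins, locus.variant_offset_a, p)
    score_b, ok_b = score_window(locus.window_b, proteins, locus.variant_offset_b, p)
    if not ok_a and not ok_b:
        verdict = "uninformative"
    elif score_a - score_b >= p.margin:
        verdict = "A" if ok_a else "uninformative"
    elif score_b - score_a >= p.margin:
        verdict = "B" if ok_b else "uninformative"
    else:
        verdict = "tie"
    return AdjudicationResult(locus, score_a, score_b, ok_a, ok_b, verdict)


def adjudicate_all(
    loci: list[DisagreementLocus],
    proteins: dict[str, str],
    params: ScoringParams | None = None,
) -> list[AdjudicationResult]:
    return [adjudicate(l, proteins, params) for l in loci]


def summarize(results: list[AdjudicationResult]) -> AdjudicationSummary:
    """Verdict counts, A:B verdict ratio, and mean score difference."""
    summary = AdjudicationSummary()
    counts = {"A": 0, "B": 0, "tie": 0, "uninformative": 0}
    diff = 0.0
    for r in results:
        counts[r.verdict] += 1
        diff += r.score_a - r.score_b
    summary.counts = counts
    if counts["B"] > 0:
        summary.ratio_a_to_b = counts["A"] / counts["B"]
    elif counts["A"] > 0:
        summary.ratio_a_to_b = float("inf")
    summary.mean_score_difference = diff / len(results) if results else 0.0
    return summary
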