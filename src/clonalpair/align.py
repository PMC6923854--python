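"""Collinear pairwise genome alignment and variant calling.

Closely related clonal genomes are aligned with a seed-chain-close strategy:
exact k-mer matches unique in both genomes are found, chained into the
highest-scoring collinear set, and inter-anchor segments are closed with
global alignment. Segments that would need more gap columns than the band
are demoted to unaligned gap intervals attributed to the genome holding the
extra sequence. Forward-strand collinearity is assumed; rearrangements and
inversions surface as gaps.

Coordinates are 0-based half-open internally; the VCF writer converts to the
format's 1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .errors import InputError, UndefinedResultError
from .genome import AnnotatedGenome

# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Anchor:
    """An exact match seed: positions in A and B, and its length."""

    a: int
    b: int
    length: int

    @property
    def a_end(self) -> int:
        return self.a + self.length

    @property
    def b_end(self) -> int:
        return self.b + self.length


@dataclass
class AlignmentBlock:
    """One collinear aligned block with a base-level alignment.

    ``ops`` is run-length encoded over '=' (match), 'X' (mismatch),
    'D' (base in A only) and 'I' (base in B only).
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    ops: list[tuple[str, int]] = field(default_factory=list)

    def op_counts(self) -> dict[str, int]:
        out = {"=": 0, "X": 0, "I": 0, "D": 0}
        for op, n in self.ops:
            out[op] += n
        return out


@dataclass
class AlignmentBlockSet:
    """Ordered collinear blocks between one replicon of A and one of B."""

    replicon_a: str
    replicon_b: str
    length_a: int
    length_b: int
    blocks: list[AlignmentBlock] = field(default_factory=list)
    gaps_a: list[tuple[int, int]] = field(default_factory=list)  # in A, absent from B
    gaps_b: list[tuple[int, int]] = field(default_factory=list)  # in B, absent from A
    tails_a: list[tuple[int, int]] = field(default_factory=list)
    tails_b: list[tuple[int, int]] = field(default_factory=list)

    @property
    def identity_aligned(self) -> float:
        m = x = 0
        for blk in self.blocks:
            c = blk.op_counts()
            m += c["="]
            x += c["X"]
        if m + x == 0:
            raise UndefinedResultError("no aligned columns")
        return m / (m + x)

    def aligned_bases(self, which: str) -> int:
        key = "D" if which == "a" else "I"
        total = 0
        for blk in self.blocks:
            c = blk.op_counts()
            total += c["="] + c["X"] + c[key]
        return total

    def accounted_bases(self, which: str) -> int:
        gaps = self.gaps_a if which == "a" else self.gaps_b
        tails = self.tails_a if which == "a" else self.tails_b
        return (
            self.aligned_bases(which)
            + sum(e - s for s, e in gaps)
            + sum(e - s for s, e in tails)
        )

    def swapped(self) -> "AlignmentBlockSet":
        """The mirrored block set (A and B exchanged)."""
        flip = {"=": "=", "X": "X", "I": "D", "D": "I"}
        return AlignmentBlockSet(
            replicon_a=self.replicon_b,
            replicon_b=self.replicon_a,
            length_a=self.length_b,
            length_b=self.length_a,
            blocks=[
                AlignmentBlock(
                    b.b_start, b.b_end, b.a_start, b.a_end,
                    [(flip[op], n) for op, n in b.ops],
                )
                for b in self.blocks
            ],
            gaps_a=list(self.gaps_b),
            gaps_b=list(self.gaps_a),
            tails_a=list(self.tails_b),
            tails_b=list(self.tails_a),
        )


@dataclass
class PairAlignment:
    """Genome-level alignment: per-replicon block sets plus unmatched replicons."""

    pairs: dict[str, AlignmentBlockSet] = field(default_factory=dict)
    only_a: dict[str, int] = field(default_factory=dict)  # replicon -> length
    only_b: dict[str, int] = field(default_factory=dict)

    @property
    def identity_aligned(self) -> float:
        m = x = 0
        for bs in self.pairs.values():
            for blk in bs.blocks:
                c = blk.op_counts()
                m += c["="]
                x += c["X"]
        if m + x == 0:
            raise UndefinedResultError("no aligned columns")
        return m / (m + x)


@dataclass(frozen=True)
class VariantRecord:
    """A SNP or small indel with dual-genome coordinates."""

    replicon_a: str
    replicon_b: str
    a_position: int
    b_position: int
    kind: str  # snp / insertion (extra in B) / deletion (absent from B)
    ref: str  # A allele ('.' for insertion)
    alt: str  # B allele ('.' for deletion)
    homopolymer_run_length: int


@dataclass
class VariantSet:
    records: list[VariantRecord] = field(default_factory=list)

    def snps(self) -> list[VariantRecord]:
        return [r for r in self.records if r.kind == "snp"]

    def indels(self) -> list[VariantRecord]:
        return [r for r in self.records if r.kind != "snp"]

    def __len__(self) -> int:
        return len(self.records)

    # -- VCF round trip ---------------------------------------------------
    def write_vcf(self, path: str | Path, seq_a: dict[str, str]) -> None:
        """Minimal VCF: genome A is the reference; INFO carries the mate
        coordinate and homopolymer run length."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, s in seq_a.items():
                fh.write(f"##contig=<ID={name},length={len(s)}>\n")
            fh.write('##INFO=<ID=MATE,Number=1,Type=Integer,Description="1-based position in genome B">\n')
            fh.write('##INFO=<ID=MATEREP,Number=1,Type=String,Description="Replicon in genome B">\n')
            fh.write('##INFO=<ID=HPL,Number=1,Type=Integer,Description="Homopolymer run length at site">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in self.records:
                if r.kind == "snp":
                    pos, ref, alt = r.a_position + 1, r.ref, r.alt
                elif r.kind == "insertion":
                    if r.a_position > 0:
                        anchor = seq_a[r.replicon_a][r.a_position - 1]
                        pos, ref, alt = r.a_position, anchor, anchor + r.alt
                    else:
                        anchor = seq_a[r.replicon_a][0]
                        pos, ref, alt = 1, anchor, r.alt + anchor
                else:  # deletion (present in A, absent in B)
                    if r.a_position > 0:
                        anchor = seq_a[r.replicon_a][r.a_position - 1]
                        pos, ref, alt = r.a_position, anchor + r.ref, anchor
                    else:
                        anchor = seq_a[r.replicon_a][len(r.ref)]
                        pos, ref, alt = 1, r.ref + anchor, anchor
                info = f"MATE={r.b_position + 1};MATEREP={r.replicon_b};HPL={r.homopolymer_run_length}"
                fh.write(f"{r.replicon_a}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")

    @classmethod
    def read_vcf(cls, path: str | Path) -> "VariantSet":
        vs = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
                fields = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
                mate = int(fields.get("MATE", 0)) - 1
                materep = fields.get("MATEREP", chrom)
                hpl = int(fields.get("HPL", 0))
                if len(ref) == 1 and len(alt) == 1:
                    vs.records.append(
                        VariantRecord(chrom, materep, int(pos) - 1, mate, "snp", ref, alt, hpl)
                    )
                elif len(alt) > len(ref):  # insertion
                    ins = alt[1:] if alt.startswith(ref) else alt[:-1]
                    vs.records.append(
                        VariantRecord(chrom, materep, int(pos), mate, "insertion", ".", ins, hpl)
                    )
                else:  # deletion
                    dele = ref[1:] if ref.startswith(alt) else ref[:-1]
                    vs.records.append(
                        VariantRecord(chrom, materep, int(pos), mate, "deletion", dele, ".", hpl)
                    )
        return vs


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        pos[km] = -1 if km in pos else i
    return {km: i for km, i in pos.items() if i >= 0}


def find_anchors(seq_a: str, seq_b: str, k: int = 21) -> list[Anchor]:
    """Exact-match seeds of length k unique in both sequences, sorted by A."""
    if k < 11:
        raise InputError("k must be >= 11")
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    ua = _unique_kmer_positions(seq_a, k)
    ub = _unique_kmer_positions(seq_b, k)
    anchors = [Anchor(ia, ub[km], k) for km, ia in ua.items() if km in ub]
    anchors.sort(key=lambda a: (a.a, a.b))
    return anchors


def _merge_anchor_runs(anchors: list[Anchor]) -> list[Anchor]:
    """Collapse overlapping/adjacent same-diagonal anchors into maximal runs."""
    if not anchors:
        return []
    runs: list[Anchor] = []
    cur = anchors[0]
    for nxt in anchors[1:]:
        if nxt.b - nxt.a == cur.b - cur.a and nxt.a <= cur.a_end:
            cur = Anchor(cur.a, cur.b, max(cur.a_end, nxt.a_end) - cur.a)
        else:
            runs.append(cur)
            cur = nxt
    runs.append(cur)
    return runs


def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Highest-scoring strictly co-increasing anchor chain, trimmed to be
    non-overlapping.

    Score is total anchored bases after trimming: a successor overlapping
    its predecessor (e.g. a junction k-mer straddling an indel) is shortened
    from the left by the overlap. Overlapping same-diagonal anchors are
    first merged into maximal runs. Ties are broken toward the leftmost
    (smallest A-coordinate) chain, so the result is deterministic.
    """
    runs = _merge_anchor_runs(sorted(anchors, key=lambda a: (a.a, a.b)))
    n = len(runs)
    if n == 0:
        return []
    a0 = np.array([r.a for r in runs])
    a1 = np.array([r.a_end for r in runs])
    b0 = np.array([r.b for r in runs])
    b1 = np.array([r.b_end for r in runs])
    w = np.array([r.length for r in runs], dtype=float)
    best = w.copy()
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        overlap = np.maximum(0, np.maximum(a1[:i] - a0[i], b1[:i] - b0[i]))
        gain = w[i] - overlap
        ok = (a0[:i] < a0[i]) & (b0[:i] < b0[i]) & (gain > 0)
        if ok.any():
            cand = np.where(ok, best[:i] + gain, -np.inf)
            j = int(np.argmax(cand))  # argmax keeps the smallest index on ties
            if cand[j] > best[i]:
                best[i] = cand[j]
                prev[i] = j
    end = int(np.argmax(best))
    picked: list[Anchor] = []
    while end != -1:
        picked.append(runs[end])
        end = prev[end]
    picked.reverse()
    # trim successors from the left so the chain is strictly non-overlapping
    chain: list[Anchor] = []
    cur_a = cur_b = -1
    for r in picked:
        delta = max(0, cur_a - r.a, cur_b - r.b)
        if delta >= r.length:
            continue
        trimmed = Anchor(r.a + delta, r.b + delta, r.length - delta)
        chain.append(trimmed)
        cur_a, cur_b = trimmed.a_end, trimmed.b_end
    return chain


# ---------------------------------------------------------------------------
# closing the alignment
# ---------------------------------------------------------------------------


def _cigar_to_ops(cigar: str) -> list[tuple[str, int]]:
    """Parse an edlib extended CIGAR; query is A, so edlib I -> 'D' (A only)
    and edlib D -> 'I' (B only)."""
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            op = {"=": "=", "X": "X", "I": "D", "D": "I", "M": "="}[ch]
            out.append((op, n))
    return out


def _max_gap_run(ops: list[tuple[str, int]]) -> int:
    return max((n for op, n in ops if op in "ID"), default=0)


def _refine_aligner():
    from Bio import Align

    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1
    aln.mismatch_score = -1
    aln.open_gap_score = -5
    aln.extend_gap_score = -2
    return aln


_REFINER = None


def _affine_ops(sa: str, sb: str) -> list[tuple[str, int]]:
    """Affine-gap global alignment preferring mismatch columns over
    insertion+deletion pairs (resolves unit-cost ties for adjacent SNPs)."""
    global _REFINER
    if _REFINER is None:
        _REFINER = _refine_aligner()
    best = _REFINER.align(sa, sb)[0]
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        push("D", a0 - pa)
        push("I", b0 - pb)
        i = a0
        j = b0
        while i < a1:
            op = "=" if sa[i] == sb[j] else "X"
            push(op, 1)
            i += 1
            j += 1
        pa, pb = a1, b1
    push("D", len(sa) - pa)
    push("I", len(sb) - pb)
    return ops


def _align_segment(sa: str, sb: str) -> list[tuple[str, int]]:
    if not sa:
        return [("I", len(sb))] if sb else []
    if not sb:
        return [("D", len(sa))]
    res = edlib.align(sa, sb, task="path", mode="NW")
    ops = _cigar_to_ops(res["cigar"])
    kinds = {op for op, _ in ops}
    if "I" in kinds and "D" in kinds:
        # unit-cost alignment may trade two mismatches for an indel pair;
        # refine with an affine scorer that prefers substitution columns
        ops = _affine_ops(sa, sb)
    return ops


class _BlockBuilder:
    def __init__(self, bs: AlignmentBlockSet):
        self.bs = bs
        self.cur: AlignmentBlock | None = None

    def extend(self, a_pos: int, b_pos: int, ops: list[tuple[str, int]]) -> None:
        if not ops:
            return
        if self.cur is None:
            self.cur = AlignmentBlock(a_pos, a_pos, b_pos, b_pos, [])
        for op, n in ops:
            if self.cur.ops and self.cur.ops[-1][0] == op:
                self.cur.ops[-1] = (op, self.cur.ops[-1][1] + n)
            else:
                self.cur.ops.append((op, n))
            if op in "=XD":
                self.cur.a_end += n
            if op in "=XI":
                self.cur.b_end += n

    def cut(self) -> None:
        if self.cur is not None and self.cur.ops:
            self.bs.blocks.append(self.cur)
        self.cur = None


def close_alignment(
    chain: list[Anchor],
    seq_a: str,
    seq_b: str,
    band: int = 50,
    join_threshold: int = 10000,
    replicon_a: str = "a",
    replicon_b: str = "b",
) -> AlignmentBlockSet:
    """Close inter-anchor segments into blocks; demote unalignable segments.

    A segment is aligned when it is shorter than ``join_threshold`` and its
    length imbalance is within ``band`` gap columns (checked again on the
    realized alignment); otherwise its bases become gap intervals attributed
    to the genome holding the extra sequence, or unaligned tails at replicon
    ends when both genomes hold sequence that cannot be joined.
    """
    if band < 1:
        raise InputError("band must be >= 1")
    bs = AlignmentBlockSet(replicon_a, replicon_b, len(seq_a), len(seq_b))
    builder = _BlockBuilder(bs)

    def handle_segment(a0: int, a1: int, b0: int, b1: int, at_edge: bool) -> None:
        la, lb = a1 - a0, b1 - b0
        if la == 0 and lb == 0:
            return
        ops = None
        if max(la, lb) <= join_threshold and abs(la - lb) <= band:
            ops = _align_segment(seq_a[a0:a1], seq_b[b0:b1])
            if _max_gap_run(ops) > band:
                ops = None  # demote: alignment needs too many gap columns
        if ops is not None:
            builder.extend(a0, b0, ops)
            return
        builder.cut()
        if la > 0 and lb == 0:
            bs.gaps_a.append((a0, a1))
        elif lb > 0 and la == 0:
            bs.gaps_b.append((b0, b1))
        elif at_edge:
            bs.tails_a.append((a0, a1))
            bs.tails_b.append((b0, b1))
        else:
            bs.gaps_a.append((a0, a1))
            bs.gaps_b.append((b0, b1))

    if not chain:
        handle_segment(0, len(seq_a), 0, len(seq_b), at_edge=True)
        builder.cut()
        return bs

    handle_segment(0, chain[0].a, 0, chain[0].b, at_edge=True)
    for i, run in enumerate(chain):
        builder.extend(run.a, run.b, [("=", run.length)])
        if i + 1 < len(chain):
            nxt = chain[i + 1]
            handle_segment(run.a_end, nxt.a, run.b_end, nxt.b, at_edge=False)
    last = chain[-1]
    handle_segment(last.a_end, len(seq_a), last.b_end, len(seq_b), at_edge=True)
    builder.cut()
    return bs


def align_sequences(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    band: int = 50,
    join_threshold: int = 10000,
    replicon_a: str = "a",
    replicon_b: str = "b",
) -> AlignmentBlockSet:
    """Anchor, chain and close: the full collinear alignment of two replicons."""
    anchors = find_anchors(seq_a, seq_b, k=k) if min(len(seq_a), len(seq_b)) >= k else []
    chain = chain_anchors(anchors)
    return close_alignment(
        chain, seq_a, seq_b, band=band, join_threshold=join_threshold,
        replicon_a=replicon_a, replicon_b=replicon_b,
    )


def align_genomes(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    k: int = 21,
    band: int = 50,
    join_threshold: int = 10000,
) -> PairAlignment:
    """Align two genomes replicon-by-replicon (matched by name).

    Replicons present in only one genome (plasmid gain/loss) are reported in
    ``only_a`` / ``only_b``.
    """
    pa = PairAlignment()
    for name, sa in genome_a.sequences.items():
        if name in genome_b.sequences:
            pa.pairs[name] = align_sequences(
                sa, genome_b.sequences[name], k=k, band=band,
                join_threshold=join_threshold, replicon_a=name, replicon_b=name,
            )
        else:
            pa.only_a[name] = len(sa)
    for name, sb in genome_b.sequences.items():
        if name not in genome_a.sequences:
            pa.only_b[name] = len(sb)
    return pa


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------


def _run_length_at(seq: str, pos: int, base: str) -> int:
    """Length of the maximal run of `base` in seq containing/starting at pos."""
    if pos >= len(seq) or seq[pos] != base:
        # site immediately left of pos may hold the run (right-edge insertion)
        pos = pos - 1
        if pos < 0 or seq[pos] != base:
            return 0
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1


def call_variants(
    alignment: AlignmentBlockSet | PairAlignment,
    seq_a: dict[str, str] | str,
    seq_b: dict[str, str] | str,
    small_indel_max: int = 50,
) -> VariantSet:
    """One record per mismatch column (SNP) and per gap run (indel).

    Indels are left-aligned within homopolymers and annotated with the
    homopolymer run length from the genome-A context (genome-B context for
    insertions, which have no A allele).
    """
    if isinstance(alignment, PairAlignment):
        vs = VariantSet()
        for name, bs in alignment.pairs.items():
            sub = call_variants(bs, seq_a[name], seq_b[name], small_indel_max)
            vs.records.extend(sub.records)
        return vs

    assert isinstance(seq_a, str) and isinstance(seq_b, str)
    vs = VariantSet()
    ra, rb = alignment.replicon_a, alignment.replicon_b
    for blk in alignment.blocks:
        a, b = blk.a_start, blk.b_start
        for op, n in blk.ops:
            if op == "=":
                a += n
                b += n
            elif op == "X":
                for i in range(n):
                    vs.records.append(
                        VariantRecord(
                            ra, rb, a + i, b + i, "snp", seq_a[a + i], seq_b[b + i],
                            _run_length_at(seq_a, a + i, seq_a[a + i]),
                        )
                    )
                a += n
                b += n
            elif op == "I":  # extra bases in B
                if n <= small_indel_max:
                    s = seq_b[b : b + n]
                    pa, pb, s = _left_align(seq_a, seq_b, a, b, s)
                    vs.records.append(
                        VariantRecord(
                            ra, rb, pa, pb, "insertion", ".", s,
                            _run_length_at(seq_a, pa, s[0]) or _run_length_at(seq_b, pb, s[0]),
                        )
                    )
                b += n
            else:  # 'D': extra bases in A
                if n <= small_indel_max:
                    s = seq_a[a : a + n]
                    pa, pb, s = _left_align(seq_a, seq_b, a, b, s)
                    vs.records.append(
                        VariantRecord(
                            ra, rb, pa, pb, "deletion", s, ".",
                            _run_length_at(seq_a, pa, s[0]),
                        )
                    )
                a += n
    return vs


def _left_align(seq_a: str, seq_b: str, a: int, b: int, s: str) -> tuple[int, int, str]:
    """Shift an indel left while the preceding aligned column matches the
    indel's trailing base (canonical homopolymer placement)."""
    while a > 0 and b > 0 and seq_a[a - 1] == seq_b[b - 1] == s[-1]:
        s = s[-1] + s[:-1]
        a -= 1
        b -= 1
    return a, b, s


# ---------------------------------------------------------------------------
# large-gap mapping
# ---------------------------------------------------------------------------


@dataclass
class GapReport:
    """Unaligned intervals strictly longer than the threshold, per genome."""

    min_len: int
    intervals_a: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    intervals_b: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    genome_length_a: int = 0
    genome_length_b: int = 0

    def gap_bases(self, which: str) -> int:
        ivs = self.intervals_a if which == "a" else self.intervals_b
        return sum(e - s for reps in ivs.values() for s, e in reps)

    @property
    def fraction_a(self) -> float:
        return self.gap_bases("a") / self.genome_length_a if self.genome_length_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.gap_bases("b") / self.genome_length_b if self.genome_length_b else 0.0

    def overlap_fraction(self, intervals: dict[str, list[tuple[int, int]]], which: str = "a") -> float:
        """Fraction of reported gap bases overlapping the given intervals
        (e.g. biosynthetic gene clusters), keyed by replicon."""
        gaps = self.intervals_a if which == "a" else self.intervals_b
        total = self.gap_bases(which)
        if total == 0:
            return 0.0
        hit = 0
        for rep, ivs in gaps.items():
            for s, e in ivs:
                for cs, ce in intervals.get(rep, []):
                    hit += max(0, min(e, ce) - max(s, cs))
        return hit / total


def map_large_gaps(
    alignment: AlignmentBlockSet | PairAlignment,
    min_len: int = 100,
    length_a: int | None = None,
    length_b: int | None = None,
) -> GapReport:
    """Report unaligned intervals strictly longer than ``min_len`` per genome.

    Whole replicons present in only one genome count as gaps of that genome.
    Fractions are (gap bases > min_len) / (total genome length).
    """
    rep = GapReport(min_len=min_len)
    if isinstance(alignment, AlignmentBlockSet):
        pairs = {alignment.replicon_a: alignment}
        only_a: dict[str, int] = {}
        only_b: dict[str, int] = {}
    else:
        pairs = alignment.pairs
        only_a, only_b = alignment.only_a, alignment.only_b
    la = sum(bs.length_a for bs in pairs.values()) + sum(only_a.values())
    lb = sum(bs.length_b for bs in pairs.values()) + sum(only_b.values())
    rep.genome_length_a = length_a if length_a is not None else la
    rep.genome_length_b = length_b if length_b is not None else lb
    for name, bs in pairs.items():
        ga = [iv for iv in _merged(bs.gaps_a) if iv[1] - iv[0] > min_len]
        gb = [iv for iv in _merged(bs.gaps_b) if iv[1] - iv[0] > min_len]
        if ga:
            rep.intervals_a[name] = ga
        if gb:
            rep.intervals_b[name] = gb
    for name, l in only_a.items():
        if l > min_len:
            rep.intervals_a[name] = [(0, l)]
    for name, l in only_b.items():
        if l > min_len:
            rep.intervals_b[name] = [(0, l)]
    return rep


def _merged(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def aligned_identity(alignment: AlignmentBlockSet | PairAlignment) -> float:
    """Matches / aligned columns (gap columns excluded), in [0, 1]."""
    return alignment.identity_aligned
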