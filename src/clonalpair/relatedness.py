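"""Marker-based relatedness, BGC overlap, and replicon-level statistics.

Extracts phylogenetic marker genes (16S rRNA plus the atpD/gyrB/recA/rpoB/
trpB housekeeping set) by best infix alignment against user-supplied
reference sequences, computes pairwise percent identity over head-to-tail
concatenated markers, builds a distance matrix (1 - identity) with an
optional neighbor-joining tree, matches biosynthetic gene cluster intervals
through a genome alignment, and summarizes per-replicon length, GC content
and GC skew at configurable window sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import AlignmentBlockSet, PairAlignment
from .errors import InputError
from .genome import AnnotatedGenome, revcomp

MARKER_NAMES = ("16S", "atpD", "gyrB", "recA", "rpoB", "trpB")

BGC_CLASS_VOCAB = frozenset(
    {
        "polyketide",
        "nrps",
        "terpene",
        "nucleoside",
        "ripp",
        "siderophore",
        "hybrid",
        "other",
    }
)


@dataclass(frozen=True)
class BGCInterval:
    """A biosynthetic gene cluster interval (0-based half-open)."""

    replicon: str
    start: int
    end: int
    bgc_class: str
    confidence: str = "high"  # 'high' or 'putative'

    def __post_init__(self):
        if not self.start < self.end:
            raise InputError("BGC interval must have start < end")
        if self.bgc_class.lower() not in BGC_CLASS_VOCAB:
            raise InputError(
                f"unknown BGC class {self.bgc_class!r}; expected one of {sorted(BGC_CLASS_VOCAB)}"
            )
        if self.confidence not in ("high", "putative"):
            raise InputError("confidence must be 'high' or 'putative'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MarkerSet:
    """Extracted marker sequences for one genome."""

    genome_id: str
    markers: dict[str, str] = field(default_factory=dict)
    coordinates: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    complete: dict[str, bool] = field(default_factory=dict)

    def shared_complete(self, other: "MarkerSet") -> list[str]:
        return [
            m
            for m in self.markers
            if self.complete.get(m) and other.complete.get(m)
        ]


def extract_markers(
    genome: AnnotatedGenome,
    references: dict[str, str],
    genome_id: str = "genome",
    min_identity: float = 0.75,
) -> MarkerSet:
    """Extract the best hit of each reference marker, in coding orientation.

    Each reference is infix-aligned against every replicon on both strands;
    the hit with the fewest edits wins. Markers whose approximate identity
    (1 - edits / reference length) falls below ``min_identity`` are flagged
    incomplete, mirroring genuinely missing loci in draft relatives.
    """
    if not references:
        raise InputError("reference marker set is empty")
    ms = MarkerSet(genome_id=genome_id)
    for name, ref in references.items():
        best = None  # (dist, replicon, start, end, strand)
        for rep, seq in genome.sequences.items():
            for strand, target in (("+", seq), ("-", revcomp(seq))):
                res = edlib.align(ref, target, mode="HW", task="locations")
                if res["editDistance"] < 0:
                    continue
                if best is None or res["editDistance"] < best[0]:
                    s, e = res["locations"][0]
                    best = (res["editDistance"], rep, s, e + 1, strand)
        identity = 1.0 - best[0] / len(ref) if best else 0.0
        if best is None or identity < min_identity:
            ms.complete[name] = False
            ms.markers[name] = ""
            continue
        _, rep, s, e, strand = best
        L = len(genome.sequences[rep])
        if strand == "+":
            extracted = genome.sequences[rep][s:e]
            coords = (rep, s, e, "+")
        else:
            # coordinates were on the reverse complement; map back
            extracted = revcomp(genome.sequences[rep][L - e : L - s])
            coords = (rep, L - e, L - s, "-")
        ms.markers[name] = extracted
        ms.coordinates[name] = coords
        ms.complete[name] = True
    return ms


@dataclass
class ConcatIdentity:
    """Percent identity of a head-to-tail marker concatenation."""

    percent: float
    per_marker: dict[str, float]
    markers_used: list[str]
    aligned_columns: int
    matches: int


def _pairwise_identity_counts(a: str, b: str) -> tuple[int, int]:
    """(matches, aligned non-gap columns) of a global alignment of a and b."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch == "=":
                matches += n
                cols += n
            elif ch in "XM":
                cols += n
            # I/D are gap columns: excluded (pairwise deletion)
    return matches, cols


def concat_identity(a: MarkerSet, b: MarkerSet) -> ConcatIdentity:
    """Percent identity over markers complete in both genomes.

    Markers are individually globally aligned and the match/column counts
    concatenated head-to-tail; identity excludes gap columns. The marker
    subset used is reported, supporting four-gene fallbacks when a marker is
    missing from one genome.
    """
    shared = a.shared_complete(b)
    if not shared:
        raise InputError("no marker complete in both genomes")
    per_marker = {}
    matches = cols = 0
    for m in shared:
        mm, cc = _pairwise_identity_counts(a.markers[m], b.markers[m])
        per_marker[m] = 100.0 * mm / cc if cc else 0.0
        matches += mm
        cols += cc
    return ConcatIdentity(
        percent=100.0 * matches / cols if cols else 0.0,
        per_marker=per_marker,
        markers_used=shared,
        aligned_columns=cols,
        matches=matches,
    )


def distance_matrix(
    marker_sets: list[MarkerSet], tree: bool = True
) -> tuple[pd.DataFrame, str | None]:
    """Pairwise distance matrix (1 - concatenated identity) and optional
    neighbor-joining tree in newick (plumbing, not a likelihood phylogeny)."""
    if len(marker_sets) < 2:
        raise InputError("need at least two genomes")
    ids = [m.genome_id for m in marker_sets]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci = concat_identity(marker_sets[i], marker_sets[j])
            d[i, j] = d[j, i] = 1.0 - ci.percent / 100.0
    df = pd.DataFrame(d, index=ids, columns=ids)
    newick = None
    if tree and n >= 3:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        newick = str(nj(DistanceMatrix(d, ids))).strip()
    return df, newick


# ---------------------------------------------------------------------------
# BGC overlap through an alignment
# ---------------------------------------------------------------------------


def project_interval(
    bs: AlignmentBlockSet, start: int, end: int
) -> list[tuple[int, int]]:
    """Map an interval of genome A to genome B coordinates through the
    block alignment; only columns aligned in both genomes contribute."""
    out: list[tuple[int, int]] = []
    for blk in bs.blocks:
        if blk.a_end <= start or blk.a_start >= end:
            continue
        a, b = blk.a_start, blk.b_start
        for op, n in blk.ops:
            if op in "=X":
                lo = max(a, start)
                hi = min(a + n, end)
                if lo < hi:
                    out.append((b + (lo - a), b + (hi - a)))
                a += n
                b += n
            elif op == "D":
                a += n
            else:
                b += n
    # merge adjacent
    merged: list[tuple[int, int]] = []
    for s, e in sorted(out):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class BGCOverlapReport:
    """Shared/total cluster counts per confidence tier and direction."""

    shared_a: dict[str, int] = field(default_factory=dict)  # tier -> count
    total_a: dict[str, int] = field(default_factory=dict)
    shared_b: dict[str, int] = field(default_factory=dict)
    total_b: dict[str, int] = field(default_factory=dict)

    def as_fractions(self) -> dict[str, str]:
        out = {}
        for tier in set(self.total_a) | set(self.total_b):
            out[f"a_{tier}"] = f"{self.shared_a.get(tier, 0)}/{self.total_a.get(tier, 0)}"
            out[f"b_{tier}"] = f"{self.shared_b.get(tier, 0)}/{self.total_b.get(tier, 0)}"
        return out


def _shared_count(
    clusters: list[BGCInterval],
    partners: list[BGCInterval],
    alignment: PairAlignment,
    direction: str,
    min_fraction: float,
) -> dict[str, int]:
    shared = {"high": 0, "putative": 0}
    for c in clusters:
        bs = alignment.pairs.get(c.replicon)
        if bs is None:
            continue  # replicon absent from the partner genome: unshared
        if direction == "b":
            bs = bs.swapped()
        projected = project_interval(bs, c.start, c.end)
        overlap = 0
        for p in partners:
            if p.replicon != c.replicon or p.bgc_class.lower() != c.bgc_class.lower():
                continue
            for s, e in projected:
                overlap += max(0, min(e, p.end) - max(s, p.start))
        if overlap >= min_fraction * c.length:
            shared[c.confidence] += 1
    return shared


def bgc_overlap(
    bgc_a: list[BGCInterval],
    bgc_b: list[BGCInterval],
    alignment: PairAlignment,
    min_fraction: float = 0.5,
) -> BGCOverlapReport:
    """Shared/total BGC counts per tier, matched by interval and class.

    A cluster of A is shared when at least ``min_fraction`` of its span maps
    through the alignment into same-class clusters of B (and vice versa).
    Clusters on replicons missing from the partner (plasmid gain/loss) are
    unshared by construction.
    """
    report = BGCOverlapReport()
    for tier in ("high", "putative"):
        report.total_a[tier] = sum(1 for c in bgc_a if c.confidence == tier)
        report.total_b[tier] = sum(1 for c in bgc_b if c.confidence == tier)
    report.shared_a = _shared_count(bgc_a, bgc_b, alignment, "a", min_fraction)
    report.shared_b = _shared_count(bgc_b, bgc_a, alignment, "b", min_fraction)
    return report


def read_bgc_tsv(path) -> list[BGCInterval]:
    """Read BGC intervals from a TSV with columns replicon, start, end,
    class, confidence (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t")
    return [
        BGCInterval(
            replicon=row["replicon"],
            start=int(row["start"]),
            end=int(row["end"]),
            bgc_class=str(row["class"]),
            confidence=str(row.get("confidence", "high")),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# replicon statistics
# ---------------------------------------------------------------------------


@dataclass
class RepliconStats:
    """Length, GC, skew and feature counts for one replicon."""

    name: str
    topology: str
    length: int
    gc_fraction: float
    gc_skew: float  # (G - C) / (G + C) over the whole replicon
    n_rrna: int
    n_trna: int
    n_cds: int
    gc_profile: dict[int, np.ndarray] = field(default_factory=dict)
    skew_profile: dict[int, np.ndarray] = field(default_factory=dict)


def replicon_stats(
    genome: AnnotatedGenome, windows: tuple[int, ...] = (10_000, 1_000_000)
) -> dict[str, RepliconStats]:
    """Per-replicon GC content and GC skew profiles at the given window sizes.

    Windows tile each replicon (the final window may be partial); skew is
    (G - C) / (G + C), defined as 0 where a window has no G or C.
    """
    out: dict[str, RepliconStats] = {}
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_g = (arr == ord("G")).astype(np.int64)
        is_c = (arr == ord("C")).astype(np.int64)
        cg = np.concatenate(([0], np.cumsum(is_g)))
        cc = np.concatenate(([0], np.cumsum(is_c)))
        L = len(seq)
        total_g, total_c = int(cg[-1]), int(cc[-1])
        gc_profiles = {}
        skew_profiles = {}
        for w in windows:
            edges = np.arange(0, L + w, w)
            edges[-1] = min(edges[-1], L)
            edges = np.unique(edges)
            g = cg[edges[1:]] - cg[edges[:-1]]
            c = cc[edges[1:]] - cc[edges[:-1]]
            span = np.diff(edges)
            gc_profiles[w] = (g + c) / span
            denom = g + c
            skew_profiles[w] = np.divide(
                g - c, denom, out=np.zeros(len(span), dtype=float), where=denom > 0
            )
        out[name] = RepliconStats(
            name=name,
            topology=genome.topology.get(name, "linear"),
            length=L,
            gc_fraction=(total_g + total_c) / L if L else 0.0,
            gc_skew=(total_g - total_c) / (total_g + total_c)
            if total_g + total_c
            else 0.0,
            n_rrna=len(genome.features_of("rRNA", name)),
            n_trna=len(genome.features_of("tRNA", name)),
            n_cds=len(genome.cds(name)),
            gc_profile=gc_profiles,
            skew_profile=skew_profiles,
        )
    return out
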