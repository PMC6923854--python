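"""Synthetic clonal genome pairs with a recorded ground truth.

Generates high-GC annotated ancestral genomes (dense CDSs, ribosome-binding
Shine-Dalgarno motifs upstream of start codons, homopolymer-enriched
intergenic sequence) and simulates clonal divergence: point mutations with a
silent bias inside CDSs and position-dependent suppression around translation
initiation signals, single-base homopolymer indels in sequencing-error mode,
large insertion/deletion events, and plasmid gain/loss. Every event is
recorded in a truth set that reconstructs the derived genome exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .codons import BASES, CODON_TO_AA, STOP_CODONS, SYNONYMOUS_ALT_COUNTS
from .errors import ParameterError, SimulationError
from .genome import AnnotatedGenome, Feature, revcomp

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass
class AncestorParams:
    """Parameters of the ancestral genome generator.

    ``gc_target`` is the genome-wide G+C fraction; ``cds_density`` the
    fraction of each replicon covered by CDSs; ``sd_motif`` an IUPAC motif
    placed on the coding strand at a distance drawn from ``sd_offset_range``
    (bases between motif end and start codon); ``homopolymer_boost``
    multiplies the probability of repeating the previous base in intergenic
    sequence (1.0 = independent bases, geometric run lengths).
    """

    replicon_lengths: list[int] = field(default_factory=lambda: [100_000])
    gc_target: float = 0.72
    cds_density: float = 0.85
    mean_cds_len: int = 900
    sd_motif: str = "AGGAGG"
    sd_offset_range: tuple[int, int] = (5, 10)
    homopolymer_boost: float = 2.0
    n_rrna: int = 0
    n_trna: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_target < 1:
            raise ParameterError("gc_target must be in (0, 1)")
        if not 0 < self.cds_density < 1:
            raise ParameterError("cds_density must be in (0, 1)")
        if any(l <= 0 for l in self.replicon_lengths):
            raise ParameterError("replicon lengths must be positive")
        if self.homopolymer_boost <= 0:
            raise ParameterError("homopolymer_boost must be positive")
        lo, hi = self.sd_offset_range
        if not (0 < lo <= hi):
            raise ParameterError("sd_offset_range must satisfy 0 < lo <= hi")
        if any(b not in _IUPAC for b in self.sd_motif.upper()):
            raise ParameterError(f"sd_motif has non-IUPAC symbols: {self.sd_motif}")


@dataclass
class DivergenceParams:
    """Parameters of the clonal-divergence simulator.

    ``snp_rate`` is the expected substitutions per base genome-wide;
    ``silent_bias`` the acceptance probability of a proposed non-synonymous
    CDS change relative to a synonymous one (site-level rejection, with the
    CDS proposal rate compensated so the realized rate still matches
    ``snp_rate``); ``sd_suppression`` / ``cds5_suppression`` multiply the
    rate inside the Shine-Dalgarno window and the 5' fraction of each CDS.
    ``large_indel_rate`` is expected events per genome; large indels are
    placed in intergenic DNA (insertions) or whole-gene spans (deletions).
    ``plasmid_gain_loss`` holds directives like
    ``{"action": "drop", "name": "plasmid1"}`` or
    ``{"action": "gain", "name": "pNew", "length": 20000, "gc": 0.70}``.
    """

    snp_rate: float = 5e-3
    silent_bias: float = 0.25
    sd_suppression: float = 0.3
    sd_window: tuple[int, int] = (5, 15)  # distances upstream of start codon
    cds5_suppression: float = 0.3
    cds5_fraction: float = 0.10
    large_indel_rate: float = 0.0
    large_indel_len_range: tuple[int, int] = (200, 2000)
    homopolymer_indel_rate: float = 0.0
    homopolymer_min_run: int = 3
    homopolymer_indel_mode: str = "insertion"
    plasmid_gain_loss: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "large_indel_rate", "homopolymer_indel_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("silent_bias", "sd_suppression", "cds5_suppression"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        lo, hi = self.large_indel_len_range
        if lo <= 100:
            raise ParameterError("large_indel_len_range minimum must exceed 100 bp")
        if lo > hi:
            raise ParameterError("large_indel_len_range must be (lo, hi) with lo <= hi")
        if self.homopolymer_indel_mode not in ("insertion", "deletion", "both"):
            raise ParameterError("homopolymer_indel_mode must be insertion|deletion|both")


# ---------------------------------------------------------------------------
# truth set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSNP:
    replicon: str
    position: int  # 0-based, ancestor coordinates
    ref: str
    alt: str
    effect: str | None  # silent/missense/nonsense/stop_loss, None outside CDS


@dataclass(frozen=True)
class TruthIndel:
    replicon: str
    position: int  # 0-based, ancestor coordinates
    seq: str  # inserted or deleted bases
    kind: str  # 'insertion' or 'deletion'
    source: str = "large"  # 'large' or 'homopolymer'


@dataclass
class DivergenceTruth:
    """Recorded divergence events, in ancestor coordinates.

    Reconstruction order (see :func:`apply_truth`): SNPs first, then all
    indels sorted by descending position, then replicon gain/loss.
    """

    snps: list[TruthSNP] = field(default_factory=list)
    indels: list[TruthIndel] = field(default_factory=list)
    replicon_events: list[tuple[str, str]] = field(default_factory=list)
    gained_sequences: dict[str, str] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("replicon\tposition\ttype\tref\talt\teffect\tsource\n")
            for s in self.snps:
                fh.write(
                    f"{s.replicon}\t{s.position}\tsnp\t{s.ref}\t{s.alt}\t"
                    f"{s.effect or '.'}\t.\n"
                )
            for i in self.indels:
                ref, alt = (".", i.seq) if i.kind == "insertion" else (i.seq, ".")
                fh.write(
                    f"{i.replicon}\t{i.position}\t{i.kind}\t{ref}\t{alt}\t.\t{i.source}\n"
                )
            for action, name in self.replicon_events:
                seq = self.gained_sequences.get(name, ".") if action == "gain" else "."
                fh.write(f"{name}\t0\treplicon_{action}\t.\t{seq}\t.\t.\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DivergenceTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("replicon")
            for line in fh:
                rep, pos, typ, ref, alt, effect, source = line.rstrip("\n").split("\t")
                if typ == "snp":
                    truth.snps.append(
                        TruthSNP(rep, int(pos), ref, alt, None if effect == "." else effect)
                    )
                elif typ in ("insertion", "deletion"):
                    seq = alt if typ == "insertion" else ref
                    truth.indels.append(TruthIndel(rep, int(pos), seq, typ, source))
                elif typ.startswith("replicon_"):
                    action = typ.split("_", 1)[1]
                    truth.replicon_events.append((action, rep))
                    if action == "gain" and alt != ".":
                        truth.gained_sequences[rep] = alt
        return truth


# ---------------------------------------------------------------------------
# base sampling
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    """[A, C, G, T] probabilities with the given GC fraction."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _markov_input_probs(target: np.ndarray, boost: float) -> np.ndarray:
    """Input base weights whose repeat-boosted Markov chain has the target
    stationary distribution.

    The chain P(b|a) ∝ p(b)·boost^[b==a] is reversible with stationary
    π(b) ∝ p(b)(1 + p(b)(boost-1)); invert that relation per base.
    """
    if abs(boost - 1.0) < 1e-12:
        return target.copy()
    beta = boost - 1.0

    def p_of(c: float) -> np.ndarray:
        # solve beta*p^2 + p = c*t per base, positive root
        return (-1.0 + np.sqrt(1.0 + 4.0 * beta * c * target)) / (2.0 * beta)

    c = brentq(lambda c: p_of(c).sum() - 1.0, 1e-9, 1e6)
    return p_of(c)


class _BaseSampler:
    """Markov base sampler with homopolymer run-extension boost."""

    def __init__(self, gc: float, boost: float, rng: np.random.Generator):
        self.rng = rng
        target = _base_probs(gc)
        p = _markov_input_probs(target, boost)
        # conditional cumulative distributions, one per previous base (+iid)
        self.cum = np.empty((5, 4))
        for prev in range(4):
            w = p.copy()
            w[prev] *= boost
            self.cum[prev] = np.cumsum(w / w.sum())
        self.cum[4] = np.cumsum(p / p.sum())
        self._buf = np.empty(0)
        self._i = 0

    def _u(self) -> float:
        if self._i >= len(self._buf):
            self._buf = self.rng.random(65536)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u

    def run(self, n: int, prev: int = 4) -> tuple[list[int], int]:
        out = []
        cum = self.cum
        for _ in range(n):
            u = self._u()
            row = cum[prev]
            prev = int(np.searchsorted(row, u, side="right"))
            if prev > 3:
                prev = 3
            out.append(prev)
        return out, prev


def _sample_codons(n: int, probs: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Sample n sense codons, bases i.i.d. from probs, stop codons rejected."""
    out: list[str] = []
    while len(out) < n:
        draw = rng.choice(4, size=(n - len(out) + 8, 3), p=probs)
        for row in draw:
            codon = BASES[row[0]] + BASES[row[1]] + BASES[row[2]]
            if CODON_TO_AA[codon] != "*":
                out.append(codon)
                if len(out) == n:
                    break
    return out


def _expand_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(_IUPAC[c]) == 1 else _IUPAC[c][rng.integers(len(_IUPAC[c]))]
        for c in motif.upper()
    )


# ---------------------------------------------------------------------------
# ancestor generation
# ---------------------------------------------------------------------------

_MIN_CDS = 90  # bases; shortest CDS the generator will emit


def generate_ancestor(params: AncestorParams) -> AnnotatedGenome:
    """Generate an annotated ancestral genome.

    Every CDS is a multiple of 3 long, starts with ATG, ends with a stop
    codon and has no internal in-frame stop; an SD motif instance sits at a
    distance in ``sd_offset_range`` upstream of every start codon
    (strand-aware). Realized genome GC lands within ~0.01 of ``gc_target``.
    """
    rng = np.random.default_rng(params.seed)
    motif_len = len(params.sd_motif)
    off_lo, off_hi = params.sd_offset_range
    min_gap = 2 * (off_hi + motif_len) + 4
    codon_probs = _base_probs(params.gc_target)

    sequences: dict[str, str] = {}
    features: list[Feature] = []

    for ri, L in enumerate(params.replicon_lengths):
        name = "chromosome" if ri == 0 else f"plasmid{ri}"
        target_cds = params.cds_density * L
        if target_cds < _MIN_CDS:
            raise ParameterError(
                f"cds_density x length = {target_cds:.0f} < one minimal CDS ({_MIN_CDS})"
            )
        mean_len = max(_MIN_CDS, (params.mean_cds_len // 3) * 3)
        if mean_len > target_cds or mean_len + min_gap * 2 > L:
            raise ParameterError(
                f"mean_cds_len {params.mean_cds_len} infeasible for replicon of {L} bp "
                f"at density {params.cds_density}"
            )
        n_genes = max(1, round(target_cds / mean_len))
        lengths = None
        while n_genes >= 1:
            raw = rng.normal(mean_len, 0.25 * mean_len, n_genes)
            cand = np.clip((raw // 3) * 3, _MIN_CDS, None).astype(int)
            # rescale towards the density target, keeping multiples of 3
            scale = target_cds / cand.sum()
            cand = np.maximum(_MIN_CDS, ((cand * scale) // 3).astype(int) * 3)
            if cand.sum() + (n_genes + 1) * min_gap <= L:
                lengths = cand
                break
            n_genes -= 1
        if lengths is None:
            raise ParameterError(
                f"cannot fit any CDS plus flanking gaps in replicon of {L} bp"
            )
        n_genes = len(lengths)
        extra = L - int(lengths.sum()) - (n_genes + 1) * min_gap
        gap_extra = rng.multinomial(extra, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        gaps = gap_extra + min_gap
        strands = rng.choice(["+", "-"], size=n_genes)
        ftypes = ["CDS"] * n_genes
        for j in range(min(params.n_rrna, n_genes)):
            ftypes[j * max(1, n_genes // max(1, params.n_rrna))] = "rRNA"
        placed_trna = 0
        for j in range(n_genes):
            if placed_trna >= params.n_trna:
                break
            if ftypes[j] == "CDS" and j % 2 == 1:
                ftypes[j] = "tRNA"
                placed_trna += 1

        sampler = _BaseSampler(params.gc_target, params.homopolymer_boost, rng)
        seq: list[str] = []
        prev = 4
        pos = 0
        sd_targets: list[tuple[int, str, int]] = []  # (feature index, strand, start/end pos)
        for gi in range(n_genes):
            bases, prev = sampler.run(int(gaps[gi]), prev)
            seq.extend(BASES[b] for b in bases)
            pos += int(gaps[gi])
            glen = int(lengths[gi])
            ftype = ftypes[gi]
            if ftype == "CDS":
                n_codons = glen // 3
                codons = _sample_codons(n_codons - 2, codon_probs, rng)
                stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
                cds = "ATG" + "".join(codons) + stop
                gseq = revcomp(cds) if strands[gi] == "-" else cds
                fid = f"{name}_cds{gi}"
                sd_targets.append((len(features), strands[gi], pos if strands[gi] == "+" else pos + glen))
            else:
                bases2, prev = sampler.run(glen, prev)
                gseq = "".join(BASES[b] for b in bases2)
                fid = f"{name}_{ftype.lower()}{gi}"
            seq.extend(gseq)
            prev = BASES.index(gseq[-1])
            features.append(
                Feature(
                    replicon=name,
                    start=pos,
                    end=pos + glen,
                    strand=str(strands[gi]),
                    ftype=ftype,
                    feature_id=fid,
                )
            )
            pos += glen
        bases, prev = sampler.run(int(gaps[n_genes]), prev)
        seq.extend(BASES[b] for b in bases)

        # overwrite SD motif instances upstream of each CDS start codon
        for _, strand, anchor in sd_targets:
            d = int(rng.integers(off_lo, off_hi + 1))
            inst = _expand_iupac(params.sd_motif, rng)
            if strand == "+":
                start = anchor - d - motif_len
                seq[start : start + motif_len] = list(inst)
            else:
                start = anchor + d
                seq[start : start + motif_len] = list(revcomp(inst))

        sequences[name] = "".join(seq)

    genome = AnnotatedGenome(sequences=sequences, features=features)
    return genome


# ---------------------------------------------------------------------------
# divergence simulation
# ---------------------------------------------------------------------------

def _cds_coding_index(feat: Feature, pos: int) -> int:
    return pos - feat.start if feat.strand == "+" else feat.end - 1 - pos


def _snp_effect(feat: Feature, cds_seq: str, pos: int, alt: str) -> tuple[str, str, str]:
    """(codon_a, codon_b, effect) for a SNP at genome position pos in feat."""
    i = _cds_coding_index(feat, pos)
    ci = i // 3
    codon_a = cds_seq[3 * ci : 3 * ci + 3]
    alt_c = alt if feat.strand == "+" else _COMPLEMENT[alt]
    off = i % 3
    codon_b = codon_a[:off] + alt_c + codon_a[off + 1 :]
    aa_a, aa_b = CODON_TO_AA[codon_a], CODON_TO_AA[codon_b]
    if aa_a == aa_b:
        eff = "silent"
    elif aa_b == "*":
        eff = "nonsense"
    elif aa_a == "*":
        eff = "stop_loss"
    else:
        eff = "missense"
    return codon_a, codon_b, eff


def _mean_synonymous_fraction(genome: AnnotatedGenome) -> float:
    """Average over CDS sites of the share of the 3 alternatives that are
    synonymous (the chance a uniformly proposed CDS SNP is silent)."""
    total_sites = 0
    syn_alts = 0
    for feat in genome.cds():
        cds = genome.cds_sequence(feat)
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci : 3 * ci + 3]
            counts = SYNONYMOUS_ALT_COUNTS.get(codon)
            if counts is None:
                continue
            syn_alts += sum(counts)
            total_sites += 3
    return syn_alts / (3 * total_sites) if total_sites else 0.0


def _intergenic_mask(genome: AnnotatedGenome, replicon: str) -> np.ndarray:
    mask = np.ones(len(genome.sequences[replicon]), dtype=bool)
    for f in genome.features:
        if f.replicon == replicon:
            mask[f.start : f.end] = False
    return mask


def simulate_divergence(
    genome: AnnotatedGenome, params: DivergenceParams
) -> tuple[AnnotatedGenome, DivergenceTruth]:
    """Simulate clonal divergence of ``genome``; returns (derived, truth).

    The derived genome differs from the input exactly by the recorded truth
    events, and the same seed reproduces identical output.
    """
    rng = np.random.default_rng(params.seed)
    truth = DivergenceTruth()

    p_syn = _mean_synonymous_fraction(genome)
    acceptance = p_syn + params.silent_bias * (1.0 - p_syn)
    cds_comp = 1.0 / acceptance if acceptance > 0 else 1.0

    drop = {d["name"] for d in params.plasmid_gain_loss if d["action"] == "drop"}
    for name in genome.replicon_names():
        if name in drop:
            truth.replicon_events.append(("drop", name))

    # ---- large indels ---------------------------------------------------
    kept = [n for n in genome.replicon_names() if n not in drop]
    deleted: dict[str, list[tuple[int, int]]] = {n: [] for n in kept}
    insert_at: dict[str, list[tuple[int, str]]] = {n: [] for n in kept}
    n_events = rng.poisson(params.large_indel_rate)
    if n_events and not kept:
        raise SimulationError("large indels requested but all replicons dropped")
    lens = np.array([len(genome.sequences[n]) for n in kept], dtype=float)
    gc = genome.gc_fraction()
    for _ in range(n_events):
        placed = False
        for _attempt in range(100):
            rep = kept[rng.choice(len(kept), p=lens / lens.sum())]
            target_len = int(rng.integers(*params.large_indel_len_range, endpoint=True))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            inter = _intergenic_mask(genome, rep)
            if kind == "insertion":
                cand = np.flatnonzero(inter)
                p = int(cand[rng.integers(len(cand))])
                if any(s <= p < e for s, e in deleted[rep]):
                    continue
                ins_seq = "".join(
                    BASES[b] for b in rng.choice(4, size=target_len, p=_base_probs(gc))
                )
                insert_at[rep].append((p, ins_seq))
                truth.indels.append(TruthIndel(rep, p, ins_seq, "insertion", "large"))
                placed = True
                break
            # deletion: whole-gene span, snapped to intergenic midpoints
            feats = sorted(
                (f for f in genome.features if f.replicon == rep), key=lambda f: f.start
            )
            if not feats:
                continue
            g0 = int(rng.integers(len(feats)))
            g1 = g0
            while (feats[g1].end - feats[g0].start) < target_len and g1 + 1 < len(feats):
                g1 += 1
            left = feats[g0 - 1].end if g0 > 0 else 0
            start = (left + feats[g0].start) // 2
            right = feats[g1 + 1].start if g1 + 1 < len(feats) else len(genome.sequences[rep])
            end = (feats[g1].end + right) // 2
            if any(s < end and start < e for s, e in deleted[rep]):
                continue
            if any(start <= p < end for p, _ in insert_at[rep]):
                continue
            deleted[rep].append((start, end))
            truth.indels.append(
                TruthIndel(rep, start, genome.sequences[rep][start:end], "deletion", "large")
            )
            placed = True
            break
        if not placed:
            raise SimulationError("could not place large indel without overlap")

    # ---- SNPs -----------------------------------------------------------
    lo, hi = params.sd_window
    f5 = params.cds5_fraction
    for rep in kept:
        seq = genome.sequences[rep]
        L = len(seq)
        rate = np.full(L, params.snp_rate)
        cds_feats = [f for f in genome.cds(rep)]
        cds_lookup: dict[int, tuple[Feature, str]] = {}
        for feat in cds_feats:
            rate[feat.start : feat.end] *= cds_comp
            n5 = math.ceil(f5 * feat.length)
            if feat.strand == "+":
                rate[feat.start : feat.start + n5] *= params.cds5_suppression
                w0, w1 = feat.start - hi, feat.start - lo + 1
            else:
                rate[feat.end - n5 : feat.end] *= params.cds5_suppression
                w0, w1 = feat.end - 1 + lo, feat.end + hi
            rate[max(0, w0) : max(0, w1)] *= params.sd_suppression
        for feat in cds_feats:
            cds_seq = genome.cds_sequence(feat)
            for p in range(feat.start, feat.end):
                cds_lookup[p] = (feat, cds_seq)
        for s, e in deleted[rep]:
            rate[s:e] = 0.0
        np.clip(rate, 0.0, 1.0, out=rate)
        hits = np.flatnonzero(rng.random(L) < rate)
        for p in hits:
            p = int(p)
            ref = seq[p]
            if ref not in _COMPLEMENT:
                continue
            alts = [b for b in BASES if b != ref]
            alt = alts[rng.integers(3)]
            entry = cds_lookup.get(p)
            if entry is None:
                truth.snps.append(TruthSNP(rep, p, ref, alt, None))
                continue
            feat, cds_seq = entry
            _, _, eff = _snp_effect(feat, cds_seq, p, alt)
            if eff != "silent" and rng.random() >= params.silent_bias:
                continue  # rejected non-synonymous proposal
            truth.snps.append(TruthSNP(rep, p, ref, alt, eff))

    # ---- homopolymer indels (intergenic, sequencing-error mode) ---------
    if params.homopolymer_indel_rate > 0:
        for rep in kept:
            seq = genome.sequences[rep]
            inter = _intergenic_mask(genome, rep)
            for s, e in deleted[rep]:
                inter[s:e] = False
            for start, length, base in _homopolymer_runs(seq, params.homopolymer_min_run):
                if not inter[start : start + length].all():
                    continue
                if rng.random() >= params.homopolymer_indel_rate:
                    continue
                kind = _pick_indel_kind(params.homopolymer_indel_mode, rng)
                truth.indels.append(TruthIndel(rep, start, base, kind, "homopolymer"))

    # ---- plasmid gains --------------------------------------------------
    for d in params.plasmid_gain_loss:
        if d["action"] != "gain":
            continue
        glen = int(d["length"])
        ggc = float(d.get("gc", genome.gc_fraction()))
        gseq = "".join(BASES[b] for b in rng.choice(4, size=glen, p=_base_probs(ggc)))
        truth.replicon_events.append(("gain", d["name"]))
        truth.gained_sequences[d["name"]] = gseq

    derived = apply_truth(genome, truth)
    return derived, truth


def _pick_indel_kind(mode: str, rng: np.random.Generator) -> str:
    if mode == "both":
        return "insertion" if rng.random() < 0.5 else "deletion"
    return mode


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= min_run as (start, length, base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(arr) == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    return [
        (int(s), int(e - s), seq[s])
        for s, e in zip(starts, ends)
        if e - s >= min_run and seq[s] in "ACGT"
    ]


# ---------------------------------------------------------------------------
# truth application (the conservation contract)
# ---------------------------------------------------------------------------

def apply_truth(genome: AnnotatedGenome, truth: DivergenceTruth) -> AnnotatedGenome:
    """Apply a truth set to an ancestor, reconstructing the derived genome.

    SNPs are applied at ancestor coordinates, then indels in descending
    position order, then replicon gain/loss. Features overlapping a deletion
    are dropped; all others are coordinate-shifted.
    """
    dropped = {name for action, name in truth.replicon_events if action == "drop"}
    sequences: dict[str, str] = {}
    features: list[Feature] = []
    for rep, seq in genome.sequences.items():
        if rep in dropped:
            continue
        s = list(seq)
        for snp in truth.snps:
            if snp.replicon != rep:
                continue
            if s[snp.position] != snp.ref:
                raise SimulationError(
                    f"truth SNP ref mismatch at {rep}:{snp.position}"
                )
            s[snp.position] = snp.alt
        indels = sorted(
            (i for i in truth.indels if i.replicon == rep),
            key=lambda i: i.position,
            reverse=True,
        )
        for ind in indels:
            if ind.kind == "deletion":
                del s[ind.position : ind.position + len(ind.seq)]
            else:
                s[ind.position : ind.position] = list(ind.seq)
        sequences[rep] = "".join(s)

        shift_events = sorted(
            (
                (i.position, len(i.seq) if i.kind == "insertion" else -len(i.seq),
                 i.position + (0 if i.kind == "insertion" else len(i.seq)))
                for i in truth.indels
                if i.replicon == rep
            ),
        )
        for feat in genome.features:
            if feat.replicon != rep:
                continue
            if any(
                delta < 0 and pos < feat.end and feat.start < span_end
                for pos, delta, span_end in shift_events
            ):
                continue  # feature removed by a deletion
            ds = sum(d for p, d, _ in shift_events if p <= feat.start)
            de = sum(d for p, d, _ in shift_events if p < feat.end)
            features.append(feat.shifted(ds, de))
    for action, name in truth.replicon_events:
        if action == "gain":
            sequences[name] = truth.gained_sequences[name]
    return AnnotatedGenome(sequences=sequences, features=features)


# ---------------------------------------------------------------------------
# standalone homopolymer error injector
# ---------------------------------------------------------------------------

def inject_homopolymer_indels(
    sequence: str,
    rate: float,
    min_run: int = 3,
    seed: int = 0,
    mode: str = "insertion",
    replicon_name: str = "seq",
) -> tuple[str, DivergenceTruth]:
    """Inject single-base indels into homopolymer runs (sequencing-error mode).

    Every recorded event is a one-base insertion or deletion whose site is
    the start of a maximal run of length >= ``min_run``; each eligible run is
    hit independently with probability ``rate``.
    """
    if not 0 <= rate <= 1:
        raise ParameterError("rate must be in [0, 1]")
    if min_run < 2:
        raise ParameterError("min_run must be >= 2")
    if mode not in ("insertion", "deletion", "both"):
        raise ParameterError("mode must be insertion|deletion|both")
    rng = np.random.default_rng(seed)
    truth = DivergenceTruth()
    for start, length, base in _homopolymer_runs(sequence, min_run):
        if rng.random() < rate:
            kind = _pick_indel_kind(mode, rng)
            truth.indels.append(TruthIndel(replicon_name, start, base, kind, "homopolymer"))
    s = list(sequence)
    for ind in sorted(truth.indels, key=lambda i: i.position, reverse=True):
        if ind.kind == "deletion":
            del s[ind.position]
        else:
            s[ind.position : ind.position] = [ind.seq]
    return "".join(s), truth


# ---------------------------------------------------------------------------
# parameter serialization
# ---------------------------------------------------------------------------

def write_params_json(path: str | Path, *param_sets) -> None:
    payload = {type(p).__name__: asdict(p) for p in param_sets}
    Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")


def read_params_json(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    out = {}
    if "AncestorParams" in raw:
        d = raw["AncestorParams"]
        d["sd_offset_range"] = tuple(d["sd_offset_range"])
        out["ancestor"] = AncestorParams(**d)
    if "DivergenceParams" in raw:
        d = raw["DivergenceParams"]
        for k in ("sd_window", "large_indel_len_range"):
            d[k] = tuple(d[k])
        out["divergence"] = DivergenceParams(**d)
    return out
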