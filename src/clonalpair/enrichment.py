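"""SNP density relative to CDS landmarks.

Two axes: absolute position upstream of start codons (strand-aware, with a
centered sliding window, matching how ribosome-binding-site de-enrichment is
visualized) and relative position within CDSs (position / CDS length, with a
null band computed from the last 90% of the CDS). A z-score formalizes the
1-/2-standard-deviation comparison against the null band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, UndefinedResultError
from .genome import AnnotatedGenome


@dataclass
class EnrichmentProfile:
    """A positional SNP-density profile with window smoothing and a null band.

    ``positions`` are upstream offsets (-max..-1) for the absolute axis or
    bin indices (0..n_bins-1) for the relative axis. ``density`` is per-CDS
    SNP density (count / contributing CDSs for the upstream axis, count /
    n_cds_used for the relative axis).
    """

    axis: str  # 'upstream_absolute' or 'cds_relative'
    positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    denominators: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    density: np.ndarray = field(default_factory=lambda: np.array([]))
    window_mean: np.ndarray = field(default_factory=lambda: np.array([]))
    window_sd: np.ndarray = field(default_factory=lambda: np.array([]))
    null_mean: float = 0.0
    null_sd: float = 0.0
    n_snps_used: int = 0
    n_cds_used: int = 0

    def region_mean_density(self, lo: int, hi: int) -> float:
        """Mean density over positions/bins in [lo, hi] inclusive."""
        mask = (self.positions >= lo) & (self.positions <= hi)
        if not mask.any():
            raise InputError(f"region [{lo}, {hi}] outside profile axis")
        return float(self.density[mask].mean())

    def bins_below_null(self, n_sd: float) -> np.ndarray:
        """Boolean mask of positions with density below null_mean - n_sd * null_sd."""
        return self.density < (self.null_mean - n_sd * self.null_sd)


def _rolling(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling mean and SD with truncated edges."""
    n = len(values)
    half = window // 2
    mean = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = values[lo:hi]
        mean[i] = seg.mean()
        sd[i] = seg.std(ddof=0)
    return mean, sd


def _snp_indicator(variants, genome: AnnotatedGenome) -> dict[str, np.ndarray]:
    records = getattr(variants, "records", variants)
    out = {name: np.zeros(len(seq), dtype=int) for name, seq in genome.sequences.items()}
    for r in records:
        if r.kind == "snp" and r.replicon_a in out:
            out[r.replicon_a][r.a_position] += 1
    return out


def upstream_profile(
    variants,
    genome: AnnotatedGenome,
    max_upstream: int = 60,
    window: int = 3,
    null_region: tuple[int, int] = (-60, -21),
) -> EnrichmentProfile:
    """Per-position SNP density upstream of start codons (strand-aware).

    For each CDS, upstream offsets -max_upstream..-1 are mapped to genome
    positions; positions that fall inside another CDS or off the replicon
    are excluded from that position's denominator, so density is comparable
    across genomes. The null band is computed over ``null_region`` (far
    upstream positions, by default -60..-21, away from both the
    Shine-Dalgarno window and the spacer next to the start codon).
    """
    cds = genome.cds()
    if not cds:
        raise InputError("annotation contains no CDS")
    snp = _snp_indicator(variants, genome)
    cds_mask = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.sequences.items()}
    for f in cds:
        cds_mask[f.replicon][f.start : f.end] = True

    offsets = np.arange(1, max_upstream + 1)  # distance upstream of the start codon
    counts = np.zeros(max_upstream, dtype=int)
    denoms = np.zeros(max_upstream, dtype=int)
    n_used = 0
    for f in cds:
        L = len(genome.sequences[f.replicon])
        pos = f.start - offsets if f.strand == "+" else f.end - 1 + offsets
        valid = (pos >= 0) & (pos < L)
        pv = pos[valid]
        inside = cds_mask[f.replicon][pv]
        pv = pv[~inside]
        keep = np.flatnonzero(valid)
        keep = keep[~inside]
        if len(keep) == 0:
            continue
        n_used += 1
        denoms[keep] += 1
        counts[keep] += snp[f.replicon][pv]

    density = np.divide(counts, denoms, out=np.zeros(max_upstream), where=denoms > 0)
    # order the axis from -max_upstream to -1
    positions = -offsets[::-1]
    density = density[::-1]
    counts = counts[::-1]
    denoms = denoms[::-1]
    wmean, wsd = _rolling(density, window)
    prof = EnrichmentProfile(
        axis="upstream_absolute",
        positions=positions,
        counts=counts,
        denominators=denoms,
        density=density,
        window_mean=wmean,
        window_sd=wsd,
        n_snps_used=int(counts.sum()),
        n_cds_used=n_used,
    )
    lo, hi = null_region
    mask = (positions >= lo) & (positions <= hi) & (denoms > 0)
    if mask.any():
        prof.null_mean = float(density[mask].mean())
        prof.null_sd = float(density[mask].std(ddof=0))
    return prof


def relative_cds_profile(
    variants,
    genome: AnnotatedGenome,
    n_bins: int = 100,
    null_start_fraction: float = 0.10,
    count_mode: str = "per_context",
) -> EnrichmentProfile:
    """SNP abundance versus relative position in CDS (position / CDS length).

    Each CDS SNP contributes to bin floor(relative_position x n_bins); the
    null mean/SD are computed over bins covering relative positions >=
    ``null_start_fraction`` (the last 90% of the CDS by default). With
    ``count_mode="per_context"`` a SNP inside overlapping CDSs contributes
    once per CDS; ``"single"`` counts it only for the first containing CDS.
    """
    if count_mode not in ("per_context", "single"):
        raise InputError("count_mode must be per_context or single")
    cds = [f for f in genome.cds() if f.length >= n_bins]
    if not cds:
        raise InputError(f"no CDS of length >= {n_bins}")
    records = [r for r in getattr(variants, "records", variants) if r.kind == "snp"]
    by_rep: dict[str, list[int]] = {}
    for r in records:
        by_rep.setdefault(r.replicon_a, []).append(r.a_position)
    counts = np.zeros(n_bins, dtype=int)
    claimed: set[tuple[str, int]] = set()
    for f in sorted(cds, key=lambda f: (f.replicon, f.start)):
        positions = by_rep.get(f.replicon, [])
        for p in positions:
            if not (f.start <= p < f.end):
                continue
            if count_mode == "single":
                if (f.replicon, p) in claimed:
                    continue
                claimed.add((f.replicon, p))
            i = p - f.start if f.strand == "+" else f.end - 1 - p
            b = min(n_bins - 1, (i * n_bins) // f.length)
            counts[b] += 1
    density = counts / len(cds)
    positions = np.arange(n_bins)
    wmean, wsd = _rolling(density, 3)
    prof = EnrichmentProfile(
        axis="cds_relative",
        positions=positions,
        counts=counts,
        denominators=np.full(n_bins, len(cds)),
        density=density,
        window_mean=wmean,
        window_sd=wsd,
        n_snps_used=int(counts.sum()),
        n_cds_used=len(cds),
    )
    first_null_bin = int(np.ceil(null_start_fraction * n_bins))
    null = density[first_null_bin:]
    prof.null_mean = float(null.mean())
    prof.null_sd = float(null.std(ddof=0))
    return prof


def enrichment_zscore(profile: EnrichmentProfile, region: tuple[int, int]) -> float:
    """Standardized deviation of a region's mean density from the null band:
    (mean density over region - null_mean) / null_sd."""
    if profile.null_sd == 0:
        raise UndefinedResultError("null SD is zero; z-score undefined")
    lo, hi = region
    return (profile.region_mean_density(lo, hi) - profile.null_mean) / profile.null_sd
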