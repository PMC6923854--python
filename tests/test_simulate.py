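"""Synthetic-genome generator and divergence simulator contracts."""

import numpy as np
import pytest
from scipy import stats

from clonalpair import (
    AncestorParams,
    DivergenceParams,
    ParameterError,
    apply_truth,
    classify_snp,
    generate_ancestor,
    inject_homopolymer_indels,
    simulate_divergence,
)
from clonalpair.align import VariantRecord
from clonalpair.codons import CODON_TO_AA
from clonalpair.simulate import DivergenceTruth, _homopolymer_runs


class TestGenerateAncestor:
    def test_gc_and_cds_density_contract(self):
        """50 kb at gc 0.72, density 0.85: realized GC in [0.71, 0.73] and
        about 42.5 kb of CDS."""
        g = generate_ancestor(
            AncestorParams(replicon_lengths=[50_000], gc_target=0.72,
                           cds_density=0.85, seed=1)
        )
        assert 0.71 <= g.gc_fraction() <= 0.73
        cds_bases = sum(f.length for f in g.cds())
        assert abs(cds_bases - 42_500) < 2_500

    def test_cds_structure_and_sd_motifs(self, ancestor_100k):
        """Every CDS is in-frame with start/stop and no internal stop; an SD
        motif sits within the offset range upstream of >= 90% of starts."""
        g = ancestor_100k
        n_with_motif = 0
        for f in g.cds():
            s = g.cds_sequence(f)
            assert len(s) % 3 == 0
            assert s[:3] == "ATG"
            assert CODON_TO_AA[s[-3:]] == "*"
            assert all(CODON_TO_AA[s[i:i + 3]] != "*" for i in range(3, len(s) - 3, 3))
            seq = g.sequences[f.replicon]
            # motif ends 5-10 bases upstream of the start codon
            if f.strand == "+":
                upstream = seq[f.start - 16 : f.start - 4]
                n_with_motif += "AGGAGG" in upstream
            else:
                upstream = seq[f.end + 4 : f.end + 16]
                n_with_motif += "CCTCCT" in upstream
            assert 0 <= f.start < f.end <= len(seq)
        assert n_with_motif >= 0.9 * len(g.cds())

    def test_homopolymer_runs_geometric_at_boost_one(self):
        """With boost 1.0 and gc 0.5 the intergenic run-length distribution
        follows the geometric law (chi-square on pooled runs)."""
        g = generate_ancestor(
            AncestorParams(replicon_lengths=[150_000], gc_target=0.5,
                           cds_density=0.2, homopolymer_boost=1.0, seed=4)
        )
        seq = g.sequences["chromosome"]
        feats = sorted(g.features, key=lambda f: f.start)
        segments, prev = [], 0
        for f in feats:
            segments.append(seq[prev + 1 : f.start - 1])
            prev = f.end
        segments.append(seq[prev + 1 :])
        lengths = []
        for s in segments:
            runs = _homopolymer_runs(s, 1)
            # drop boundary-truncated runs
            for start, length, _ in runs:
                if start > 0 and start + length < len(s):
                    lengths.append(length)
        lengths = np.array(lengths)
        kmax = 6
        observed = [np.sum(lengths == k) for k in range(1, kmax)]
        observed.append(np.sum(lengths >= kmax))
        p = 0.25  # continuation probability at gc 0.5
        probs = [(1 - p) * p ** (k - 1) for k in range(1, kmax)]
        probs.append(1 - sum(probs))
        expected = np.array(probs) * len(lengths)
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_infeasible_density_raises(self):
        with pytest.raises(ParameterError):
            generate_ancestor(
                AncestorParams(replicon_lengths=[300], cds_density=0.99,
                               mean_cds_len=10_000, seed=0)
            )

    def test_determinism(self):
        p = AncestorParams(replicon_lengths=[30_000], seed=9)
        g1, g2 = generate_ancestor(p), generate_ancestor(p)
        assert g1.sequences == g2.sequences
        assert g1.features == g2.features


class TestSimulateDivergence:
    def test_null_divergence_is_identity(self, ancestor_100k):
        d, truth = simulate_divergence(
            ancestor_100k,
            DivergenceParams(snp_rate=0.0, seed=3),
        )
        assert d.sequences == ancestor_100k.sequences
        assert not truth.snps and not truth.indels and not truth.replicon_events

    def test_snp_count_poisson(self, ancestor_100k):
        """At 5e-3 per base on 100 kb, realized SNP count is within 3 sigma
        of 500 under a Poisson law."""
        _, truth = simulate_divergence(
            ancestor_100k,
            DivergenceParams(snp_rate=5e-3, sd_suppression=1.0,
                             cds5_suppression=1.0, seed=5),
        )
        assert abs(len(truth.snps) - 500) < 3 * np.sqrt(500)

    def test_sd_suppression_rate_ratio(self):
        """Realized SNP density in SD windows over elsewhere-intergenic
        density recovers the suppression multiplier."""
        g = generate_ancestor(AncestorParams(replicon_lengths=[200_000], seed=6))
        params = DivergenceParams(snp_rate=0.05, sd_suppression=0.2,
                                  cds5_suppression=1.0, seed=7)
        _, truth = simulate_divergence(g, params)
        seq_len = len(g.sequences["chromosome"])
        sd_mask = np.zeros(seq_len, dtype=bool)
        cds_mask = np.zeros(seq_len, dtype=bool)
        lo, hi = params.sd_window
        for f in g.cds():
            cds_mask[f.start:f.end] = True
            if f.strand == "+":
                sd_mask[max(0, f.start - hi) : max(0, f.start - lo + 1)] = True
            else:
                sd_mask[f.end - 1 + lo : f.end + hi] = True
        inter_mask = ~cds_mask & ~sd_mask
        snp_pos = np.array([s.position for s in truth.snps])
        sd_density = sd_mask[snp_pos].sum() / sd_mask.sum()
        inter_density = inter_mask[snp_pos].sum() / inter_mask.sum()
        assert 0.08 < sd_density / inter_density < 0.4

    def test_conservation_and_determinism(self, ancestor_100k):
        """Applying the truth to the ancestor reconstructs the derived genome
        exactly, including indels and plasmid gain/loss; same seed, same output."""
        params = DivergenceParams(
            seed=8, large_indel_rate=2, homopolymer_indel_rate=0.05,
            plasmid_gain_loss=[{"action": "gain", "name": "pNew", "length": 5_000}],
        )
        d1, t1 = simulate_divergence(ancestor_100k, params)
        d2, t2 = simulate_divergence(ancestor_100k, params)
        assert d1.sequences == d2.sequences and t1.snps == t2.snps
        rebuilt = apply_truth(ancestor_100k, t1)
        assert rebuilt.sequences == d1.sequences
        assert "pNew" in d1.sequences and len(d1.sequences["pNew"]) == 5_000

    def test_truth_effects_match_classifier(self, pair_100k):
        """Truth effect labels agree with the independent per-SNP classifier
        run on the ancestor annotation."""
        anc, _, truth = pair_100k
        for s in truth.snps:
            v = VariantRecord(s.replicon, s.replicon, s.position, s.position,
                              "snp", s.ref, s.alt, 1)
            eff = classify_snp(v, anc)
            assert (eff.effect if eff else None) == s.effect

    def test_truth_tsv_round_trip(self, pair_100k, tmp_path):
        _, _, truth = pair_100k
        path = tmp_path / "truth.tsv"
        truth.write_tsv(path)
        back = DivergenceTruth.read_tsv(path)
        assert back.snps == truth.snps
        assert back.indels == truth.indels
        assert back.replicon_events == truth.replicon_events

    def test_plasmid_drop(self):
        g = generate_ancestor(AncestorParams(replicon_lengths=[30_000, 10_000], seed=10))
        d, truth = simulate_divergence(
            g, DivergenceParams(seed=11, plasmid_gain_loss=[
                {"action": "drop", "name": "plasmid1"}]),
        )
        assert "plasmid1" not in d.sequences
        assert ("drop", "plasmid1") in truth.replicon_events


class TestInjectHomopolymerIndels:
    def test_zero_rate_is_identity(self):
        out, truth = inject_homopolymer_indels("ACGTACGTAAACCC", rate=0.0, seed=1)
        assert out == "ACGTACGTAAACCC" and not truth.indels

    def test_rate_one_hits_every_run(self):
        out, truth = inject_homopolymer_indels(
            "AAAAATTTTT", rate=1.0, min_run=5, seed=1, mode="insertion"
        )
        assert len(truth.indels) == 2
        assert out == "AAAAAATTTTTT"
        kinds = {i.kind for i in truth.indels}
        assert kinds == {"insertion"}

    def test_events_only_in_long_runs(self):
        seq = "AAAA" + "CG" * 10 + "TTTTT" + "ACGT" * 5
        out, truth = inject_homopolymer_indels(seq, rate=1.0, min_run=4, seed=2,
                                               mode="deletion")
        runs = {(s, l) for s, l, _ in _homopolymer_runs(seq, 4)}
        assert len(truth.indels) == len(runs)
        for ind in truth.indels:
            assert any(s <= ind.position < s + l for s, l in runs)
        assert len(out) == len(seq) - len(truth.indels)

    def test_binomial_count(self):
        """rate 0.5 on 1000 eligible runs: count within binomial 3 sigma of 500."""
        seq = "AAAAC" * 1000
        _, truth = inject_homopolymer_indels(seq, rate=0.5, min_run=3, seed=3)
        sigma = np.sqrt(1000 * 0.25)
        assert abs(len(truth.indels) - 500) < 3 * sigma

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            inject_homopolymer_indels("ACGT", rate=1.5)
        with pytest.raises(ParameterError):
            inject_homopolymer_indels("ACGT", rate=0.5, min_run=1)
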