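"""cis windows, trans correlation, and miRNA complementarity scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triadscreen import (
    DegenerateInputError,
    SampleMismatchError,
    ThresholdConfig,
    TranscriptRecord,
    ValidationError,
    cis_targets,
    mir_target_score,
    pearson_p,
    scan_best_site,
    trans_targets,
)

from conftest import make_matrix


def feat(tid, chrom="chr1", start=1, end=100, strand="+"):
    return TranscriptRecord(tid, chrom, start, end, strand, 1, end - start + 1)


class TestCisTargets:
    LNC = feat("lnc1", start=1_000_000, end=1_001_000)

    def test_gene_within_window(self):
        gene = feat("g1", start=1_050_000, end=1_052_000)
        edges = cis_targets([self.LNC], [gene])
        assert len(edges) == 1
        assert edges[0].distance == 48_999

    def test_boundary_gap_of_exactly_window_is_included(self):
        gene = feat("g1", start=1_101_001, end=1_102_000)
        edges = cis_targets([self.LNC], [gene])
        assert len(edges) == 1 and edges[0].distance == 100_000

    def test_gap_one_past_window_is_excluded(self):
        gene = feat("g1", start=1_101_002, end=1_102_000)
        assert cis_targets([self.LNC], [gene]) == []

    def test_other_chromosome_never_matches(self):
        gene = feat("g1", chrom="chr2", start=1_000_500, end=1_000_600)
        assert cis_targets([self.LNC], [gene]) == []

    def test_overlap_counts_as_distance_zero(self):
        gene = feat("g1", start=1_000_500, end=1_003_000)
        edges = cis_targets([self.LNC], [gene])
        assert edges[0].distance == 0

    def test_matches_brute_force_and_is_symmetric(self):
        rng = np.random.default_rng(31)
        cfg = ThresholdConfig()
        for _ in range(100):
            lncs = [feat(f"l{i}", chrom=f"chr{rng.integers(1, 3)}",
                         start=(s := int(rng.integers(1, 500_000))),
                         end=s + int(rng.integers(100, 5000)))
                    for i in range(int(rng.integers(1, 8)))]
            genes = [feat(f"g{i}", chrom=f"chr{rng.integers(1, 3)}",
                          start=(s := int(rng.integers(1, 500_000))),
                          end=s + int(rng.integers(100, 5000)))
                     for i in range(int(rng.integers(1, 8)))]
            got = {(e.source, e.target, e.distance)
                   for e in cis_targets(lncs, genes, cfg)}
            expected = set()
            for l in lncs:
                for g in genes:
                    if l.chrom != g.chrom:
                        continue
                    if l.start <= g.end and g.start <= l.end:
                        d = 0
                    else:
                        d = max(l.start, g.start) - min(l.end, g.end) - 1
                    if d <= cfg.cis_window:
                        expected.add((l.transcript_id, g.transcript_id, d))
            assert got == expected
            # the gap metric is symmetric: scanning genes against lncs
            # yields the mirrored edge set
            mirrored = {(e.target, e.source, e.distance)
                        for e in cis_targets(genes, lncs, cfg)}
            assert got == mirrored


class TestPearsonP:
    def test_perfect_linearity(self):
        x = np.arange(12.0)
        r, p = pearson_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_r_09_at_n12_is_significant_below_001(self):
        # engineer an exact r = 0.9 pair at n = 12
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        xs = (x - x.mean()) / x.std()
        zc = z - z.mean() - np.dot(z - z.mean(), xs) * xs / np.dot(xs, xs)
        zs = zc / zc.std()
        y = 0.9 * xs + np.sqrt(1 - 0.81) * zs
        r, p = pearson_p(x, y)
        assert r == pytest.approx(0.9, abs=1e-10)
        assert p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_p(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pearson_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestTransTargets:
    def test_duplicated_row_yields_r_one(self):
        rng = np.random.default_rng(19)
        row = rng.normal(10, 2, 12)
        lnc = make_matrix(row[None, :], unit="FPKM", prefix="l")
        gene = make_matrix(np.vstack([row, rng.normal(10, 2, 12)]),
                           unit="FPKM", prefix="g")
        edges = trans_targets(lnc, gene)
        assert any(e.target == "g0" and e.r == pytest.approx(1.0)
                   for e in edges)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(37)
        cfg = ThresholdConfig(trans_r=0.5, trans_p=0.2)  # permissive: more hits
        for _ in range(100):
            a = rng.normal(size=(5, 12))
            b = rng.normal(size=(6, 12))
            lnc = make_matrix(a - a.min() + 1, unit="FPKM", prefix="l")
            gene = make_matrix(b - b.min() + 1, unit="FPKM", prefix="g")
            got = {(e.source, e.target) for e in trans_targets(lnc, gene, cfg)}
            expected = set()
            for i in range(5):
                for j in range(6):
                    r, p = pearson_p(lnc.values.iloc[i], gene.values.iloc[j])
                    if abs(r) > cfg.trans_r and p < cfg.trans_p:
                        expected.add((f"l{i}", f"g{j}"))
            assert got == expected

    def test_invariant_under_common_sample_permutation(self):
        rng = np.random.default_rng(41)
        a, b = rng.normal(5, 1, (4, 12)), rng.normal(5, 1, (5, 12))
        lnc = make_matrix(a, unit="FPKM", prefix="l")
        gene = make_matrix(b, unit="FPKM", prefix="g")
        base = {(e.source, e.target) for e in trans_targets(lnc, gene)}
        perm = rng.permutation(12)
        cols = [lnc.samples[i] for i in perm]
        lnc_p = lnc.subset_samples(cols)
        gene_p = gene.subset_samples(cols)
        assert {(e.source, e.target)
                for e in trans_targets(lnc_p, gene_p)} == base

    def test_sample_mismatch_lists_columns(self):
        lnc = make_matrix(np.ones((2, 12)) + np.arange(12), unit="FPKM")
        gene = make_matrix(np.ones((2, 12)) + np.arange(12), unit="FPKM")
        bad = gene.subset_samples(gene.samples[::-1])
        with pytest.raises(SampleMismatchError):
            trans_targets(lnc, bad)

    def test_planted_trans_pair_recovered(self, default_sim):
        from triadscreen import fpkm

        lnc_fpkm = fpkm(default_sim.counts["lncRNA"], default_sim.lengths)
        gene_fpkm = fpkm(default_sim.counts["mRNA"], default_sim.lengths)
        edges = {(e.source, e.target)
                 for e in trans_targets(lnc_fpkm, gene_fpkm)}
        planted = [(e.source, e.target)
                   for e in default_sim.truth.planted_edges
                   if e.etype == "lnc_trans"]
        assert planted, "the default configuration plants trans pairs"
        for pair in planted:
            assert pair in edges


RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class TestMirTargetScore:
    MIR = "UGACAGAAGAGAGUGAGCACA"  # 21 nt

    def site(self, mutate_at=None, to=None):
        """Reverse complement of MIR, optionally mutated at a miRNA
        position (1-based from the miRNA 5' end)."""
        bases = [RC[b] for b in self.MIR]  # bases[i] pairs miRNA pos i+1
        if mutate_at is not None:
            bases[mutate_at - 1] = to
        return "".join(reversed(bases))

    def test_perfect_reverse_complement_scores_zero(self):
        assert mir_target_score(self.MIR, self.site()) == 0.0

    def test_gu_wobble_outside_core_scores_half(self):
        # miRNA position 15 is G; pairing it with U makes a G:U wobble
        assert self.MIR[14] == "G"
        assert mir_target_score(self.MIR, self.site(mutate_at=15, to="U")) == 0.5

    def test_mismatch_in_core_scores_two(self):
        # miRNA position 5 is A; an A:G apposition is a plain mismatch,
        # doubled inside positions 2-13
        assert mir_target_score(self.MIR, self.site(mutate_at=5, to="G")) == 2.0

    def test_dna_alphabet_accepted_via_t_to_u(self):
        assert mir_target_score(self.MIR.replace("U", "T"),
                                self.site().replace("U", "T")) == 0.0

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValidationError):
            mir_target_score("UGACAGAAGAGAGUGAGCACX", self.site())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mir_target_score(self.MIR, self.site()[:-1])

    def test_scan_finds_embedded_perfect_site(self):
        rng = np.random.default_rng(3)
        flank = "".join(rng.choice(list("ACGU"), 30))
        transcript = flank + self.site() + flank
        score, offset = scan_best_site(self.MIR, transcript)
        assert score == 0.0
        assert offset == 30
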