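"""Diversity and divergence estimators against brute-force oracles and
closed forms."""

import math

import numpy as np
import pytest

from invpop.diversity import (
    divergence_silent,
    diversity_summary,
    harmonic,
    haplotype_count,
    jukes_cantor,
    nucleotide_diversity,
    segregating_sites,
    silent_diversity,
    sliding_window_pi,
    watterson_theta_silent,
)
from invpop.errors import InsufficientSampleError, UndefinedValueError
from invpop.io import GeneAnnotation, classify_sites, complete_deletion_mask
from invpop.simulate import ClassSample, CoalescentConfig, simulate_arrangements

from conftest import make_aln


class TestSegregatingSites:
    def test_monomorphic(self):
        aln = make_aln({f"s{i}": "ACGT" for i in range(4)})
        assert segregating_sites(aln) == (0, 0)

    def test_column_scan_oracle(self):
        """Exhaustive scan of a 3-column fixture: both polymorphic columns
        have minor count 1, so S=2 and both are singletons."""
        aln = make_aln({"s1": "AAA", "s2": "AAT", "s3": "AAT", "s4": "GAT"})
        seqs = ["AAA", "AAT", "AAT", "GAT"]
        S_oracle = sing_oracle = 0
        for c in range(3):
            col = [s[c] for s in seqs]
            counts = {b: col.count(b) for b in set(col)}
            if len(counts) >= 2:
                S_oracle += 1
                if sum(counts.values()) - max(counts.values()) == 1:
                    sing_oracle += 1
        assert segregating_sites(aln) == (S_oracle, sing_oracle) == (2, 2)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            segregating_sites(make_aln({"s1": "ACGT"}))

    def test_expected_s_under_neutrality(self):
        """E[S] = θ·a1·L on neutral single-class simulations (100 seeds)."""
        theta, L, n = 0.005, 1000, 12
        vals = []
        for seed in range(1, 101):
            cfg = CoalescentConfig(
                classes=[ClassSample("A", "P", n, 0.0)],
                locus_length=L, theta_per_site=theta, seed=seed,
            )
            aln, _ = simulate_arrangements(cfg)
            vals.append(segregating_sites(aln)[0])
        expected = theta * harmonic(n) * L
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se + 0.5


class TestNucleotideDiversity:
    def test_single_pair(self):
        aln = make_aln({"s1": "A" * 100, "s2": "T" + "A" * 99})
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_monomorphic_zero(self):
        aln = make_aln({f"s{i}": "ACGT" * 5 for i in range(4)})
        assert nucleotide_diversity(aln) == 0.0

    def test_all_pairs_oracle_and_reorder_invariance(self, sim_pair):
        _, aln, _ = sim_pair
        sub = aln.by_arrangement("anc")
        mask = complete_deletion_mask(sub)
        pi = nucleotide_diversity(sub, mask)
        # quadratic brute force over Hamming proportions
        seqs = [s for s in sub.sequences]
        L = mask.sum()
        idx = np.nonzero(mask)[0]
        acc, k = 0.0, 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                acc += sum(seqs[i][c] != seqs[j][c] for c in idx) / L
                k += 1
        assert pi == pytest.approx(acc / k, abs=1e-12)
        # invariant under sequence reordering
        perm = sub.subset(list(reversed(sub.seq_ids)))
        assert nucleotide_diversity(perm, mask) == pytest.approx(pi, abs=1e-15)


class TestSilentStatistics:
    def test_intron_only_equals_pi(self, sim_pair):
        _, aln, _ = sim_pair
        sub = aln.by_arrangement("anc")
        mask = complete_deletion_mask(sub)
        annot = GeneAnnotation("g", [])  # no exons: everything noncoding
        sc = classify_sites(sub, annot, mask)
        assert silent_diversity(sub, mask, sc) == pytest.approx(
            nucleotide_diversity(sub, mask) * mask.sum() / sc.silent_sites_total
        )

    def test_nonsynonymous_pair_contributes_zero(self):
        # GGA (Gly) vs GTA (Val): one nonsynonymous change, no silent diff
        aln = make_aln({"s1": "GGA", "s2": "GTA"})
        sc = classify_sites(aln, GeneAnnotation("g", [(0, 3)]))
        assert silent_diversity(aln, None, sc) == 0.0

    def test_synonymous_pair_counts_one(self):
        # GGA vs GGC: synonymous third-position difference
        aln = make_aln({"s1": "GGAGGG", "s2": "GGCGGG"})
        sc = classify_sites(aln, GeneAnnotation("g", [(0, 6)]))
        assert silent_diversity(aln, None, sc) == pytest.approx(
            1.0 / sc.silent_sites_total
        )

    def test_mixed_codon_pathway_oracle(self):
        """Two-difference codon pair: silent count averages over the two
        minimal pathways, enumerated here independently."""
        from Bio.Seq import Seq

        c1, c2 = "TTA", "CTG"  # Leu/Leu, differs at positions 0 and 2
        paths = []
        for order in ([0, 2], [2, 0]):
            cur, syn = c1, 0
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                    syn += 1
                cur = nxt
            paths.append(syn)
        expected_syn = np.mean(paths)
        aln = make_aln({"s1": c1 + "GGG", "s2": c2 + "GGG"})
        sc = classify_sites(aln, GeneAnnotation("g", [(0, 6)]))
        assert silent_diversity(aln, None, sc) == pytest.approx(
            expected_syn / sc.silent_sites_total
        )

    def test_watterson_examples(self):
        # n=2: a1=1; 3 silent segregating sites over 100 silent sites
        s1 = "A" * 100
        s2 = "C" * 3 + "A" * 97
        aln = make_aln({"s1": s1, "s2": s2})
        sc = classify_sites(aln, GeneAnnotation("g", []))
        assert watterson_theta_silent(aln, None, sc) == pytest.approx(0.03)

    def test_watterson_harmonic_oracle_n10(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), 200)
        seqs = {}
        for i in range(10):
            s = base.copy()
            if i < 5:
                s[i] = "T" if base[i] != "T" else "G"
            seqs[f"s{i}"] = "".join(s)
        aln = make_aln(seqs)
        sc = classify_sites(aln, GeneAnnotation("g", []))
        S, _ = segregating_sites(aln)
        a1 = sum(1 / i for i in range(1, 10))
        assert a1 == pytest.approx(2.8289682539682537)
        assert watterson_theta_silent(aln, None, sc) == pytest.approx(S / (a1 * 200))


class TestDivergence:
    def test_identical_outgroup_zero(self):
        aln = make_aln(
            {"s1": "ACGT" * 10, "s2": "ACGT" * 10, "out": "ACGT" * 10},
            outgroup_id="out",
        )
        sc = classify_sites(aln, GeneAnnotation("g", []))
        assert divergence_silent(aln, None, sc) == 0.0

    def test_jc_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_jc_monotone_and_small_p(self):
        ps = np.linspace(0.001, 0.70, 200)
        ks = [jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        for p in (0.001, 0.005, 0.01):
            assert abs(jukes_cantor(p) - p) / p < 0.014

    def test_jc_saturation_error(self):
        with pytest.raises(UndefinedValueError):
            jukes_cantor(0.76)

    def test_simulated_divergence_band(self):
        """A noncoding locus with outgroup divergence set to give raw
        difference p ≈ 0.17 yields K_sil in the ≈0.19 band (the deepest
        silent divergences of intron-rich genes)."""
        cfg = CoalescentConfig(
            classes=[ClassSample("A", "P", 10, 0.0)],
            locus_length=2000, theta_per_site=0.005,
            outgroup_divergence=0.195,  # JC scale; observed p ≈ 0.17
            seed=9,
        )
        aln, _ = simulate_arrangements(cfg)
        mask = complete_deletion_mask(aln)
        sc = classify_sites(aln, GeneAnnotation("g", []), mask)
        p_raw = divergence_silent(aln, mask, sc, jc_correct=False)
        assert 0.15 < p_raw < 0.19
        k = divergence_silent(aln, mask, sc)
        assert 0.17 < k < 0.23


class TestHaplotypesAndWindows:
    def test_haplotype_counts(self):
        aln = make_aln({f"s{i}": "AAAA" for i in range(5)})
        assert haplotype_count(aln) == 1
        seqs = {f"s{i}": "AAA" + "ACGT"[i] for i in range(4)}
        assert haplotype_count(make_aln(seqs)) == 4
        # one duplicated pair among 10
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 30)) for i in range(9)}
        seqs["s9"] = seqs["s0"]
        assert haplotype_count(make_aln(seqs)) == 9

    def test_window_count_arithmetic(self):
        aln = make_aln({"s1": "A" * 200, "s2": "A" * 200})
        assert len(sliding_window_pi(aln, window=100, step=25)) == 5

    def test_flat_profile_on_uniform_alignment(self):
        s1 = "AT" * 100
        s2 = "AC" * 100  # differs at every second column, uniformly
        aln = make_aln({"s1": s1, "s2": s2})
        prof = sliding_window_pi(aln, window=100, step=100)
        glob = nucleotide_diversity(aln)
        assert all(v == pytest.approx(glob) for _, v in prof)

    def test_concentrated_variability_matches_windowed_oracle(self, sim_pair):
        _, aln, _ = sim_pair
        sub = aln.by_arrangement("derived")
        mask = complete_deletion_mask(sub)
        prof = sliding_window_pi(sub, mask, window=100, step=25)
        # oracle: direct all-pairs computation inside one arbitrary window
        start = 250
        cols = [c for c in range(start, start + 100) if mask[c]]
        seqs = sub.sequences
        acc, k = 0.0, 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                acc += sum(seqs[i][c] != seqs[j][c] for c in cols)
                k += 1
        expected = acc / k / len(cols)
        got = dict(prof)[start + 50.0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_short_alignment_empty_series(self):
        aln = make_aln({"s1": "ACGT", "s2": "ACGT"})
        with pytest.warns(UserWarning):
            assert sliding_window_pi(aln, window=100, step=25) == []


class TestNeutralExpectation:
    def test_pi_matches_theta_watterson_in_expectation(self):
        """π and θ_W agree in expectation on neutral equilibrium
        simulations (paired over 200 seeds)."""
        theta, L, n = 0.004, 800, 10
        diffs = []
        for seed in range(1, 201):
            cfg = CoalescentConfig(
                classes=[ClassSample("A", "P", n, 0.0)],
                locus_length=L, theta_per_site=theta, seed=seed,
            )
            aln, _ = simulate_arrangements(cfg)
            mask = complete_deletion_mask(aln)
            sc = classify_sites(aln, GeneAnnotation("g", []), mask)
            diffs.append(
                nucleotide_diversity(aln, mask)
                - watterson_theta_silent(aln, mask, sc)
            )
        se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se + 1e-4


class TestSummary:
    def test_summary_invariants(self, sim_pair):
        cfg, aln, _ = sim_pair
        sub = aln.by_arrangement("derived", keep_outgroup=True)
        mask = complete_deletion_mask(sub)
        annot = GeneAnnotation("g", cfg.exon_intervals, cfg.frame)
        sc = classify_sites(sub, annot, mask)
        s = diversity_summary(sub, sc, mask)
        assert s.h <= s.n
        assert s.singletons <= s.S
        assert s.pi >= 0 and s.pi_sil >= 0 and s.theta_sil >= 0
        assert s.K_sil is not None and s.K_sil > 0
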