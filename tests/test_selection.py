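"""Nei-Gojobori counting, JC correction, bootstrap rates and the Z-test."""

import itertools
import math
import warnings

import numpy as np
import pytest

from mhcamp import selection as sel

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]

CODE = {}
from Bio.Data.CodonTable import standard_dna_table as _t

CODE.update(_t.forward_table)


def oracle_sites(codon):
    """Straight-line enumeration of the 9 single-base mutants."""
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if m in STOPS:
                continue
            valid += 1
            syn += CODE[m] == CODE[codon]
        s += syn / valid
    return s, 3 - s


def oracle_pathways(c1, c2):
    """Equal-weight average over all minimal pathways, stops excluded."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None  # caller skips the all-blocked corner
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def oracle_pairwise(s1, s2):
    """Independent brute-force Nei-Gojobori on a codon pair list."""
    Nd = Sd = n1 = s1_ = n2 = s2_ = 0.0
    for i in range(0, len(s1), 3):
        a, b = s1[i : i + 3], s2[i : i + 3]
        sa, na = oracle_sites(a)
        sb, nb = oracle_sites(b)
        pw = oracle_pathways(a, b)
        if pw is None:
            return None
        s1_ += sa
        n1_ = na
        n1 += na
        s2_ += sb
        n2 += nb
        Sd += pw[0]
        Nd += pw[1]
    return Nd, Sd, (n1 + n2) / 2, (s1_ + s2_) / 2


def random_codon_pair_seqs(rng, n_codons=30, rate=0.3):
    s1 = "".join(rng.choice(SENSE, n_codons))
    out = []
    for i in range(0, 3 * n_codons, 3):
        c = s1[i : i + 3]
        if rng.random() < rate:
            for _ in range(50):
                j = int(rng.integers(3))
                alt = rng.choice([x for x in "ACGT" if x != c[j]])
                m = c[:j] + alt + c[j + 1 :]
                if m not in STOPS:
                    c = m
                    break
        out.append(c)
    return s1, "".join(out)


class TestSiteCounts:
    def test_phenylalanine_and_tryptophan(self):
        assert sel.ng_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert sel.ng_site_counts("TGG") == pytest.approx((0.0, 3.0))

    def test_all_sense_codons_match_enumeration_and_conserve(self):
        for codon in SENSE:
            s, n = sel.ng_site_counts(codon)
            assert (s, n) == pytest.approx(oracle_sites(codon))
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            sel.ng_site_counts("TAA")


class TestPathways:
    def test_single_difference_leucine(self):
        # TTT (Phe) -> TTA (Leu): one nonsynonymous step
        assert sel.pathway_differences("TTT", "TTA") == (0.0, 1.0)

    def test_identical_codons(self):
        assert sel.pathway_differences("ATG", "ATG") == (0.0, 0.0)

    def test_matches_enumeration_on_all_two_step_pairs(self):
        rng = np.random.default_rng(4)
        idx = rng.integers(0, len(SENSE), size=(400, 2))
        for i, j in idx:
            c1, c2 = SENSE[i], SENSE[j]
            expected = oracle_pathways(c1, c2)
            if expected is None:
                continue
            assert sel.pathway_differences(c1, c2) == pytest.approx(expected)


class TestPairwise:
    def test_identical_sequences(self):
        p = sel.pairwise_ng("TTTATG", "TTTATG")
        assert (p.Nd, p.Sd, p.dN, p.dS) == (0, 0, 0, 0)

    def test_single_codon_example(self):
        p = sel.pairwise_ng("TTT", "TTA", jc_correction=False)
        assert (p.Nd, p.Sd) == (1.0, 0.0)
        assert (p.n_sites, p.s_sites) == pytest.approx((2.5, 0.5))

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            s1, s2 = random_codon_pair_seqs(rng)
            a = sel.pairwise_ng(s1, s2)
            b = sel.pairwise_ng(s2, s1)
            assert (a.dN, a.dS) == pytest.approx((b.dN, b.dS), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(15)
        checked = 0
        while checked < 60:
            s1, s2 = random_codon_pair_seqs(rng)
            expected = oracle_pairwise(s1, s2)
            if expected is None:
                continue
            p = sel.pairwise_ng(s1, s2, jc_correction=False)
            assert (p.Nd, p.Sd, p.n_sites, p.s_sites) == pytest.approx(expected)
            checked += 1

    def test_close_to_independent_library_implementation(self):
        """Biopython's NG86 counts stop-codon neighbours as nonsynonymous
        sites (denominator 3) where this implementation excludes them, so
        the two agree approximately, not exactly."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                s1, s2 = random_codon_pair_seqs(rng)
                mine = sel.pairwise_ng(s1, s2)
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
                assert mine.dN == pytest.approx(dn, abs=0.02)
                assert mine.dS == pytest.approx(ds, rel=0.25, abs=0.02)

    def test_gap_codons_excluded_pairwise(self):
        p_ref = sel.pairwise_ng("TTTATG", "TTAATG")
        p_gap = sel.pairwise_ng("TTTATG---", "TTAATGAAA")
        assert (p_gap.Nd, p_gap.Sd) == (p_ref.Nd, p_ref.Sd)

    def test_saturation_flagged(self):
        assert math.isinf(sel.jukes_cantor(0.8))


class TestJukesCantor:
    def test_monotone_and_at_least_p(self):
        grid = np.linspace(0, 0.74, 50)
        ds = [sel.jukes_cantor(p) for p in grid]
        assert all(b >= a for a, b in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, grid))


class TestMeanRates:
    def test_identical_sequences_zero_rates_zero_se(self):
        est = sel.mean_rates(["TTTATGGGA", "TTTATGGGA"], bootstrap_reps=50, seed=0)
        assert (est.dN, est.dS, est.SE_dN, est.SE_dS) == (0, 0, 0, 0)

    def test_equal_rate_simulation_gives_ratio_near_one(self):
        rng = np.random.default_rng(33)
        anc = "".join(rng.choice(SENSE, 120))
        seqs = []
        for _ in range(6):
            cods = []
            for i in range(0, len(anc), 3):
                c = list(anc[i : i + 3])
                for j in range(3):
                    if rng.random() < 0.05:
                        c[j] = rng.choice([x for x in "ACGT" if x != c[j]])
                cod = "".join(c)
                cods.append(anc[i : i + 3] if cod in STOPS else cod)
            seqs.append("".join(cods))
        est = sel.mean_rates(seqs, bootstrap_reps=300, seed=1)
        z = sel.z_test(est, alternative="two-sided")
        assert z.p > 0.01  # no systematic dN/dS departure under neutrality

    def test_abs_partition_separates_planted_selection(self):
        """Nonsynonymous changes planted only at ABS codons: the ABS
        partition shows dN > dS while non-ABS stays near dS."""
        rng = np.random.default_rng(40)
        n_codons = 90
        mask = np.zeros(n_codons, dtype=bool)
        mask[::3] = True  # every third codon is ABS
        anc = list(rng.choice(SENSE, n_codons))
        seqs = []
        for _ in range(6):
            cods = []
            for c_i, c in enumerate(anc):
                c_new = c
                if mask[c_i] and rng.random() < 0.6:
                    # force a nonsynonymous change
                    for _ in range(100):
                        j = int(rng.integers(3))
                        alt = rng.choice([x for x in "ACGT" if x != c_new[j]])
                        m = c_new[:j] + alt + c_new[j + 1 :]
                        if m not in STOPS and CODE[m] != CODE[c_new]:
                            c_new = m
                            break
                elif not mask[c_i] and rng.random() < 0.2:
                    # synonymous-preferring background
                    for _ in range(100):
                        j = int(rng.integers(3))
                        alt = rng.choice([x for x in "ACGT" if x != c_new[j]])
                        m = c_new[:j] + alt + c_new[j + 1 :]
                        if m not in STOPS and CODE[m] == CODE[c_new]:
                            c_new = m
                            break
                cods.append(c_new)
            seqs.append("".join(cods))
        abs_est = sel.mean_rates(seqs, mask, "ABS", bootstrap_reps=200, seed=2)
        non_est = sel.mean_rates(seqs, mask, "nonABS", bootstrap_reps=200, seed=2)
        assert abs_est.dN > abs_est.dS
        assert sel.z_test(abs_est).p < 0.05
        assert sel.z_test(non_est).p > 0.05

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            sel.mean_rates(["TTT", "TTA"], [False], "ABS", bootstrap_reps=10)

    def test_seeded_bootstrap_bit_reproducible(self):
        rng = np.random.default_rng(50)
        seqs = [random_codon_pair_seqs(rng, 40)[1] for _ in range(4)]
        a = sel.mean_rates(seqs, bootstrap_reps=100, seed=9)
        b = sel.mean_rates(seqs, bootstrap_reps=100, seed=9)
        assert (a.SE_dN, a.SE_dS) == (b.SE_dN, b.SE_dS)


class TestZTest:
    def test_equal_rates_give_zero(self):
        est = sel.RateEstimate(0.1, 0.1, 0.02, 0.02, 2, 10, "all")
        z = sel.z_test(est)
        assert z.z == 0.0

    def test_published_style_inputs(self):
        est = sel.RateEstimate(0.455, 0.128, 0.081, 0.054, 0, 0, "ABS")
        z = sel.z_test(est)
        assert z.z == pytest.approx(3.36, abs=0.01)
        assert z.p < 0.001

    def test_degenerate_zero_se_flags(self):
        est = sel.RateEstimate(0.2, 0.1, 0.0, 0.0, 2, 10, "all")
        assert sel.z_test(est).degenerate
        est0 = sel.RateEstimate(0.1, 0.1, 0.0, 0.0, 2, 10, "all")
        z = sel.z_test(est0)
        assert (z.z, z.p) == (0.0, 1.0)

    def test_two_sided_doubles_one_tail(self):
        est = sel.RateEstimate(0.3, 0.1, 0.05, 0.05, 2, 10, "all")
        one = sel.z_test(est, "positive")
        two = sel.z_test(est, "two-sided")
        assert two.p == pytest.approx(2 * one.p)


class TestAbsMask:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "abs.txt"
        path.write_text("# contact codons\n1\n5\n9\n")
        mask = sel.load_abs_mask(path, 10)
        assert list(np.flatnonzero(mask) + 1) == [1, 5, 9]

    def test_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "abs.txt"
        path.write_text("11\n")
        with pytest.raises(ValueError):
            sel.load_abs_mask(path, 10)
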