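"""Replication filter, chimera explanation, MPAF thresholds, indel flags."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mhcamp import variant_filter as vf
from mhcamp.demultiplex import demultiplex
from mhcamp.simulate import PRIMER_IUPAC


def table_from(counts: dict, totals: dict | None = None) -> vf.VariantTable:
    df = pd.DataFrame(counts).fillna(0).astype(int)
    t = pd.Series(totals) if totals else None
    return vf.VariantTable(df, t)


def oracle_chimera(variant, amplicon_counts):
    """Exhaustive reference: all ordered parent pairs x all breakpoints."""
    own = amplicon_counts.get(variant, 0)
    L = len(variant)
    parents = [s for s, c in amplicon_counts.items() if c > own]
    for a, b in itertools.permutations(parents, 2):
        for k in range(1, L):
            rec = a[:k] + b[k:]
            if rec == variant and rec != a and rec != b:
                return True
    return False


def random_amplicon(rng, n_variants, length=12):
    seqs = set()
    while len(seqs) < n_variants:
        seqs.add("".join("ACGT"[b] for b in rng.integers(0, 2, length)))
    return {s: int(rng.integers(1, 60)) for s in seqs}


class TestReplicationCriterion:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"amp1": {"AAAA": 10}}, []),  # one PCR only
            ({"amp1": {"AAAA": 3}, "amp2": {"AAAA": 3}}, ["AAAA"]),
            ({"amp1": {"AAAA": 3}, "amp2": {"AAAA": 2}}, []),  # < 3 copies
        ],
    )
    def test_two_pcrs_three_copies_rule(self, counts, expected):
        table = table_from(counts)
        got = vf.apply_replication_criterion(table, vf.FilterConfig())
        assert got == expected

    def test_relaxing_thresholds_never_shrinks_candidates(self):
        rng = np.random.default_rng(3)
        names = set()
        while len(names) < 30:
            names.add("".join("ACGT"[b] for b in rng.integers(0, 4, 10)))
        df = pd.DataFrame(rng.integers(0, 6, size=(30, 8)), index=sorted(names))
        df = df[df.sum(axis=1) > 0]
        table = vf.VariantTable(df)
        base = set(vf.apply_replication_criterion(table, vf.FilterConfig()))
        for mp, mc in [(1, 3), (2, 2), (1, 1)]:
            relaxed = set(
                vf.apply_replication_criterion(
                    table, vf.FilterConfig(min_pcrs=mp, min_copies=mc)
                )
            )
            assert base <= relaxed


class TestChimeraExplanation:
    def test_textbook_single_crossover(self):
        counts = {"AAAAAA": 100, "TTTTTT": 90, "AATTTT": 5}
        w = vf.explainable_as_chimera("AATTTT", counts)
        assert w is not None
        assert w.reconstruct() == "AATTTT"
        assert {w.parent_a, w.parent_b} == {"AAAAAA", "TTTTTT"}
        assert w.breakpoint == 2

    def test_no_crossover_explains_variant(self):
        counts = {"AAAAAA": 100, "TTTTTT": 90, "AAGTTT": 5}
        assert vf.explainable_as_chimera("AAGTTT", counts) is None

    def test_most_abundant_variant_never_explainable(self):
        counts = {"AAAAAA": 100, "TTTTTT": 90, "AATTTT": 5}
        assert vf.explainable_as_chimera("AAAAAA", counts) is None

    def test_equal_counts_do_not_qualify_as_parents(self):
        counts = {"AAAAAA": 5, "TTTTTT": 5, "AATTTT": 5}
        assert vf.explainable_as_chimera("AATTTT", counts) is None

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            amplicon = random_amplicon(rng, int(rng.integers(2, 13)))
            variant = sorted(amplicon)[int(rng.integers(len(amplicon)))]
            got = vf.explainable_as_chimera(variant, amplicon)
            assert (got is not None) == oracle_chimera(variant, amplicon)
            if got is not None:
                assert got.reconstruct() == variant
                assert amplicon[got.parent_a] > amplicon.get(variant, 0)
                assert amplicon[got.parent_b] > amplicon.get(variant, 0)


class TestMpaf:
    def test_arithmetic(self):
        table = table_from(
            {"amp1": {"AAAA": 5, "CCCC": 495}, "amp2": {"AAAA": 20, "CCCC": 980}},
        )
        assert vf.compute_mpaf("AAAA", table) == pytest.approx(0.02)

    def test_absent_variant_is_zero(self):
        table = table_from({"amp1": {"AAAA": 5}})
        assert vf.compute_mpaf("GGGG", table) == 0.0

    def test_candidate_minimum_matches_direct_recomputation(self, noisy_run):
        demux = demultiplex(
            noisy_run.reads, noisy_run.tag_sheet, PRIMER_IUPAC, noisy_run.config.window
        )
        table = vf.VariantTable.from_demux(demux)
        candidates = vf.apply_replication_criterion(table, vf.FilterConfig())
        freqs = table.counts.div(table.totals, axis=1)
        direct = min(freqs.loc[c].max() for c in candidates)
        assert min(vf.compute_mpaf(c, table) for c in candidates) == pytest.approx(
            direct
        )


class TestClassification:
    def test_no_explainable_variants_all_become_alleles(self):
        table = table_from(
            {
                "amp1": {"AAAA": 300, "CGCG": 3, "GTAC": 4},
                "amp2": {"AAAA": 300, "CGCG": 3, "GTAC": 4},
            }
        )
        candidates = vf.apply_replication_criterion(table, vf.FilterConfig())
        records = vf.classify_by_mpaf(candidates, table, vf.FilterConfig())
        assert all(r.status == vf.STATUS_ALLELE for r in records.values())

    def test_variant_in_fewer_amplicons_examines_all_of_them(self):
        cfg = vf.FilterConfig(n_check_amplicons=3)
        table = table_from(
            {
                "amp1": {"AAAA": 500, "TTTT": 400, "AATT": 4},
                "amp2": {"AAAA": 500, "TTTT": 400, "AATT": 3},
            },
            totals={"amp1": 1000, "amp2": 1000},
        )
        records = vf.classify_by_mpaf(["AAAA", "TTTT", "AATT"], table, cfg)
        rec = records["AATT"]
        assert rec.status == vf.STATUS_CHIMERA
        assert len(rec.witnesses) == 2  # both occupied amplicons checked

    def test_most_abundant_per_amplicon_never_labelled_chimera(self, noisy_run):
        demux = demultiplex(
            noisy_run.reads, noisy_run.tag_sheet, PRIMER_IUPAC, noisy_run.config.window
        )
        table = vf.VariantTable.from_demux(demux)
        candidates = vf.apply_replication_criterion(table, vf.FilterConfig())
        records = vf.classify_by_mpaf(candidates, table, vf.FilterConfig(), full_scan=True)
        top = {table.counts[amp].idxmax() for amp in table.amplicons}
        for seq in top:
            if seq in records:
                assert records[seq].status != vf.STATUS_CHIMERA

    def test_every_chimera_label_has_reconstructing_witness(self, noisy_run):
        demux = demultiplex(
            noisy_run.reads, noisy_run.tag_sheet, PRIMER_IUPAC, noisy_run.config.window
        )
        table = vf.VariantTable.from_demux(demux)
        candidates = vf.apply_replication_criterion(table, vf.FilterConfig())
        records = vf.classify_by_mpaf(candidates, table, vf.FilterConfig())
        for seq, rec in records.items():
            if rec.status == vf.STATUS_CHIMERA:
                assert rec.witnesses
                for w in rec.witnesses:
                    assert w.reconstruct() == seq

    def test_planted_chimeras_with_cooccurring_parents_are_flagged(self, stress_run):
        """Simulator truth oracle: planted chimeras whose parents co-occur at
        higher abundance in every checked amplicon must be labelled."""
        noisy_run = stress_run
        cfg = vf.FilterConfig()
        demux = demultiplex(
            noisy_run.reads, noisy_run.tag_sheet, PRIMER_IUPAC, noisy_run.config.window
        )
        table = vf.VariantTable.from_demux(demux)
        candidates = set(vf.apply_replication_criterion(table, cfg))
        records = vf.classify_by_mpaf(sorted(candidates), table, cfg, full_scan=True)
        truth = noisy_run.truth
        true_seqs = set(truth.seq_to_allele())
        planted = {
            truth.chimera_window_seq(o)
            for o in truth.provenance.values()
            if o.is_chimera
        } - true_seqs
        checked = 0
        for seq in planted & candidates:
            amps = vf._check_amplicons(seq, table, cfg.n_check_amplicons)
            explainable_everywhere = all(
                vf.explainable_as_chimera(seq, table.amplicon_counts(a)) is not None
                for a in amps
            )
            if explainable_everywhere:
                checked += 1
                assert records[seq].status == vf.STATUS_CHIMERA
        assert checked > 0  # the scenario actually exercises the label


class TestThreshold:
    def test_forced_by_definition(self):
        records = {}
        for m, status in [
            (0.006, vf.STATUS_CHIMERA),
            (0.009, vf.STATUS_CHIMERA),
            (0.0051, vf.STATUS_ALLELE),
            (0.0097, vf.STATUS_ALLELE),
            (0.02, vf.STATUS_ALLELE),
        ]:
            records[f"seq{m}"] = vf.VariantRecord("A", mpaf=m, status=status)
        assert vf.derive_threshold(records) == pytest.approx(0.0097)

    def test_without_chimeras_smallest_allele_mpaf(self):
        records = {
            "a": vf.VariantRecord("A", 0.004, vf.STATUS_ALLELE),
            "b": vf.VariantRecord("C", 0.01, vf.STATUS_ALLELE),
        }
        assert vf.derive_threshold(records) == pytest.approx(0.004)

    def test_empty_classification_rejected(self):
        with pytest.raises(ValueError):
            vf.derive_threshold({})

    def test_matches_bruteforce_scan_on_simulated_classification(self, noisy_run):
        demux = demultiplex(
            noisy_run.reads, noisy_run.tag_sheet, PRIMER_IUPAC, noisy_run.config.window
        )
        table = vf.VariantTable.from_demux(demux)
        candidates = vf.apply_replication_criterion(table, vf.FilterConfig())
        records = vf.classify_by_mpaf(candidates, table, vf.FilterConfig())
        mpafs = sorted((r.mpaf, r.status) for r in records.values())
        best = None
        for i, (m, status) in enumerate(mpafs):
            if status != vf.STATUS_ALLELE:
                continue
            if all(s == vf.STATUS_ALLELE for _, s in mpafs[i:]):
                best = m
                break
        assert vf.derive_threshold(records) == pytest.approx(best)


class TestScaleThreshold:
    def test_published_scalings(self):
        assert round(
            vf.scale_threshold(0.97, 0.164, 0.718), 2
        ) == pytest.approx(4.25)
        assert round(
            vf.scale_threshold(0.97, 0.164, 0.118), 2
        ) == pytest.approx(0.70)

    def test_identity_and_linearity(self):
        assert vf.scale_threshold(0.0097, 0.2, 0.2) == pytest.approx(0.0097, abs=1e-15)
        rng = np.random.default_rng(5)
        for _ in range(50):
            t, p = rng.uniform(0.001, 0.9, 2)
            q = rng.uniform(0.001, 0.5)
            a = vf.scale_threshold(t, p, q)
            assert vf.scale_threshold(t, p, 2 * q) == pytest.approx(2 * a, abs=1e-12)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            vf.scale_threshold(0.01, 0.0, 0.5)
        with pytest.raises(ValueError):
            vf.scale_threshold(0.01, 0.5, 1.5)


def oracle_homopolymer_variants(parent, min_len):
    """All single 1-bp indel edits of ``parent`` inside homopolymer runs of
    length >= min_len."""
    out = set()
    i = 0
    while i < len(parent):
        j = i
        while j < len(parent) and parent[j] == parent[i]:
            j += 1
        if j - i >= min_len:
            out.add(parent[:i] + parent[i] + parent[i:])  # insertion
            out.add(parent[:i] + parent[i + 1 :])  # deletion
        i = j
    out.discard(parent)
    return out


class TestHomopolymerIndel:
    def test_deletion_in_run_of_four(self):
        assert vf.flag_homopolymer_indel("AAATG", ["AAAATG"])

    def test_single_substitution_not_flagged(self):
        assert not vf.flag_homopolymer_indel("AAACTG", ["AAAATG"])

    def test_agrees_with_edit_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        cfg = vf.FilterConfig()
        for _ in range(300):
            parent = "".join("ACGT"[b] for b in rng.integers(0, 2, 30))
            candidates = oracle_homopolymer_variants(parent, cfg.homopolymer_min_len)
            for v in candidates:
                assert vf.flag_homopolymer_indel(v, [parent], cfg)
            # a non-run indel must not be flagged
            runs = oracle_homopolymer_variants(parent, cfg.homopolymer_min_len)
            for pos in range(1, len(parent) - 1):
                edited = parent[:pos] + parent[pos + 1 :]
                if edited not in runs and edited != parent:
                    assert not vf.flag_homopolymer_indel(edited, [parent], cfg)
                    break
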