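"""Simulator: digestion, library, fitness, selection dynamics, reads."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from funscreen import simulate as sim
from funscreen.io_model import GROUP_CULTURE47, GROUP_CULTURE47_FAS, GROUP_D0, GenomeSequence


class TestDigest:
    def test_single_motif_cut_mid_motif(self):
        g = GenomeSequence({"chrT": "AAATTTAAACCC"})
        frags = sim.digest_genome(g, (sim.DRAI,))["DraI"]
        assert list(map(tuple, frags[["start", "end"]].to_numpy())) == [(0, 6), (6, 12)]

    def test_no_motif_single_fragment(self):
        g = GenomeSequence({"c": "ACGT" * 10})
        frags = sim.digest_genome(g, (sim.DRAI,))["DraI"]
        assert len(frags) == 1
        assert (frags.iloc[0]["start"], frags.iloc[0]["end"]) == (0, 40)

    def test_overlapping_motifs_all_cut(self):
        # TTTAAA occurrences at 0 and 3 in TTTAAATTTAAA... craft overlap:
        seq = "TTTAAATAAATTTAAA"
        cuts = sim.find_motif_cuts(seq, sim.DRAI)
        expect = [m.start() + 3 for m in re.finditer("(?=TTTAAA)", seq)]
        assert list(cuts) == sorted(set(expect))

    def test_combined_pool_contains_both_digests(self):
        g = GenomeSequence({"c": "AAATTTAAACCCTTATAACCC"})
        d = sim.digest_genome(g)
        assert len(d["combined"]) == len(d["DraI"]) + len(d["AanI"])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_reassembly_of_random_genome_is_exact(self, seed):
        g = sim.random_genome({"chrR": 100_000}, seed=seed, motif_spacing=800.0)
        digests = sim.digest_genome(g)
        for enz in ("DraI", "AanI"):
            rebuilt = sim.reassemble_digest(g, digests[enz])
            assert rebuilt["chrR"] == g["chrR"]

    def test_every_internal_boundary_is_a_motif_cut(self):
        g = sim.random_genome({"c": 50_000}, seed=3, motif_spacing=500.0)
        for enz in (sim.DRAI, sim.AANI):
            frags = sim.digest_genome(g, (enz,))[enz.name]
            for b in frags["start"].iloc[1:]:
                motif_start = b - enz.cut_offset
                assert g["c"][motif_start : motif_start + 6] == enz.recognition

    def test_non_palindromic_enzyme_rejected(self):
        with pytest.raises(ValueError, match="palindromic"):
            sim.RestrictionEnzyme("X", "TTTAAC", 3)


class TestBuildLibrary:
    @staticmethod
    def _frags(lengths):
        rows, pos = [], 0
        for L in lengths:
            rows.append(("c", pos, pos + L, "DraI"))
            pos += L
        return pd.DataFrame(rows, columns=["seqid", "start", "end", "enzyme"])

    def test_size_window_and_both_orientations(self):
        lib = sim.build_library(self._frags([300, 800, 5000]), 500, 4000)
        assert len(lib) == 2
        assert set(lib["orientation"]) == {"sense", "antisense"}

    def test_observed_insert_range_retains_all(self):
        lib = sim.build_library(self._frags([300, 800, 5000]), 132, 8293)
        assert len(lib) == 6

    def test_seed_determinism(self):
        f = self._frags([200, 300, 400])
        a = sim.build_library(f, 132, 8293, seed=4, orientations="single")
        b = sim.build_library(f, 132, 8293, seed=4, orientations="single")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="size window"):
            sim.build_library(self._frags([10_000]), 132, 8293)


class TestAssignFitness:
    @staticmethod
    def _library(n):
        frags = pd.DataFrame(
            [("c", i * 1000, i * 1000 + 500, "DraI") for i in range(n)],
            columns=["seqid", "start", "end", "enzyme"],
        )
        return sim.build_library(frags, 132, 8293)

    def test_counts_and_effects(self):
        lib = self._library(500)
        ins, truth = sim.assign_fitness(lib, 20, 10, seed=0)
        assert (truth["class"] == "growth").sum() == 20
        assert (truth["class"] == "survival").sum() == 10
        surv = ins[ins["class"] == "survival"]
        assert (surv["fitness_survival"] == sim.DEFAULT_SURVIVAL_EFFECT).all()
        # nested mode: survival hits persist through competitive culture
        assert (surv["fitness_growth"] == sim.DEFAULT_GROWTH_EFFECT).all()

    def test_disjoint_mode_keeps_survival_growth_neutral(self):
        ins, _ = sim.assign_fitness(self._library(100), 5, 5, seed=1, mode="disjoint")
        surv = ins[ins["class"] == "survival"]
        assert (surv["fitness_growth"] == 0.0).all()

    def test_zero_hits_all_neutral(self):
        ins, truth = sim.assign_fitness(self._library(50), 0, 0)
        assert truth.empty and (ins["class"] == "neutral").all()

    def test_too_many_hits_rejected(self):
        with pytest.raises(ValueError, match="hits"):
            sim.assign_fitness(self._library(10), 8, 8)


def _two_insert_library(g):
    lib = pd.DataFrame(
        [
            ("n", "c", 0, 500, "DraI", "sense", 0.0, 0.025),
            ("h", "c", 1000, 1500, "DraI", "sense", g, 0.025),
        ],
        columns=sim.LIBRARY_COLUMNS,
    )
    return lib


class TestSelection:
    def test_growth_ratio_matches_closed_form(self):
        """Relative enrichment of a growth hit over a neutral insert after
        deterministic exponential growth + multinomial dilution matches the
        closed form exp(rate * g * t) in expectation."""
        g = 0.3
        lib = _two_insert_library(g)
        regime = sim.SelectionRegime(
            n_cells=500_000, days=10, subculture_interval_days=2.5,
            challenge=None, seed=0,
        )
        hours = 10 * 24.0
        expected = np.exp(np.log(2) / 26.3 * g * hours)
        ratios = []
        for seed in range(20):
            regime.seed = seed
            ab = sim.simulate_selection(lib, regime, n_replicates=1)
            d47 = ab[ab["group"] == GROUP_CULTURE47].set_index("insert_id")["cells"]
            ratios.append(d47["h"] / d47["n"])
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)

    def test_census_restored_after_dilution(self):
        lib = _two_insert_library(0.2)
        regime = sim.SelectionRegime(n_cells=10_000, days=5, challenge=None, seed=2)
        ab = sim.simulate_selection(lib, regime, n_replicates=2)
        d47 = ab[ab["group"] == GROUP_CULTURE47]
        assert (d47.groupby("replicate")["cells"].sum() == 10_000).all()

    def test_challenge_binomial_oracle(self):
        """10^4 neutral cells at measured survival 0.025 over the reference
        window leave ~250 survivors, within 3 binomial SDs."""
        rng = np.random.default_rng(0)
        ch = sim.Challenge(survival_neutral=0.025, duration_h=22.0, reference_h=22.0)
        counts = np.array([10_000])
        sd = np.sqrt(10_000 * 0.025 * 0.975)
        for seed in range(10):
            out = sim.apply_challenge(counts, np.array([0.025]), ch, np.random.default_rng(seed))
            assert abs(out[0] - 250) <= 3 * sd

    def test_challenge_duration_compounds_hazard(self):
        ch = sim.Challenge(survival_neutral=0.025, duration_h=44.0, reference_h=22.0)
        counts = np.array([2_000_000])
        out = sim.apply_challenge(counts, np.array([0.025]), ch, np.random.default_rng(1))
        expect = 2_000_000 * 0.025 ** 2
        assert out[0] == pytest.approx(expect, rel=0.2)

    def test_replicates_differ_but_share_truth(self):
        lib = _two_insert_library(0.3)
        regime = sim.SelectionRegime(n_cells=5_000, days=5, challenge=None, seed=3)
        ab = sim.simulate_selection(lib, regime, n_replicates=4)
        d0 = ab[ab["group"] == GROUP_D0].pivot(index="insert_id", columns="replicate", values="cells")
        assert d0.shape[1] == 4
        assert d0.nunique(axis=1).max() > 1  # substreams differ

    def test_extinction_raises(self):
        lib = _two_insert_library(0.0)
        lib["fitness_survival"] = 0.0
        regime = sim.SelectionRegime(n_cells=100, days=2, seed=0)
        with pytest.raises(sim.ExtinctionError):
            sim.simulate_selection(lib, regime, n_replicates=1)


def _mini_genome_and_inserts():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    g = GenomeSequence({"c": seq})
    inserts = pd.DataFrame(
        [
            ("s1", "c", 100, 500, "DraI", "sense", 0.0, 0.025),
            ("a1", "c", 800, 1300, "DraI", "antisense", 0.0, 0.025),
        ],
        columns=sim.LIBRARY_COLUMNS,
    )
    ab = pd.DataFrame(
        {"insert_id": ["s1", "a1"], "group": GROUP_D0, "replicate": "A",
         "cells": [500, 500]}
    )
    return g, inserts, ab


class TestSimulateReads:
    def test_error_free_r1_is_flank_plus_insert_prefix(self, tmp_path):
        g, inserts, ab = _mini_genome_and_inserts()
        sim.simulate_reads(inserts, ab, g, reads_per_cell=0.05, seed=0,
                           fastq_dir=tmp_path)
        from funscreen.io_model import iter_fastq

        frag = g["c"][100:500]
        expect = (sim.FLANK_FWD + frag)[:300]
        reads = {rid: s for rid, s, _ in iter_fastq(tmp_path / "D0_A_R1.fastq")}
        truth = sim.simulate_reads(inserts, ab, g, reads_per_cell=0.05, seed=0)
        r1 = truth[(truth["mate"] == "R1")]
        sense_ids = r1[r1["strand"] == "+"]["read_id"]
        assert len(sense_ids) > 0
        for rid in sense_ids:
            assert reads[rid] == expect

    def test_antisense_truth_span_matches_fragment(self):
        g, inserts, ab = _mini_genome_and_inserts()
        truth = sim.simulate_reads(inserts, ab, g, reads_per_cell=0.05, seed=1)
        anti_r1 = truth[(truth["mate"] == "R1") & (truth["strand"] == "-")]
        assert len(anti_r1) > 0
        # 500 bp antisense insert, 240 genomic bases in R1 from the fragment end
        assert (anti_r1["end"] == 1300).all()
        assert (anti_r1["start"] == 1300 - 240).all()

    def test_directional_flag_only_on_r1(self):
        g, inserts, ab = _mini_genome_and_inserts()
        truth = sim.simulate_reads(inserts, ab, g, reads_per_cell=0.1, seed=2)
        assert truth[truth["mate"] == "R1"]["directional"].all()
        assert not truth[truth["mate"] == "R2"]["directional"].any()

    def test_substitution_error_rate_matches_binomial_oracle(self, tmp_path):
        g, inserts, ab = _mini_genome_and_inserts()
        ab = ab.assign(cells=[20_000, 0])
        rate = 0.005
        sim.simulate_reads(inserts, ab, g, error_rate=rate, reads_per_cell=0.1,
                           seed=3, fastq_dir=tmp_path)
        from funscreen.io_model import iter_fastq

        expect = (sim.FLANK_FWD + g["c"][100:500])[:300]
        n_mm = n_bases = 0
        for _, s, _ in iter_fastq(tmp_path / "D0_A_R1.fastq"):
            n_bases += len(s)
            n_mm += sum(a != b for a, b in zip(s, expect))
        sd = np.sqrt(n_bases * rate * (1 - rate))
        assert abs(n_mm - n_bases * rate) <= 3 * sd

    def test_short_insert_reads_truncated_not_error(self):
        g = GenomeSequence({"c": "ACGT" * 200})
        inserts = pd.DataFrame(
            [("t", "c", 10, 60, "DraI", "sense", 0.0, 0.025)],
            columns=sim.LIBRARY_COLUMNS,
        )
        ab = pd.DataFrame({"insert_id": ["t"], "group": GROUP_D0,
                           "replicate": "A", "cells": [100]})
        truth = sim.simulate_reads(inserts, ab, g, reads_per_cell=0.5, seed=0)
        assert (truth["end"] - truth["start"] == 50).all()  # clipped to insert

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        g, inserts, ab = _mini_genome_and_inserts()
        t1 = sim.simulate_reads(inserts, ab, g, error_rate=0.01, reads_per_cell=0.2,
                                seed=5, fastq_dir=tmp_path / "a")
        t2 = sim.simulate_reads(inserts, ab, g, error_rate=0.01, reads_per_cell=0.2,
                                seed=5, fastq_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(t1, t2)
        assert (tmp_path / "a" / "D0_A_R1.fastq").read_bytes() == (
            tmp_path / "b" / "D0_A_R1.fastq"
        ).read_bytes()


@settings(derandomize=True, max_examples=30)
@given(st.text(alphabet="ACGT", min_size=1, max_size=400))
def test_digest_reassembly_property(seq):
    """Ordered fragment concatenation reproduces any sequence exactly."""
    g = GenomeSequence({"c": seq})
    for enz in (sim.DRAI, sim.AANI):
        frags = sim.digest_genome(g, (enz,))[enz.name]
        assert sim.reassemble_digest(g, frags)["c"] == seq
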