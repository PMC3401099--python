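"""Pileup bookkeeping, the adaptive-error binomial test, FDR correction and
the pooled-then-per-run calling procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biss.align import AlignmentResult, MappedRead
from biss.caller import (
    SitePileup,
    adaptive_error,
    bh_adjust,
    binom_pvalue,
    call_methylome,
    call_pooled,
    classify_context,
    pileup,
    refine_by_runs,
)
from biss.kmer import ConversionMode

from conftest import bh_oracle, binom_upper_tail_oracle

CT = ConversionMode.CT
GA = ConversionMode.GA


def make_read(read_id, query, contig, ref_start, mode, run_id="run1"):
    """A gapless unique alignment covering the whole query."""
    aln = AlignmentResult(
        score=4 * len(query),
        ref_start=ref_start,
        ref_end=ref_start + len(query),
        read_start=0,
        read_end=len(query),
        columns="=" * len(query),
        mode=mode,
        identity=1.0,
        contig=contig,
        query=query,
    )
    return MappedRead(read_id, run_id, "unique", aln)


def make_site(contig="c", pos=0, strand="+", **run_counts):
    """SitePileup from run_id=(n_C, n_T, n_other) keyword arguments."""
    return SitePileup(contig, pos, strand, "CG", {k: list(v) for k, v in run_counts.items()})


class TestContext:
    genome = {"g": "ACGAATCAGC"}
    #          pos: 0123456789

    @pytest.mark.parametrize(
        "genome,pos,strand,expected",
        [
            ({"g": "ACGT"}, 1, "+", "CG"),
            ({"g": "ACAGT"}, 1, "+", "CHG"),
            ({"g": "ACATT"}, 1, "+", "CHH"),
            ({"g": "ACCCT"}, 1, "+", "CHH"),
            ({"g": "TTC"}, 2, "+", "NA"),  # runs off the contig
            ({"g": "TCNG"}, 1, "+", "NA"),
            ({"g": "CGT"}, 1, "-", "CG"),  # Crick: reads pos-1, pos-2
            ({"g": "TCTG"}, 3, "-", "CHG"),
            ({"g": "ATTG"}, 3, "-", "CHH"),
            ({"g": "GA"}, 0, "-", "NA"),
        ],
    )
    def test_contexts(self, genome, pos, strand, expected):
        assert classify_context(genome, "g", pos, strand) == expected

    def test_non_cytosine_errors(self):
        with pytest.raises(ValueError):
            classify_context({"g": "AAAA"}, "g", 0, "+")
        with pytest.raises(ValueError):
            classify_context({"g": "AAAA"}, "g", 0, "-")


class TestPileup:
    genome = {"g": "AACGTTGCAA"}
    #          pos: 0123456789  (C at 2, G at 3 and 6, C at 7)

    def test_ct_read_with_c_over_watson_c(self):
        reads = {"run1": [make_read("r", "AACGT", "g", 0, CT)]}
        piles = pileup(reads, self.genome)
        assert piles[("g", 2, "+")].counts() == (1, 0, 0)

    def test_ct_read_with_t_over_watson_c(self):
        reads = {"run1": [make_read("r", "AATGT", "g", 0, CT)]}
        assert pileup(reads, self.genome)[("g", 2, "+")].counts() == (0, 1, 0)

    def test_ct_read_other_base_over_watson_c(self):
        reads = {"run1": [make_read("r", "AAGGT", "g", 0, CT)]}
        assert pileup(reads, self.genome)[("g", 2, "+")].counts() == (0, 0, 1)

    def test_ga_read_with_a_over_forward_g_is_converted_evidence(self):
        # GA-mode query is already in forward orientation; A over the G at 6
        reads = {"run1": [make_read("r", "TTACA", "g", 4, GA)]}
        piles = pileup(reads, self.genome)
        assert piles[("g", 6, "-")].counts() == (0, 1, 0)

    def test_ga_read_with_g_over_forward_g_is_methylated_evidence(self):
        reads = {"run1": [make_read("r", "TTGCA", "g", 4, GA)]}
        assert pileup(reads, self.genome)[("g", 6, "-")].counts() == (1, 0, 0)

    def test_directionality_ct_reads_never_feed_crick_sites(self):
        reads = {"run1": [make_read("r", "AACGTTGCAA", "g", 0, CT)]}
        piles = pileup(reads, self.genome)
        assert ("g", 3, "-") not in piles
        assert ("g", 6, "-") not in piles
        # and the Watson sites got their evidence
        assert piles[("g", 2, "+")].counts() == (1, 0, 0)
        assert piles[("g", 7, "+")].counts() == (1, 0, 0)

    def test_per_run_counts_sum_to_pooled(self):
        reads = {
            "run1": [make_read("a", "AACGT", "g", 0, CT, "run1")],
            "run2": [make_read("b", "AATGT", "g", 0, CT, "run2")],
        }
        site = pileup(reads, self.genome)[("g", 2, "+")]
        assert site.counts("run1") == (1, 0, 0)
        assert site.counts("run2") == (0, 1, 0)
        assert site.counts() == (1, 1, 0)

    def test_non_unique_input_rejected(self):
        bad = MappedRead("r", "run1", "ambiguous")
        with pytest.raises(ValueError):
            pileup({"run1": [bad]}, self.genome)

    def test_unknown_contig_rejected(self):
        reads = {"run1": [make_read("r", "AACGT", "nope", 0, CT)]}
        with pytest.raises(KeyError):
            pileup(reads, self.genome)

    def test_gap_columns_contribute_nothing(self):
        aln = AlignmentResult(
            score=0, ref_start=0, ref_end=5, read_start=0, read_end=4,
            columns="==D==", mode=CT, identity=1.0, contig="g", query="AAGT",
        )
        piles = pileup({"run1": [MappedRead("r", "run1", "unique", aln)]}, self.genome)
        assert ("g", 2, "+") not in piles  # the C at 2 fell in the deletion


class TestAdaptiveError:
    def test_baseline_when_no_other_bases(self):
        em = adaptive_error(make_site(run1=(5, 5, 0)), p0=0.04)
        assert em.p_site == 0.04

    def test_local_mismatch_frequency_wins_when_larger(self):
        em = adaptive_error(make_site(run1=(2, 2, 1)), p0=0.04)
        assert em.p_site == pytest.approx(0.2)

    def test_capped_below_one(self):
        em = adaptive_error(make_site(run1=(0, 0, 7)), p0=0.04)
        assert 0 < em.p_site < 1

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            adaptive_error(make_site(run1=(0, 0, 0)))


class TestBinomPvalue:
    def test_whole_support(self):
        assert binom_pvalue(0, 7, 0.04) == 1.0

    def test_two_of_two(self):
        assert binom_pvalue(2, 2, 0.04) == pytest.approx(0.0016, abs=1e-12)

    def test_matches_enumeration(self):
        for n in range(1, 13):
            for m in range(n + 1):
                for p in (0.01, 0.04, 0.2):
                    assert binom_pvalue(m, n, p) == pytest.approx(
                        binom_upper_tail_oracle(m, n, p), abs=1e-12
                    )

    def test_monotone_in_m(self):
        values = [binom_pvalue(m, 10, 0.04) for m in range(11)]
        assert values == sorted(values, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_pvalue(3, 2, 0.04)
        with pytest.raises(ValueError):
            binom_pvalue(1, 2, 0.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_matches_step_up_oracle(self, pvalues):
        assert np.allclose(bh_adjust(pvalues), bh_oracle(pvalues), atol=1e-12)


class TestCallPooled:
    def test_below_coverage_is_x(self):
        calls = call_pooled({("c", 0, "+"): make_site(run1=(1, 0, 0))})
        assert calls.iloc[0]["status"] == "X"

    def test_strong_methylation_is_m(self):
        calls = call_pooled({("c", 0, "+"): make_site(run1=(20, 0, 0))})
        row = calls.iloc[0]
        assert row["status"] == "M"
        assert row["p_raw"] < 1e-20
        assert row["level"] == 1.0

    def test_fully_converted_is_u(self):
        calls = call_pooled({("c", 0, "+"): make_site(run1=(0, 20, 0))})
        row = calls.iloc[0]
        assert row["status"] == "U"
        assert row["p_raw"] == pytest.approx(1.0)

    def test_bh_runs_over_tested_set_only(self):
        # 40 null sites plus one borderline: its adjusted p must exceed raw
        piles = {("c", i, "+"): make_site(run1=(0, 10, 0)) for i in range(40)}
        piles[("c", 99, "+")] = make_site(run1=(2, 8, 0))
        calls = call_pooled(piles)
        row = calls[calls["pos"] == 99].iloc[0]
        assert row["p_adj"] > row["p_raw"]

    def test_adding_c_read_never_flips_m_to_u(self):
        piles1 = {("c", 0, "+"): make_site(run1=(5, 5, 0))}
        piles2 = {("c", 0, "+"): make_site(run1=(6, 5, 0))}
        s1 = call_pooled(piles1).iloc[0]["status"]
        s2 = call_pooled(piles2).iloc[0]["status"]
        assert not (s1 == "M" and s2 == "U")

    def test_conservative_echo_high_level_high_coverage_always_m(self):
        """Sites with level >= 0.5 at n >= 10 and baseline error are always
        significant in the pooled test."""
        piles = {
            ("c", i, "+"): make_site(run1=(m, n - m, 0))
            for i, (m, n) in enumerate(
                (m, n) for n in range(10, 26) for m in range(n + 1) if m / n >= 0.5
            )
        }
        calls = call_pooled(piles)
        assert (calls["status"] == "M").all()


class TestRefineByRuns:
    def _prelim_m(self, site_key):
        return pd.DataFrame(
            [
                {
                    "contig": site_key[0], "pos": site_key[1], "strand": site_key[2],
                    "context": "CG", "n_C": 0, "n_T": 0, "n_other": 0, "n": 0,
                    "level": 1.0, "p_raw": 0.0, "p_adj": 0.0, "p_site": 0.04,
                    "status": "M",
                }
            ]
        )

    def test_majority_upholds(self):
        key = ("c", 0, "+")
        piles = {key: make_site(run1=(8, 0, 0), run2=(8, 0, 0), run3=(0, 8, 0))}
        out = refine_by_runs(self._prelim_m(key), piles)
        assert out.iloc[0]["status"] == "M"
        assert out.iloc[0]["runs_testable"] == 3
        assert out.iloc[0]["runs_voting_M"] == 2

    def test_tie_demotes(self):
        key = ("c", 0, "+")
        piles = {key: make_site(run1=(8, 0, 0), run2=(0, 8, 0))}
        out = refine_by_runs(self._prelim_m(key), piles)
        assert out.iloc[0]["status"] == "U"

    def test_no_testable_run_keeps_pooled_decision(self):
        key = ("c", 0, "+")
        piles = {key: make_site(run1=(1, 0, 0), run2=(1, 0, 0))}
        out = refine_by_runs(self._prelim_m(key), piles)
        assert out.iloc[0]["status"] == "M"
        assert out.iloc[0]["runs_testable"] == 0

    def test_u_sites_pass_through(self):
        key = ("c", 0, "+")
        prelim = self._prelim_m(key)
        prelim.loc[0, "status"] = "U"
        piles = {key: make_site(run1=(8, 0, 0))}
        assert refine_by_runs(prelim, piles).iloc[0]["status"] == "U"


class TestCallMethylome:
    def test_no_reads_all_x_and_partition(self):
        genome = {"g": "ACGTTGCCAG"}
        calls = call_methylome({"run1": []}, genome)
        n_cytosines = genome["g"].count("C") + genome["g"].count("G")
        assert len(calls) == n_cytosines
        assert (calls["status"] == "X").all()

    def test_every_cytosine_called_exactly_once(self):
        genome = {"g": "AACGTTGCAA"}
        reads = {"run1": [make_read("r", "AACGT", "g", 0, CT)]}
        calls = call_methylome(reads, genome)
        n_cytosines = genome["g"].count("C") + genome["g"].count("G")
        assert len(calls) == n_cytosines
        assert calls["status"].isin(["M", "U", "X"]).all()
        assert not calls.duplicated(["contig", "pos", "strand"]).any()
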