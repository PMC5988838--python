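import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sangerhts import (
    CommunityProfile,
    assign_to_otu,
    categorize_sample,
    concordance_table,
    greedy_cluster,
    pairwise_identity,
    resolution_comparison,
)
from sangerhts.assignment_concordance import (
    AssignmentResult,
    CategoryRecord,
    align_global,
)
from sangerhts.sanger import CalledSequence

# ---------------------------------------------------------------------------
# Independent brute-force alignment oracle: enumerate every global alignment
# as a sequence of diagonal/up/left moves and score it directly. A gap run of
# length L costs 2 + (L - 1), matching the production scoring scheme but
# sharing no code with it.

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "M": "AC", "R": "AG", "W": "AT",
    "S": "CG", "Y": "CT", "K": "GT", "V": "ACG", "H": "ACT", "D": "AGT",
    "B": "CGT", "N": "ACGT",
}


def brute_force_alignments(a, b):
    """Yields (score, matched, columns) over ALL global alignments of a and b."""
    results = []

    def rec(i, j, score, matched, columns, last):
        if i == len(a) and j == len(b):
            results.append((score, matched, columns))
            return
        if i < len(a) and j < len(b):
            hit = b[j] in _IUPAC[a[i]]
            rec(i + 1, j + 1, score + (1 if hit else -1),
                matched + (1 if hit else 0), columns + 1, "D")
        if i < len(a):  # query base against a gap ("up")
            cost = 1 if last == "Y" else 2
            rec(i + 1, j, score - cost, matched, columns + 1, "Y")
        if j < len(b):  # subject base against a gap ("left")
            cost = 1 if last == "X" else 2
            rec(i, j + 1, score - cost, matched, columns + 1, "X")

    rec(0, 0, 0, 0, 0, None)
    return results


def brute_force_best(a, b):
    """(max score, {(matched, columns) of score-optimal alignments})."""
    results = brute_force_alignments(a, b)
    best = max(s for s, _, _ in results)
    return best, {(m, c) for s, m, c in results if s == best}


class TestAlignmentOracle:
    def test_exhaustive_small_enumeration(self):
        # every pair of sequences of length 1-2 over {A, C, G}
        seqs = [
            "".join(t)
            for n in (1, 2)
            for t in itertools.product("ACG", repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                score, matched, columns = align_global(a, b)
                oracle_score, optimal = brute_force_best(a, b)
                assert score == oracle_score, (a, b)
                assert (matched, columns) in optimal, (a, b)

    def test_random_pairs_up_to_length_8(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            la, lb = rng.integers(3, 9, size=2)
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            score, matched, columns = align_global(a, b)
            oracle_score, optimal = brute_force_best(a, b)
            assert score == oracle_score, (a, b)
            assert (matched, columns) in optimal, (a, b)

    def test_iupac_queries_against_oracle(self):
        rng = np.random.default_rng(7)
        codes = list("ACGTMRWSYKN")
        for _ in range(25):
            la, lb = rng.integers(2, 7, size=2)
            a = "".join(rng.choice(codes, size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            score, matched, columns = align_global(a, b)
            oracle_score, optimal = brute_force_best(a, b)
            assert score == oracle_score, (a, b)
            assert (matched, columns) in optimal, (a, b)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 150
        identity, length = pairwise_identity(seq, seq)
        assert identity == 100.0 and length == 600

    def test_six_substitutions_in_600(self):
        a = "ACGT" * 150
        b = list(a)
        for pos in (10, 110, 210, 310, 410, 510):
            b[pos] = "C" if a[pos] != "C" else "G"
        identity, length = pairwise_identity(a, "".join(b))
        assert identity == pytest.approx(99.0)  # 594/600
        assert length == 600

    def test_iupac_code_counts_as_match(self):
        identity, _ = pairwise_identity("AMGT", "ACGT")  # M covers C
        assert identity == 100.0

    def test_gap_columns_in_denominator(self):
        # ACGT vs AGT: one deletion column -> 3 matches over 4 columns
        identity, length = pairwise_identity("ACGT", "AGT")
        assert length == 4
        assert identity == pytest.approx(75.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")
        with pytest.raises(ValueError):
            pairwise_identity("ACGT", "")

    def test_ambiguous_subject_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            pairwise_identity("ACGT", "ACGN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_self_identity_is_always_100(self, seq):
        identity, length = pairwise_identity(seq, seq)
        assert identity == 100.0 and length == len(seq)


class TestAssignToOtu:
    def _passing(self, seq, marker="ITS2_only"):
        return CalledSequence("s1", marker, seq, qc_status="pass")

    def test_exact_its2_query_assigned(self, panel):
        query = self._passing(panel[2].region("ITS2"))
        result = assign_to_otu(query, panel)
        assert result.status == "assigned"
        assert result.best_otu == "OTU3"
        assert result.best_identity == 100.0

    def test_full_its_query_assigned(self, panel):
        query = self._passing(panel[4].sequence, marker="full_ITS")
        result = assign_to_otu(query, panel)
        assert result.status == "assigned" and result.best_otu == "OTU5"

    def test_tie_at_top_excluded(self, panel):
        import dataclasses

        twin = dataclasses.replace(panel[0], otu_id="OTUdup")
        query = self._passing(panel[0].region("ITS2"))
        result = assign_to_otu(query, panel + [twin])
        assert result.status == "tie_at_top"
        assert result.best_otu is None

    def test_below_accept_not_assigned(self, panel):
        # mutate ~1.7% of the ITS2 region: best hit lands in [95, 99)
        region = list(panel[0].region("ITS2"))
        rng = np.random.default_rng(3)
        for pos in rng.choice(len(region), size=3, replace=False):
            region[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[region[pos]]
        result = assign_to_otu(self._passing("".join(region)), panel)
        assert result.status == "no_clear_best"
        assert result.best_otu is None
        assert 95.0 <= result.best_identity < 99.0

    def test_below_floor(self, panel):
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("ACGT"), size=180))
        result = assign_to_otu(self._passing(junk), panel)
        assert result.status == "below_floor"

    def test_qc_failed_short_circuits(self, panel):
        called = CalledSequence("s1", "ITS2_only", "ACGT", qc_status="fail",
                                fail_reason="ambiguous_calls")
        result = assign_to_otu(called, panel)
        assert result.status == "qc_failed"
        assert result.best_identity is None

    def test_second_best_never_exceeds_best(self, panel):
        result = assign_to_otu(self._passing(panel[1].region("ITS2")), panel)
        assert result.second_best_identity <= result.best_identity

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            assign_to_otu(self._passing("ACGT"), [])


class TestCategorizeSample:
    def test_single_photobiont_is_category_1(self):
        rec = categorize_sample({"OTU1": 1.0, "OTU2": 0.0}, "s")
        assert rec.category == 1 and rec.secondary_fraction == 0.0
        assert rec.dominant_otu == "OTU1"

    def test_35_percent_secondary_is_category_5(self):
        assert categorize_sample({"A": 0.65, "B": 0.35}, "s").category == 5

    def test_boundary_10_percent_in_category_2(self):
        assert categorize_sample({"A": 0.90, "B": 0.10}, "s").category == 2

    @pytest.mark.parametrize("f,expected", [
        (0.05, 2), (0.15, 3), (0.20, 3), (0.25, 4), (0.30, 4), (0.31, 5)])
    def test_bin_edges(self, f, expected):
        assert categorize_sample({"A": 1 - f, "B": f}, "s").category == expected

    def test_dominant_tie_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            categorize_sample({"A": 0.5, "B": 0.5}, "s")

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            categorize_sample({"A": 0.6, "B": 0.2}, "s")

    @given(f=st.floats(0.0, 0.499, exclude_max=True))
    @settings(max_examples=100, deadline=None)
    def test_every_fraction_gets_exactly_one_category(self, f):
        rec = categorize_sample({"A": 1 - f, "B": f}, "s")
        assert rec.category in (1, 2, 3, 4, 5)
        assert (rec.category == 1) == (f == 0.0)
        assert (rec.category == 5) == (f * 100 > 30)


def _qc_records(marker, n_pass, n_total):
    out = []
    for i in range(n_total):
        status = "pass" if i < n_pass else "fail"
        reason = None if status == "pass" else "ambiguous_calls"
        bases = "ACGT" if status == "pass" else "MMMM"
        amb = () if status == "pass" else (0, 1, 2, 3)
        out.append(CalledSequence(f"S{i}", marker, bases, ambiguous_positions=amb,
                                  qc_status=status, fail_reason=reason))
    return out


def _assignments_for(qc_records, dominant="OTU1"):
    out = []
    for rec in qc_records:
        if rec.qc_status == "pass":
            out.append(AssignmentResult(rec.sample_id, rec.marker, dominant, 100.0,
                                        97.0, "assigned"))
        else:
            out.append(AssignmentResult(rec.sample_id, rec.marker, None, None, None,
                                        "qc_failed"))
    return out


def _categories(n_total, category=1, dominant="OTU1"):
    secondary = {1: 0.0, 2: 5.0, 3: 15.0, 4: 25.0, 5: 40.0}[category]
    return [CategoryRecord(f"S{i}", category, secondary, dominant) for i in range(n_total)]


class TestConcordanceTable:
    def test_success_rate_183_of_240(self):
        qc = _qc_records("full_ITS", 183, 240)
        summary = concordance_table(_assignments_for(qc), _categories(240), qc)
        assert summary.success_rate("full_ITS") == pytest.approx(76.25)

    def test_success_rate_198_of_240(self):
        qc = _qc_records("ITS2_only", 198, 240)
        summary = concordance_table(_assignments_for(qc), _categories(240), qc)
        assert summary.success_rate("ITS2_only") == pytest.approx(82.5)

    def test_category_pass_percentage_54_of_61(self):
        qc = _qc_records("ITS2_only", 54, 61)
        summary = concordance_table(_assignments_for(qc), _categories(61), qc)
        assert summary.category_pass_percent("ITS2_only", 1) == pytest.approx(88.52, abs=0.005)

    def test_all_failing_category_has_zero_pass(self):
        qc = _qc_records("ITS2_only", 0, 16)
        summary = concordance_table(_assignments_for(qc), _categories(16, category=5), qc)
        assert summary.category_pass_percent("ITS2_only", 5) == 0.0
        row = summary.per_category.loc[("ITS2_only", 5)]
        assert row["n_fail"] == 16 and row["n_pass"] == 0

    def test_category_counts_partition_samples(self):
        qc = _qc_records("full_ITS", 7, 10)
        summary = concordance_table(_assignments_for(qc), _categories(10, category=2), qc)
        row = summary.per_category.loc[("full_ITS", 2)]
        assert row["n_pass"] + row["n_fail"] == 10

    def test_concordant_fraction(self):
        qc = _qc_records("full_ITS", 5, 5)
        asg = _assignments_for(qc, dominant="OTU2")
        cats = _categories(5, dominant="OTU2")
        summary = concordance_table(asg, cats, qc)
        assert summary.concordant_fraction["full_ITS"] == 1.0

    def test_unmatched_samples_reported_not_dropped_silently(self):
        qc = _qc_records("full_ITS", 3, 3)
        cats = _categories(2)  # S2 has no category record
        summary = concordance_table(_assignments_for(qc), cats, qc)
        assert summary.unmatched_samples == ["S2"]
        assert summary.per_marker.loc["full_ITS", "n_total"] == 2

    def test_long_table_is_plot_ready(self):
        qc = _qc_records("full_ITS", 2, 4)
        summary = concordance_table(_assignments_for(qc), _categories(4, category=3), qc)
        lt = summary.long_table
        assert set(lt.columns) == {"marker", "category", "outcome", "count", "proportion"}
        assert lt["count"].sum() == 4


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        clusters = greedy_cluster(["ACGTACGT"] * 4)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_indices) == [0, 1, 2, 3]

    def test_diverged_pair_splits_at_99(self):
        a = "ACGT" * 25
        b = a[:10] + "T" + a[11:50] + "A" + a[51:]  # 2 mismatches -> 98%
        identity, _ = pairwise_identity(a, b)
        assert identity < 99.0  # oracle for the threshold
        clusters = greedy_cluster([a, b], identity_threshold=99.0)
        assert len(clusters) == 2

    def test_duplicate_member_does_not_change_centroids(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        base = greedy_cluster(seqs)
        dup = greedy_cluster(seqs + [seqs[2]])
        assert [c.centroid for c in base] == [c.centroid for c in dup]

    def test_abundance_order_controls_centroid_choice(self):
        a = "ACGT" * 25
        b = a[:10] + "T" + a[11:]  # 99% identical to a
        clusters = greedy_cluster([a, b], abundances=[1, 5])
        assert clusters[0].centroid == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([])


class TestResolutionComparison:
    def _assigned(self, sample, marker, otu):
        return AssignmentResult(sample, marker, otu, 100.0, 97.0, "assigned")

    def test_three_way_match(self):
        its1 = [self._assigned("S1", "ITS1_only", "OTU1")]
        its2 = [self._assigned("S1", "ITS2_only", "OTU1")]
        summary = resolution_comparison(its1, its2, {"S1": "OTU1"})
        assert summary.match_fraction == 1.0 and summary.n_complete == 1

    def test_mismatch_counted(self):
        its1 = [self._assigned("S1", "ITS1_only", "OTU1")]
        its2 = [self._assigned("S1", "ITS2_only", "OTU2")]
        summary = resolution_comparison(its1, its2, {"S1": "OTU1"})
        assert summary.match_fraction == 0.0

    def test_single_marker_sample_incomplete(self):
        its2 = [self._assigned("S1", "ITS2_only", "OTU1")]
        summary = resolution_comparison([], its2, {"S1": "OTU1"})
        assert summary.n_incomplete == 1 and summary.n_complete == 0
        assert summary.match_fraction is None

    def test_empty_overlap_is_undefined_not_zero(self):
        summary = resolution_comparison([], [], {})
        assert summary.match_fraction is None
        assert len(summary.table) == 0
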