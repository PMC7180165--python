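"""Pairwise distances, species summaries, NN analysis and clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxgap import (
    AlignmentError,
    AnalysisError,
    BarcodeAlignment,
    InputError,
    NoOverlapError,
    PairwiseSiteCounts,
    SequenceRecord,
    count_site_patterns,
    distance_matrix,
    intraspecific_summary,
    k2p_distance,
    nearest_neighbor_analysis,
    nn_overall_summary,
    p_distance,
    threshold_cluster,
)
from conftest import (
    naive_counts,
    naive_k2p,
    naive_single_linkage,
    naive_species_summaries,
    related_alignment,
)


def _aln(seqs: dict[str, str], species: dict[str, str]) -> BarcodeAlignment:
    return BarcodeAlignment(
        [SequenceRecord(s, species[s], q) for s, q in seqs.items()]
    )


class TestSitePatternCounts:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", (4, 0, 0)),  # identity
            ("ACGT", "GCGA", (4, 1, 1)),  # A<->G transition, T<->A transversion
            ("AC-TN", "ACGTA", (3, 0, 0)),  # gap and N pairwise-deleted
            ("AAAA", "GGGG", (4, 4, 0)),
            ("ACGT", "acgt", (4, 0, 0)),  # case-insensitive
            ("RYSW", "ACGT", (0, 0, 0)),  # IUPAC ambiguity = missing
        ],
    )
    def test_examples(self, a, b, expected):
        c = count_site_patterns(a, b)
        assert (c.n, c.ts, c.tv) == expected

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            count_site_patterns("ACGT", "ACG")

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_matches_naive_counter(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        a = "".join(rng.choice(list("ACGTN-RY"), size=n))
        b = "".join(rng.choice(list("ACGTN-RY"), size=n))
        c = count_site_patterns(a, b)
        assert (c.n, c.ts, c.tv) == naive_counts(a, b)


class TestDistances:
    def test_zero_distance(self):
        assert k2p_distance(PairwiseSiteCounts(4, 0, 0)) == 0.0
        assert p_distance(PairwiseSiteCounts(658, 0, 0)) == 0.0

    def test_k2p_closed_form_value(self):
        # P = 1/4, Q = 0  ->  -1/2 ln(1/2)
        d = k2p_distance(PairwiseSiteCounts(4, 1, 0))
        assert d == pytest.approx(0.5 * math.log(2.0), abs=1e-12)

    def test_k2p_undefined_at_saturation(self):
        # P = 1/2, Q = 1/4: the first log argument hits zero
        assert k2p_distance(PairwiseSiteCounts(4, 2, 1)) is None

    def test_no_overlap_is_an_error_not_undefined(self):
        with pytest.raises(NoOverlapError):
            k2p_distance(PairwiseSiteCounts(0, 0, 0))
        with pytest.raises(NoOverlapError):
            p_distance(PairwiseSiteCounts(0, 0, 0))

    def test_p_distance_arithmetic(self):
        assert p_distance(PairwiseSiteCounts(4, 1, 1)) == 0.5

    @given(
        st.integers(1, 500),
        st.integers(0, 500),
        st.integers(0, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_correction_never_shrinks(self, n, ts, tv):
        """K2P >= p-distance wherever K2P is defined; equal only at 0."""
        if ts + tv > n:
            return
        c = PairwiseSiteCounts(n, ts, tv)
        d = k2p_distance(c)
        if d is None:
            return
        p = p_distance(c)
        assert d >= p - 1e-15
        assert (d == 0.0) == (p == 0.0)

    def test_monotone_in_transitions(self):
        prev = -1.0
        for ts in range(0, 40):  # P < 0.5 keeps the estimator defined
            d = k2p_distance(PairwiseSiteCounts(100, ts, 5))
            assert d > prev
            prev = d


class TestDistanceMatrix:
    def test_identical_pair(self):
        aln = _aln({"a": "ACGT", "b": "ACGT"}, {"a": "x", "b": "x"})
        dm = distance_matrix(aln)
        assert np.array_equal(dm.values, np.zeros((2, 2)))
        assert dm.defined.all()

    def test_symmetry_and_per_pair_agreement(self):
        rng = np.random.default_rng(3)
        seqs, species = related_alignment(rng, 6)
        dm = distance_matrix(_aln(seqs, species))
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)
        assert np.array_equal(dm.defined, dm.defined.T)
        assert np.all(np.diag(dm.values) == 0)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j and dm.defined[i, j]:
                    assert dm.values[i, j] == pytest.approx(
                        naive_k2p(seqs[a], seqs[b]), abs=1e-12
                    )

    def test_zero_overlap_flagged_not_crash(self):
        aln = _aln({"a": "NNNN", "b": "ACGT"}, {"a": "x", "b": "y"})
        dm = distance_matrix(aln)
        assert not dm.defined[0, 1]
        assert math.isnan(dm.values[0, 1])

    def test_simulated_gap(self, two_species_sim):
        """With d_inter >> d_intra every within-species distance sits far
        below every between-species distance."""
        _, aln, smap = two_species_sim
        dm = distance_matrix(aln)
        sp = [smap[s] for s in dm.ids]
        intra = [
            dm.values[i, j]
            for i in range(len(sp))
            for j in range(i + 1, len(sp))
            if sp[i] == sp[j]
        ]
        inter = [
            dm.values[i, j]
            for i in range(len(sp))
            for j in range(i + 1, len(sp))
            if sp[i] != sp[j]
        ]
        assert max(intra) < min(inter)


class TestSummaries:
    def test_singleton_species_not_available(self):
        aln = _aln(
            {"a": "ACGT", "b": "ACGT", "c": "AGGT"},
            {"a": "x", "b": "x", "c": "y"},
        )
        dm = distance_matrix(aln)
        rows = {r.species: r for r in intraspecific_summary(dm, {"a": "x", "b": "x", "c": "y"})}
        assert rows["y"].n == 1
        assert rows["y"].mean_intra is None and rows["y"].max_intra is None
        assert rows["x"].mean_intra == 0.0 and rows["x"].max_intra == 0.0

    def test_unmapped_sample_listed(self):
        aln = _aln({"a": "ACGT", "b": "AGGT"}, {"a": "x", "b": "y"})
        dm = distance_matrix(aln)
        with pytest.raises(InputError, match="b"):
            intraspecific_summary(dm, {"a": "x"})

    def test_single_species_nn_rejected(self):
        aln = _aln({"a": "ACGT", "b": "AGGT"}, {"a": "x", "b": "x"})
        dm = distance_matrix(aln)
        with pytest.raises(AnalysisError):
            nearest_neighbor_analysis(dm, {"a": "x", "b": "x"})

    def test_two_species_nn_symmetric(self):
        aln = _aln(
            {"a": "AAAAAAAA", "b": "AAAAAAAA", "c": "AAAAAAGG", "d": "AAAAAAGG"},
            {"a": "x", "b": "x", "c": "y", "d": "y"},
        )
        dm = distance_matrix(aln)
        nn = {r.species: r for r in nearest_neighbor_analysis(dm, {"a": "x", "b": "x", "c": "y", "d": "y"})}
        assert nn["x"].nn_species == "y" and nn["y"].nn_species == "x"
        assert nn["x"].nn_distance == pytest.approx(nn["y"].nn_distance)

    def test_brute_force_oracle_agreement(self):
        """Mean/max intraspecific and NN minima match exhaustive
        enumeration over all pairs on random small instances."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            seqs, species = related_alignment(rng, n)
            dm = distance_matrix(_aln(seqs, species))
            _, intra_oracle, nn_oracle = naive_species_summaries(seqs, species)
            for row in intraspecific_summary(dm, species):
                n_o, mean_o, max_o = intra_oracle[row.species]
                assert row.n == n_o
                if mean_o is None:
                    assert row.mean_intra is None
                else:
                    assert row.mean_intra == pytest.approx(mean_o, abs=1e-12)
                    assert row.max_intra == pytest.approx(max_o, abs=1e-12)
            for row in nearest_neighbor_analysis(dm, species):
                sp_o, d_o = nn_oracle[row.species]
                if d_o is None:
                    assert row.nn_distance is None
                else:
                    assert row.nn_distance == pytest.approx(d_o, abs=1e-12)


class TestNNOverallSummary:
    def test_published_column(self):
        """The seven per-species NN distances of the worked example."""
        s = nn_overall_summary([5.25, 3.24, 3.14, 3.14, 3.46, 3.82, 3.46])
        assert s.min == 3.14
        assert s.max == 5.25
        assert s.mean == pytest.approx(25.51 / 7, abs=1e-12)
        assert s.se > 0

    def test_constant_values(self):
        s = nn_overall_summary([0.3, 0.3, 0.3])
        assert s.min == s.mean == s.max == 0.3
        assert s.se == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            nn_overall_summary([])


class TestThresholdCluster:
    def test_threshold_above_max_single_cluster(self, two_species_sim):
        _, aln, _ = two_species_sim
        dm = distance_matrix(aln)
        assert len(set(threshold_cluster(dm, 1.0).values())) == 1

    def test_threshold_zero_all_singletons(self, two_species_sim):
        _, aln, _ = two_species_sim
        dm = distance_matrix(aln)
        clusters = threshold_cluster(dm, 0.0)
        assert len(set(clusters.values())) == len(dm.ids)

    def test_gap_recovers_species(self, two_species_sim):
        """A 2% threshold between the intra (~0.4%) and inter (~4.4%)
        levels yields exactly one cluster per species."""
        _, aln, smap = two_species_sim
        dm = distance_matrix(aln)
        clusters = threshold_cluster(dm, 0.02)
        partition = {}
        for s, c in clusters.items():
            partition.setdefault(c, set()).add(smap[s])
        assert len(partition) == 2
        assert all(len(v) == 1 for v in partition.values())

    def test_undefined_distances_guarded(self):
        aln = _aln({"a": "NNNN", "b": "ACGT", "c": "ACGT"}, dict.fromkeys("abc", "x"))
        dm = distance_matrix(aln)
        with pytest.raises(AnalysisError):
            threshold_cluster(dm, 0.02)
        clusters = threshold_cluster(dm, 0.02, ignore_undefined=True)
        assert clusters["b"] == clusters["c"] != clusters["a"]

    def test_matches_networkx_components(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            seqs, species = related_alignment(rng, int(rng.integers(3, 11)))
            dm = distance_matrix(_aln(seqs, species))
            dist, _, _ = naive_species_summaries(seqs, species)
            thr = float(rng.uniform(0.0, 0.2))
            ours = {}
            for s, c in threshold_cluster(dm, thr, ignore_undefined=True).items():
                ours.setdefault(c, set()).add(s)
            assert {frozenset(v) for v in ours.values()} == naive_single_linkage(
                list(seqs), dist, thr
            )
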