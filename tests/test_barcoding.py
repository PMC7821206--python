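"""K2P distances, gap statistics, net divergence, bootstrap, clustering."""

import math

import numpy as np
import pytest

from gouania.barcoding import (
    Alignment,
    DistanceMatrix,
    SequenceRecord,
    barcoding_gap,
    bootstrap_se,
    cluster_lineages,
    k2p_distance,
    net_between_group,
    pairwise_k2p,
)


def _toy_pair(length, ts, tv):
    """Two sequences differing by exactly `ts` transitions and `tv`
    transversions over `length` valid sites."""
    s1 = "A" * length
    s2 = "G" * ts + "C" * tv + "A" * (length - ts - tv)
    return s1, s2


def _k2p_formula(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2PDistance:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_derived_value(self):
        s1, s2 = _toy_pair(100, 10, 5)
        assert k2p_distance(s1, s2) == pytest.approx(_k2p_formula(0.10, 0.05), abs=1e-12)

    def test_saturation_is_flagged_not_raised(self):
        s1, s2 = _toy_pair(100, 50, 0)  # P = 0.5, Q = 0: 1-2P-Q = 0
        assert math.isnan(k2p_distance(s1, s2))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    def test_pairwise_deletion_ignores_gaps_and_ambiguity(self):
        # same differences, but 10 masked sites must not dilute P and Q
        s1 = "A" * 20 + "N" * 5 + "-" * 5
        s2 = "G" * 2 + "C" * 1 + "A" * 17 + "A" * 10
        expected = _k2p_formula(2 / 20, 1 / 20)
        assert k2p_distance(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_zero_valid_sites_undefined(self):
        assert math.isnan(k2p_distance("NNNN", "ACGT"))


class TestPairwiseK2P:
    def test_identical_records_zero_matrix(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGT" * 5) for i in range(3)])
        m = pairwise_k2p(aln)
        assert np.allclose(m.values, 0.0)

    def test_matches_per_pair_formula_on_toy_alignment(self):
        seqs = ["AAAAAAAAAAAAAAAAAAAA",
                "GGAAAAAAAAAAAAAAAAAA",
                "CCCAAAAAAAAAAAAAAAAA",
                "GACAAAAAAAAAAAAAAAAA"]
        aln = Alignment([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])
        m = pairwise_k2p(aln)
        for i in range(4):
            for j in range(4):
                d = k2p_distance(seqs[i], seqs[j])
                assert m.values[i, j] == pytest.approx(d, abs=1e-15)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            pairwise_k2p(Alignment([SequenceRecord("s", "ACGT")]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment([SequenceRecord("s", "ACGT"), SequenceRecord("s", "ACGT")])


def _matrix_two_species(within=0.01, between=0.10):
    ids = ["a1", "a2", "b1", "b2"]
    v = np.full((4, 4), between)
    v[0, 1] = v[1, 0] = within
    v[2, 3] = v[3, 2] = within
    np.fill_diagonal(v, 0.0)
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return DistanceMatrix(ids, v), labels


class TestBarcodingGap:
    def test_two_species_gap_in_percent(self):
        m, labels = _matrix_two_species()
        gap = barcoding_gap(m, labels)
        assert np.allclose(gap["max_intra_pct"], 1.0)
        assert np.allclose(gap["min_inter_pct"], 10.0)
        assert np.allclose(gap["gap_pct"], 9.0)

    def test_singleton_species_max_intra_zero(self):
        ids = ["a1", "a2", "b1"]
        v = np.array([[0, 0.01, 0.1], [0.01, 0, 0.1], [0.1, 0.1, 0]])
        gap = barcoding_gap(DistanceMatrix(ids, v), {"a1": "A", "a2": "A", "b1": "B"})
        assert gap.loc["b1", "max_intra_pct"] == 0.0

    def test_all_singletons(self):
        ids = ["a", "b", "c"]
        v = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        gap = barcoding_gap(DistanceMatrix(ids, v), {"a": "A", "b": "B", "c": "C"})
        assert (gap["max_intra_pct"] == 0.0).all()
        assert gap.loc["a", "min_inter_pct"] == pytest.approx(20.0)

    def test_single_species_rejected(self):
        ids = ["a1", "a2"]
        v = np.array([[0.0, 0.01], [0.01, 0.0]])
        with pytest.raises(ValueError):
            barcoding_gap(DistanceMatrix(ids, v), {"a1": "A", "a2": "A"})


class TestNetBetweenGroup:
    def test_arithmetic_oracle(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.10)
        v[0, 1] = v[1, 0] = 0.02
        v[2, 3] = v[3, 2] = 0.02
        np.fill_diagonal(v, 0.0)
        res = net_between_group(
            DistanceMatrix(ids, v), {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ("A", "B")
        )
        assert res.net == pytest.approx(0.08, abs=1e-15)
        assert res.d_between == pytest.approx(0.10)

    def test_zero_within_diversity_gives_net_equal_between(self):
        m, labels = _matrix_two_species(within=0.0, between=0.07)
        res = net_between_group(m, labels, ("A", "B"))
        assert res.net == pytest.approx(res.d_between)

    def test_degenerate_pair_rejected(self):
        m, labels = _matrix_two_species()
        with pytest.raises(ValueError):
            net_between_group(m, labels, ("A", "A"))
        with pytest.raises(KeyError):
            net_between_group(m, labels, ("A", "C"))

    def test_singleton_within_flagged_as_zero(self):
        ids = ["a1", "b1", "b2"]
        v = np.array([[0, 0.1, 0.1], [0.1, 0, 0.02], [0.1, 0.02, 0]])
        res = net_between_group(
            DistanceMatrix(ids, v), {"a1": "A", "b1": "B", "b2": "B"}, ("A", "B")
        )
        assert res.d_within_1 == 0.0
        assert "singleton:A" in res.flags
        assert res.net == pytest.approx(0.1 - 0.01)

    def test_invariant_to_relabelling_within_species(self):
        rng = np.random.default_rng(7)
        n = 6
        v = rng.uniform(0.01, 0.2, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        ids = [f"s{i}" for i in range(n)]
        labels = {f"s{i}": ("X" if i < 3 else "Y") for i in range(n)}
        base = net_between_group(DistanceMatrix(ids, v), labels, ("X", "Y")).net
        perm = [2, 0, 1, 5, 3, 4]  # permute within each species block
        v2 = v[np.ix_(perm, perm)]
        ids2 = [ids[p] for p in perm]
        swapped = net_between_group(DistanceMatrix(ids2, v2), labels, ("X", "Y")).net
        assert swapped == pytest.approx(base, abs=1e-15)


def _two_group_alignment(rng=None, L=200, diverged=True):
    rng = rng or np.random.default_rng(0)
    base = "".join(rng.choice(list("ACGT"), L))
    seqs = {"x1": base, "x2": base}
    if diverged:
        mutated = list(base)
        for pos in rng.choice(L, size=L // 10, replace=False):
            mutated[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[pos]]
        seqs["y1"] = "".join(mutated)
        seqs["y2"] = "".join(mutated)
    else:
        seqs["y1"] = base
        seqs["y2"] = base
    records = [SequenceRecord(k, s, "X" if k.startswith("x") else "Y")
               for k, s in seqs.items()]
    return Alignment(records), {r.id: r.species for r in records}


class TestBootstrapSE:
    def test_zero_variable_sites_gives_zero_se(self):
        aln, labels = _two_group_alignment(diverged=False)
        se = bootstrap_se(aln, labels, ("X", "Y"), replicates=50, seed=1)
        assert se == 0.0

    def test_deterministic_under_seed(self):
        aln, labels = _two_group_alignment()
        se1 = bootstrap_se(aln, labels, ("X", "Y"), replicates=100, seed=11)
        se2 = bootstrap_se(aln, labels, ("X", "Y"), replicates=100, seed=11)
        assert se1 == se2
        assert se1 > 0

    def test_too_few_replicates_rejected(self):
        aln, labels = _two_group_alignment()
        with pytest.raises(ValueError):
            bootstrap_se(aln, labels, ("X", "Y"), replicates=1, seed=0)


class TestClusterLineages:
    def _matrix(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.10)
        v[0, 1] = v[1, 0] = 0.01
        v[2, 3] = v[3, 2] = 0.01
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(ids, v)

    def test_threshold_above_max_single_cluster(self):
        assert set(cluster_lineages(self._matrix(), 0.5)) == {1}

    def test_threshold_zero_all_singletons(self):
        assert cluster_lineages(self._matrix(), 0.0) == [1, 2, 3, 4]

    def test_two_clades_recovered(self):
        labels = cluster_lineages(self._matrix(), 0.05)
        assert labels == [1, 1, 2, 2]

    def test_first_occurrence_labelling_is_deterministic(self):
        labels = cluster_lineages(self._matrix(), 0.05)
        assert labels[0] == 1  # first individual always opens cluster 1

    def test_undefined_entries_rejected_with_pair_list(self):
        m = self._matrix()
        m.values[0, 2] = m.values[2, 0] = np.nan
        with pytest.raises(ValueError, match="a1.*b1"):
            cluster_lineages(m, 0.05)
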