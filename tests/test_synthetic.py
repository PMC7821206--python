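"""Generators: determinism, model behaviour, and closure with the analyses."""

import numpy as np
import pytest

from gouania.barcoding import barcoding_gap, cluster_lineages, k2p_distance, pairwise_k2p
from gouania.key_engine import identify
from gouania.synthetic import (
    SimulationConfig,
    simulate_alignment,
    simulate_profiles,
    simulate_specimens,
)


def _ts_tv_counts(s1, s2):
    ts = tv = 0
    for a, b in zip(s1, s2):
        if a == b:
            continue
        if {a, b} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    return ts, tv


class TestSimulateAlignment:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(length=120, n_per_species=2, seed=99)
        a1 = simulate_alignment(cfg)
        a2 = simulate_alignment(cfg)
        assert [(r.id, r.sequence, r.species) for r in a1.records] == [
            (r.id, r.sequence, r.species) for r in a2.records
        ]

    def test_different_seed_differs(self):
        cfg = SimulationConfig(length=120, n_per_species=2, seed=1)
        assert simulate_alignment(cfg).records[0].sequence != simulate_alignment(
            cfg.with_seed(2)
        ).records[0].sequence

    def test_zero_within_depth_conspecifics_identical(self):
        cfg = SimulationConfig(length=200, n_per_species=3, within_depth=0.0, seed=5)
        aln = simulate_alignment(cfg)
        by_species = {}
        for r in aln.records:
            by_species.setdefault(r.species, set()).add(r.sequence)
        assert all(len(seqs) == 1 for seqs in by_species.values())
        gap = barcoding_gap(pairwise_k2p(aln), {r.id: r.species for r in aln.records})
        assert (gap["max_intra_pct"] == 0.0).all()

    def test_two_taxon_distance_recovery(self):
        # total path 0.10 subs/site; at 10 kb the estimate should sit within
        # a few analytic SEs of the truth
        tree = "(A:0.05,B:0.05);"
        cfg = SimulationConfig(
            tree=tree, n_per_species=1, within_depth=0.0, length=10_000, seed=31
        )
        aln = simulate_alignment(cfg)
        d = k2p_distance(aln.records[0].sequence, aln.records[1].sequence)
        se_approx = np.sqrt(0.1 / 10_000)  # order-of-magnitude analytic SE
        assert abs(d - 0.10) < 4 * se_approx

    def test_transition_bias_increases_with_kappa(self):
        tree = "(A:0.1,B:0.1);"
        ratios = []
        for kappa in (1.0, 2.0, 8.0):
            ts = tv = 0
            for rep in range(5):
                cfg = SimulationConfig(
                    tree=tree, kappa=kappa, n_per_species=1, within_depth=0.0,
                    length=4000, seed=1000 + rep,
                )
                aln = simulate_alignment(cfg)
                t, v = _ts_tv_counts(aln.records[0].sequence, aln.records[1].sequence)
                ts += t
                tv += v
            ratios.append(ts / tv)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="newick"):
            simulate_alignment(SimulationConfig(tree="((A:0.1,B:0.1;"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(kappa=0)
        with pytest.raises(ValueError):
            SimulationConfig(length=0)
        with pytest.raises(ValueError):
            SimulationConfig(within_depth=-0.1)


class TestPipelineClosure:
    def test_default_config_recovers_five_lineages_and_gap(self):
        aln = simulate_alignment(SimulationConfig(seed=4))
        labels = {r.id: r.species for r in aln.records}
        matrix = pairwise_k2p(aln)
        gap = barcoding_gap(matrix, labels)
        assert (gap["gap_pct"] > 0).all()
        clusters = cluster_lineages(matrix, 0.05)
        assert len(set(clusters)) == 5
        # clusters coincide with the true species partition
        mapping = {}
        for rid, cl in zip(matrix.ids, clusters):
            mapping.setdefault(cl, set()).add(labels[rid])
        assert all(len(sps) == 1 for sps in mapping.values())


class TestSimulateSpecimens:
    def test_values_inside_published_ranges(self, table):
        specimens = simulate_specimens(table, "G. pigra", 100, seed=8)
        caudal = [s.percent_sl("Caudal fin length") for s in specimens]
        assert all(11.1 <= c <= 12.7 for c in caudal)
        sl_span = table.sl_span("G. pigra")
        assert all(sl_span.lo <= s.sl_mm <= sl_span.hi for s in specimens)

    def test_truncnorm_variant_also_inside_ranges(self, table):
        specimens = simulate_specimens(
            table, "G. adriatica", 50, seed=9, distribution="truncnorm"
        )
        for s in specimens:
            for character, mm in s.measurements.items():
                r = table.combined("G. adriatica", character)
                assert r.lo - 1e-9 <= 100 * mm / s.sl_mm <= r.hi + 1e-9

    def test_empty_and_determinism(self, table):
        assert simulate_specimens(table, "G. pigra", 0, seed=1) == []
        a = simulate_specimens(table, "G. pigra", 5, seed=3)
        b = simulate_specimens(table, "G. pigra", 5, seed=3)
        assert a == b

    def test_unknown_species_rejected(self, table):
        with pytest.raises(KeyError):
            simulate_specimens(table, "G. atlantica", 3, seed=0)

    def test_simulated_profiles_identify_to_true_species(self, table, key):
        for species in table.species:
            for profile in simulate_profiles(table, species, 20, seed=17):
                assert identify(profile, key).candidates == {species}
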