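import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import greedy_pairing_trace
from rfsim.aam import PassthroughMapper
from rfsim.chem_io import parse_reaction_smiles
from rfsim.enzyme_db import Database, process_reaction
from rfsim.fragments import RFWeightVector
from rfsim.similarity import (
    CompoundPairing,
    SidePairing,
    pair_compounds,
    rf_containment,
    sim_2018_score,
    sim_rf_score,
    tanimoto,
)


class TestTanimoto:
    def test_identical_multisets(self):
        assert tanimoto({1: 2, 2: 1}, {1: 2, 2: 1}) == 1.0

    def test_disjoint_keys(self):
        assert tanimoto({1: 1}, {2: 1}) == 0.0

    def test_counted_example(self):
        # min-sum 1 (key a), max-sum 4 (2 + 1 + 1)
        assert tanimoto({"a": 2, "b": 1}, {"a": 1, "c": 1}) == 0.25

    def test_both_empty_defined_zero(self):
        assert tanimoto({}, {}) == 0.0

    @given(
        st.dictionaries(st.integers(0, 20), st.integers(1, 5), max_size=10),
        st.dictionaries(st.integers(0, 20), st.integers(1, 5), max_size=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        s = tanimoto(a, b)
        assert s == tanimoto(b, a)
        assert 0.0 <= s <= 1.0
        if a == b and a:
            assert s == 1.0


class TestPairCompounds:
    def pair_with_matrix(self, matrix):
        """Run pair_compounds with tanimoto replaced by a matrix lookup."""
        # encode each row/col as a one-key fingerprint and monkeypatch is
        # avoidable: call the greedy directly on synthetic fingerprints is
        # impossible for arbitrary matrices, so replicate via the internal
        # hook: build fake fps carrying indices.
        import rfsim.similarity as sim

        q_fps = [{"q": i} for i in range(len(matrix))]
        d_fps = [{"d": j} for j in range(len(matrix[0]) if matrix else 0)]
        original = sim.tanimoto
        sim.tanimoto = lambda a, b: matrix[a["q"]][b["d"]]
        try:
            return sim.pair_compounds(q_fps, d_fps)
        finally:
            sim.tanimoto = original

    def test_global_greedy_not_optimal_assignment(self):
        # greedy fixes (0,0)=0.9 first, forcing (1,1)=0.1; the optimal
        # assignment 0.8+0.2 is deliberately not taken
        pairing = self.pair_with_matrix([[0.9, 0.2], [0.8, 0.1]])
        assert pairing.pairs == [(0, 0, 0.9), (1, 1, 0.1)]

    def test_single_cell(self):
        pairing = self.pair_with_matrix([[0.7]])
        assert pairing.pairs == [(0, 0, 0.7)]

    def test_surplus_query_unmatched(self):
        pairing = self.pair_with_matrix([[0.5], [0.4]])
        assert pairing.pairs == [(0, 0, 0.5)]
        assert pairing.unmatched_query == [1]

    def test_tie_break_lowest_indices(self):
        pairing = self.pair_with_matrix([[0.5, 0.5], [0.5, 0.5]])
        assert pairing.pairs == [(0, 0, 0.5), (1, 1, 0.5)]

    def test_agrees_with_brute_force_trace_on_random_matrices(self):
        """Greedy pairing equals an independent literal greedy re-trace."""
        rng = np.random.RandomState(42)
        for _ in range(1000):
            n_q = rng.randint(1, 5)
            n_d = rng.randint(1, 5)
            matrix = np.round(rng.random_sample((n_q, n_d)), 3).tolist()
            got = self.pair_with_matrix(matrix)
            want = greedy_pairing_trace(matrix)
            assert got.pairs == want


def _processed(smiles, rxn_id="q"):
    return process_reaction(parse_reaction_smiles(smiles, rxn_id=rxn_id),
                            PassthroughMapper())


class TestSim2018:
    def test_self_similarity_is_one(self):
        p = _processed("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH:2]=[O:3]")
        score, _ = sim_2018_score(p.fps_sub, p.fps_prod, p.fps_sub, p.fps_prod)
        assert score == 1.0

    def test_disjoint_reactions_score_zero(self):
        a = _processed("CCCCC>>CCCCCC")
        b = _processed("O=S=O>>OS(=O)O")
        score, _ = sim_2018_score(a.fps_sub, a.fps_prod, b.fps_sub, b.fps_prod)
        assert score == 0.0

    def test_reversed_db_orientation_recovered(self):
        q = _processed("CCO>>CC=O")
        d = _processed("CC=O>>CCO")  # same reaction written backwards
        score, pairing = sim_2018_score(q.fps_sub, q.fps_prod, d.fps_sub, d.fps_prod)
        assert score == 1.0
        assert pairing.db_swapped

    def test_symmetry_for_matching_orientation(self):
        a = _processed("CCO>>CC=O")
        b = _processed("CCCO>>CCC=O")
        ab, _ = sim_2018_score(a.fps_sub, a.fps_prod, b.fps_sub, b.fps_prod)
        ba, _ = sim_2018_score(b.fps_sub, b.fps_prod, a.fps_sub, a.fps_prod)
        assert ab == pytest.approx(ba, abs=1e-12)


class TestRFContainment:
    w = RFWeightVector(entries={"a": 0.6489, "b": 0.3511}, raw={"a": 0.9241, "b": 0.5})

    def test_identical_sets_full_containment(self):
        assert rf_containment(self.w, {"a", "b"}) == pytest.approx(1.0)

    def test_no_shared_keys(self):
        assert rf_containment(self.w, {"z"}) == 0.0

    def test_partial_containment_sums_weights(self):
        assert rf_containment(self.w, {"a"}) == pytest.approx(0.6489)

    def test_empty_vector_undefined(self):
        with pytest.raises(ValueError):
            rf_containment(RFWeightVector(entries={}, raw={}), {"a"})

    def test_asymmetric_by_design(self):
        """Containment of q in d differs from containment of d in q."""
        q = RFWeightVector(entries={"a": 1.0}, raw={"a": 0.9})
        d = RFWeightVector(entries={"a": 0.5, "b": 0.5}, raw={"a": 0.9, "b": 0.9})
        assert rf_containment(q, d.keys) == 1.0
        assert rf_containment(d, q.keys) == 0.5


def _rf_score(s_weights, p_weights, d_sub, d_prod):
    pairing = CompoundPairing(
        substrates=SidePairing(pairs=[(i, i, 1.0) for i in range(len(s_weights))]),
        products=SidePairing(pairs=[(i, i, 1.0) for i in range(len(p_weights))]),
    )
    return sim_rf_score(s_weights, p_weights, d_sub, d_prod, pairing)


def _wv(**entries):
    total = sum(entries.values())
    return RFWeightVector(entries={k: v / total for k, v in entries.items()},
                          raw=dict(entries))


class TestSimRF:
    def test_zero_times_one_is_zero(self):
        rf = _rf_score([_wv(a=1)], [_wv(b=1)], [frozenset({"z"})], [frozenset({"b"})])
        assert rf.s_mean == 0.0 and rf.p_mean == pytest.approx(1.0)
        assert rf.sim_rf == 0.0

    def test_geometric_mean_of_half_and_half(self):
        rf = _rf_score(
            [_wv(a=1, b=1)], [_wv(c=1, d=1)],
            [frozenset({"a"})], [frozenset({"c"})],
        )
        assert rf.sim_rf == pytest.approx(0.5)

    def test_unavailable_when_side_has_no_rf_compound(self):
        empty = RFWeightVector(entries={}, raw={})
        rf = _rf_score([empty], [_wv(a=1)], [frozenset()], [frozenset({"a"})])
        assert not rf.available

    def test_geometric_mean_penalises_imbalance(self):
        """For fixed S̄+P̄ the score is maximal at S̄ = P̄."""
        balanced = math.sqrt(0.5 * 0.5)
        for s in (0.1, 0.3, 0.45):
            assert math.sqrt(s * (1.0 - s)) < balanced

    def test_self_comparison_scores_one(self, planted_db):
        for entry in planted_db.entries:
            if not entry.mappable or not any(entry.rf_x_sub) or not any(entry.rf_x_prod):
                continue
            _, rf, _ = planted_db.score(entry, entry)
            assert rf.available
            assert rf.sim_rf == pytest.approx(1.0, abs=1e-9)


class TestLocalityProperties:
    def test_shared_compounds_different_centre(self, planted_db, planted_queries):
        """Same scaffold, different reacting centre: whole-compound score stays
        high while the RF score collapses."""
        q = planted_queries[0]  # Q_A1: alcohol oxidation on scaffold AB1
        decoy = next(e for e in planted_db.entries if e.id == "R_B1")
        s2018, rf, _ = planted_db.score(q, decoy)
        assert s2018 > 0.6
        assert rf.available and rf.sim_rf < 0.05

    def test_distal_modification_keeps_rf_high(self, planted_db, planted_queries):
        """Family member differing >=6 bonds from the centre: RF similarity
        stays above the whole-compound score."""
        q = planted_queries[0]
        neighbour = next(e for e in planted_db.entries if e.id == "R_A2")
        s2018, rf, _ = planted_db.score(q, neighbour)
        assert rf.available
        assert rf.sim_rf > 0.85 > s2018

    def test_spectator_compound_leaves_rf_unchanged(self, planted_db):
        """Adding a fully-mapped spectator to the query does not move sim_RF."""
        plain, with_spectator = _spectator_pair()
        base = planted_db.prepare_query(parse_reaction_smiles(plain, rxn_id="plain"))
        spect = planted_db.prepare_query(
            parse_reaction_smiles(with_spectator, rxn_id="spect"))
        target = next(e for e in planted_db.entries if e.id == "R_C3")
        _, rf_base, _ = planted_db.score(base, target)
        _, rf_spect, _ = planted_db.score(spect, target)
        assert rf_base.available and rf_spect.available
        assert rf_spect.sim_rf == pytest.approx(rf_base.sim_rf, abs=1e-12)


def _spectator_pair():
    from rfsim.fixtures import _cd_scaffold

    sub, prod_c, _ = _cd_scaffold(12, ())
    plain = f"{sub}>>{prod_c}"
    spect = f"{sub}.[CH4:99]>>{prod_c}.[CH4:99]"
    return plain, spect
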