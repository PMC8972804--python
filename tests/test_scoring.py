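"""Candidate enumeration, sub-term evaluation and the pairing score."""

import math

import numpy as np
import pytest

from cssr.params import GeometryParams, TermStats, pair_class
from cssr.scoring import (candidate_pairs, cssr_score, score_structure,
                          term_value)
from cssr.structure_io import (ATOM_TYPES, CoarseNucleotide, RnaChain,
                               StructureIndex)
from cssr.synthetic import (add_noise, make_duplex, make_hairpin,
                            subset_atoms)

from oracles import nts_from_chains, score_pair, table_from_params


def chain_from_sequence(seq, chain_id="A", spacing=6.0):
    """A chain with the given bases and one P atom per nucleotide (the
    geometry is irrelevant for candidate enumeration)."""
    chain = RnaChain(chain_id=chain_id)
    for k, base in enumerate(seq):
        chain.nucleotides.append(CoarseNucleotide(
            chain_id=chain_id, seq_index=k, residue_number=str(k + 1),
            base=base, coords={"P": np.array([k * spacing, 0.0, 0.0])}))
    return chain


class TestCandidatePairs:
    def test_gggg_has_no_candidates(self):
        assert candidate_pairs([chain_from_sequence("GGGG")]) == []

    def test_gaaac_single_candidate(self):
        assert candidate_pairs([chain_from_sequence("GAAAC")]) == [(0, 4)]

    def test_min_separation_excludes_close_pairs(self):
        chain = chain_from_sequence("GAAC")
        assert candidate_pairs([chain], min_separation=4) == []
        assert candidate_pairs([chain], min_separation=3) == [(0, 3)]

    def test_inter_chain_flag(self):
        a = chain_from_sequence("GG", chain_id="A")
        b = chain_from_sequence("CC", chain_id="B")
        assert candidate_pairs([a, b]) == []
        got = candidate_pairs([a, b], inter_chain=True)
        assert got == [(0, 2), (0, 3), (1, 2), (1, 3)]

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=30))
            chain = chain_from_sequence(seq)
            expected = [
                (i, j)
                for i in range(30) for j in range(i + 1, 30)
                if j - i >= 4 and pair_class(seq[i], seq[j]) is not None
            ]
            assert candidate_pairs([chain]) == expected


class TestTermValue:
    def test_terminal_pair_loses_down_and_jlead(self):
        chains, gt = make_duplex("GGCAUC")
        index = StructureIndex(chains)
        i, j = min(gt.pairs)     # (0, 11): 5' end of A, 3' end of B
        assert term_value(index, i, j, "P", "dis_down") is None
        assert term_value(index, i, j, "P", "dih_j") is None
        for kind in ("dis0", "dis_up", "ang_i", "ang_j", "dih_i"):
            assert term_value(index, i, j, "P", kind) is not None

    def test_interior_pair_has_all_seven_terms(self):
        chains, gt = make_duplex("GGCAUC")
        index = StructureIndex(chains)
        interior = sorted(gt.pairs)[2]
        present = [k for k in ("dis0", "dis_up", "dis_down", "ang_i",
                               "ang_j", "dih_i", "dih_j")
                   if term_value(index, *interior, "P", k) is not None]
        assert len(present) == 7

    def test_values_match_hand_computation(self):
        from oracles import ang, dih, dist
        chains, gt = make_duplex("GGCAUC")
        index = StructureIndex(chains)
        i, j = sorted(gt.pairs)[2]
        p = lambda pos: tuple(index.nucleotide(pos).coords["C4'"])
        assert term_value(index, i, j, "C4'", "dis0") == \
            pytest.approx(dist(p(i), p(j)), abs=1e-12)
        assert term_value(index, i, j, "C4'", "dis_up") == \
            pytest.approx(dist(p(i + 1), p(j - 1)), abs=1e-12)
        assert term_value(index, i, j, "C4'", "ang_i") == \
            pytest.approx(ang(p(i + 1), p(i), p(j)), abs=1e-9)
        assert term_value(index, i, j, "C4'", "dih_i") == \
            pytest.approx(dih(p(i + 1), p(i), p(j), p(j - 1)), abs=1e-9)

    def test_missing_atom_gives_none(self):
        chains, gt = make_duplex("GGCAUC")
        chains = subset_atoms(chains, ["P"])
        index = StructureIndex(chains)
        i, j = min(gt.pairs)
        assert term_value(index, i, j, "C4'", "dis0") is None


def _two_nt_index(base_i="A", base_j="U", separation=18.0):
    a = RnaChain(chain_id="A")
    a.nucleotides.append(CoarseNucleotide("A", 0, "1", base_i,
                                          {"P": np.array([0.0, 0.0, 0.0])}))
    b = RnaChain(chain_id="B")
    b.nucleotides.append(CoarseNucleotide("B", 0, "1", base_j,
                                          {"P": np.array([separation, 0.0, 0.0])}))
    return StructureIndex([a, b])


def _single_term_params(mean=18.0, sigma=1.0):
    return GeometryParams(table={
        ("WC", "P", "dis0"): TermStats(mean=mean, sigma=sigma, n_obs=10)})


class TestCssrScore:
    def test_perfect_geometry_scores_one(self, ideal_wc_params):
        chains, gt = make_duplex("GGCAUCGG")
        index = StructureIndex(chains)
        for i, j in sorted(gt.pairs):
            ps = cssr_score(index, i, j, ideal_wc_params)
            assert ps.score == pytest.approx(1.0, abs=1e-9)

    def test_half_maximum_at_fwhm_delta(self):
        sigma = 1.0
        delta = sigma * math.sqrt(2 * math.log(2))
        index = _two_nt_index(separation=18.0 + delta)
        ps = cssr_score(index, 0, 1, _single_term_params(sigma=sigma))
        assert ps.n_terms == 1
        assert ps.score == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_exact(self, noisy_params):
        chains, _ = make_hairpin(6, 4, rng=8)
        chains = add_noise(chains, 0.4, seed=8)
        index = StructureIndex(chains)
        for i, j in candidate_pairs(index):
            a = cssr_score(index, i, j, noisy_params)
            b = cssr_score(index, j, i, noisy_params)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.score == b.score  # exact, not approximate

    def test_bounds(self, noisy_params):
        chains, _ = make_hairpin(6, 4, rng=9)
        chains = add_noise(chains, 1.0, seed=9)
        index = StructureIndex(chains)
        for i, j in candidate_pairs(index):
            ps = cssr_score(index, i, j, noisy_params)
            if ps is not None:
                assert 0.0 <= ps.score <= 1.0
                assert ps.n_terms >= 1

    def test_monotone_decay_in_single_term_deviation(self):
        params = _single_term_params(sigma=0.8)
        scores = [cssr_score(_two_nt_index(separation=18.0 + d), 0, 1,
                             params).score
                  for d in (0.0, 0.3, 0.8, 1.5, 3.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_incompatible_bases_return_none(self):
        index = _two_nt_index(base_i="A", base_j="G")
        assert cssr_score(index, 0, 1, _single_term_params()) is None

    def test_no_evaluable_terms_returns_none(self):
        index = _two_nt_index()
        empty = GeometryParams(table={
            ("WOBBLE", "P", "dis0"): TermStats(18.0, 1.0, 10)})
        assert cssr_score(index, 0, 1, empty) is None

    def test_p_only_input_uses_at_most_seven_terms(self, noisy_params):
        chains, gt = make_hairpin(5, 4, rng=10)
        chains = subset_atoms(chains, ["P"])
        index = StructureIndex(chains)
        for i, j in sorted(gt.pairs):
            ps = cssr_score(index, i, j, noisy_params)
            assert ps is not None and ps.n_terms <= 7

    def test_removing_an_atom_type_only_drops_its_terms(self, noisy_params):
        chains, gt = make_hairpin(5, 4, rng=12)
        noisy = add_noise(chains, 0.3, seed=12)
        full = StructureIndex(noisy)
        wo_n = StructureIndex(subset_atoms(noisy, set(ATOM_TYPES) - {"N"}))
        i, j = sorted(gt.pairs)[2]
        a = cssr_score(full, i, j, noisy_params)
        b = cssr_score(wo_n, i, j, noisy_params)
        assert b.n_terms == a.n_terms - 7
        # totals differ exactly by the N-atom contributions
        assert a.score * a.n_terms - b.score * b.n_terms == pytest.approx(
            sum_n_contributions(full, i, j, noisy_params), abs=1e-9)

    def test_oracle_equivalence_on_noisy_pairs(self, noisy_params, rng):
        chains, _ = make_hairpin(7, 5, rng=13, wobble_frac=0.2)
        noisy = add_noise(chains, 0.5, seed=13)
        index = StructureIndex(noisy)
        nts = nts_from_chains(noisy)
        table = table_from_params(noisy_params)
        for i, j in candidate_pairs(index):
            ours = cssr_score(index, i, j, noisy_params)
            ref = score_pair(nts, i, j, table)
            assert (ours is None) == (ref is None)
            if ours is not None:
                assert ours.score == pytest.approx(ref[0], abs=1e-12)
                assert ours.n_terms == ref[1]

    def test_nested_mean_differs_but_agrees_at_perfection(self, ideal_wc_params):
        chains, gt = make_duplex("GGCAUCGG")
        index = StructureIndex(chains)
        i, j = sorted(gt.pairs)[3]
        flat = cssr_score(index, i, j, ideal_wc_params)
        nested = cssr_score(index, i, j, ideal_wc_params, nested_mean=True)
        assert nested.score == pytest.approx(flat.score, abs=1e-9)


def sum_n_contributions(index, i, j, params):
    """Total contribution of the N-atom sub-terms (helper for the
    missing-atom consistency check)."""
    from cssr.geometry import angular_difference
    from cssr.params import TERM_KINDS, is_angular
    total = 0.0
    for kind in TERM_KINDS:
        st = params.get(cssr_class(index, i, j), "N", kind)
        if st is None:
            continue
        v = term_value(index, i, j, "N", kind)
        if v is None:
            continue
        d = angular_difference(v, st.mean) if is_angular(kind) else v - st.mean
        total += math.exp(-d * d / (2 * st.sigma ** 2))
    return total


def cssr_class(index, i, j):
    return pair_class(index.base(i), index.base(j))


def test_score_structure_min_terms_filter(noisy_params):
    chains, _ = make_hairpin(5, 4, rng=14)
    chains = subset_atoms(chains, ["P"])
    index = StructureIndex(chains)
    all_scores = score_structure(index, noisy_params)
    strict = score_structure(index, noisy_params, min_terms=6)
    assert {(s.i, s.j) for s in strict} <= {(s.i, s.j) for s in all_scores}
    assert all(s.n_terms >= 6 for s in strict)
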