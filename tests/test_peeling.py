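"""Peeling factors and cycles, checked against hand rules and enumeration."""

import numpy as np
import pytest

from recpeel.core import GeneticMap, PeelingParams, STATE_DOSAGE, PAT, MAT
from recpeel.peeling import (
    anterior,
    call_probabilities,
    penetrance,
    posterior_from_offspring,
    run_peeling_cycles,
    segregation_evidence,
)

from _oracles import trio_enumeration
from conftest import make_genotypes, make_pedigree


EPS = 0.01


class TestPenetrance:
    def test_missing_is_uninformative(self):
        assert np.array_equal(penetrance(9, EPS), np.ones(4))

    @pytest.mark.parametrize(
        "call,expected",
        [
            (0, [0.99, 0.01 / 3, 0.01 / 3, 0.01 / 3]),
            (1, [0.005, 0.99, 0.99, 0.005]),
            (2, [0.01 / 3, 0.01 / 3, 0.01 / 3, 0.99]),
        ],
    )
    def test_consistent_states_get_bulk_and_others_share_eps(self, call, expected):
        # enumeration of the four ordered states against the stated rule
        assert np.allclose(penetrance(call, EPS), expected)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            penetrance(3, EPS)


class TestAnterior:
    def test_forced_transmission(self):
        out = anterior([0, 0, 0, 1], [1, 0, 0, 0], [0.5, 0.5], [0.5, 0.5])
        assert np.allclose(out, [0, 0, 1, 0])  # (A,a)

    def test_uniform_parents_give_uniform_child(self):
        u = [0.25] * 4
        assert np.allclose(anterior(u, u, [0.5, 0.5], [0.5, 0.5]), 0.25)

    def test_heterozygous_father_with_skewed_segregation(self):
        out = anterior([0, 1, 0, 0], [1, 0, 0, 0], [0.7, 0.3], [0.5, 0.5])
        assert np.allclose(out, [0.7, 0, 0.3, 0])


class TestCalling:
    def test_confident_state_called(self):
        assert call_probabilities([0.995, 0.003, 0.001, 0.001], 0.99) == 0

    def test_uncertain_state_missing(self):
        assert call_probabilities([0.6, 0.4], 0.99) is None

    def test_boundary_calls_at_threshold(self):
        assert call_probabilities([0.90, 0.10], 0.90) == 0

    @pytest.mark.parametrize("state", range(4))
    def test_calling_is_idempotent_on_called_states(self, state):
        onehot = np.eye(4)[state]
        assert call_probabilities(onehot, 0.99) == state


class TestSegregationEvidence:
    def test_het_parent_with_called_child_allele(self):
        child = [1 - EPS, 1 - EPS, EPS, EPS]  # paternal allele called 'a'
        e = segregation_evidence(child, [0, 1, 0, 0], [0.5, 0.5], side=PAT)
        assert np.allclose(e, [1 - EPS, EPS])

    def test_homozygous_parent_is_uninformative(self):
        child = [1 - EPS, 1 - EPS, EPS, EPS]
        e = segregation_evidence(child, [0, 0, 0, 1], [0.5, 0.5], side=PAT)
        assert np.allclose(e, [0.5, 0.5])

    def test_uncertain_child_marginalises(self):
        # child paternal-allele belief 0.7 'a' / 0.3 'A' through the error floor
        m0 = 0.7 * (1 - EPS) + 0.3 * EPS
        m1 = 0.3 * (1 - EPS) + 0.7 * EPS
        child = [m0, m0, m1, m1]
        e = segregation_evidence(child, [0, 1, 0, 0], [0.5, 0.5], side=PAT)
        expected = np.array([m0, m1]) / (m0 + m1)
        assert np.allclose(e, expected)


class TestPosterior:
    def test_no_offspring_is_uniform(self):
        post = posterior_from_offspring(PAT, [], EPS, n_loci=3)
        assert np.allclose(post, 0.25)

    def test_single_called_offspring(self):
        # transmitted allele A via haplotype 0
        geno = np.array([2])  # child (A, a)
        seg = np.array([0])
        post = posterior_from_offspring(PAT, [(geno, seg)], EPS)
        w = np.array([EPS, EPS, 1 - EPS, 1 - EPS])
        assert np.allclose(post[0], w / w.sum())

    def test_product_over_offspring_matches_brute_force(self):
        rng = np.random.default_rng(2)
        L = 6
        offspring = []
        for _ in range(3):
            geno = rng.integers(-1, 4, size=L)
            seg = rng.integers(-1, 2, size=L)
            offspring.append((geno, seg))
        post = posterior_from_offspring(MAT, offspring, EPS)
        # independent oracle: explicit per-state product
        hap_allele = {0: [0, 0, 1, 1], 1: [0, 1, 0, 1]}
        for j in range(L):
            expected = np.ones(4)
            for geno, seg in offspring:
                if geno[j] < 0 or seg[j] < 0:
                    continue
                transmitted = [0, 1, 0, 1][geno[j]]  # maternal slot of the state
                for g in range(4):
                    match = hap_allele[seg[j]][g] == transmitted
                    expected[g] *= (1 - EPS) if match else EPS
            expected /= expected.sum()
            assert np.allclose(post[j], expected)


class TestPeelIndividual:
    def test_triple_product_normalised(self):
        from recpeel.peeling import peel_individual

        ant = np.array([[0.5, 0.5, 0.0, 0.0]])
        pen = np.array([[0.2, 0.8, 0.8, 0.2]])
        post = np.array([[1.0, 1.0, 1.0, 1.0]])
        out = peel_individual(ant, pen, post)
        expected = np.array([0.1, 0.4, 0.0, 0.0])
        assert np.allclose(out, expected / expected.sum())

    def test_conflicting_evidence_falls_back_to_penetrance(self):
        from recpeel.peeling import peel_individual

        ant = np.array([[1.0, 0.0, 0.0, 0.0]])
        pen = np.array([[0.0, 0.5, 0.5, 0.0]])
        post = np.ones((1, 4))
        out = peel_individual(ant, pen, post)
        assert np.allclose(out, [[0.0, 0.5, 0.5, 0.0]])


def _run_trio(calls_f, calls_m, calls_c, eps=EPS, cycles=1, total_cm=80.0):
    ped = make_pedigree([("F", "0", "0", "M"), ("M", "0", "0", "F"),
                         ("C", "F", "M", "U")])
    gt = make_genotypes(ped, {"F": calls_f, "M": calls_m, "C": calls_c})
    L = len(calls_c)
    gmap = GeneticMap.uniform("1", L, total_cm)
    params = PeelingParams(genotype_error=eps, n_outer_cycles=cycles)
    return ped, run_peeling_cycles(ped, gt, gmap, params)


def test_founder_closed_form():
    ped = make_pedigree([("X", "0", "0", "U")])
    gt = make_genotypes(ped, {"X": [0, 9]})
    res = run_peeling_cycles(ped, gt, GeneticMap.uniform("1", 2, 1.0),
                             PeelingParams(genotype_error=EPS))
    expected = (1 - EPS) / ((1 - EPS) + 3 * (EPS / 3))
    assert res.genotype_probs[0, 0, 0] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(res.genotype_probs[0, 1], 0.25)


def test_ungenotyped_child_of_homozygous_parents_is_imputed():
    L = 5
    _, res = _run_trio([2] * L, [2] * L, [9] * L)
    child = res.genotype_probs[2]
    assert child[:, 3].min() > 0.95  # (A,A) essentially certain


def test_error_free_trio_phases_mendelianly():
    # het father, hom mother, het child: child phase must be (A, a)
    L = 6
    _, res = _run_trio([1] * L, [0] * L, [1] * L, cycles=3)
    child = res.genotype_probs[2]
    assert np.argmax(child, axis=1).tolist() == [2] * L
    assert child[:, 2].min() > 0.9


def test_all_missing_data_stays_uniform():
    L = 4
    _, res = _run_trio([9] * L, [9] * L, [9] * L, cycles=4)
    assert np.allclose(res.genotype_probs, 0.25)
    assert np.allclose(res.seg_gamma, 0.5)


def test_trio_matches_joint_enumeration():
    """Peeled child marginals equal full-joint enumeration.

    The mother is genotyped homozygous so the factorised parent sides are
    exact up to O(eps); eps is tiny so agreement is far below 1e-6.
    """
    eps = 1e-9
    calls_f = [1, 1, 9, 1, 0, 1]
    calls_m = [0, 0, 0, 0, 0, 0]
    calls_c = [0, 1, 9, 1, 0, 1]
    L = len(calls_c)
    ped = make_pedigree([("F", "0", "0", "M"), ("M", "0", "0", "F"),
                         ("C", "F", "M", "U")])
    gt = make_genotypes(ped, {"F": calls_f, "M": calls_m, "C": calls_c})
    gmap = GeneticMap.uniform("1", L, 120.0)
    r = gmap.rec_fractions
    res = run_peeling_cycles(
        ped, gt, gmap, PeelingParams(genotype_error=eps, n_outer_cycles=1)
    )
    geno_o, seg_o, switch_o = trio_enumeration(calls_f, calls_m, calls_c, r, r, eps)
    c = ped.index_of("C")
    assert np.abs(res.genotype_probs[c] - geno_o).max() < 1e-6
    assert np.abs(res.seg_gamma[c, PAT] - seg_o).max() < 1e-6
    assert np.abs(res.crossover_expectation[c, PAT] - switch_o).max() < 1e-6


def test_distributions_stay_normalised_after_cycles(small_sim):
    res = run_peeling_cycles(
        small_sim.pedigree,
        small_sim.genotypes,
        GeneticMap.uniform("1", small_sim.config.n_loci, 100.0),
        PeelingParams(n_outer_cycles=2),
    )
    sums = res.genotype_probs.sum(axis=-1)
    assert np.abs(sums - 1.0).max() < 1e-8
    assert res.genotype_probs.min() >= 0
    assert np.abs(res.seg_gamma.sum(axis=-1) - 1.0).max() < 1e-8


def test_error_free_complete_genotyping_imputes_true_dosages():
    """With eps -> 0 and full observation, expected dosages match the calls."""
    from recpeel.simulate import SimConfig, simulate

    sim = simulate(
        SimConfig(
            n_founders=40, n_per_generation=40, n_sires=5, n_dams=20,
            n_loci=40, panel_fractions=(1.0, 0.0, 0.0), seed=21,
        )
    )
    res = run_peeling_cycles(
        sim.pedigree,
        sim.genotypes,
        GeneticMap.uniform("1", 40, 100.0),
        PeelingParams(genotype_error=1e-6, n_outer_cycles=3),
    )
    dosage = res.genotype_probs @ STATE_DOSAGE.astype(float)
    assert np.abs(dosage - sim.true_genotypes).max() < 1e-3
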