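"""Generator properties: landscape shape, LD model, meiosis, genotyping."""

import numpy as np
import pytest
from scipy import stats

from recpeel.core import GeneticMap, MISSING
from recpeel.simulate import (
    SimConfig,
    apply_genotyping,
    build_landscape,
    drop_gametes,
    simulate,
    simulate_founders,
    simulate_pedigree,
)

from conftest import make_pedigree


class TestBuildLandscape:
    def test_no_elevation_degenerates_to_flat(self):
        gm = build_landscape(90.0, 301, end_elevation=1.0)
        assert np.allclose(gm.interval_cm, 90.0 / 300)

    def test_total_length_conserved_exactly(self):
        gm = build_landscape(123.4, 500)
        assert gm.total_cm == pytest.approx(123.4, abs=1e-9)

    def test_continuity_at_the_junctions(self):
        L1 = 1000
        gm = build_landscape(100.0, L1 + 1)
        d = gm.interval_cm
        mid = d[int(0.5 * L1)]
        # interval just left of the 30% junction: polynomial at t ~ 0
        left_adjacent = d[int(0.30 * L1) - 1]
        assert abs(left_adjacent - mid) < mid * 0.01
        # and the middle region is exactly constant
        middle = d[int(0.31 * L1): int(0.69 * L1)]
        assert np.allclose(middle, mid)

    def test_ends_rise_monotonically_to_the_elevation(self):
        gm = build_landscape(100.0, 401, end_elevation=3.0)
        d = gm.interval_cm
        left = d[: int(0.30 * 400)]
        assert (np.diff(left) < 0).all()  # decreasing toward the middle
        mid = d[200]
        assert d[0] / mid == pytest.approx(3.0, rel=0.02)
        assert d[-1] / mid == pytest.approx(3.0, rel=0.02)


class TestFounders:
    def test_independent_loci_have_no_association(self, rng):
        haps = simulate_founders(2000, 30, (0.3, 0.7), ld_decay=0.0, rng=rng)
        cors = [
            abs(np.corrcoef(haps[:, j], haps[:, j + 1])[0, 1]) for j in range(29)
        ]
        assert max(cors) < 0.08

    def test_full_copying_gives_constant_haplotypes(self, rng):
        haps = simulate_founders(50, 20, (0.2, 0.8), ld_decay=1.0, rng=rng)
        assert (haps == haps[:, :1]).all()

    def test_ld_decays_with_distance(self, rng):
        haps = simulate_founders(3000, 60, (0.2, 0.8), ld_decay=0.9, rng=rng)

        def mean_r2(lag):
            vals = []
            for j in range(0, 60 - lag, 5):
                a, b = haps[:, j], haps[:, j + lag]
                if a.std() > 0 and b.std() > 0:
                    vals.append(np.corrcoef(a, b)[0, 1] ** 2)
            return np.mean(vals)

        assert mean_r2(1) > mean_r2(50)


def _mating_pair_pedigree(n_offspring):
    records = [("S", "0", "0", "M"), ("D", "0", "0", "F")]
    records += [(f"C{k}", "S", "D", "U") for k in range(n_offspring)]
    return make_pedigree(records)


class TestDropGametes:
    def test_zero_recombination_copies_a_parental_haplotype(self, rng):
        ped = _mating_pair_pedigree(20)
        L = 30
        founders = rng.integers(0, 2, size=(4, L)).astype(np.uint8)
        zero = GeneticMap("1", np.zeros(L - 1))
        haps, truth = drop_gametes(ped, founders, zero, zero, rng)
        sire = ped.index_of("S")
        for k in range(20):
            c = ped.index_of(f"C{k}")
            pat = haps[c, 0]
            assert (pat == haps[sire, 0]).all() or (pat == haps[sire, 1]).all()
        assert truth.n_crossovers.sum() == 0

    def test_mean_crossovers_match_map_expectation(self, rng):
        n = 5000
        ped = _mating_pair_pedigree(n)
        L = 80
        founders = rng.integers(0, 2, size=(4, L)).astype(np.uint8)
        gm_m = build_landscape(90.0, L, sex="M")
        gm_f = GeneticMap("1", gm_m.interval_cm * 1.3, sex="F")
        _, truth = drop_gametes(ped, founders, gm_f, gm_m, rng)
        for side, gm in ((0, gm_m), (1, gm_f)):
            counts = truth.n_crossovers[2:, side]
            expect = gm.rec_fractions.sum()
            sd = np.sqrt((gm.rec_fractions * (1 - gm.rec_fractions)).sum() / n)
            assert abs(counts.mean() - expect) < 3 * sd

    def test_female_male_ratio_near_config(self, rng):
        n = 8000
        ped = _mating_pair_pedigree(n)
        L = 60
        founders = rng.integers(0, 2, size=(4, L)).astype(np.uint8)
        gm_m = build_landscape(85.0, L, sex="M")
        gm_f = GeneticMap("1", gm_m.interval_cm * 1.3, sex="F")
        _, truth = drop_gametes(ped, founders, gm_f, gm_m, rng)
        ratio = truth.n_crossovers[2:, 1].mean() / truth.n_crossovers[2:, 0].mean()
        assert ratio == pytest.approx(1.3, abs=0.08)

    def test_per_interval_frequency_is_binomial_consistent(self, rng):
        # chi-square goodness of fit of realised switch counts against r_j
        n = 10_000
        ped = _mating_pair_pedigree(n)
        L = 40
        founders = rng.integers(0, 2, size=(4, L)).astype(np.uint8)
        gm = build_landscape(120.0, L)
        _, truth = drop_gametes(ped, founders, gm, gm, rng)
        counts = truth.crossovers[2:].sum(axis=(0, 1))  # per interval, 2n meioses
        r = gm.rec_fractions
        expected = 2 * n * r
        chi2 = ((counts - expected) ** 2 / (expected * (1 - r))).sum()
        p = stats.chi2.sf(chi2, df=L - 1)
        assert p > 0.01

    def test_mendelian_consistency_of_transmitted_alleles(self, small_sim):
        ped = small_sim.pedigree
        haps = small_sim.truth.haplotypes
        rng = np.random.default_rng(0)
        for c in rng.choice(np.flatnonzero(~ped.founders), size=30, replace=False):
            s, d = ped.sire[c], ped.dam[c]
            pat_ok = (haps[c, 0] == haps[s, 0]) | (haps[c, 0] == haps[s, 1])
            mat_ok = (haps[c, 1] == haps[d, 0]) | (haps[c, 1] == haps[d, 1])
            assert pat_ok.all() and mat_ok.all()


class TestApplyGenotyping:
    def _true(self, rng, n=400, L=60):
        return rng.integers(0, 3, size=(n, L)).astype(np.uint8)

    def test_error_free_high_panel_reproduces_truth(self, rng):
        cfg = SimConfig(panel_fractions=(1.0, 0.0, 0.0), genotype_error=0.0)
        truth = self._true(rng)
        gm = apply_genotyping(truth, cfg, rng)
        assert np.array_equal(gm.calls, truth)

    def test_ungenotyped_individuals_all_missing(self, rng):
        cfg = SimConfig(panel_fractions=(0.0, 0.0, 1.0), genotype_error=0.0)
        truth = self._true(rng)
        gm = apply_genotyping(truth, cfg, rng)
        assert (gm.calls == MISSING).all()
        assert (gm.panel == "ungenotyped").all()

    def test_low_panel_observes_evenly_spaced_subset(self, rng):
        cfg = SimConfig(
            panel_fractions=(0.0, 1.0, 0.0),
            low_panel_fraction_of_loci=0.25,
            genotype_error=0.0,
        )
        truth = self._true(rng, n=50, L=100)
        gm = apply_genotyping(truth, cfg, rng)
        observed = gm.calls[0] != MISSING
        assert observed.sum() == 25
        assert (observed == observed[None, :].repeat(50, axis=0)[0]).all()

    def test_flip_count_binomially_consistent(self, rng):
        cfg = SimConfig(panel_fractions=(1.0, 0.0, 0.0), genotype_error=0.01)
        truth = self._true(rng, n=1000, L=100)  # 1e5 calls
        gm = apply_genotyping(truth, cfg, rng)
        flips = (gm.calls != truth).sum()
        n_calls = truth.size
        sd = np.sqrt(n_calls * 0.01 * 0.99)
        assert abs(flips - n_calls * 0.01) < 3 * sd
        # flipped calls are still valid wrong dosages
        assert np.isin(gm.calls, [0, 1, 2]).all()


class TestDeterminismAndStructure:
    def test_identical_seeds_reproduce_byte_identical_outputs(self):
        cfg = SimConfig(n_founders=50, n_per_generation=50, n_sires=5,
                        n_dams=20, n_loci=40, seed=99)
        a, b = simulate(cfg), simulate(cfg)
        assert a.pedigree.ids == b.pedigree.ids
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert np.array_equal(a.truth.crossovers, b.truth.crossovers)
        assert np.array_equal(a.truth.haplotypes, b.truth.haplotypes)

    def test_pedigree_has_expected_structure(self):
        cfg = SimConfig(n_founders=80, n_generations=4, n_per_generation=80,
                        n_sires=6, n_dams=30)
        ped = simulate_pedigree(cfg, np.random.default_rng(31))
        assert len(ped) == 4 * 80
        assert ped.generation.max() == 3
        # non-founders draw parents from the previous generation
        for c in np.flatnonzero(~ped.founders):
            g = ped.generation[c]
            assert ped.generation[ped.sire[c]] == g - 1
            assert ped.generation[ped.dam[c]] == g - 1
            assert ped.sex[ped.sire[c]] == "M"
            assert ped.sex[ped.dam[c]] == "F"

    def test_true_genotypes_are_haplotype_sums(self, small_sim):
        assert np.array_equal(
            small_sim.true_genotypes, small_sim.truth.haplotypes.sum(axis=1)
        )

    def test_panel_fractions_roughly_respected(self, small_sim):
        panel = small_sim.genotypes.panel
        frac_high = (panel == "high").mean()
        assert abs(frac_high - 0.39) < 0.06
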