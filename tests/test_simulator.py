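"""Engine checks against closed-form one-locus selection and LD identities."""

import itertools

import numpy as np
import pytest

from resistsim import (
    allele_frequencies,
    init_population,
    linkage_disequilibrium,
    step_generation,
)
from resistsim.simulator import (
    ExtinctionError,
    PopulationState,
    transmission_tensor,
)


def one_locus_recursion(p, w_ss, w_sr, w_rr):
    """Independent closed-form recursion for selection at a single locus."""
    mean_w = p * p * w_rr + 2 * p * (1 - p) * w_sr + (1 - p) * (1 - p) * w_ss
    return p * (p * w_rr + (1 - p) * w_sr) / mean_w


def locus1_table(w_ss, w_sr, w_rr):
    """3x3 table varying only with locus 1."""
    return np.repeat(np.array([[w_ss], [w_sr], [w_rr]]), 3, axis=1)


def monomorphic_locus2_state(p1):
    hap = np.array([1 - p1, 0.0, p1, 0.0])
    return PopulationState(hap, hap.copy())


class TestInitAndFrequencies:
    def test_linkage_equilibrium_decomposition(self):
        state = init_population(0.01, 0.01)
        assert state.hap_female[3] == pytest.approx(1e-4)
        assert state.hap_female.sum() == pytest.approx(1.0)
        ld = linkage_disequilibrium(state)
        assert ld.d_female == pytest.approx(0.0, abs=1e-15)

    def test_asymmetric_start(self):
        state = init_population(0.01, 0.001)
        assert state.hap_female[2] == pytest.approx(0.00999)

    @pytest.mark.parametrize("p1,p2", [(0.0, 0.5), (0.5, 1.0), (-0.1, 0.5)])
    def test_rejects_out_of_range_frequencies(self, p1, p2):
        with pytest.raises(ValueError):
            init_population(p1, p2)

    def test_round_trip_allele_frequencies(self):
        freqs = allele_frequencies(init_population(0.01, 0.3))
        assert freqs.p1_mean == pytest.approx(0.01)
        assert freqs.p2_mean == pytest.approx(0.3)

    def test_uniform_haplotypes_give_half(self):
        state = PopulationState(np.full(4, 0.25), np.full(4, 0.25))
        freqs = allele_frequencies(state)
        assert freqs.p1_mean == pytest.approx(0.5)
        assert freqs.p2_mean == pytest.approx(0.5)


class TestLinkageDisequilibrium:
    def test_maximal_coupling(self):
        hap = np.array([0.5, 0.0, 0.0, 0.5])
        ld = linkage_disequilibrium(PopulationState(hap, hap.copy()))
        assert ld.d_female == pytest.approx(0.25)
        assert ld.dprime_female == pytest.approx(1.0)

    def test_monomorphic_locus_gives_zero(self):
        ld = linkage_disequilibrium(monomorphic_locus2_state(0.3))
        assert ld.d_female == 0.0
        assert ld.dprime_female == 0.0

    def test_d_equals_covariance_of_allele_indicators(self):
        # brute-force covariance over the 4-haplotype distribution
        rng = np.random.default_rng(7)
        for _ in range(20):
            hap = rng.dirichlet(np.ones(4))
            state = PopulationState(hap, hap.copy())
            r1 = np.array([0, 0, 1, 1])
            r2 = np.array([0, 1, 0, 1])
            cov = float(hap @ (r1 * r2) - (hap @ r1) * (hap @ r2))
            assert linkage_disequilibrium(state).d_female == pytest.approx(cov, abs=1e-14)


class TestStepGeneration:
    def test_neutrality_is_identity(self):
        state = init_population(0.2, 0.4)
        ones = np.ones((3, 3))
        for c in (0.0, 0.17, 0.5):
            nxt = step_generation(state, ones, ones, c)
            assert np.allclose(nxt.hap_female, state.hap_female, atol=1e-14)
            assert np.allclose(nxt.hap_male, state.hap_male, atol=1e-14)
        assert nxt.generation == 1

    def test_one_locus_oracle_over_100_generations(self):
        w = (0.75, 0.8125, 0.875)  # base-scenario marginal fitnesses at locus 1
        table = locus1_table(*w)
        state = monomorphic_locus2_state(0.01)
        p_expected = 0.01
        for _ in range(100):
            state = step_generation(state, table, table, 0.5)
            p_expected = one_locus_recursion(p_expected, *w)
            assert allele_frequencies(state).p1_mean == pytest.approx(
                p_expected, abs=1e-10
            )

    def test_symmetric_loci_stay_symmetric(self):
        from resistsim import InsecticideParams, marginal_fitness

        p = InsecticideParams(cost=0.05, dominance_cost=0.3)
        table = marginal_fitness(p, p, {1, 2}, exposure=0.5)
        state = init_population(0.01, 0.01)
        for _ in range(50):
            state = step_generation(state, table, table, 0.5)
            freqs = allele_frequencies(state)
            assert freqs.p1_mean == pytest.approx(freqs.p2_mean, abs=1e-14)

    def test_recombination_halves_neutral_ld(self):
        # D_t = D_0 * (1 - c)^t under neutrality
        hap = np.array([0.4, 0.1, 0.1, 0.4])
        state = PopulationState(hap, hap.copy())
        d0 = linkage_disequilibrium(state).d_female
        ones = np.ones((3, 3))
        for c in (0.1, 0.3, 0.5):
            s = PopulationState(hap, hap.copy())
            for t in range(1, 11):
                s = step_generation(s, ones, ones, c)
                d = linkage_disequilibrium(s).d_female
                assert d == pytest.approx(d0 * (1 - c) ** t, abs=1e-13)

    def test_frequencies_stay_normalised(self):
        rng = np.random.default_rng(11)
        state = init_population(0.05, 0.2)
        table_f = rng.uniform(0.1, 1.0, size=(3, 3))
        table_m = rng.uniform(0.1, 1.0, size=(3, 3))
        for _ in range(200):
            state = step_generation(state, table_f, table_m, 0.23)
            assert state.hap_female.sum() == pytest.approx(1.0, abs=1e-12)
            assert state.hap_male.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mean_fitness_signals_extinction(self):
        state = init_population(0.01, 0.01)
        with pytest.raises(ExtinctionError):
            step_generation(state, np.zeros((3, 3)), np.ones((3, 3)), 0.5)


class TestTransmission:
    @pytest.mark.parametrize("c", [0.0, 0.2, 0.5])
    def test_rows_are_distributions(self, c):
        T = transmission_tensor(c)
        assert np.allclose(T.sum(axis=2), 1.0)

    def test_double_heterozygote_recombination(self):
        T = transmission_tensor(0.2)
        # coupling genotype S1S2/R1R2: parental 0 and 3, recombinant 1 and 2
        assert T[0, 3, 0] == pytest.approx(0.4)
        assert T[0, 3, 3] == pytest.approx(0.4)
        assert T[0, 3, 1] == pytest.approx(0.1)
        assert T[0, 3, 2] == pytest.approx(0.1)

    def test_non_heterozygote_unaffected_by_recombination(self):
        for c in (0.0, 0.5):
            T = transmission_tensor(c)
            # S1S2/R1S2 shares the locus-2 allele: half each parental haplotype
            assert T[0, 2, 0] == pytest.approx(0.5)
            assert T[0, 2, 2] == pytest.approx(0.5)

    def test_enumerated_gamete_distribution(self):
        # brute-force: enumerate ordered allele picks with crossover indicator
        c = 0.37
        T = transmission_tensor(c)
        alleles = {h: ((h >> 1) & 1, h & 1) for h in range(4)}
        code = {v: k for k, v in alleles.items()}
        for a, b in itertools.product(range(4), repeat=2):
            expected = np.zeros(4)
            for first, co in itertools.product((a, b), (False, True)):
                other = b if first == a else a
                gamete = (
                    alleles[first]
                    if not co
                    else (alleles[first][0], alleles[other][1])
                )
                expected[code[gamete]] += 0.5 * (c if co else 1 - c)
            assert np.allclose(T[a, b], expected)
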