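import math

import numpy as np
import pytest

from nucdhmm import dhmm
from nucdhmm.models import (NUC_LEN, LinkerLengthDistribution, LinkerModel,
                            NucleosomeModel, linker_loglik)

from conftest import (feasible_instance, random_linker_model,
                      random_nucleosome_model, random_sequence,
                      uniform_linker_model, uniform_nucleosome_model)
from oracles import brute_force_posteriors


def make_instance(rng, tau, m=None, order=1):
    n = feasible_instance(rng, tau, m)
    return (random_sequence(rng, n),
            random_nucleosome_model(rng, order=order),
            random_linker_model(rng, order=order),
            LinkerLengthDistribution(rng.dirichlet(np.ones(tau)) * 0.999
                                     + 0.001 / tau))


class TestForwardBackward:
    def test_short_sequence_is_pure_linker(self, rng):
        # n < 149: the only valid path is a single linker block
        nuc = random_nucleosome_model(rng)
        link = random_linker_model(rng)
        F = LinkerLengthDistribution.uniform(150)
        seq = random_sequence(rng, 100)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        expected = math.log(F.pmf[99]) + linker_loglik(seq, link)
        assert fb.loglik == pytest.approx(expected, rel=1e-10)

    def test_uniform_emissions_path_sum(self, rng):
        # with flat emissions log P factorizes into emissions x duration sum
        nuc = uniform_nucleosome_model()
        link = uniform_linker_model()
        tau = 300
        F = LinkerLengthDistribution.uniform(tau)
        seq = random_sequence(rng, 300)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        from oracles import enumerate_segmentations
        path_sum = sum(
            (1.0 / tau) ** len(ks) for ks in enumerate_segmentations(300, tau))
        assert fb.loglik == pytest.approx(600 * math.log(0.25)
                                          + math.log(path_sum), rel=1e-10)

    def test_forward_equals_backward_on_random_instances(self, rng):
        for _ in range(25):
            seq, nuc, link, F = make_instance(rng, tau=int(rng.integers(5, 26)))
            fb = dhhm_fb = dhmm.forward_backward(seq, nuc, link, F)
            assert fb.loglik == pytest.approx(fb.loglik_backward,
                                              rel=1e-9, abs=1e-6)

    def test_all_zero_F_rejected(self, rng):
        zero = LinkerLengthDistribution.uniform(5)
        zero.pmf = np.zeros(5)  # bypass the validating constructor
        with pytest.raises(ValueError):
            dhmm.forward_backward("ACGT", uniform_nucleosome_model(),
                                  uniform_linker_model(), zero)


class TestOccupancy:
    def test_zero_when_no_nucleosome_fits(self, rng):
        nuc = random_nucleosome_model(rng)
        link = random_linker_model(rng)
        F = LinkerLengthDistribution.uniform(150)
        fb = dhmm.forward_backward(random_sequence(rng, 120), nuc, link, F)
        assert np.all(dhmm.occupancy(fb) == 0)

    def test_uniform_emission_occupancy_matches_enumeration(self, rng):
        nuc = uniform_nucleosome_model()
        link = uniform_linker_model()
        F = LinkerLengthDistribution.uniform(20)
        seq = random_sequence(rng, 320)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        ref = brute_force_posteriors(seq, nuc, link, F)
        assert np.abs(dhmm.occupancy(fb) - ref["occupancy"]).max() < 1e-8

    def test_forced_segmentation_pins_occupancy(self, rng):
        # linker emissions ~0 for C/G (on either strand) with two 10-bp A/T
        # islands flanking a 147-bp C/G core -> the core must be occupied
        eps = 1e-9
        stat = np.array([0.5 - eps, eps, eps, 0.5 - eps])
        link = LinkerModel(order=1, stationary=stat,
                           cond=(np.tile(stat, (4, 1)),))
        nuc = uniform_nucleosome_model()
        seq = "AT" * 5 + "".join(rng.choice(list("CG"), size=NUC_LEN)) + "TA" * 5
        F = LinkerLengthDistribution.uniform(20)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        occ = dhmm.occupancy(fb)
        assert occ[10:10 + NUC_LEN].min() > 0.999

    def test_occupancy_sum_ties_to_linker_count_posterior(self, rng):
        # sum(o_i) = 147 * E[#nucleosomes] and E[#linkers] = E[#nuc] + 1
        seq, nuc, link, F = make_instance(rng, tau=15, m=2)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        occ_sum = dhmm.occupancy(fb).sum()
        nk = dhmm.expected_linker_counts(fb, F)
        assert occ_sum == pytest.approx(
            NUC_LEN * (nk.sum() - 1.0), rel=1e-8, abs=1e-8)

    def test_interior_shift_invariance(self, rng):
        # a poly-A flank under a nucleosome chain that forbids A anywhere
        # forces pure linker there and must not perturb interior occupancy
        probs = np.array([0.0, 1 / 3, 1 / 3, 1 / 3])
        nuc = NucleosomeModel(order=1, init=(probs[None, :],),
                              body=np.tile(probs, (146, 4, 1)))
        link = uniform_linker_model()
        tau = 60
        F = LinkerLengthDistribution.uniform(tau)
        core = "".join(rng.choice(list("CGT"), size=800))
        flank = "A" * 150
        occ_plain = dhmm.occupancy(dhmm.forward_backward(core, nuc, link, F))
        occ_flank = dhmm.occupancy(
            dhmm.forward_backward(flank + core + flank, nuc, link, F))
        margin = tau + NUC_LEN
        inner = slice(margin, 800 - margin)
        assert np.abs(occ_flank[150 + margin:150 + 800 - margin]
                      - occ_plain[inner]).max() < 1e-9


class TestViterbi:
    def test_pure_linker_path(self, rng):
        nuc = random_nucleosome_model(rng)
        link = random_linker_model(rng)
        F = LinkerLengthDistribution.uniform(150)
        path = dhmm.viterbi(random_sequence(rng, 100), nuc, link, F)
        assert path.blocks == [("L", 1, 100)]

    def test_matches_brute_force_argmax(self, rng):
        for _ in range(10):
            seq, nuc, link, F = make_instance(rng, tau=12)
            ref = brute_force_posteriors(seq, nuc, link, F)
            path = dhmm.viterbi(seq, nuc, link, F)
            assert path.nucleosome_starts.tolist() == ref["viterbi_starts"]

    def test_deterministic(self, rng):
        seq, nuc, link, F = make_instance(rng, tau=15, m=1)
        a = dhmm.viterbi(seq, nuc, link, F)
        b = dhmm.viterbi(seq, nuc, link, F)
        assert a.blocks == b.blocks

    def test_no_path_raises(self, rng):
        nuc = random_nucleosome_model(rng)
        link = random_linker_model(rng)
        F = LinkerLengthDistribution.uniform(5)
        # n = 30 > tau and too short for a nucleosome: no valid segmentation
        with pytest.raises(dhmm.NoPathError):
            dhmm.viterbi(random_sequence(rng, 30), nuc, link, F)


class TestAffinity:
    def test_zero_when_models_identical(self, rng):
        probs = np.tile(np.array([0.3, 0.2, 0.2, 0.3]), (4, 1))
        nuc = NucleosomeModel(order=1, init=(probs[:1],),
                              body=np.tile(probs, (146, 1, 1)))
        link = LinkerModel(order=1, stationary=probs[0], cond=(probs,))
        seq = random_sequence(rng, 400)
        a = dhmm.affinity(seq, nuc, link)
        valid = ~np.isnan(a)
        assert valid.sum() == 400 - 146
        assert np.abs(a[valid]).max() < 1e-9

    def test_neg_inf_for_forbidden_window(self, rng):
        probs = np.array([0.0, 1 / 3, 1 / 3, 1 / 3])
        nuc = NucleosomeModel(order=1, init=(probs[None, :],),
                              body=np.tile(probs, (146, 4, 1)))
        link = uniform_linker_model()
        seq = "A" + random_sequence(rng, 200).replace("A", "C")
        a = dhmm.affinity(seq, nuc, link)
        assert a[73] == -math.inf  # window containing the leading A

    def test_matches_direct_two_likelihood_oracle(self, rng):
        from nucdhmm.models import linker_loglik, nucleosome_loglik
        nuc = random_nucleosome_model(rng, order=4)
        link = random_linker_model(rng, order=4)
        seq = random_sequence(rng, 250)
        a = dhmm.affinity(seq, nuc, link)
        for center in (74, 120, 250 - 73):
            win = seq[center - 74:center + 73]
            expected = nucleosome_loglik(win, nuc) - linker_loglik(win, link)
            assert a[center - 1] == pytest.approx(expected, rel=1e-9)

    def test_too_short_gives_empty(self, rng):
        a = dhmm.affinity(random_sequence(rng, 100),
                          uniform_nucleosome_model(), uniform_linker_model())
        assert a.size == 0


class TestExpectedLinkerCounts:
    def test_single_forced_path(self, rng):
        nuc = random_nucleosome_model(rng)
        link = random_linker_model(rng)
        F = LinkerLengthDistribution.uniform(150)
        fb = dhmm.forward_backward(random_sequence(rng, 100), nuc, link, F)
        nk = dhmm.expected_linker_counts(fb, F)
        assert nk[99] == pytest.approx(1.0, rel=1e-10)
        assert nk.sum() == pytest.approx(1.0, rel=1e-10)

    def test_matches_enumeration(self, rng):
        seq, nuc, link, F = make_instance(rng, tau=12, m=2)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        ref = brute_force_posteriors(seq, nuc, link, F)
        nk = dhmm.expected_linker_counts(fb, F)
        assert np.abs(nk - ref["linker_counts"]).max() < 1e-8

    def test_at_least_one_linker(self, rng):
        for _ in range(5):
            seq, nuc, link, F = make_instance(rng, tau=10)
            fb = dhmm.forward_backward(seq, nuc, link, F)
            assert dhmm.expected_linker_counts(fb, F).sum() >= 1.0 - 1e-9

    def test_mismatched_F_rejected(self, rng):
        seq, nuc, link, F = make_instance(rng, tau=10, m=0)
        fb = dhmm.forward_backward(seq, nuc, link, F)
        other = LinkerLengthDistribution.uniform(F.tau_l)
        with pytest.raises(ValueError):
            dhmm.expected_linker_counts(fb, other)


class TestAmbiguity:
    def test_n_bases_are_neutral_and_finite(self, rng):
        seq, nuc, link, F = make_instance(rng, tau=15, m=1)
        noisy = seq[:50] + "N" + seq[51:]
        fb = dhmm.forward_backward(noisy, nuc, link, F)
        assert np.isfinite(fb.loglik)
        occ = dhmm.occupancy(fb)
        assert np.all((occ >= 0) & (occ <= 1))


class TestStatePath:
    def test_validation_rejects_bad_paths(self):
        with pytest.raises(ValueError):
            dhmm.StatePath([("N", 1, 147), ("L", 148, 10)]).validate(157, 50)
        with pytest.raises(ValueError):
            dhmm.StatePath([("L", 1, 10), ("L", 11, 10)]).validate(20, 50)

    def test_state_vector_and_centers(self):
        path = dhmm.StatePath([("L", 1, 10), ("N", 11, 147), ("L", 158, 5)])
        path.validate(162, 50)
        z = path.state_vector(162)
        assert z.sum() == 147
        assert path.nucleosome_centers.tolist() == [84]
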