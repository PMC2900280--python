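import math

import numpy as np
import pytest

from nucdhmm import models as m
from nucdhmm.models import (BaseComposition, LinkerLengthDistribution,
                            base_composition, linker_loglik, nucleosome_loglik,
                            read_linker_length_distribution, read_model,
                            rescale_model, revcomp,
                            write_linker_length_distribution, write_model)

from conftest import (random_linker_model, random_nucleosome_model,
                      random_sequence, uniform_linker_model,
                      uniform_nucleosome_model)
from oracles import naive_strand_loglik_link, naive_strand_loglik_nuc


class TestNucleosomeLoglik:
    def test_uniform_model_is_flat(self, rng):
        nuc = uniform_nucleosome_model()
        seq = random_sequence(rng, 147)
        assert nucleosome_loglik(seq, nuc) == pytest.approx(294 * math.log(0.25))

    def test_zero_probability_transition_is_neg_inf(self):
        # all mass on A: the Watson strand of poly-A scores 0, but its
        # reverse complement is poly-T -> forbidden -> -inf sentinel
        init = (np.array([[1.0, 0, 0, 0]]),)
        body = np.zeros((146, 4, 4))
        body[:, :, 0] = 1.0
        nuc = m.NucleosomeModel(order=1, init=init, body=body)
        assert nucleosome_loglik("A" * 147, nuc) == -math.inf

    @pytest.mark.parametrize("order", [1, 4])
    def test_matches_per_position_product_oracle(self, order):
        rng = np.random.default_rng(1)
        nuc = random_nucleosome_model(rng, order=order)
        seq = nuc.sample(rng, 1)[0]
        expected = (naive_strand_loglik_nuc(seq, nuc)
                    + naive_strand_loglik_nuc(revcomp(seq), nuc))
        assert nucleosome_loglik(seq, nuc) == pytest.approx(expected, rel=1e-12)

    def test_both_strand_score_is_revcomp_invariant(self, rng):
        nuc = random_nucleosome_model(rng, order=4)
        seq = random_sequence(rng, 147)
        assert nucleosome_loglik(seq, nuc) == pytest.approx(
            nucleosome_loglik(revcomp(seq), nuc), rel=1e-12)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError, match="147"):
            nucleosome_loglik("ACGT", uniform_nucleosome_model())

    def test_ambiguous_base_is_neutral(self, rng):
        nuc = random_nucleosome_model(rng, order=1)
        seq = random_sequence(rng, 147)
        with_n = seq[:73] + "N" + seq[74:]
        assert np.isfinite(nucleosome_loglik(with_n, nuc))


class TestLinkerLoglik:
    def test_uniform_model(self, rng):
        link = uniform_linker_model()
        seq = random_sequence(rng, 17)
        assert linker_loglik(seq, link) == pytest.approx(34 * math.log(0.25))

    def test_single_base_uses_stationary(self, rng):
        link = random_linker_model(rng, order=4)
        expected = math.log(link.stationary[0]) + math.log(link.stationary[3])
        assert linker_loglik("A", link) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("order,k", [(1, 20), (4, 20), (4, 3)])
    def test_matches_chain_rule_oracle(self, order, k):
        # k < order exercises the shorter-history tables
        rng = np.random.default_rng(2)
        link = random_linker_model(rng, order=order)
        seq = random_sequence(rng, k)
        expected = (naive_strand_loglik_link(seq, link)
                    + naive_strand_loglik_link(revcomp(seq), link))
        assert linker_loglik(seq, link) == pytest.approx(expected, rel=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            linker_loglik("", uniform_linker_model())


class TestRescale:
    def test_identity_when_compositions_equal(self, rng):
        nuc = random_nucleosome_model(rng, order=1)
        comp = BaseComposition.from_at(0.617)
        out = rescale_model(nuc, comp, comp)
        assert np.allclose(out.body, nuc.body)
        for a, b in zip(out.init, nuc.init):
            assert np.allclose(a, b)

    def test_celegans_class_factors(self):
        # A/T class scaled by 0.645/0.617, G/C class by 0.355/0.383
        nuc = uniform_nucleosome_model()
        out = rescale_model(nuc, BaseComposition.from_at(0.617),
                            BaseComposition.from_at(0.645))
        raw = 0.25 * np.array([0.645 / 0.617, 0.355 / 0.383,
                               0.355 / 0.383, 0.645 / 0.617])
        expected = raw / raw.sum()
        assert np.allclose(out.body[0, 0], expected, atol=1e-12)

    def test_maize_gc_factor(self):
        # the maize G/C class factor relative to yeast is 1.2
        yeast = BaseComposition.from_at(0.617)
        maize = BaseComposition.from_at(1 - 0.383 * 1.2)
        assert maize.gc / yeast.gc == pytest.approx(1.2)
        link = uniform_linker_model()
        out = rescale_model(link, yeast, maize)
        ratio = (out.stationary[1] / out.stationary[0]) \
            / (link.stationary[1] / link.stationary[0])
        assert ratio == pytest.approx(1.2 / (maize.at / yeast.at))

    def test_normalized_for_many_random_models(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            link = random_linker_model(rng, order=1, concentration=1.0)
            src = BaseComposition.from_at(rng.uniform(0.3, 0.7))
            tgt = BaseComposition.from_at(rng.uniform(0.3, 0.7))
            out = rescale_model(link, src, tgt)
            assert np.allclose(out.cond[0].sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(out.stationary.sum(), 1.0, atol=1e-9)

    def test_zero_source_class_rejected(self):
        nuc = uniform_nucleosome_model()
        with pytest.raises(ValueError):
            rescale_model(nuc, BaseComposition.from_at(0.0),
                          BaseComposition.from_at(0.5))


class TestBaseComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", (0.25, 0.25, 0.25, 0.25)),
        ("AAAA", (1.0, 0.0, 0.0, 0.0)),
        ("AANN", (1.0, 0.0, 0.0, 0.0)),  # skip-ambiguity policy
    ])
    def test_fractions(self, seq, expected):
        comp = base_composition(seq)
        assert comp.as_array() == pytest.approx(np.array(expected))

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            base_composition("NNN")


class TestSerialization:
    @pytest.mark.parametrize("ext", ["tsv", "json", "yaml"])
    def test_nucleosome_round_trip_bit_identical(self, tmp_path, rng, ext):
        nuc = random_nucleosome_model(rng, order=4)
        path = tmp_path / f"nuc.{ext}"
        write_model(nuc, path)
        back = read_model(path)
        assert back.order == nuc.order
        assert np.array_equal(back.body, nuc.body)
        for a, b in zip(back.init, nuc.init):
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("ext", ["tsv", "json"])
    def test_linker_round_trip_bit_identical(self, tmp_path, rng, ext):
        link = random_linker_model(rng, order=4)
        path = tmp_path / f"link.{ext}"
        write_model(link, path)
        back = read_model(path)
        assert np.array_equal(back.stationary, link.stationary)
        for a, b in zip(back.cond, link.cond):
            assert np.array_equal(a, b)

    def test_linker_length_round_trip(self, tmp_path, rng):
        pmf = rng.dirichlet(np.ones(50))
        dist = LinkerLengthDistribution(pmf)
        path = tmp_path / "fl.tsv"
        write_linker_length_distribution(dist, path)
        back = read_linker_length_distribution(path)
        assert np.array_equal(back.pmf, dist.pmf)


class TestInvariants:
    def test_model_validation_catches_bad_tables(self):
        with pytest.raises(ValueError):
            m.NucleosomeModel(order=1, init=(np.array([[0.5, 0.5, 0.5, 0.5]]),),
                              body=np.full((146, 4, 4), 0.25))

    def test_linker_distribution_validation(self):
        with pytest.raises(ValueError):
            LinkerLengthDistribution(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            LinkerLengthDistribution(np.array([1.5, -0.5]))

    def test_sampled_sequences_follow_the_tables(self, rng):
        # qN(G|.) = 1 everywhere -> every read is poly-G
        init = (np.array([[0.0, 0, 1.0, 0]]),)
        body = np.zeros((146, 4, 4))
        body[:, :, 2] = 1.0
        nuc = m.NucleosomeModel(order=1, init=init, body=body)
        assert nuc.sample(rng, 3) == ["G" * 147] * 3
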