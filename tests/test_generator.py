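"""Codon Markov model fitting and the temperature/top-k/top-p sampler."""

import pytest

from seqtriage import (
    CodingSequence,
    CodonMarkovModel,
    SamplingConfig,
    fit_codon_markov,
    sample_many,
    sample_sequence,
)
from seqtriage.generator import END_TOKEN, _truncated_distribution

from oracles import tally_ngrams


def cds(dna, seq_id="s"):
    return CodingSequence(seq_id, dna)


class TestFit:
    def test_single_path_corpus(self):
        model = fit_codon_markov([cds("ATGAAATAA")], order=1)
        assert model.probabilities(("ATG",)) == {"AAA": 1.0}
        assert model.probabilities(("AAA",)) == {"TAA": 1.0}

    def test_copies_scale_counts_not_probabilities(self):
        one = fit_codon_markov([cds("ATGAAATAA")], order=1)
        many = fit_codon_markov([cds("ATGAAATAA", f"s{i}") for i in range(5)], order=1)
        for ctx in one.transition_counts:
            assert many.probabilities(ctx) == one.probabilities(ctx)
            assert sum(many.transition_counts[ctx].values()) == 5 * sum(
                one.transition_counts[ctx].values()
            )

    def test_counts_equal_hand_tally(self):
        # two sequences sharing the ATG context; stop codon ends the first,
        # the second ends without one and records the end token
        corpus = [cds("ATGAAAGGGTAA", "a"), cds("ATGAAACCC", "b")]
        model = fit_codon_markov(corpus, order=1)
        expected = tally_ngrams(
            [["ATG", "AAA", "GGG", "TAA"], ["ATG", "AAA", "CCC", END_TOKEN]], order=1
        )
        assert model.transition_counts == expected
        assert model.probabilities(("AAA",)) == {"GGG": 0.5, "CCC": 0.5}

    def test_empty_corpus_and_negative_order_error(self):
        with pytest.raises(ValueError):
            fit_codon_markov([], order=1)
        with pytest.raises(ValueError):
            CodonMarkovModel(order=-1)

    def test_stop_codon_truncates_training_sequence(self):
        model = fit_codon_markov([cds("ATGTAAGGG")], order=1)
        # GGG lies after the stop and must not be tallied
        assert ("TAA",) not in model.transition_counts
        assert model.probabilities(("ATG",)) == {"TAA": 1.0}


class TestSampling:
    def test_deterministic_model_reproduces_training_sequence(self):
        model = fit_codon_markov([cds("ATGAAAGGGTGCTAA")], order=1)
        for seed in (0, 1, 99):
            out = sample_sequence(model, SamplingConfig(seed=seed))
            assert out.dna == "ATGAAAGGGTGCTAA"

    def test_greedy_top_k1_is_seed_independent(self):
        corpus = [cds("ATGAAAGGGTAA", "a"), cds("ATGAAACCCTAA", "b"), cds("ATGAAACCCTAA", "c")]
        model = fit_codon_markov(corpus, order=1)
        outs = {
            sample_sequence(model, SamplingConfig(top_k=1, seed=s)).dna
            for s in range(5)
        }
        assert outs == {"ATGAAACCCTAA"}  # CCC outweighs GGG after AAA

    def test_seeded_determinism(self):
        model = fit_codon_markov(
            [cds("ATGAAAGGGTAA", "a"), cds("ATGCCCGGGTAA", "b")], order=1
        )
        cfg = SamplingConfig(seed=7)
        assert sample_sequence(model, cfg).dna == sample_sequence(model, cfg).dna

    def test_output_begins_with_prompt_and_respects_max(self):
        # loop-y model without stop codons: generation must hit max_codons
        model = fit_codon_markov([cds("ATGAAAATGAAAATGAAA")], order=1)
        out = sample_sequence(model, SamplingConfig(max_codons=8, top_p=1.0, seed=3))
        assert out.dna.startswith("ATG")
        assert len(out.codons) <= 8

    def test_backoff_to_unconditional_distribution(self):
        model = fit_codon_markov([cds("ATGAAATAA")], order=2)
        # prompt GGG was never seen: back off to shorter contexts
        out = sample_sequence(model, SamplingConfig(prompt="GGG", seed=0))
        assert out.dna.startswith("GGG")

    def test_unfitted_model_errors_with_context(self):
        model = CodonMarkovModel(order=1)
        with pytest.raises(KeyError, match="context"):
            sample_sequence(model, SamplingConfig(seed=0))


class TestTruncation:
    def test_distribution_normalized_and_supported_on_top_k(self):
        probs = {c: p for c, p in zip(["AAA", "AAC", "AAG", "AAT", "ACA"], [0.4, 0.3, 0.15, 0.1, 0.05])}
        for k in (1, 2, 3, 5):
            toks, p = _truncated_distribution(probs, SamplingConfig(top_k=k, top_p=1.0))
            assert len(toks) <= k
            assert p.sum() == pytest.approx(1.0)

    def test_nucleus_keeps_smallest_prefix(self):
        probs = {"AAA": 0.5, "AAC": 0.3, "AAG": 0.2}
        toks, p = _truncated_distribution(probs, SamplingConfig(top_p=0.5))
        assert toks == ["AAA"] and p[0] == pytest.approx(1.0)
        toks, _ = _truncated_distribution(probs, SamplingConfig(top_p=0.75))
        assert toks == ["AAA", "AAC"]

    def test_probability_ties_broken_lexicographically(self):
        probs = {"CCC": 0.25, "AAA": 0.25, "BBB": 0.25, "DDD": 0.25}  # tokens sorted
        toks, _ = _truncated_distribution(probs, SamplingConfig(top_k=2, top_p=1.0))
        assert toks == ["AAA", "BBB"]

    def test_temperature_sharpens_and_flattens(self):
        probs = {"AAA": 0.7, "AAC": 0.3}
        _, cold = _truncated_distribution(probs, SamplingConfig(temperature=0.25, top_p=1.0))
        _, hot = _truncated_distribution(probs, SamplingConfig(temperature=4.0, top_p=1.0))
        assert cold[0] > 0.7 > hot[0] > 0.5


class TestRoundTrip:
    def test_tsv_serialization_roundtrip(self, tmp_path):
        model = fit_codon_markov(
            [cds("ATGAAAGGGTAA", "a"), cds("ATGCCC", "b")], order=1
        )
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = CodonMarkovModel.from_tsv(path)
        assert back.order == model.order
        assert back.transition_counts == model.transition_counts

    def test_parameter_recovery_smoke(self):
        """Refit from 1500 samples recovers order-1 probabilities within 3
        standard errors (the acceptance suite runs 10,000 samples)."""
        base = fit_codon_markov(
            [
                cds("ATGAAAGGGAAATGCTAA", "a"),
                cds("ATGAAATGCGGGTAA", "b"),
                cds("ATGGGGAAAGGGTGCTAA", "c"),
            ],
            order=1,
        )
        cfg = SamplingConfig(top_p=1.0, top_k=64, seed=11)
        samples = sample_many(base, cfg, 1500)
        refit = fit_codon_markov(samples, order=1)
        for ctx in base.transition_counts:
            if len(ctx) != 1:
                continue
            n = sum(refit.transition_counts.get(ctx, {}).values())
            if n < 30:
                continue
            probs = base.probabilities(ctx)
            refit_probs = refit.probabilities(ctx)
            for tok, p in probs.items():
                se = max((p * (1 - p) / n) ** 0.5, 1e-6)
                assert abs(refit_probs.get(tok, 0.0) - p) <= 3 * se + 1e-9
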