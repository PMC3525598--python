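"""Synthetic generators vs their closed-form expectations."""

import io

import pytest

from inframe import (
    ConstraintError,
    ConstructDesign,
    FrequencyModel,
    LengthDistribution,
    Outcome,
    analyze_utr,
    capture_probability,
    classify_context,
    default_kozak_model,
    expected_summary,
    first_stop_codon_index,
    gen_kozak_contexts,
    gen_transcripts,
    gen_utr_db,
    predict_expression,
    summarize,
    write_fasta,
)
from inframe.synthetic_data import VARIABLE_KOZAK_COORDS, parse_length_spec

from conftest import within_3se


class TestLengthDistribution:
    def test_pmf_items_sum_to_one(self):
        for dist in (
            LengthDistribution.uniform(1, 300),
            LengthDistribution.fixed(90),
            LengthDistribution.empirical([5, 5, 8]),
        ):
            items = list(dist.pmf_items())
            assert sum(p for _, p in items) == pytest.approx(1.0)
            assert all(length >= 1 for length, _ in items)

    def test_empirical_weights_duplicates(self):
        items = dict(LengthDistribution.empirical([5, 5, 8]).pmf_items())
        assert items[5] == pytest.approx(2 / 3)

    @pytest.mark.parametrize(
        "spec,expected",
        [
            ("uniform:1:300", LengthDistribution.uniform(1, 300)),
            ("fixed:90", LengthDistribution.fixed(90)),
            ("empirical:5,5,8", LengthDistribution.empirical([5, 5, 8])),
        ],
    )
    def test_parse_spec(self, spec, expected):
        assert parse_length_spec(spec) == expected

    @pytest.mark.parametrize("bad", ["gaussian:3", "uniform:5:2", "fixed:0", "fixed:x"])
    def test_bad_specs_rejected(self, bad):
        with pytest.raises(ConstraintError):
            parse_length_spec(bad)


class TestFrequencyModel:
    def test_distributions_must_sum_to_one(self):
        with pytest.raises(ConstraintError):
            FrequencyModel(base_freqs={"A": 0.5, "C": 0.5, "G": 0.1, "T": 0.0})

    def test_p_stop_uniform(self):
        assert FrequencyModel().p_stop_codon() == pytest.approx(3 / 64)

    def test_default_kozak_model_quotes_positions(self):
        m = default_kozak_model()
        assert m.kozak_position_freqs[-12] == {"A": 0.23, "C": 0.35, "G": 0.23, "T": 0.19}
        assert m.kozak_position_freqs[-4] == {"A": 0.25, "C": 0.53, "G": 0.15, "T": 0.07}

    def test_position_table_keys_restricted(self):
        with pytest.raises(ConstraintError):
            FrequencyModel(kozak_position_freqs={1: {"A": 1.0}})  # +1 is fixed ATG


class TestExpectedSummary:
    def test_fixed_length_3_uniform(self):
        e = expected_summary(LengthDistribution.fixed(3))
        assert e.p_stop_codon == pytest.approx(3 / 64)
        assert e.frac_frameshift == 0.0
        assert e.frac_stop == pytest.approx(3 / 64)
        assert e.frac_correct == pytest.approx(61 / 64)

    def test_all_lengths_one_mod_three(self):
        e = expected_summary(LengthDistribution.empirical([1, 4, 7]))
        assert e.frac_frameshift == 1.0
        assert e.frac_correct == 0.0

    def test_uniform_lengths_one_to_three(self):
        e = expected_summary(LengthDistribution.empirical([1, 2, 3]))
        assert e.frac_frameshift == pytest.approx(2 / 3)
        assert e.frac_stop == pytest.approx(1 / 64)
        assert e.frac_correct == pytest.approx(61 / 192)

    @pytest.mark.parametrize("k", [1, 4, 100])
    def test_uniform_grid_frameshift_is_two_thirds(self, k):
        e = expected_summary(LengthDistribution.uniform(1, 3 * k))
        assert e.frac_frameshift == pytest.approx(2 / 3)


class TestGenUtrDb:
    def test_zero_records(self):
        assert gen_utr_db(0, LengthDistribution.fixed(10), seed=1) == []

    def test_seeded_determinism_byte_identical(self):
        a, b = io.StringIO(), io.StringIO()
        for buf in (a, b):
            write_fasta(
                gen_utr_db(50, LengthDistribution.uniform(1, 40), seed=99), buf
            )
        assert a.getvalue() == b.getvalue()
        c = io.StringIO()
        write_fasta(gen_utr_db(50, LengthDistribution.uniform(1, 40), seed=100), c)
        assert a.getvalue() != c.getvalue()

    def test_lengths_respect_distribution_support(self):
        records = gen_utr_db(200, LengthDistribution.empirical([5, 8]), seed=3)
        assert {len(r) for r in records} <= {5, 8}

    def test_composition_bias_shows_up(self):
        model = FrequencyModel(base_freqs={"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1})
        records = gen_utr_db(100, LengthDistribution.fixed(100), model, seed=4)
        frac_a = sum(r.bases.count("A") for r in records) / 10_000
        assert within_3se(frac_a, 0.7, 10_000)


class TestSimulationVsClosedForm:
    """summarize() on generated databases recovers expected_summary."""

    N = 30_000

    SETTINGS = [
        ("uniform-1-300", 101, LengthDistribution.uniform(1, 300), FrequencyModel()),
        ("fixed-3", 102, LengthDistribution.fixed(3), FrequencyModel()),
        (
            "at-rich",
            103,
            LengthDistribution.uniform(10, 100),
            FrequencyModel(base_freqs={"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}),
        ),
        (
            "gc-rich",
            104,
            LengthDistribution.uniform(30, 200),
            FrequencyModel(base_freqs={"A": 0.1, "C": 0.4, "G": 0.4, "T": 0.1}),
        ),
        (
            "frame-neutral-lengths",
            105,
            LengthDistribution.empirical([9, 30, 60]),
            FrequencyModel(base_freqs={"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}),
        ),
    ]

    @pytest.mark.parametrize(
        "name,seed,lengths,model", SETTINGS, ids=[s[0] for s in SETTINGS]
    )
    def test_fractions_within_3se(self, name, seed, lengths, model):
        records = gen_utr_db(self.N, lengths, model, seed=seed)
        s = summarize(records)
        e = expected_summary(lengths, model)
        assert within_3se(s.frac_frameshift, e.frac_frameshift, self.N)
        assert within_3se(s.frac_stop, e.frac_stop, self.N)
        assert within_3se(s.frac_correct, e.frac_correct, self.N)


class TestKozakContexts:
    def test_requires_position_table(self):
        with pytest.raises(ConstraintError):
            gen_kozak_contexts(5, FrequencyModel(), seed=0)

    def test_atg_fixed_and_deterministic(self):
        a = gen_kozak_contexts(100, seed=5)
        b = gen_kozak_contexts(100, seed=5)
        assert a == b
        assert all(c.window[12:15] == "ATG" for c in a)

    def test_point_mass_on_primer1_context(self, primer_set):
        target = "CCCGCCGCCACCATGG"
        freqs = {
            coord: {target[i]: 1.0}
            for coord, i in zip(VARIABLE_KOZAK_COORDS, list(range(12)) + [15])
        }
        model = FrequencyModel(kozak_position_freqs=freqs)
        for ctx in gen_kozak_contexts(20, model, seed=6):
            assert classify_context(primer_set, ctx) == ["primer_1"]

    def test_marginals_recover_position_table(self):
        n = 10_000
        model = default_kozak_model()
        contexts = gen_kozak_contexts(n, model, seed=7)
        col = [c.window[0] for c in contexts]  # Kozak -12
        for base, expected in model.kozak_position_freqs[-12].items():
            assert within_3se(col.count(base) / n, expected, n)


class TestCaptureProbability:
    def test_pyrimidine_at_minus3_gives_zero(self, primer_set):
        model = FrequencyModel(kozak_position_freqs={-3: {"C": 1.0}})
        assert capture_probability(primer_set, model) == pytest.approx(0.0)
        model_t = FrequencyModel(kozak_position_freqs={-3: {"T": 1.0}})
        assert capture_probability(primer_set, model_t) == pytest.approx(0.0)

    def test_uniform_model_equals_union_count_over_4_to_13(self, primer_set):
        # under uniform contexts every 16-mer with fixed ATG is equally
        # likely: capture prob = |union| / 4^13
        expected = 177_149 / 4**13
        assert capture_probability(primer_set, FrequencyModel(
            kozak_position_freqs={-12: {b: 0.25 for b in "ACGT"}}
        )) == pytest.approx(expected)

    def test_simulated_capture_within_3se_of_exact(self, primer_set):
        n = 10_000
        model = default_kozak_model()
        exact = capture_probability(primer_set, model)
        contexts = gen_kozak_contexts(n, model, seed=8)
        observed = sum(
            bool(classify_context(primer_set, c)) for c in contexts
        ) / n
        assert within_3se(observed, exact, n)


class TestGenTranscripts:
    UTR = LengthDistribution.uniform(12, 60)
    CDS = LengthDistribution.fixed(30)

    def test_structure_and_stop_freedom(self):
        txs = gen_transcripts(50, self.UTR, self.CDS, seed=9)
        for t in txs:
            assert t.cds.bases.startswith("ATG")
            assert t.cds[-3:] in {"TAA", "TAG", "TGA"}
            assert first_stop_codon_index(t.cds[:-3], 0) is None
            assert t.utr[-12:] == t.context.window[:12]
            assert t.cds[3] == t.context.window[15]
            assert t.full.bases == t.utr.bases + t.cds.bases

    def test_seeded_determinism(self):
        a = gen_transcripts(20, self.UTR, self.CDS, seed=10)
        b = gen_transcripts(20, self.UTR, self.CDS, seed=10)
        assert a == b

    def test_invalid_cds_lengths_rejected(self):
        with pytest.raises(ConstraintError):
            gen_transcripts(5, self.UTR, LengthDistribution.fixed(31), seed=0)
        with pytest.raises(ConstraintError):
            gen_transcripts(5, LengthDistribution.fixed(5), self.CDS, seed=0)

    def test_stop_free_neutral_utrs_give_full_length_fusions(self):
        txs = gen_transcripts(
            30,
            LengthDistribution.empirical([12, 24, 48]),
            self.CDS,
            seed=11,
            utr_stop_free=True,
        )
        for t in txs:
            assert analyze_utr(t.utr).correct
            d = ConstructDesign(
                tag_cds="ATGGGA", insert_utr=t.utr, insert_cds=t.cds
            )
            assert predict_expression(d).outcome is Outcome.FULL_LENGTH_FUSION
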