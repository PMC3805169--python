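"""Grammar enumeration, exact conditionals and the sentence generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mandarin_rc.grammar import (
    CATEGORY_UNITS,
    Category,
    GrammarSpec,
    UNIT_CATEGORY,
    UngrammaticalPrefixError,
    VOCABULARY,
    Corpus,
    enumerate_templates,
    generate_corpus,
    sample_category_sequence,
    sample_sentence,
)

C = Category


class TestVocabularyLayout:
    def test_28_units_partition_into_six_categories(self):
        sizes = {c: len(u) for c, u in CATEGORY_UNITS.items()}
        assert sizes == {C.ANI_N: 7, C.INA_N: 7, C.VT: 6, C.VI: 6, C.DE: 1, C.EOS: 1}
        assert len(VOCABULARY) == 28
        assert len(set(VOCABULARY)) == 28
        # every unit belongs to exactly one category
        assert sorted(i for u in CATEGORY_UNITS.values() for i in u) == list(range(28))
        assert all(i in CATEGORY_UNITS[UNIT_CATEGORY[i]] for i in range(28))


class TestGrammarSpec:
    def test_default_splits_are_valid(self, grammar):
        grammar.validate()

    @pytest.mark.parametrize("field,value", [
        ("p_subject", {"overt": 0.8, "prodrop": 0.3}),
        ("subject_np", {"ani": 0.5, "ina": 0.34, "rc": 0.3}),
        ("p_vp", {"vi": -0.1, "vt": 1.1}),
    ])
    def test_invalid_splits_rejected(self, field, value):
        with pytest.raises(ValueError):
            GrammarSpec(**{field: value})

    def test_yaml_round_trip(self, grammar, tmp_path):
        path = tmp_path / "grammar.yml"
        grammar.to_yaml(path)
        loaded = GrammarSpec.from_yaml(path)
        assert loaded == grammar
        assert loaded.hash() == grammar.hash()

    def test_structural_variant_touches_only_zero_cells(self, grammar):
        sv = grammar.structural_variant(1e-9)
        assert sv.orc_head["subject"]["ina"]["ani"] > 0
        assert sv.orc_head["object"]["ina"]["ani"] > 0
        assert sv.src_head == grammar.src_head
        assert sv.p_subject == grammar.p_subject


class TestEnumeration:
    def test_probabilities_sum_to_one(self, templates):
        assert sum(t.probability for t in templates) == pytest.approx(1.0, abs=1e-9)

    def test_category_patterns_are_unique_and_end_in_eos(self, templates):
        seqs = [t.categories for t in templates]
        assert len(seqs) == len(set(seqs))
        assert all(s[-1] is C.EOS for s in seqs)
        assert all(C.EOS not in s[:-1] for s in seqs)

    def test_impossible_animacy_patterns_absent(self, templates):
        """An ORC with an inanimate embedded noun never has an animate head."""
        for t in templates:
            for rc in (t.subject_rc, t.object_rc):
                if rc is not None and rc.rc_type == "ORC" and rc.embedded_animacy == "ina":
                    assert rc.head_animacy == "ina"

    def test_no_rc_nested_inside_an_rc(self, templates):
        """DE appears once per RC, immediately before the head; at most one RC
        per matrix position."""
        for t in templates:
            n_de = sum(1 for c in t.categories if c is C.DE)
            n_rc = (t.subject_rc is not None) + (t.object_rc is not None)
            assert n_de == n_rc
            for rc in (t.subject_rc, t.object_rc):
                if rc is not None:
                    assert t.categories[rc.de_index] is C.DE
                    assert t.categories[rc.head_index] in (C.ANI_N, C.INA_N)
                    assert rc.head_index == rc.de_index + 1

    def test_template_set_equals_sampling_oracle(self, grammar, templates):
        """Brute force: the distinct category strings in 10^6 generative
        samples are exactly the enumerated patterns."""
        rng = np.random.default_rng(123_457)
        sampled = set()
        for _ in range(1_000_000):
            sampled.add(sample_category_sequence(grammar, rng))
        assert sampled == {t.categories for t in templates}


class TestPrefixMass:
    """Exact prefix masses against hand-derived products of the grammar."""

    def test_printed_subject_part_derivations(self, templates):
        # subject-modifying intransitive SRC with animate head:
        # 0.7 * 0.16 * 0.11 * 0.2 ~ 0.0025
        m = templates.mass(
            lambda t: t.subject_rc is not None
            and t.subject_rc.rc_type == "SRC_VI"
            and t.subject_rc.head_animacy == "ani"
        )
        assert m == pytest.approx(0.7 * 0.16 * 0.11 * 0.2)
        assert round(m, 4) == 0.0025
        # pro-drop transitive: 0.3 * 0.79 ~ 0.24
        m = templates.mass(lambda t: t.subject_kind == "prodrop" and t.vp_kind == "vt")
        assert round(m, 2) == 0.24
        # subject-modifying transitive SRC: 0.7 * 0.16 * 0.58 ~ 0.065
        m = templates.mass(
            lambda t: t.subject_rc is not None and t.subject_rc.rc_type == "SRC"
        )
        assert round(m, 3) == 0.065

    def test_sentence_initial_vt_mass(self, templates):
        assert round(templates.prefix_mass([C.VT]), 2) == 0.30

    def test_bare_subject_family_masses(self, templates):
        """Sentence-initial bare-noun subject masses; the full prefix masses
        additionally include ORC-initial embedded nouns."""
        ani = templates.mass(lambda t: t.subject_kind == "ani")
        ina = templates.mass(lambda t: t.subject_kind == "ina")
        assert ani == pytest.approx(0.35)
        assert round(100 * ina, 1) == 23.8
        assert templates.prefix_mass([C.ANI_N]) > ani
        assert templates.prefix_mass([C.INA_N]) > ina

    def test_prefix_matching_no_template_has_zero_mass(self, templates):
        assert templates.prefix_mass([C.DE]) == 0
        assert templates.prefix_mass([C.EOS]) == 0
        assert templates.prefix_mass([C.VI, C.VI]) == 0

    def test_mass_conservation_over_continuations(self, templates):
        """For any proper prefix, continuation masses sum to the prefix mass."""
        for t in templates:
            for n in range(len(t.categories)):
                prefix = t.categories[:n]
                total = sum(
                    templates.prefix_mass(prefix + (c,)) for c in Category
                )
                assert total == pytest.approx(templates.prefix_mass(prefix), abs=1e-12)


class TestNextCategoryDistribution:
    def test_distributions_are_normalised(self, templates):
        for prefix in [(), (C.VT,), (C.ANI_N,), (C.VT, C.ANI_N, C.DE)]:
            dist = templates.next_category_distribution(prefix)
            assert sum(dist.values()) == pytest.approx(1.0)
            assert all(p >= 0 for p in dist.values())

    def test_intransitive_vp_forces_end_of_sentence(self, templates):
        dist = templates.next_category_distribution([C.ANI_N, C.VI])
        assert dist[C.EOS] == pytest.approx(1.0)

    def test_zero_mass_prefix_raises_with_first_bad_position(self, templates):
        with pytest.raises(UngrammaticalPrefixError) as err:
            templates.next_category_distribution([C.ANI_N, C.DE])
        assert err.value.first_bad == 1
        with pytest.raises(UngrammaticalPrefixError) as err:
            templates.next_category_distribution(
                [C.INA_N, C.VT, C.DE, C.ANI_N]  # impossible animate ORC head
            )
        assert err.value.first_bad == 3

    def test_conditionals_match_monte_carlo(self, grammar, templates):
        """Exact conditionals agree with relative frequencies in 300k
        generative samples for every prefix of length <= 4 with mass >=
        0.005 (within 4 standard errors; seeded)."""
        rng = np.random.default_rng(424_242)
        n = 300_000
        counts: dict[tuple, int] = {}
        for _ in range(n):
            seq = sample_category_sequence(grammar, rng)
            for k in range(1, min(len(seq), 5) + 1):
                key = seq[:k]
                counts[key] = counts.get(key, 0) + 1
        checked = 0
        for t in templates:
            for k in range(1, min(len(t.categories), 4)):
                prefix = t.categories[:k]
                mass = templates.prefix_mass(prefix)
                if mass < 0.005:
                    continue
                n_prefix = counts.get(prefix, 0)
                dist = templates.next_category_distribution(prefix)
                for c, p in dist.items():
                    n_cont = counts.get(prefix + (c,), 0)
                    se = np.sqrt(max(p * (1 - p), 1e-12) / n_prefix)
                    assert abs(n_cont / n_prefix - p) <= 4 * se + 1e-9, (
                        prefix, c, p, n_cont / n_prefix
                    )
                    checked += 1
        assert checked > 100

    def test_locality_of_productions(self, templates):
        """Changing the object-NP split must not affect conditionals for
        prefixes that never reach an object position."""
        modified = GrammarSpec(object_np={"ani": 0.5, "ina": 0.4, "rc": 0.1})
        other = enumerate_templates(modified)
        for prefix in [(), (C.VT, C.ANI_N, C.DE), (C.INA_N,), (C.VI, C.DE)]:
            a = enumerate_templates(GrammarSpec()).next_category_distribution(prefix)
            b = other.next_category_distribution(prefix)
            for c in Category:
                assert a[c] == pytest.approx(b[c], abs=1e-12)


class TestSampling:
    def test_sampling_is_deterministic_given_seed(self, grammar, templates):
        a = [sample_sentence(grammar, np.random.default_rng(5), templates) for _ in range(20)]
        b = [sample_sentence(grammar, np.random.default_rng(5), templates) for _ in range(20)]
        assert [s.tokens for s in a] == [s.tokens for s in b]

    def test_degenerate_grammar_forces_single_template(self):
        """All probability mass on one pattern: pro-drop intransitive."""
        g = GrammarSpec(p_subject={"overt": 0.0, "prodrop": 1.0},
                        p_vp={"vi": 1.0, "vt": 0.0})
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert sample_category_sequence(g, rng) == (C.VI, C.EOS)

    def test_prodrop_rate_matches_grammar(self, grammar, templates):
        n = 30_000
        rng = np.random.default_rng(78)
        prodrop = 0
        ts = templates
        for _ in range(n):
            seq = sample_category_sequence(grammar, rng)
            if ts.lookup(seq).subject_kind == "prodrop":
                prodrop += 1
        p = grammar.p_subject["prodrop"]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(prodrop / n - p) < 3 * se

    def test_words_uniform_within_category(self, grammar):
        rng = np.random.default_rng(99)
        corpus = generate_corpus(grammar, 20_000, 13)
        counts = np.zeros(28, int)
        for s in corpus:
            for tok in s.tokens:
                counts[tok] += 1
        for cat, units in CATEGORY_UNITS.items():
            if len(units) == 1:
                continue
            obs = counts[list(units)]
            assert stats.chisquare(obs).pvalue > 0.001, cat


class TestCorpus:
    def test_generate_corpus_is_reproducible(self, grammar):
        a = generate_corpus(grammar, 200, seed=3)
        b = generate_corpus(grammar, 200, seed=3)
        assert [s.tokens for s in a] == [s.tokens for s in b]
        c = generate_corpus(grammar, 200, seed=4)
        assert [s.tokens for s in a] != [s.tokens for s in c]

    def test_invalid_size_rejected(self, grammar):
        with pytest.raises(ValueError):
            generate_corpus(grammar, 0, seed=1)

    def test_write_read_round_trip(self, grammar, templates, tmp_path):
        corpus = generate_corpus(grammar, 100, seed=8, templates=templates)
        path = tmp_path / "corpus.txt"
        corpus.write(path)
        loaded = Corpus.read(path, templates=templates)
        assert [s.tokens for s in loaded] == [s.tokens for s in corpus]
        assert loaded.grammar_hash == grammar.hash()
        assert loaded.seed == 8
        assert loaded.sentences[0].template is corpus.sentences[0].template

    def test_corpus_lines_are_vocabulary_words(self, grammar, tmp_path):
        corpus = generate_corpus(grammar, 20, seed=2)
        path = tmp_path / "c.txt"
        corpus.write(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("#")
        vocab = set(VOCABULARY)
        for line in lines[1:]:
            words = line.split()
            assert words[-1] == "EOS"
            assert set(words) <= vocab


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_sampled_sentences_always_grammatical(seed):
    """Every generated sentence has a positive-probability template and its
    tokens map back to the template's categories."""
    g = GrammarSpec()
    ts = enumerate_templates(g)
    s = sample_sentence(g, np.random.default_rng(seed), ts)
    assert s.template is not None
    assert s.categories == s.template.categories
    assert ts.prefix_mass(s.categories) == pytest.approx(s.template.probability)
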