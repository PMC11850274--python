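"""Lexicon loading, proportion profiles, t-tests and correlation word sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stylegauge.lexicon_analytics import (
    DEFAULT_SET_MAPPING,
    Lexicon,
    build_word_sets,
    category_proportions,
    compare_groups,
    gender_difference_table,
    group_tables,
    load_lexicon,
    set_representation,
    whitespace_tokenize,
    char_unigram_tokenize,
)

from conftest import make_post


class TestLoadLexicon:
    def test_tsv_parse_and_sizes(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("happy\t佳\nhappy\t笑\nsad\t哭\n", encoding="utf-8")
        lex = load_lexicon(str(p))
        assert set(lex.categories) == {"happy", "sad"}
        assert len(lex.categories["happy"]) == 2
        assert len(lex.categories["sad"]) == 1

    def test_duplicates_removed(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("a\tx\na\tx\na\ty\n")
        assert len(load_lexicon(str(p)).categories["a"]) == 2

    def test_json_format(self, tmp_path):
        p = tmp_path / "lex.json"
        p.write_text('{"a": ["x", "y"], "b": ["z"]}')
        lex = load_lexicon(str(p))
        assert lex.categories["a"] == frozenset({"x", "y"})

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="no categories"):
            load_lexicon(str(p))

    def test_unknown_format_errors(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("a\tx\n")
        with pytest.raises(ValueError, match="unknown lexicon format"):
            load_lexicon(str(p), fmt="xml")

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Lexicon("bad", {"a": frozenset()})


class TestCategoryProportions:
    def test_basic_fraction(self):
        lex = Lexicon("l", {"X": frozenset({"A"})})
        prof = category_proportions([make_post("A A B")], lex)
        assert prof.proportions["X"] == pytest.approx(100 * 2 / 3)

    def test_no_matches(self):
        lex = Lexicon("l", {"X": frozenset({"Z"})})
        prof = category_proportions([make_post("A B")], lex)
        assert prof.proportions["X"] == 0.0

    def test_overlapping_categories_independent(self):
        lex = Lexicon("l", {"X": frozenset({"A"}), "Y": frozenset({"A", "B"})})
        prof = category_proportions([make_post("A B")], lex)
        assert prof.proportions["X"] == 50.0
        assert prof.proportions["Y"] == 100.0

    def test_order_and_concatenation_invariance(self):
        lex = Lexicon("l", {"X": frozenset({"A"})})
        posts = [make_post("A B", 0), make_post("B B A A", 1)]
        a = category_proportions(posts, lex).proportions
        b = category_proportions(posts[::-1], lex).proportions
        c = category_proportions([make_post("A B B B A A")], lex).proportions
        assert a == b == c

    def test_zero_tokens_error(self):
        lex = Lexicon("l", {"X": frozenset({"A"})})
        with pytest.raises(ValueError):
            category_proportions([], lex)

    def test_wildcard_prefix_matching(self):
        lex = Lexicon("l", {"X": frozenset({"happ*"})})
        prof = category_proportions(
            [make_post("happy happiness sad")], lex, wildcards=True
        )
        assert prof.proportions["X"] == pytest.approx(100 * 2 / 3)

    def test_char_unigram_tokenizer(self):
        lex = Lexicon("l", {"X": frozenset({"哭"})})
        prof = category_proportions(
            [make_post("哭了哭")], lex, tokenizer=char_unigram_tokenize
        )
        assert prof.n_tokens == 3
        assert prof.proportions["X"] == pytest.approx(100 * 2 / 3)


class TestCompareGroups:
    def test_identical_groups(self):
        c = compare_groups([1, 2, 3], [1, 2, 3])
        assert c.t == 0.0 and c.p == 1.0

    def test_zero_variance_distinct_means(self):
        c = compare_groups([0, 0, 0, 0], [1, 1, 1, 1])
        assert np.isinf(c.t) and c.t < 0 and c.p == 0.0

    def test_hand_computed_pooled_t(self):
        # means 3 vs 2, each sample variance 2, pooled sp^2 = 2,
        # se = sqrt(2*(1/2+1/2)) = sqrt(2)  ->  t = 1/sqrt(2)
        c = compare_groups([2, 4], [1, 3])
        assert c.mean_diff == pytest.approx(1.0)
        assert c.t == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_definition(self, a, b):
        """Pooled t from the textbook formula to 1e-10."""
        a, b = np.array(a), np.array(b)
        sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((len(a) - 1) * sa2 + (len(b) - 1) * sb2) / (len(a) + len(b) - 2)
        if sp2 < 1e-12:
            return
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        c = compare_groups(a, b)
        assert c.t == pytest.approx(expected, abs=1e-10)

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1, 2, 3])

    def test_welch_flag(self):
        a, b = [1.0, 2, 3, 9], [1.0, 1.1, 0.9, 1.2, 0.8]
        t_welch = compare_groups(a, b, welch=True).t
        expected = stats.ttest_ind(a, b, equal_var=False).statistic
        assert t_welch == pytest.approx(float(expected))


def _profiles(values, cat="sad"):
    from stylegauge.lexicon_analytics import ProportionProfile

    return [
        ProportionProfile(user_id=f"u{i}", proportions={cat: v}, n_tokens=100)
        for i, v in enumerate(values)
    ]


class TestGroupTables:
    def test_max_flag_on_larger_group(self):
        tables = group_tables(
            {"neg": _profiles([5.0, 6.0, 7.0]), "pos": _profiles([1.0, 2.0, 1.5])}
        )
        assert tables["max_group"]["sad"] == "neg"
        assert tables["max_vs_runner_up"]["sad"].p < 0.05

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            group_tables({"only": _profiles([1.0, 2.0])})

    def test_empty_group_warned_and_dropped(self):
        tables = group_tables(
            {"a": _profiles([1.0, 2.0]), "b": _profiles([3.0, 4.0]), "c": []}
        )
        assert tables["warnings"] == ["c"]

    def test_gender_strata_rows(self):
        tables = group_tables(
            {"a": _profiles([1.0, 2.0]), "b": _profiles([3.0, 4.0])},
            genders_by_group={"a": ["male", "female"], "b": ["female", "female"]},
        )
        idx = tables["means"].index
        assert ("a", "male", 1) in idx and ("b", "#All", 2) in idx


class TestBuildWordSets:
    def test_disjoint_union(self):
        t = Lexicon("t", {"health": frozenset("abc"), "death": frozenset("de"),
                          "love": frozenset("f")})
        e = Lexicon("e", {"sad": frozenset("xy"), "fear": frozenset("z"),
                          "hate": frozenset("w")})
        bundle = build_word_sets(
            t, e, {"T_n": ("health", "death", "love"), "E_n": ("sad", "fear", "hate")}
        )
        assert bundle.sizes() == {"T_n": 6, "E_n": 4}

    def test_published_emotion_set_sizes(self):
        """Synthetic lexicons at the printed category sizes reproduce the
        published emotion-set cardinalities exactly."""
        sizes = {"happy": 1967, "like": 11108, "surprise": 228, "angry": 388,
                 "sad": 2314, "fear": 1179, "hate": 10282}
        emo = Lexicon(
            "emo",
            {c: frozenset(f"{c}{i}" for i in range(n)) for c, n in sizes.items()},
        )
        topic = Lexicon("top", {c: frozenset({f"{c}_w"}) for c in
                                ("social", "family", "friend", "work", "leisure",
                                 "money", "psychology", "religion", "health",
                                 "death", "love")})
        bundle = build_word_sets(topic, emo)
        assert len(bundle.sets["E_p"]) == 2355    # happy + angry
        assert len(bundle.sets["E_m"]) == 11336   # like + surprise
        assert len(bundle.sets["E_n"]) == 13775   # sad + fear + hate

    def test_overlap_union_semantics(self):
        t = Lexicon("t", {"health": frozenset({"a", "b"}), "death": frozenset({"b", "c"}),
                          "love": frozenset({"c"})})
        e = Lexicon("e", {"sad": frozenset({"s"}), "fear": frozenset({"s"}),
                          "hate": frozenset({"h"})})
        bundle = build_word_sets(
            t, e, {"T_n": ("health", "death", "love"), "E_n": ("sad", "fear", "hate")}
        )
        assert len(bundle.sets["T_n"]) == 3
        assert len(bundle.sets["E_n"]) == 2

    def test_missing_category_errors(self):
        t = Lexicon("t", {"health": frozenset({"a"})})
        e = Lexicon("e", {"sad": frozenset({"s"})})
        with pytest.raises(ValueError, match="death"):
            build_word_sets(t, e, {"T_n": ("health", "death")})

    def test_default_mapping_covers_all_18_categories(self):
        cats = [c for cs in DEFAULT_SET_MAPPING.values() for c in cs]
        assert len(cats) == 18 and len(set(cats)) == 18


class TestSetRepresentation:
    embedder = staticmethod(lambda w: np.array([float(len(w)), float(ord(w[0]))]))

    def test_single_word(self):
        v = set_representation({"abc"}, self.embedder)
        assert np.allclose(v, [3.0, ord("a")])

    def test_mean_of_two(self):
        emb = {"p": np.array([0.0, 0.0]), "q": np.array([2.0, 4.0])}
        v = set_representation({"p", "q"}, lambda w: emb[w])
        assert np.allclose(v, [1.0, 2.0])

    def test_permutation_invariance_and_bounds(self):
        words = [f"w{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        emb = {w: rng.standard_normal(4) for w in words}
        v1 = set_representation(words, lambda w: emb[w])
        v2 = set_representation(words[::-1], lambda w: emb[w])
        assert np.allclose(v1, v2)
        mat = np.stack(list(emb.values()))
        assert np.all(v1 >= mat.min(axis=0)) and np.all(v1 <= mat.max(axis=0))

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            set_representation(set(), self.embedder)
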