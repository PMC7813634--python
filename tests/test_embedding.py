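"""Embedding backends, cosine neighborhoods, curation, model comparison."""

from __future__ import annotations

import numpy as np
import pytest

from opiomine.corpus import load_corpus, preprocess
from opiomine.embedding import (
    EmbeddingModel,
    LexiconExpansion,
    TrainingParams,
    accepted_percentage,
    apply_curation,
    build_candidate_set,
    compare_models,
    coverage_gain,
    semantic_neighborhood,
    train_embedding,
)
from opiomine.synth import SynonymClass, SyntheticSpec, generate_corpus, write_ndjson

from .conftest import make_corpus, make_post
from .oracles import cosine_neighbors_bruteforce

SYNONYM_CLASSES = tuple(
    SynonymClass(name=f"class{i}", terms=tuple(f"slang{i}{j}" for j in range(4)))
    for i in range(6)
)


def synonym_corpus(tmp_path, seed=7, n_windows=3000):
    spec = SyntheticSpec(
        seed=seed,
        n_authors=5,
        synonym_classes=SYNONYM_CLASSES,
        n_context_windows=n_windows,
    )
    lines, gt = generate_corpus(spec)
    path = tmp_path / "syn.ndjson"
    write_ndjson(lines, path)
    corpus = preprocess(load_corpus(path), min_lemma_freq=1)
    return corpus, gt


def toy_model():
    """Five terms with hand-set vectors; rankings computable by hand."""
    vectors = np.array(
        [
            [1.0, 0.0],   # alpha
            [0.9, 0.1],   # bravo
            [0.0, 1.0],   # charlie
            [-1.0, 0.0],  # delta
            [0.7, 0.7],   # echo
        ]
    )
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return EmbeddingModel(
        terms=["alpha", "bravo", "charlie", "delta", "echo"],
        vectors=vectors,
        params=TrainingParams(dim=2),
    )


class TestNeighborhood:
    def test_matches_bruteforce_on_toy_vectors(self):
        model = toy_model()
        for seed_term in model.terms:
            got = semantic_neighborhood(model, seed_term, n=4)
            want = cosine_neighbors_bruteforce(
                model.terms, model.vectors.tolist(), seed_term, 4
            )
            assert [t for t, _ in got] == [t for t, _ in want]
            np.testing.assert_allclose(
                [c for _, c in got], [c for _, c in want], atol=1e-12
            )

    def test_seed_excluded_and_exhaustive_n(self):
        model = toy_model()
        nb = semantic_neighborhood(model, "alpha", n=100)
        assert len(nb) == 4
        assert "alpha" not in {t for t, _ in nb}

    def test_cosines_non_increasing(self):
        nb = semantic_neighborhood(toy_model(), "echo", n=4)
        cosines = [c for _, c in nb]
        assert cosines == sorted(cosines, reverse=True)
        assert all(-1.0 - 1e-9 <= c <= 1.0 + 1e-9 for c in cosines)

    def test_unknown_seed_raises(self):
        with pytest.raises(KeyError, match="not in embedding vocabulary"):
            semantic_neighborhood(toy_model(), "zulu")


class TestTraining:
    @pytest.mark.parametrize("backend", ["svd", "sgns"])
    def test_deterministic_given_seed(self, tmp_path, backend):
        corpus, _ = synonym_corpus(tmp_path, n_windows=400)
        params = TrainingParams(backend=backend, dim=16, epochs=2, seed=3)
        m1 = train_embedding(corpus, params)
        m2 = train_embedding(corpus, params)
        assert m1.terms == m2.terms
        np.testing.assert_array_equal(m1.vectors, m2.vectors)

    def test_min_count_threshold(self):
        posts = [make_post(post_id=f"p{i}", body="common stuff common stuff rare.")
                 for i in range(3)]
        corpus = make_corpus(posts)
        model = train_embedding(corpus, TrainingParams(dim=2, min_count=4))
        assert "common" in model and "stuff" in model
        assert "rare" not in model

    def test_too_small_corpus_errors(self):
        corpus = make_corpus([make_post(body="lonely words here.")])
        with pytest.raises(ValueError, match="min_count"):
            train_embedding(corpus, TrainingParams(min_count=100))

    def test_planted_synonyms_beat_random_pairs(self, tmp_path):
        corpus, _ = synonym_corpus(tmp_path)
        model = train_embedding(corpus, TrainingParams(dim=30, min_count=5, seed=0))
        rng = np.random.default_rng(0)
        n = len(model.terms)
        random_cos = [
            float(model.vectors[i] @ model.vectors[j])
            for i, j in rng.integers(0, n, size=(1000, 2))
            if i != j
        ]
        threshold = np.percentile(random_cos, 95)
        syn_cos = float(model.vector("slang00") @ model.vector("slang01"))
        assert syn_cos > threshold


class TestSynonymRecovery:
    def test_planted_synonyms_in_top20_neighborhood(self, tmp_path):
        corpus, gt = synonym_corpus(tmp_path)
        model = train_embedding(corpus, TrainingParams(dim=30, min_count=5, seed=0))
        for sc in gt.spec.synonym_classes:
            seed_term = sc.terms[0]
            nb = {t for t, _ in semantic_neighborhood(model, seed_term, n=20)}
            planted = set(sc.terms) - {seed_term}
            recovered = len(planted & nb) / len(planted)
            assert recovered >= 0.8, (sc.name, planted - nb)

    def test_neighborhoods_equal_bruteforce_sort(self, tmp_path):
        corpus, _ = synonym_corpus(tmp_path, n_windows=800)
        model = train_embedding(corpus, TrainingParams(dim=20, min_count=5, seed=0))
        assert len(model.terms) <= 500
        for seed_term in ("slang00", "slang31", "slang52"):
            got = semantic_neighborhood(model, seed_term, n=20)
            want = cosine_neighbors_bruteforce(
                model.terms, model.vectors.tolist(), seed_term, 20
            )
            assert [t for t, _ in got] == [t for t, _ in want]


class TestCandidateSet:
    def _model(self):
        return toy_model()

    def test_seeds_always_included(self):
        exp = build_candidate_set(self._model(), {"alpha", "offvocab"}, n=2)
        assert {"alpha", "offvocab"} <= exp.candidate_set
        assert exp.oov_seeds == {"offvocab"}

    def test_union_dedup_bound(self):
        exp = build_candidate_set(self._model(), {"alpha", "bravo"}, n=2)
        assert len(exp.candidate_set) <= 2 * 2 + 2

    def test_invariant_to_seed_order(self):
        a = build_candidate_set(self._model(), ["alpha", "echo"], n=3)
        b = build_candidate_set(self._model(), ["echo", "alpha"], n=3)
        assert a.candidate_set == b.candidate_set

    def test_all_seeds_oov_is_error(self):
        with pytest.raises(ValueError):
            build_candidate_set(self._model(), {"nope"}, n=2)

    def test_candidate_union_matches_oracle(self):
        model = self._model()
        exp = build_candidate_set(model, {"alpha", "charlie"}, n=2)
        oracle = {"alpha", "charlie"}
        for s in ("alpha", "charlie"):
            oracle |= {
                t for t, _ in cosine_neighbors_bruteforce(
                    model.terms, model.vectors.tolist(), s, 2
                )
            }
        assert exp.candidate_set == oracle


class TestCuration:
    def _expansion(self):
        return LexiconExpansion(
            seeds={"alpha"},
            neighborhoods={},
            candidate_set={"alpha", "bravo", "charlie"},
            oov_seeds=set(),
            n=2,
        )

    def test_all_rejected_gives_empty_vocabulary(self):
        decisions = [("alpha", "c1", "reject"), ("bravo", "c1", "reject")]
        assert apply_curation(self._expansion(), decisions) == {}

    def test_accept_with_classes(self):
        decisions = [("alpha", "heroin", "accept"), ("bravo", "heroin", "accept")]
        assert apply_curation(self._expansion(), decisions) == {
            "alpha": "heroin", "bravo": "heroin",
        }

    def test_decision_outside_candidates_is_error(self):
        with pytest.raises(ValueError, match="outside E"):
            apply_curation(self._expansion(), [("zulu", "c", "accept")])

    def test_double_class_accept_is_error(self):
        decisions = [("alpha", "c1", "accept"), ("alpha", "c2", "accept")]
        with pytest.raises(ValueError, match="two classes"):
            apply_curation(self._expansion(), decisions)

    def test_tsv_decision_file(self, tmp_path):
        path = tmp_path / "decisions.tsv"
        path.write_text(
            "term\tdomain\tclass_label\tdecision\tnote\n"
            "alpha\tsubstance\theroin\taccept\t\n"
            "bravo\tsubstance\theroin\treject\tnoise\n"
        )
        assert apply_curation(self._expansion(), str(path)) == {"alpha": "heroin"}


class TestCoverage:
    def _corpus(self):
        posts = [
            make_post(post_id=f"s{i}", body="heroin talk.") for i in range(4)
        ] + [
            make_post(post_id=f"e{i}", body="dope talk.") for i in range(2)
        ] + [
            make_post(post_id=f"n{i}", body="nothing here.") for i in range(3)
        ]
        return make_corpus(posts)

    def test_identity_is_zero(self):
        corpus = self._corpus()
        assert coverage_gain(corpus, {"heroin"}, {"heroin"}) == 0.0

    def test_direct_arithmetic(self):
        corpus = self._corpus()
        # seeds reach 4 comments, expansion adds 2 more -> 50% growth
        assert coverage_gain(corpus, {"heroin"}, {"heroin", "dope"}) == pytest.approx(50.0)

    def test_matches_naive_scan(self):
        corpus = self._corpus()
        seeds, expanded = {"heroin"}, {"heroin", "dope"}

        def naive(terms):
            n = 0
            for p in corpus:
                if p.kind != "comment":
                    continue
                toks = {w for s in corpus.post_sentences(p.post_id) for w in s}
                n += bool(toks & terms)
            return n

        expected = 100 * (naive(expanded) - naive(seeds)) / naive(seeds)
        assert coverage_gain(corpus, seeds, expanded) == pytest.approx(expected)

    def test_zero_seed_occurrences_flagged(self):
        with pytest.raises(ValueError, match="zero comments"):
            coverage_gain(self._corpus(), {"absentterm"}, {"heroin"})

    def test_gain_nonnegative_when_seeds_subset(self):
        corpus = self._corpus()
        assert coverage_gain(corpus, {"heroin"}, {"heroin", "dope", "talk"}) >= 0


class TestCompareModels:
    @pytest.mark.parametrize(
        "accepted, candidates, pct",
        [(128, 297, 43.1), (110, 369, 29.8), (1, 3, 33.3)],
    )
    def test_accepted_percentage_rounding(self, accepted, candidates, pct):
        assert accepted_percentage(accepted, candidates) == pct

    def test_identical_expansions(self, tmp_path):
        corpus, _ = synonym_corpus(tmp_path, n_windows=500)
        model = train_embedding(corpus, TrainingParams(dim=16, min_count=5))
        exp_a = build_candidate_set(model, {"slang00"}, n=5)
        exp_b = build_candidate_set(model, {"slang00"}, n=5)
        for e in (exp_a, exp_b):
            apply_curation(e, [(t, "class0", "accept") for t in sorted(e.candidate_set)])
        cmp = compare_models(exp_a, exp_b, corpus)
        assert cmp.common_terms == cmp.candidates_a == cmp.candidates_b
        assert cmp.comments_a == cmp.comments_b
        assert cmp.accepted_pct_a == cmp.accepted_pct_b == 100.0

    def test_two_backends_share_planted_synonyms(self, tmp_path):
        corpus, gt = synonym_corpus(tmp_path, n_windows=1500)
        seeds = {sc.terms[0] for sc in gt.spec.synonym_classes}
        m_svd = train_embedding(corpus, TrainingParams(backend="svd", dim=24))
        m_sgns = train_embedding(
            corpus, TrainingParams(backend="sgns", dim=24, epochs=3, seed=1)
        )
        exp_a = build_candidate_set(m_svd, seeds, n=10)
        exp_b = build_candidate_set(m_sgns, seeds, n=10)
        cmp = compare_models(exp_a, exp_b, corpus)
        assert cmp.common_terms >= len(seeds)
        planted = {t for sc in gt.spec.synonym_classes for t in sc.terms}
        assert planted <= exp_a.candidate_set or planted <= exp_b.candidate_set

    def test_mismatched_seeds_rejected(self):
        e1 = LexiconExpansion({"a"}, {}, {"a"}, set(), 1)
        e2 = LexiconExpansion({"b"}, {}, {"b"}, set(), 1)
        with pytest.raises(ValueError):
            compare_models(e1, e2, None)
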