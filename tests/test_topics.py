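import math

import numpy as np
import pytest

from forumtopics.corpus_io import Post
from forumtopics.lda import LdaModel, TrainingConfig
from forumtopics.preprocess import BowDoc
from forumtopics.topics import (
    TopicAssignment,
    TopicDistribution,
    assign_posts,
    corpus_word_probs,
    format_label,
    label_topic,
    source_topic_proportions,
    topic_distance_projection,
    topic_graph,
    word_association,
)


def _model_from_phi(phi, scale=1000.0):
    phi = np.asarray(phi, dtype=float)
    return LdaModel(phi * scale + 1e-9, TrainingConfig(n_topics=phi.shape[0]))


def _dists(thetas):
    return [TopicDistribution(f"p{i}", np.asarray(t)) for i, t in enumerate(thetas)]


class TestAssignPosts:
    def test_threshold_is_strict(self):
        model = _model_from_phi(np.eye(4) + 0.01)
        dists = _dists([
            [0.76, 0.08, 0.08, 0.08],   # above -> assigned
            [0.75, 0.25 / 3, 0.25 / 3, 0.25 / 3],  # exactly 0.75 -> not
            [0.25, 0.25, 0.25, 0.25],   # uniform -> not
        ])
        out = assign_posts(model, [], distributions=dists)
        assert out[0].topic == 0 and out[0].probability == pytest.approx(0.76)
        assert out[1].topic is None and out[1].probability == pytest.approx(0.75)
        assert out[2].topic is None

    def test_assignment_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        thetas = rng.dirichlet(np.full(4, 0.3), size=200)
        model = _model_from_phi(np.eye(4) + 0.01)
        dists = _dists(thetas)
        counts = []
        for thr in (0.5, 0.75, 0.9):
            out = assign_posts(model, [], threshold=thr, distributions=dists)
            counts.append(sum(a.topic is not None for a in out))
        assert counts[0] >= counts[1] >= counts[2]


class TestWordAssociation:
    def test_log_one_is_zero(self):
        assert word_association(1.0, 1.0) == 0.0

    def test_literal_formula(self):
        # log(0.1) + log(0.1)/0.1 = -2.302585 - 23.025851
        assert word_association(0.1, 0.1) == pytest.approx(-25.328436, abs=1e-6)

    def test_monotone_in_phi(self):
        assert word_association(0.3, 0.2) > word_association(0.2, 0.2)

    def test_relevance_form(self):
        phi, P = 0.2, 0.05
        assert word_association(phi, P, form="relevance") == pytest.approx(
            math.log(phi) + math.log(phi / P)
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            word_association(0.0, 0.5)
        with pytest.raises(ValueError):
            word_association(0.5, 0.0)


class TestLabelTopic:
    def test_planted_topic_words_and_format(self):
        # topic 0 concentrated on words 0-3, which are rare in the corpus
        phi = np.full((2, 8), 0.02)
        phi[0, :4] = 0.23
        phi[1, 4:] = 0.23
        model = _model_from_phi(phi / phi.sum(axis=1, keepdims=True))
        P = np.full(8, 1 / 8)
        words = label_topic(model, 0, P, n_label_words=4)
        assert sorted(words) == ["0", "1", "2", "3"]
        assert format_label(["sleep", "night", "wake", "feed"]) == (
            "sleep+night+wake+feed"
        )

    def test_tie_broken_lexicographically(self):
        phi = np.array([[0.25, 0.25, 0.25, 0.25]])
        model = _model_from_phi(phi)
        P = np.full(4, 0.25)
        assert label_topic(model, 0, P, n_label_words=2) == ["0", "1"]

    def test_invariant_to_lambda_rescaling(self):
        rng = np.random.default_rng(4)
        lam = rng.gamma(2.0, 1.0, (3, 10)) + 0.1
        P = rng.dirichlet(np.ones(10))
        m1 = LdaModel(lam, TrainingConfig(n_topics=3))
        m2 = LdaModel(lam * 17.5, TrainingConfig(n_topics=3))
        for k in range(3):
            assert label_topic(m1, k, P) == label_topic(m2, k, P)

    def test_too_many_label_words_rejected(self):
        model = _model_from_phi(np.full((1, 4), 0.25))
        with pytest.raises(ValueError):
            label_topic(model, 0, np.full(4, 0.25), n_label_words=5)


class TestTopicGraph:
    def _assignments(self, topics):
        return [TopicAssignment(f"p{i}", t, 0.9) for i, t in enumerate(topics)]

    def test_identical_topics_similarity_edge(self):
        phi = np.array([[0.5, 0.5, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0]])
        g = topic_graph(_model_from_phi(phi), self._assignments([0, 0, 1]), top_n=1)
        assert g.edges[0, 1]["type"] in ("similarity", "both")
        assert g.edges[0, 1]["cosine"] == pytest.approx(1.0)

    def test_disjoint_topics_no_similarity_edge(self):
        phi = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        g = topic_graph(_model_from_phi(phi), self._assignments([0, 1]), top_n=2)
        assert (0, 1) not in g.edges

    def test_shared_word_only_edge(self):
        # one shared top word, low cosine
        phi = np.array(
            [[0.90, 0.05, 0.05, 0.0, 0.0], [0.10, 0.0, 0.0, 0.45, 0.45]]
        )
        g = topic_graph(
            _model_from_phi(phi), self._assignments([0, 1]), top_n=3
        )
        assert g.edges[0, 1]["type"] == "shared_word"
        assert 0 in g.edges[0, 1]["shared_words"]

    def test_node_sizes_sum_to_assigned(self):
        phi = np.array([[0.9, 0.1], [0.1, 0.9]])
        assignments = self._assignments([0, 1, 1, None, 0, 1])
        g = topic_graph(_model_from_phi(phi), assignments)
        total = sum(g.nodes[k]["size"] for k in g.nodes)
        assert total == sum(a.topic is not None for a in assignments)


class TestTopicDistanceProjection:
    def test_identical_topics_coincide(self):
        phi = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        coords = topic_distance_projection(_model_from_phi(phi))
        assert np.allclose(coords[0], coords[1], atol=1e-8)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-12)

    def test_equidistant_topics_form_equilateral_triangle(self):
        phi = np.array(
            [[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]]
        )
        coords = topic_distance_projection(_model_from_phi(phi))
        sides = [
            np.linalg.norm(coords[i] - coords[j])
            for i, j in ((0, 1), (1, 2), (0, 2))
        ]
        assert max(sides) / min(sides) == pytest.approx(1.0, abs=1e-6)

    def test_single_topic_rejected(self):
        with pytest.raises(ValueError):
            topic_distance_projection(_model_from_phi(np.array([[1.0, 0.0]])))


class TestSourceTopicProportions:
    def _posts(self, sources):
        return [Post(f"p{i}", s, "body text") for i, s in enumerate(sources)]

    def test_single_source_single_topic(self):
        posts = self._posts(["A", "A"])
        assignments = [TopicAssignment("p0", 1, 0.9), TopicAssignment("p1", 1, 0.8)]
        table = source_topic_proportions(assignments, posts)
        assert table.loc["A", 1] == 1.0

    def test_rows_sum_to_one_over_assigned(self):
        rng = np.random.default_rng(1)
        sources = ["A"] * 40 + ["B"] * 40
        posts = self._posts(sources)
        assignments = [
            TopicAssignment(
                p.post_id,
                int(rng.integers(3)) if rng.random() < 0.7 else None,
                0.9,
            )
            for p in posts
        ]
        table = source_topic_proportions(assignments, posts, n_topics=3)
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_source_without_assignments_warns_all_zero(self):
        posts = self._posts(["A", "B"])
        assignments = [
            TopicAssignment("p0", 0, 0.9),
            TopicAssignment("p1", None, 0.4),
        ]
        with pytest.warns(UserWarning, match="no assigned"):
            table = source_topic_proportions(assignments, posts)
        assert table.loc["B"].sum() == 0.0

    def test_biased_source_has_larger_share(self, small_spec):
        """A 2x prevalence tilt on one source shows up in the table."""
        from forumtopics.lda import train_lda, infer_corpus
        from forumtopics.preprocess import build_dictionary, encode_corpus
        from forumtopics.synthetic import (
            SyntheticSpec, generate_corpus, generate_token_docs, match_topics,
            pseudo_word,
        )

        spec = SyntheticSpec(
            K_true=3, vocab_size=120,
            n_docs={"synthetic_A": 300, "synthetic_B": 300},
            doc_length_mean=40.0, topic_separation=0.9,
            source_topic_bias={"synthetic_B": {1: 2.0}}, seed=3,
        )
        docs, truth = generate_token_docs(spec)
        d = build_dictionary(docs, min_collection_count=1, max_doc_fraction=1.0)
        bows, _ = encode_corpus(docs, d)
        model = train_lda(bows, TrainingConfig(n_topics=3, passes=10, seed=0), d)
        cols = [d.word2id[pseudo_word(i)] for i in range(spec.vocab_size)]
        perm, _ = match_topics(model.topic_word()[:, cols], truth.topic_word_true)
        assignments = assign_posts(model, bows)
        posts = [Post(doc.post_id, doc.post_id.rsplit("-", 1)[0], "x")
                 for doc in docs]
        table = source_topic_proportions(assignments, posts, n_topics=3)
        est_topic = int(np.flatnonzero(perm == 1)[0])
        assert table.loc["synthetic_B", est_topic] > table.loc["synthetic_A", est_topic]
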