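"""Filters and fractional H-I-T scoring."""

import math
import random

import pytest

from hitmap import ArticleRecord, HITCounts, MeshHeading, UnscorableArticle, \
    exclusion_reason, hit_counts, hit_score, includes_h_and_i, mean_scores, \
    score_corpus
from hitmap.simulate import GeneratorConfig, generate_corpus
from hitmap.synthetic_examples import worked_example_1, worked_example_2
from hitmap.vocabulary import MeshDescriptor, MeshTree


def _record(names, title="t", pub_types=("Journal Article",)):
    return ArticleRecord(pmid="1", title=title, publication_types=tuple(pub_types),
                         headings=tuple(MeshHeading(n, major=True) for n in names))


class TestExclusion:
    def test_meta_analysis_major_topic_excluded(self):
        rec = _record(["Meta-Analysis as Topic", "Heart Diseases"])
        assert exclusion_reason(rec).startswith("major_topic")

    def test_systematic_reviews_major_topic_excluded(self):
        rec = _record(["Systematic Reviews as Topic"])
        assert exclusion_reason(rec).startswith("major_topic")

    def test_review_and_retracted_publication_types_excluded(self):
        assert exclusion_reason(_record(["A"], pub_types=["Review"])) \
            == "publication_type:Review"
        assert exclusion_reason(
            _record(["A"], pub_types=["Retracted Publication"])) \
            == "publication_type:Retracted Publication"

    def test_bibliometric_title_excluded_case_insensitive(self):
        rec = _record(["A"], title="A Bibliometric overview of informatics")
        assert exclusion_reason(rec) == "title_keyword:bibliometric"

    def test_plain_article_not_excluded(self):
        assert exclusion_reason(_record(["Heart Diseases"])) is None

    def test_non_major_excluded_topic_does_not_trigger(self):
        rec = ArticleRecord(pmid="1", headings=(
            MeshHeading("Meta-Analysis as Topic", major=False),
            MeshHeading("Heart Diseases", major=True)))
        assert exclusion_reason(rec) is None


class TestInclusion:
    def test_h_and_i_topics_included(self, example_tree):
        rec = _record(["Heart Diseases", "Telemedicine"])
        assert includes_h_and_i(rec, example_tree)

    def test_h_only_not_included(self, example_tree):
        assert not includes_h_and_i(_record(["Heart Diseases"]), example_tree)

    def test_t_only_not_included(self, example_tree):
        rec = _record(["Remote Sensing Technology",
                       "Defibrillators, Implantable"])
        assert not includes_h_and_i(rec, example_tree)


class TestHitCounts:
    def test_worked_example_one(self, example_tree):
        assert hit_counts(worked_example_1(), example_tree) == HITCounts(2, 1, 0)

    def test_worked_example_two(self, example_tree):
        assert hit_counts(worked_example_2(), example_tree) == HITCounts(2, 2, 6)

    def test_no_categorized_codes(self, example_tree):
        rec = _record(["Program Context (synthetic)"])
        assert hit_counts(rec, example_tree) == HITCounts(0, 0, 0)

    def test_descriptor_with_codes_in_two_categories(self):
        tree = MeshTree([MeshDescriptor("D1", "Dual", ("C01.100", "E05.200"))])
        assert hit_counts(_record(["Dual"]), tree) == HITCounts(1, 0, 1)

    def test_per_descriptor_mode_collapses_same_category_codes(self, example_tree):
        rec = _record(["Telemedicine"])  # two L codes
        assert hit_counts(rec, example_tree) == HITCounts(0, 2, 0)
        assert hit_counts(rec, example_tree, per_descriptor=True) \
            == HITCounts(0, 1, 0)

    def test_invariant_under_heading_permutation(self, example_tree):
        names = ["Heart Diseases", "Quality of Life", "Telemedicine",
                 "Remote Sensing Technology"]
        base = hit_counts(_record(names), example_tree)
        rng = random.Random(3)
        for _ in range(5):
            rng.shuffle(names)
            assert hit_counts(_record(names), example_tree) == base

    def test_unresolvable_descriptor_logged_and_skipped(self, example_tree, caplog):
        rec = _record(["Heart Diseases", "Not A Descriptor"])
        with caplog.at_level("WARNING"):
            counts = hit_counts(rec, example_tree)
        assert counts == HITCounts(1, 0, 0)
        assert any("Not A Descriptor" in r.message for r in caplog.records)


class TestHitScore:
    @pytest.mark.parametrize("counts,expected", [
        (HITCounts(2, 1, 0), (2 / 3, 1 / 3, 0.0)),
        (HITCounts(2, 2, 6), (0.2, 0.2, 0.6)),
        (HITCounts(5, 0, 0), (1.0, 0.0, 0.0)),
    ])
    def test_fractions(self, counts, expected):
        score = hit_score(counts)
        assert score.as_tuple() == pytest.approx(expected, abs=1e-15)

    def test_zero_total_unscorable(self):
        with pytest.raises(UnscorableArticle):
            hit_score(HITCounts(0, 0, 0))

    def test_components_sum_to_one(self, fixture_tree, small_corpus):
        records, _ = small_corpus
        for s in score_corpus(records, fixture_tree, apply_filters=False):
            if s.score is not None:
                assert abs(sum(s.score.as_tuple()) - 1.0) < 1e-12


class TestMeanScores:
    def test_two_pure_scores(self):
        from hitmap import HITScore
        assert mean_scores([HITScore(1, 0, 0), HITScore(0, 1, 0)]) \
            == pytest.approx((0.5, 0.5, 0.0))

    def test_singleton(self):
        from hitmap import HITScore
        s = HITScore(0.2, 0.2, 0.6)
        assert mean_scores([s]) == pytest.approx(s.as_tuple())

    def test_empty_corpus_error(self):
        with pytest.raises(Exception, match="empty"):
            mean_scores([])

    def test_mixture_recovery_within_3se(self, fixture_tree):
        """Parameter recovery at n=10,000 against a binomial SE bound."""
        mixture = (0.45, 0.27, 0.28)
        config = GeneratorConfig(n_articles=10_000, mixture=mixture, seed=11)
        records, _ = generate_corpus(config, fixture_tree)
        scored = score_corpus(records, fixture_tree, apply_filters=False)
        means = mean_scores([s.score for s in scored if s.score])
        for got, p in zip(means, mixture):
            se = math.sqrt(p * (1 - p) / config.n_articles)
            assert abs(got - p) < 3 * se


class TestPipeline:
    def test_filter_order_independent_membership(self, fixture_tree):
        config = GeneratorConfig(n_articles=300, seed=5, excluded_rate=0.2)
        records, _ = generate_corpus(config, fixture_tree)
        from hitmap.scoring import exclusion_reason as excl, includes_h_and_i as incl
        # exclusion-then-inclusion vs inclusion-then-exclusion
        a = {r.pmid for r in records
             if excl(r) is None and incl(r, fixture_tree)}
        b = {r.pmid for r in records
             if incl(r, fixture_tree) and excl(r) is None}
        scored = score_corpus(records, fixture_tree)
        c = {s.pmid for s in scored if s.included}
        assert a == b
        assert c <= a  # pipeline additionally drops unscorable records
        assert all(s.score is not None for s in scored if s.included)
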