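"""Rollups, co-occurrence matrices, topical subsets, Sankey edges."""

import pytest

from hitmap import ArticleRecord, InteractionMatrix, MeshHeading, \
    RollupScheme, cooccurrence_matrix, rollup_code, sankey_edges, \
    subset_by_subtree, subtree_rollup
from hitmap.interactions import POPULATION_HEALTH_LABEL, InteractionError
from hitmap.vocabulary import MeshDescriptor, MeshTree


@pytest.fixture(scope="module")
def itree():
    return MeshTree([
        MeshDescriptor("D1", "Cardiovascular Diseases", ("C14",)),
        MeshDescriptor("D2", "Heart Diseases", ("C14.280",)),
        MeshDescriptor("D3", "Hypertension", ("C14.907.489",)),
        MeshDescriptor("D4", "Health Surveys", ("N06.850.520",)),
        MeshDescriptor("D5", "Computing Methodologies", ("L01.224",)),
        MeshDescriptor("D6", "Artificial Intelligence", ("L01.224.050.375",)),
        MeshDescriptor("D7", "Natural Language Processing",
                       ("L01.224.050.375.580",)),
        MeshDescriptor("D8", "Medical Informatics", ("L01.313",)),
        MeshDescriptor("D9", "Electronic Health Records", ("L01.313.500",)),
        MeshDescriptor("D10", "Diagnosis", ("E01",)),
        MeshDescriptor("D11", "Diagnostic Imaging", ("E01.370.350",)),
    ])


def _rec(pmid, names):
    return ArticleRecord(pmid=pmid, headings=tuple(
        MeshHeading(n, major=True) for n in names))


class TestRollup:
    def test_population_health_merge(self, itree):
        assert rollup_code("N06.850.520", itree) == POPULATION_HEALTH_LABEL

    def test_informatics_depth_two(self, itree):
        assert rollup_code("L01.224.050.375", itree) == "Computing Methodologies"

    def test_disease_first_level(self, itree):
        assert rollup_code("C14.907.489", itree) == "Cardiovascular Diseases"

    def test_depth_exceeding_code_uses_max_available(self, itree):
        # depth 2 for I but the code has... a one-segment L code rolls to itself
        rollup = RollupScheme(depths={"H": 1, "I": 3, "T": 1})
        assert rollup_code("L01.224", itree, rollup) == "Computing Methodologies"

    def test_uncategorized_code_rejected(self, itree):
        with pytest.raises(InteractionError):
            rollup_code("B01.050", itree)

    def test_invalid_depth_rejected(self):
        with pytest.raises(InteractionError):
            RollupScheme(depths={"H": 0})


class TestCooccurrence:
    def test_single_pair_increments_cell(self, itree):
        corpus = [_rec("1", ["Health Surveys", "Computing Methodologies"])]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        assert m.table.loc[POPULATION_HEALTH_LABEL, "Computing Methodologies"] == 1
        assert m.total == 1

    def test_same_pair_via_two_codes_counts_once_per_article(self, itree):
        # two distinct H descriptors rolling to the same label
        corpus = [_rec("1", ["Heart Diseases", "Hypertension",
                             "Artificial Intelligence"])]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        assert m.table.loc["Cardiovascular Diseases", "Computing Methodologies"] == 1

    def test_per_article_dedup_matches_brute_force_sets(self, itree):
        corpus = [
            _rec("1", ["Heart Diseases", "Hypertension", "Health Surveys",
                       "Artificial Intelligence", "Diagnosis"]),
            _rec("2", ["Heart Diseases", "Electronic Health Records"]),
            _rec("3", ["Health Surveys", "Medical Informatics",
                       "Natural Language Processing"]),
        ]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        brute = {}
        label_of = {"Heart Diseases": "Cardiovascular Diseases",
                    "Hypertension": "Cardiovascular Diseases",
                    "Health Surveys": POPULATION_HEALTH_LABEL,
                    "Artificial Intelligence": "Computing Methodologies",
                    "Natural Language Processing": "Computing Methodologies",
                    "Medical Informatics": "Medical Informatics",
                    "Electronic Health Records": "Medical Informatics"}
        h_names = {"Heart Diseases", "Hypertension", "Health Surveys"}
        i_names = set(label_of) - h_names
        for rec in corpus:
            names = [h.descriptor_name for h in rec.headings]
            pairs = {(label_of[a], label_of[b])
                     for a in names if a in h_names
                     for b in names if b in i_names}
            for pair in pairs:
                brute[pair] = brute.get(pair, 0) + 1
        for (a, b), k in brute.items():
            assert m.table.loc[a, b] == k
        assert m.total == sum(brute.values())

    def test_empty_corpus_all_zero(self, itree):
        m = cooccurrence_matrix([], itree, axis="HxT")
        assert m.total == 0

    def test_one_h_one_i_per_article_total_equals_corpus_size(self, itree):
        corpus = [_rec(str(k), ["Heart Diseases", "Medical Informatics"])
                  for k in range(7)]
        assert cooccurrence_matrix(corpus, itree, axis="HxI").total == 7

    def test_invalid_axis_rejected(self, itree):
        with pytest.raises(InteractionError, match="axis"):
            cooccurrence_matrix([], itree, axis="HxH")


class TestSubsets:
    def test_ai_subtree_includes_nlp_article(self, itree):
        corpus = [_rec("1", ["Natural Language Processing"]),
                  _rec("2", ["Electronic Health Records"])]
        subset = subset_by_subtree(corpus, itree, "Artificial Intelligence")
        assert [r.pmid for r in subset] == ["1"]

    def test_ehr_subset_excludes_article_without_it(self, itree):
        corpus = [_rec("1", ["Heart Diseases"])]
        assert subset_by_subtree(corpus, itree, "Electronic Health Records") == []

    def test_subset_and_complement_partition_corpus(self, fixture_tree, small_corpus):
        records, _ = small_corpus
        root = next(d.name for d in fixture_tree if d.name.endswith("Group 01"))
        subset = subset_by_subtree(records, fixture_tree, root)
        ids = {r.pmid for r in subset}
        assert len(subset) <= len(records)
        complement = [r for r in records if r.pmid not in ids]
        assert len(subset) + len(complement) == len(records)

    def test_subtree_rollup_depth_below_root(self, itree):
        rollup = subtree_rollup(itree, "Artificial Intelligence")
        assert rollup.depths["I"] == 5
        assert rollup_code("L01.224.050.375.580", itree, rollup) \
            == "Natural Language Processing"


class TestSankey:
    def test_single_cell_matrix(self, itree):
        corpus = [_rec(str(k), ["Heart Diseases", "Medical Informatics"])
                  for k in range(7)]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        assert sankey_edges(m, min_count=1) \
            == [("Cardiovascular Diseases", "Medical Informatics", 7)]

    def test_threshold_above_max_empty(self, itree):
        corpus = [_rec("1", ["Heart Diseases", "Medical Informatics"])]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        assert sankey_edges(m, min_count=2) == []

    def test_edge_weight_conservation(self, itree):
        corpus = [
            _rec("1", ["Heart Diseases", "Medical Informatics", "Diagnosis"]),
            _rec("2", ["Health Surveys", "Artificial Intelligence"]),
            _rec("3", ["Health Surveys", "Artificial Intelligence"]),
        ]
        m = cooccurrence_matrix(corpus, itree, axis="HxI")
        retained = sankey_edges(m, min_count=2)
        assert sum(w for *_, w in retained) == sum(
            int(m.table.loc[a, b]) for a in m.table.index
            for b in m.table.columns if m.table.loc[a, b] >= 2)
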