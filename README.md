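# hitmap

**H-I-T content mapping of biomedical literature via MeSH tree numbers.**

`hitmap` is a toolkit for scientometric analysis of medical-informatics
research. It classifies publications by their MeSH major topics into three
categories defined by branches of the MeSH hierarchy —

| Category | MeSH branches | Meaning |
|---|---|---|
| **H** — Health demand | Diseases `[C]`, Health `[N01.400]`, Public Health `[N06.850]`, Public Health discipline `[H02.403.720]` | diseases and population-health needs |
| **I** — Informatics supply | Information Science `[L]` | informatics concepts and techniques |
| **T** — Technological applications | Analytical, Diagnostic and Therapeutic Techniques, and Equipment `[E]` | the functions informatics realizes |

and computes, for each article, the fractional **H-I-T score**

```
h = n_H / (n_H + n_I + n_T),   i = n_I / (…),   t = n_T / (…)
```

where `n_X` counts the tree-number codes of the article's *major-topic*
descriptors falling in branch set X (a descriptor occupying two category
positions contributes two codes). Corpora of scores are visualized on a
ternary simplex subdivided into `n²` equal-area sub-triangles ("tribins"),
rolled up to first-level branch labels for H×I / H×T / I×T co-occurrence
matrices and Sankey edge lists, and correlated with disease burden via an
ICD-10 → MeSH subtree mapping with exclusion rules and a through-origin
regression `y = βx` (β = Σxy/Σx², R² uncentered).

The intended users are bibliometricians and health-informatics researchers
mapping how informatics research effort lines up with health needs.

## Worked example

The package ships a small vocabulary subset backing two fully worked
scoring examples (see `hitmap.synthetic_examples`):

```python
>>> from hitmap import hit_counts, hit_score
>>> from hitmap.synthetic_examples import worked_example_tree, worked_example_2
>>> tree = worked_example_tree()
>>> record = worked_example_2()   # six major topics: Heart Diseases,
...                               # Quality of Life, Telemedicine, and three
...                               # device/technique descriptors
>>> counts = hit_counts(record, tree)
>>> (counts.n_h, counts.n_i, counts.n_t)
(2, 2, 6)
>>> score = hit_score(counts)
>>> (score.h, score.i, score.t)
(0.2, 0.2, 0.6)
```

The six descriptors expand to ten category codes — two in disease/health
branches, two informatics codes, six technique/equipment codes — so this
article sits in the T-heavy interior of the triangle: a telemonitoring
study whose devices link heart-disease demand to telemedicine supply.

The command line drives the same pipeline end to end:

```bash
hitmap simulate --n-articles 1000 --seed 1 \
    --out-corpus corpus.jsonl --out-mesh mesh.tsv --out-truth truth.tsv
hitmap score --mesh mesh.tsv --corpus corpus.jsonl --out scores.tsv
hitmap triangle --scores scores.tsv --n 10 --out grid.tsv
hitmap interactions --mesh mesh.tsv --corpus corpus.jsonl --axis HxI --out hxi.tsv
```

`score` prints a filter tally and writes one row per article
(`pmid, n_h, n_i, n_t, h, i, t, included, exclusion_reason`); every output
is accompanied by a manifest recording input hashes, configuration and the
vocabulary version.

## Layout

```
src/hitmap/
  vocabulary.py          MeSH loading (XML + TSV dialect), subtree queries
  categories.py          H/I/T scheme, code & descriptor classification
  corpus.py              PubMed XML + JSONL records, major-topic extraction
  scoring.py             filters, H-I-T counts/scores, corpus pipeline
  ternary.py             simplex geometry, tribin binning, plotting adapter
  interactions.py        rollups, co-occurrence matrices, subsets, Sankey
  burden.py              ICD-10→MeSH mapping, DALY regression
  simulate.py            synthetic vocabulary & corpus generator
  synthetic_examples.py  worked-example fixtures (synthetic stand-ins)
  cli.py                 `hitmap` command group
```

See `docs/methods.md` for the model, conventions and design choices.
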