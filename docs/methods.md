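# Methods

## The H-I-T model

MeSH descriptors occupy positions in a rooted hierarchy identified by
dot-delimited tree numbers (`C14.907.489` = Hypertension). The model
partitions three regions of that hierarchy into categories: health demand
**H** (the Diseases branch `C`, plus the population-health subtrees
`N01.400` Health, `N06.850` Public Health, and by default the Public Health
*discipline* branch `H02.403.720` — Epidemiology, Preventive Medicine and
kin, toggleable via `CategoryScheme.default(include_public_health_discipline=False)`);
informatics supply **I** (Information Science, `L`); and technological
applications **T** (Analytical, Diagnostic and Therapeutic Techniques, and
Equipment, `E`).

Only **major topics** — headings starred at the descriptor or at any
subheading combination — enter any computation; non-major headings describe
context, not core content. Classification is per *code*: every tree number
of every major-topic descriptor is classified independently, so a
descriptor occupying two H positions contributes 2 to `n_H`. The fractional
score divides each category count by the three-category total and is
undefined (the article is "unscorable" and excluded from placement) when
that total is zero. A per-descriptor counting mode (`per_descriptor=True`)
is provided for sensitivity analysis; per-code is the default because the
worked examples convert terms to codes before counting.

### Corpus membership

A record belongs to the mapped health-informatics corpus when (a) no
exclusion applies — major topic in {Systematic Reviews as Topic,
Meta-Analysis as Topic}, publication type in {Review, Retracted
Publication}, or the case-insensitive substring "bibliometric" in the title
— and (b) its major topics hit both H and I (the co-indexing rule). Both
are independent per-record predicates, so evaluation order cannot change
membership. Language is never a filter. Descriptor names that do not
resolve in the loaded vocabulary (year drift between corpus indexing and
vocabulary) are logged and skipped rather than fatal.

### Tree-number semantics

Subtree membership is segment-wise on the dot-split code — `C14.9` is *not*
an ancestor of `C14.907` — with one branch-letter exception mirroring MeSH
itself: a bare letter (`C`, `L`, `E`) denotes the whole branch and matches
any code whose first segment carries that letter, since no descriptor sits
at the letter. Category prefix sets must be pairwise non-overlapping under
this relation; an overlapping user-supplied scheme fails at load rather
than silently picking a winner.

## Ternary placement and tribins

A score is a barycentric point on the 2-simplex (apexes = pure H, I, T;
default plane layout: equilateral triangle, H on top, the H–I edge on the
left so a 50/50 H-I article sits at that edge's midpoint). Cutting each
edge into *n* parts in all three directions yields n² congruent, equal-area
sub-triangles; under uniform simplex sampling the cell counts are therefore
statistically uniform, which the tests check by chi-square.

Binning floors the scaled coordinates `(hn, in, tn)`; the floored triple
sums to n−1 (upward cell) or n−2 (downward cell). Scores are
small-denominator rationals that frequently sit exactly on lattice lines,
so a deterministic tie-break is part of the contract: scaled coordinates
within 1e-9 of an integer snap to it, and when the floored triple overshoots
(sum n — lattice vertices and edges), the first snapped coordinate with a
positive floor, in fixed h→i→t priority, is pushed into the cell below.
The chosen cell always contains the point in its closure, vertices land in
their corner cells, and the result agrees with a brute-force Cartesian
point-in-triangle oracle (tests cover n ∈ {2,3,5,8} on 1,000 random points
plus all exact lattice rationals up to n=6). Cells serialize as
`(row, position, orientation)`: row = lattice steps from the H–I edge
toward T, position = steps from the H side toward I, orientation up/down.
The default grid is n=10; rendering is an adapter over the pure-geometry
core.

## Rollups and interaction matrices

For interaction profiles, codes roll up to the descriptor label at a fixed
number of leading segments: 1 for H and T (first-level disease classes
`C14`, technique classes `E01`), 2 for I — the L branch has a single
first-level node, and the informative groups (Computing Methodologies,
Informatics, Communications Media) live one level deeper. All three
population-health subtrees merge to one "Population Health" label. If no
descriptor exists at the truncated position the deepest available ancestor
label is used, then the truncated code itself.

A co-occurrence matrix counts, for each article, each unordered pair of
distinct rolled labels across the two chosen categories **once per
article** (an article with three cardiovascular codes and one telemedicine
code adds 1, not 3); per-code multiplicity is available by flag. Topical
sub-datasets (e.g. Artificial Intelligence, Electronic Health Records) are
articles with ≥1 major-topic code under the named descriptor's subtree; for
such subsets `subtree_rollup` sets the I-axis depth to one level below the
subset root, so an AI analysis resolves to the secondary terms beneath the
AI node. Sankey edge lists are the matrix cells at or above a weight
threshold.

## Burden mapping and regression

The ICD-10 → MeSH table (TSV; multi-code cells are semicolon-joined, `N/A`
means none) assigns each disease matched subtrees and optional excluded
subtrees. An article maps to a disease iff some major-topic code is under a
matched code **and** that code is under no excluded code — exclusion
always wins, per code. With exclusions emptied the rule reduces to plain
subtree membership. Per-disease publication counts (an article counts once
per disease it maps to) are regressed through the origin on DALYs:
slope = Σxy/Σx², R² = 1 − Σ(y−ŷ)²/Σy². The uncentered total sum of squares
is the standard convention for zero-intercept fits (centered R² available
by flag); the two diverge and neither is comparable to an
intercept-model R². Units of the slope follow the DALY units of the input
table. No burden estimates ship with the package beyond a clearly labelled
synthetic demonstration table; the cardiovascular ICD-10 correspondence
rows are packaged as published.

## Synthetic data

`make_fixture_tree` builds a deterministic MeSH-like vocabulary covering
every category branch plus distractor branches (Organisms- and
Chemicals-like) with parent/child pairs, a dual-position public-health
descriptor, and an excluded-topic descriptor. `generate_corpus` draws, per
article, `1 + Poisson(topics_mean − 1)` topics (default mean 6, matching
the typical 5–10 major terms per record, floored at 1), assigns each draw a
category from the target mixture, and samples distinct descriptors from
per-category pools restricted to single-code descriptors — so each draw
contributes exactly one categorized code, the expected mean score equals
the mixture exactly, and recovery can be tested against the conservative
binomial bound SE = √(p(1−p)/N). The default mixture (0.45, 0.27, 0.28)
represents a realistic health-demand-leaning corpus composition. Exact
per-article ground truth is recorded at draw time; its agreement with the
full scoring pipeline, article by article, is the strongest end-to-end
test in the suite. `included_only` rejection-samples articles until they
satisfy the H×I rule (slightly biasing the conditional mixture, which is
why recovery tests run without it). A single seeded generator drives all
randomness; the seed is echoed in the vocabulary version string and run
manifests.

What the generator does **not** emulate: realistic descriptor frequencies,
MEDLINE indexing depth, correlated topic selection, or per-country and
per-year structure beyond uniform draws. Passing tests therefore validate
the *mechanics* (classification, filtering, scoring, binning, counting) on
controlled inputs, not corpus-level findings about real literatures.

## Problem sizes and numerics

Test and acceptance runs use 200–10,000 synthetic articles, tribin grids to
n = 12, and 1,000-point geometric oracle sweeps — sizes at which binomial
and chi-square checks are already sharp. Score normalization is asserted to
1e-12; ternary-point validity to 1e-9 (scores rounded to 6 decimals in text
output are renormalized on re-read); lattice snapping to 1e-9. Degenerate
inputs fail loudly: empty corpora for means, zero-total scores, all-zero
DALY vectors, collinear triangle layouts, duplicate tree numbers,
overlapping category prefixes.

## Known limitations

* The vocabulary-wide term counts per category depend on the official
  descriptor XML for a given MeSH year, which is not redistributable with
  the package; both counting conventions (unique descriptors vs tree
  positions) are implemented because published branch totals rarely state
  which was used.
* The worked-example fixtures are synthetic stand-ins reproducing the
  documented code-count structure of the original records; tree numbers not
  published anywhere are invented (and marked) rather than copied from the
  real vocabulary.
* Country attribution parses the first author's affiliation against a small
  gazetteer; multi-country papers are counted once, by first author.
* Density-contour display of the simplex is out of scope; the tribin grid
  and the plotting adapter are the supported visualization.
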