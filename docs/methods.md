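# Methods

## Overview

`drugcascade` chains five analyses: literature mining of disease-associated
proteins, induction of a disease PPI network, receptor-anchored drug
interactome and shortest-cascade extraction, gene-set over-representation,
and case-control expression statistics. This note records the models, the
parameter defaults and why, the numerical choices, and what the synthetic
validation does and does not establish.

## Corpus mining and PMI

Curation is modelled as mechanical filters — publication-year window
(default 1990–2023), case-insensitive keyword inclusion, exclusion terms,
de-duplication by record id. Semantic study-type screening (human-only,
primary-research-only) is out of scope; exclusion terms are the only
instrument provided.

Mention tagging is dictionary matching: text and lexicon are both
uppercased (effectively case-insensitive), matches must sit on word
boundaries (neighbouring character non-alphanumeric or string edge;
hyphens are boundaries, so "BDNF-dependent" yields a BDNF hit), the
longest match wins at any position, and resolved hits never overlap.
Symbols or synonyms shorter than 3 characters are blocklisted unless
whitelisted — one- and two-letter tokens ("IT", "ER", "F2") are
overwhelmingly false positives in free text. A surface form claimed by
two canonical symbols is rejected at load (or routed to the blocklist on
request): silent ambiguity would corrupt every downstream count.

Association strength is document-level pointwise mutual information in
log base 2: `pmi = log2(n_xd·N / (n_x·n_d))`, counting each abstract at
most once per symbol regardless of repeat mentions. Base 2 only shifts
scale; document-level (rather than token-level) counting makes the
statistic insensitive to verbosity. A symbol never co-mentioned with the
disease (`n_xd = 0`) gets a −∞ sentinel and is excluded from ranking;
an add-0.5 continuity correction is available behind a flag, but the
default refuses to manufacture evidence from absence. Ranking is by PMI
descending, then symbol ascending, so output order is deterministic.
There is no canonical PMI cut-off for "disease-associated"; it is a
configuration parameter (pipeline default 0.25 with ≥ 5 supporting
abstracts, chosen so that genuinely associated symbols in corpora of a
few hundred abstracts clear it with margin while independent symbols,
whose PMI concentrates near 0, do not).

## Disease network

The disease network is the subgraph of a user-supplied reference
interaction catalogue induced on the mined protein list: an edge is kept
iff both endpoints were mined. Graphs are undirected and simple —
self-loops and duplicate edges are dropped at load, each edge stored once
with endpoints in lexicographic order. Mined proteins touching no kept
edge remain as degree-0 nodes by default, because the mined list (not the
connected core) is the natural enrichment universe; a flag drops them.
Optional edge weights are carried but ignored by path computations:
"shortest" means fewest hops throughout, which is also the only notion
the source workflow supports.

## Drug interactomes and signal cascades

For each drug, the receptors are looked up in the network and the anchor
protein (BDNF) fixed. The **shortest cascade** is the set of all
minimum-hop simple paths from any receptor to the anchor (global minimum
over receptors; per-receptor minima behind a flag), sorted by length and
then lexicographically by node sequence; the first path is canonical.
Returning all ties and designating one canonically gives determinism
without discarding information. A receptor equal to the anchor yields the
trivial length-0 path; a disconnected drug yields an empty list plus a
warning flag rather than an exception, so batch runs survive sparse
networks.

The **interactome** is the union of all simple receptor→anchor paths of
length at most a hop budget; nodes and edges must lie on at least one
qualifying path. Unbounded "all possible connections" is combinatorially
explosive, so the default budget is the shortest-path length + 2, which
keeps the hub-and-cascade neighbourhood while bounding enumeration;
the budget is configurable. Paths are simple (no node revisits), and
"downstream" order is read along the path from receptor to anchor.

Correctness of both operations is established against an exhaustive
depth-first enumeration of simple paths on random graphs of ≤ 12 nodes
(hundreds of seeded graphs, exact set equality).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail:
for query size `n` within a universe of size `N`, a term covering `K`
universe genes and overlap `k`, `p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`.
Term gene sets are intersected with the universe first; query genes
outside the universe are dropped with a warning; terms with zero overlap
are omitted (their p is identically 1). The significance filter is raw
`p < 0.01` by default — matching the workflow this package reimplements,
which applied no multiple-testing correction — with Benjamini–Hochberg
available behind a flag. The universe defaults to the disease network's
node set and is configurable, since no canonical universe exists for
literature-mined lists. The tail probability is delegated to scipy's
log-space survival function and verified against exhaustive enumeration
of all C(N, n) draws for every parameter combination with N ≤ 12.

## Expression statistics

**2^−ΔΔCT.** Technical replicates are averaged to one Ct per
(sample, gene) before any statistic — treating replicate wells as
independent samples would be pseudo-replication. Then per sample
ΔCt = Ct_gene − Ct_reference (reference default GAPDH),
ΔΔCt = ΔCt − mean(ΔCt over the calibrator group), fold = 2^−ΔΔCt.
The calibrator defaults to the healthy-control arm, the group against
which the study's figures compare everything. By construction the
calibrator group's mean ΔΔCt is 0 and its geometric-mean fold is 1, and
per-sample Ct shifts (RNA input) cancel — both are enforced as tests.
Samples missing the reference gene are excluded with a warning; an empty
calibrator is an error. No amplification-efficiency (Pfaffl) correction
is applied: the implemented estimator is the plain 2^−ΔΔCT.

**ANOVA + Tukey.** Group comparisons run on per-sample fold values
(matching how such results are plotted as mean ± SD of relative
expression); analysing ΔCt instead — statistically preferable since ΔCt
is closer to normal — is a documented alternative the caller can apply by
passing ΔCt values. The F statistic is computed from classical
between/within sums of squares with df (G−1, Σn_g−G); zero within-group
variance is handled explicitly (F = 0/p = 1 if means agree, F = ∞/p = 0
otherwise). Tukey's HSD uses the Tukey–Kramer statistic
`q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j))` with the adjusted p
from the studentized-range distribution with parameters (G, Σn_g−G);
it is cross-checked in the tests against scipy's independent
implementation and against direct numerical integration of the
studentized-range tail (agreement to 1e−6). Because the study's figures
mark significance versus control only and the adjustment behind those
marks is not determinable, the pipeline report emits both Tukey-adjusted
p-values for all pairs and unadjusted pooled-variance t-tests against the
calibrator.

**ELISA.** The standard curve is linear by default (the bundled synthetic
plates are generated from a linear response); a four-parameter logistic
`A(c) = d + (a − d)/(1 + (c/c50)^b)` is available, fitted by iterative
least squares started from a = min absorbance, d = max absorbance,
c50 = median positive standard, b = 1, since real sandwich-ELISA
responses are sigmoidal. Interpolation inverts the fitted model;
absorbances outside the standards' response span are flagged out of range
and yield no number unless extrapolation is explicitly requested.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their spec (numpy PCG64, explicit seed;
the generator family and seed are recorded in every sidecar).

*Corpus*: disease membership and symbol mentions are independent
Bernoulli draws per document with planted conditional rates; symbols are
embedded in templated sentences with proper word boundaries, a constant
broad retrieval keyword in every abstract (so keyword curation retains
both disease and non-disease documents — the contrast PMI requires), and
an optional hard mode planting confusable substrings ("xBDNFx") that a
boundary-aware matcher must ignore. The sidecar records exact per-document
memberships, so mining must reproduce `n_x`, `n_d`, `n_xd` perfectly.
It does not emulate real biomedical prose, synonymy ambiguity across a
full gene dictionary, or species confusion.

*Network*: G(n, p) background (default 60 nodes, p = 0.05) plus planted
receptor→anchor paths; a rejection step removes background edges that
would create an alternative receptor→anchor route as short as the planted
path, so planted-path recovery is exact by construction. The study-shaped
default plants the two reported cascades — PRKAB1→APP→BDNF and
KCNJ11→AP2M1→ESR1→BDNF — among longer decoys. Real PPI topology
(scale-free degree, clustering) is not modelled, and the source
workflow's absolute counts (thousands of proteins and edges, hundreds of
intermediaries) are environment-dependent and deliberately not
reproduced.

*Expression*: four arms of n = 30, triplicate reactions. Each sample has
a baseline Ct (mean 20, SD 0.5) shifting all its genes equally (cancels
in ΔCt); each replicate reading adds independent measurement noise
(default SD 0.3 cycles for targets and reference alike — the scale of
routine qPCR technical variability). Planted fold changes follow the
reported direction: cascade genes depressed in untreated disease and
raised under treatment, with glimepiride lifting BDNF most. Under these
defaults a planted two-fold change is recovered (group geometric mean
within ±10%) in ≈ 97–98% of seeds. Biological covariance between genes,
outliers, and efficiency differences between amplicons are not modelled.

*ELISA*: absorbances from a known linear curve (intercept 0.02,
slope 0.05 per ng/mL, standards 0–20 ng/mL) with Gaussian noise
(SD 0.005 A); group concentration means span 6–12 ng/mL so all samples
fall inside the quantifiable range.

Passing these validations shows the arithmetic, graph algorithms and
statistics are correct and calibrated under the stated generative
assumptions; it does not certify mining accuracy on real abstracts or
cascade validity under a different interaction catalogue.

## Pipeline determinism and problem sizes

The pipeline writes every stage artifact plus a single `report.json`
with sorted keys and no timestamps; two runs with the same inputs and
seed are byte-identical, and `--from <stage>` resumes from on-disk
artifacts reproducing downstream outputs byte-identically. Default
validation sizes — 300-abstract corpora, 60-node catalogues, 200–500
random graphs or simulation seeds per property, 1,000-seed null
calibrations — were chosen as the smallest sizes at which the binomial
noise on each estimated rate is comfortably below the margin being
asserted.

## Known limitations

- Keyword filters cannot reproduce human study-type curation; corpora
  curated differently will mine different protein lists.
- PMI is a co-occurrence statistic: it cannot distinguish positive from
  negative association polarity, and rare symbols have high-variance
  scores (hence the minimum-document threshold).
- Hop-count shortest paths ignore interaction confidence and direction;
  a weighted or directed catalogue would need a different path model.
- Raw-p enrichment filtering (the reimplemented workflow's choice)
  inflates family-wise error; use the BH flag for defensible inference.
- ANOVA on fold values inherits the right-skew of 2^−ΔΔCt; for small
  groups prefer the ΔCt-scale analysis.
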