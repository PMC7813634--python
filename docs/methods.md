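# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## Text model

Posts are treated as bags of lemmas organized into ordered sentences; only
sentence *indices* matter downstream (for distance-thresholded
co-occurrence), never word order within a sentence.

* **Segmentation** splits on terminal punctuation (`.`, `!`, `?`) followed
  by whitespace or end of text, after collapsing URLs; a body with no
  terminator is one sentence.  This is deterministic and dependency-free;
  the segmenter/tokenizer is a pluggable contract so a full NLP backend can
  replace it without touching any counting code.
* **Lemmatization** is lowercasing plus rule-based suffix stripping
  (`ing`, `ed`, `es`, `s`, first match, stem ≥ 3 chars) with a small
  exception list, and stop-word removal against a fixed list packaged in
  the repository.  A consequence is that inflected vocabulary terms
  (e.g. *boofing*) normalize onto their base form before matching; the
  packaged vocabularies list both forms within the same class, so class
  counts are unaffected.
* **Frequency filtering** is per calendar year: lemmas under the yearly
  floor (default 100, the production setting for multi-million-post dumps)
  are dropped from that year only.  Desk-scale synthetic runs set the floor
  to 1; every example and test states the value it uses.
* **Deleted authors** keep their posts for volume statistics but are
  excluded from every author-distinct count (cohorts, popularity,
  prevalence).
* **Quarters** are UTC calendar quarters (Q1 = Jan–Mar).
* Submission titles, when present, are prepended as sentence 0.

## Community retrieval

The retrieval procedure is a deterministic reconstruction of the
semiautomatic query-expansion family: the original algorithm's scoring and
expansion functions are not published in detail, so this package commits to
fully specified choices and flags them as a faithful-in-spirit
reconstruction, not a reproduction.

* **Community score**: mean over query terms of
  `log( ((n_c(t)+1)/(N_c+V)) / ((n(t)+1)/(N+V)) )` — add-one-smoothed
  log-lift of the community's relative term frequency over the corpus-wide
  one.  Smoothing keeps tiny communities finite; the mean (not sum) keeps
  scores comparable across query sizes.
* **Query expansion**: candidate lemmas ranked by add-one-smoothed log-odds
  of occurring in the top-k communities versus the background; only
  candidates with positive enrichment qualify, so the iteration reaches a
  fixed point when nothing is enriched.  The query only ever grows.
* **Tie-breaks** are lexicographic everywhere, making every ranking a total
  order; `k` (communities kept, default 150) and `m` (terms added per
  round, default 10) are configurable.
* The final inclusion judgment is human.  The package represents it as a
  TSV curation format plus Fleiss κ (delegated to statsmodels; the test
  suite checks it against an independently coded direct-formula oracle to
  1e-12).  A rating matrix whose every cell falls in one category has
  undefined κ and is returned flagged degenerate with observed agreement 1.

## Embeddings and lexicon expansion

Two backends implement one contract (train → vocabulary + unit-norm
vectors):

* **PPMI + SVD** (default): positive pointwise mutual information over a
  symmetric 5-token context window, truncated SVD (ARPACK with a fixed
  start vector, so runs are exactly reproducible), vectors `U·√S`.
  Count-based methods are strong on small corpora, which makes this the
  reference backend for desk-scale work.
* **Skip-gram with negative sampling**: vectorized numpy SGD, unigram^0.75
  noise distribution, 5 negatives, learning rate decaying 0.025 → 1e-4,
  deterministic under a fixed seed and single-threaded execution.

Default dimension 100, window 5, 5 epochs, `min_count` aligned with the
corpus lemma floor.  These are standard small-corpus settings; all are
configurable, and nothing downstream depends on a particular backend.  A
single pooled model over the whole span is used rather than per-year
models: neighborhoods are consumed once per domain, not per year.

Neighborhoods take the top-*n* = 20 terms by cosine (seed excluded, ties
lexicographic).  The candidate set `E` is the union of all in-vocabulary
seeds' neighborhoods plus the seed set; out-of-vocabulary seeds are
recorded and warned about, never silently dropped.  Curation decisions are
the single source of truth for the accepted vocabulary `V`: the code never
auto-accepts, and accepting one term into two classes of a domain is an
error.  Coverage gain is measured over comments: `100 · (hits(V) − hits(K))
/ hits(K)` where a hit is a comment containing ≥ 1 term of the set.

## Taxonomy

Three TSV fixtures ship with the package: substance classes (12), the
two-level ROA taxonomy (5 primary routes; *Rectally* is its own terminal
secondary), and tampering classes (11).  Within a domain a term belongs to
exactly one class; the same surface form may appear in different domains.
Chewing is modeled as a secondary ROA under ingestion, not as tampering.
*Intrathecal* and *Urogenital* are loaded but flagged low-support; the
association grid excludes flagged classes by default (overridable) because
their mention volume is too thin for stable odds ratios.  Duplicate
surface forms within one class in the source material are deduplicated at
transcription, keeping the seed flag.

## Trends

Cohort = distinct non-deleted authors with ≥ 1 post in a selected
community over the span.  Prevalence (reported to 4 decimals, unrounded
internally) = cohort authors / all platform authors, per year.  Quarterly
popularity of a class = share of cohort authors mentioning it at least
once that quarter.  The denominator is a policy choice with two readings,
both implemented and tagged on the output:

* `active` (default): cohort authors who posted in that quarter — a
  relative measure robust to a platform whose active base grows ~30% a
  year;
* `cohort`: the fixed full-span cohort size.

Mentions outside the selected communities are ignored by default
(configurable), and the binary per-author rule makes shares invariant to
any author's posting volume.

## Association analysis

The contingency table counts *events*, not a partition of posts: a post
whose A and B mentions all exceed ρ contributes one A-only **and** one
B-only event.  The n00 universe is posts holding ≥ 1 mention from either
of the pair's two domains ("either" policy); the alternative "both" policy
is available for sensitivity but makes n00 structurally 0 and is not the
default.  Matching is class-level: a post mentions class X if any term of
X matches.

Estimation: OR = n11·n00 / (n10·n01); Woolf log-normal CI
`exp(ln OR ± z·√(Σ 1/n_ij))`; Pearson χ² of independence without Yates
correction (correction selectable), significance at α = .01.  Zero cells
get the Haldane–Anscombe +0.5 on all four cells and the result is flagged
`corrected`; a policy `undefined` is available instead.  Tables with an
empty margin are reported as undefined results, never silently dropped.
Association runs default to a single year's posts (configurable), with
submissions and comments pooled.  No multiple-testing correction is
applied across the grid; grids are exploratory, and ORs are correlations,
not causal effects.

Invariants the tests enforce exactly: n11 is non-decreasing in ρ while
n11+n10 and n11+n01 are constant (events migrate between joint and
separate, never vanish); every table equals a brute-force double-loop
recount on corpora ≤ 200 posts; OR is invariant to transposing the pair.

## Synthetic generator

The generator emulates only the statistics the pipeline consumes:

* posts per author: discrete power law (exponent 2.1) capped at 300,
  calibrated so the top 1% of authors produce > 30% of content;
* deleted authors: 25% of submissions, 7% of comments;
* sentence counts per post: an explicit pmf on 1–20 with P(≤ 2) = 0.5,
  P(> 10) = 0.2, median 2;
* planted associations: post-level joint probabilities inverted from the
  requested true OR (unique root of the OR quadratic inside the Fréchet
  bounds), with co-mention sentence distances drawn from a configurable
  profile so ρ-sensitivity is observable; neutral anchor mentions pin
  every association-channel post into the n00 universe;
* planted synonym classes: terms emitted interchangeably inside
  class-specific context windows, the structure cosine neighborhoods
  recover;
* quarterly trends: per-author Bernoulli mention probability linear in the
  quarter index.

Text is template sentences of filler lemmas with vocabulary terms slotted
in; only lemma-stable single tokens are planted so raw-text scans and the
lemmatizing pipeline agree exactly.  One seed governs all randomness and a
fixed spec yields byte-identical output; the planning stage is separable
from text realization, so large parameter-recovery studies can run on the
planted mention structure directly while small corpora verify the full
text round trip exactly.

**What passing tests do not show**: the generator has no linguistic
realism — no topic drift, polysemy, misspellings, n-gram structure,
threading, or non-English text.  Recovery results demonstrate estimator
correctness under the stated statistical conditions, not robustness to
real social-media language; on real dumps the lemmatizer and the
single-token matching are the first things to revisit.

## Problem sizes used in checks

Report arithmetic is exact and instantaneous.  Oracle-equivalence checks
use 20 seeded corpora of ≤ 200 posts (exhaustive recounts are quadratic).
Odds-ratio recovery uses 20 000-post universes with 20 replicates per true
OR in the test suite (10 in the acceptance script); CI coverage uses 500
simulated tables at n = 2000 events.  Synonym recovery uses 8 planted
classes × 4 terms over 4000 context windows.  Generator fidelity is
checked at ~10 000 posts, where the stated tolerances (±3 points on the
sentence profile, ±2 on deleted shares) comfortably contain sampling
noise.

## Known limitations

* The retrieval scoring/expansion functions are this package's own
  reconstruction; rankings on real data will differ from any specific
  prior implementation of the semiautomatic procedure.
* Single-token matching only: multiword expressions ("cold water
  extraction") must enter the vocabulary as single-token surrogates
  (e.g. *cwe*).
* The rule-based lemmatizer conflates some forms and misses irregulars;
  it is the default *test* backend, with real deployments expected to plug
  in an NLP pipeline.
* No language identification is performed; non-English posts pass through
  and dilute counts.
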