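# Methods

## Model and pipeline

The package treats a decade of biomedical literature as a set of per-year
corpora and asks two questions of each year: *what were the research foci*
(hotspots) and *which diseases co-occur in those foci* (relations). The
answer is computed in five stages, each with an explicit probabilistic or
algorithmic contract.

### Pre-processing

Titles and abstracts are segmented on punctuation and whitespace and
lowercased; tokens are lemmatized, POS-tagged, filtered to nouns and
adjectives (NN*/JJ* tag families), and stripped of stop words. Tokens of a
single character and pure digits are additionally dropped: digits are already
excluded by the noun/adjective filter through the CD tag, and one-letter
tokens are segmentation debris.

The lemmatizer and tagger are small deterministic rule systems rather than
statistical models: an irregular-form table plus suffix stripping with
consonant-doubling repair (iterated to a fixed point, so lemmatization is
idempotent), and closed-class word lists plus suffix heuristics with NN as
the open-class default. On biomedical abstracts the quantities that matter
downstream are (a) which tokens survive to the bag of words and (b) that the
map is deterministic and idempotent; both are tested directly. The rule
tagger will mis-tag some rare verbs as nouns — an accepted source of extra
vocabulary, not of lost content words. The `-ing`/`-ed` stripper does not
restore silent `e` (`making → mak`); the map is still injective enough in
practice and, crucially, consistent across a corpus, which is what matters
for vocabulary unification before LDA.

### LDA by collapsed Gibbs sampling

Topics φ_k ~ Dirichlet(β), document mixtures θ_m ~ Dirichlet(α), token topics
z ~ Cat(θ_m), words w ~ Cat(φ_z). With φ and θ integrated out, each token's
topic is resampled from

    p(z = k | rest) ∝ (n_mk + α) · (n_kw + β) / (n_k + Vβ)

where counts exclude the current token. Point estimates come from the final
sweep:

    φ_kw = (n_kw + β) / (n_k + Vβ),    θ_mk = (n_mk + α) / (N_m + Kα).

Defaults: K = 100 topics, α = 5/K = 0.05, β = 0.01, 500 sweeps, top 20 words
kept per topic. No burn-in discarding or sample averaging is applied — the
final sweep is the estimate; with the corpus sizes used here the count tables
change little over the last hundreds of sweeps, and a single-sweep estimate
keeps the output a deterministic function of (corpus, config, seed). The
sweep kernel is compiled with numba; all randomness is pre-drawn from one
seeded numpy Generator, so results are bit-reproducible and independent of
the kernel's compilation.

### Skip-gram embeddings

One embedding table per year-corpus, trained with the skip-gram
negative-sampling objective by SGD: for each (center, context) pair within a
dynamically shrunk window, one positive update and `negative` noise-word
updates with noise distribution ∝ unigram^0.75. Defaults dim = 100,
window = 5, negative = 5, epochs = 5, min_count = 1, initial learning rate
0.025 decaying linearly across epochs. Negative sampling is preferred over
hierarchical softmax for robustness on small corpora. Training is
single-threaded and deterministic per seed. Every analysis of a year's
topics uses that year's table, so all topic centroids live in one semantic
space; words are never silently replaced by zero vectors — lookups return an
explicit out-of-vocabulary marker.

### Topic representation and similarity

Each topic's top-W words are replaced by their embeddings (out-of-vocabulary
words dropped, surviving probabilities renormalized — cosine scale-invariance
makes the renormalization immaterial to similarities, but stored centroids
are then weighted averages of a proper distribution). The centroid is the
probability-weighted row average; pairwise similarity is

    s(i,j) = −1 / cos θ          if cos θ > x
    s(i,j) = −1 / x              if cos θ ≤ x        (x = 1e-6 by default)

s is strictly increasing in cos θ on (x, 1], with s = −1 the maximum at
identical directions. The clamp at x generalizes "add a minimal value at
cos θ = 0": applying −1/cos θ to a *negative* cosine would produce a positive
similarity and invert the ranking affinity propagation depends on, so
cosines at or below x — orthogonal or opposed centroids — are all treated as
maximally dissimilar (s = −1/x). This is a deliberate design decision for
real embedding geometry, where negative cosines occur.

### Affinity propagation

Standard responsibility/availability message passing over s, all pairs
updated synchronously per iteration, each update damped as
m_t ← (1−λ)·m_new + λ·m_{t−1}. Exemplars are the points with
r(k,k) + a(k,k) > 0; non-exemplars join their most similar exemplar (ties to
the lowest index). The preference (diagonal of S) defaults to the median of
the off-diagonal similarities — the classical choice when no cluster-count
prior exists.

Numerical choices, found necessary in practice:

* **Damping default λ = 0.5** (the Frey–Dueck and scikit-learn default).
  Similarity matrices from this pipeline contain exact ties — duplicated
  topics give identical centroids, hence blocks of s = −1 — and with λ = 0.9
  the heavily damped dynamics can ride past the good configuration into
  fixed points with markedly worse net similarity. λ = 0.9 remains available
  for genuinely oscillating problems.
* **max_iter = 500, conv_window = 50.** Convergence is declared when the
  exemplar set is unchanged for `conv_window` consecutive iterations; the
  dynamics pass through metastable transients tens of iterations long, so a
  short window declares convergence prematurely.
* **Tie-breaking jitter.** Exactly interchangeable points keep the messages
  perfectly symmetric and no exemplar ever emerges. A deterministic Gaussian
  jitter of 1e-6 × (range of S), applied to the message-passing copy of S
  only (assignments and net similarity use the original S), breaks such
  ties; it is configurable and can be set to 0.
* If no point satisfies the exemplar criterion at termination, the single
  best r(k,k)+a(k,k) candidate is returned, so a ClusterResult always has at
  least one cluster.

Quality is bounded in tests against an exhaustive oracle: over random
symmetric similarity matrices (n ≤ 8) with median preference, the
message-passing net similarity Σ_i s(i, exemplar(i)) must be within ~5% (in
magnitude) of the optimum over all exemplar subsets in ≥ 90% of draws — AP
carries no optimality guarantee, so this bounds practical quality rather
than asserting exactness.

### Hotspots, trends and relations

A year's central words are the rank-1 words of its exemplar topics (the
probability-sorted topic rows make this deterministic; human summaries of a
cluster would sometimes choose differently — this proxy is the documented
convention). Merging all exemplar rows of a year gives the year's word-cloud
data; duplicate words keep their maximum weight. Counting the years in which
a central word (or an explicit, user-supplied synonym group, e.g.
cataract/retina/retinopathy) appears assigns the trend tier: count > 3
more-than-thrice, = 3 thrice, = 2 twice, = 1 once.

A relation edge (seed disease, lexicon disease) is emitted when any synonym
of the lexicon disease occurs among any exemplar topic's top words of the
seed disease's corpus with probability ≥ `min_weight`, in any year; the edge
weight is the maximum such probability. This replaces the manual reading of
cluster word clouds with a deterministic rule; like any lexicon scan it
cannot flag a disease phrased only in words outside the lexicon.

## Synthetic data: what it emulates and what it does not

The generator samples corpora from exactly the generative process the topic
model assumes — Dirichlet topics over a vocabulary of pronounceable
consonant-vowel pseudo-words (which survive pre-processing as nouns),
Dirichlet document mixtures, Poisson document lengths, year labels as
metadata. Default conditions: 10 topics, 500-word vocabulary, 200 documents
of mean length 60 (roughly an abstract's noun/adjective yield), α_true = 0.1,
β_true = 0.01.

"Planted" disease topics support end-to-end tests: a planted topic puts
`boost` of its mass uniformly on a real-word list (e.g. depression, mental,
anxiety, psychological, mood), dominates `doc_fraction` of each active
year's documents with mixture weight `doc_weight`, and is inactive in other
years. The end-to-end study conditions (two seed-disease corpora, 2 years ×
100 documents, 4 background topics + 1 planted depression topic with
boost 0.95, doc_fraction 0.4, doc_weight 0.9; LDA fitted with K = 8 so the
planted content splits into multiple topics that then cluster, mirroring how
hotspot clusters arise at K = 100 on real corpora) were fixed once as a
regime where the planted signal is genuinely separable.

What passing these tests shows: the estimation and clustering machinery
recovers structure that is actually present, end to end, including the
year-bookkeeping and file formats. What it does not show: behavior under
model misspecification — real abstracts have burstiness, multiword terms,
rhetorical structure and vocabulary drift that the generative process lacks,
and real topic counts/cluster counts are corpus-dependent outputs, not
contracts.

## Topic-recovery conditions and metric

Recovery tests use a clearly separated regime fixed in advance: 5 topics,
100-word vocabulary, 300 documents of mean length 120, α_true = 0.05 (nearly
single-topic documents), β_true = 0.01 (sparse topics), 300 Gibbs sweeps.
`recovery_score` greedily matches true to estimated topics by total-variation
distance (best pair first, one-to-one) and returns 1 − mean matched TV; the
threshold 0.8 corresponds to mean matched TV ≤ 0.2. Observed values are
≈ 0.99 across seeds.

## Degenerate inputs and tie-breaks

* Empty corpora, empty synonym lists, λ ∉ (0,1), fewer than 2 topics for
  similarity/clustering, zero-norm vectors in cosine: argument errors.
* A topic whose top words are all out-of-vocabulary raises a degenerate-topic
  error naming the topic; the pipeline driver records such topics in the
  manifest and clusters the rest.
* Ties in top-word probabilities are broken by vocabulary order (stable
  argsort); assignment ties in AP by lowest index; duplicate words in a
  year's merged table keep the maximum weight.
* MEDLINE records missing both title and abstract, or with no parseable
  4-digit year in the date field, are dropped and logged, never silently
  kept.

## Problem sizes

Tests and the reproduction script run on reduced corpora (hundreds of
documents, vocabularies of 100–150 words, K up to 100 for the table-geometry
check and K = 5–8 elsewhere); these sizes were chosen as the smallest at
which each property is stably exhibited, and the whole suite completes in
well under a minute on one CPU.

## Known limitations

* The rule-based tagger/lemmatizer trades linguistic coverage for
  determinism; no multiword chunking, abbreviation expansion or UMLS
  normalization is attempted.
* Relation extraction sees only lexicon terms inside exemplar topics'
  top-W words; diseases discussed outside those words are invisible.
* The negative-cosine clamp in the similarity is a documented deviation from
  the plain −1/cos θ formula, which is undefined in intent for cos θ < 0.
* Cluster counts depend on the preference; no preference scanning to force a
  target count is provided.
* Queries for bibliographic databases are emitted as strings; no network
  access is performed.
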