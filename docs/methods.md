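# Methods

## The model

Latent Dirichlet allocation treats each post d as a mixture θ_d over K
topics and each topic k as a distribution φ_k over the vocabulary:
θ_d ~ Dirichlet(α), φ_k ~ Dirichlet(η), and each token draws a topic
z ~ θ_d then a word w ~ φ_z. Fitting is by online variational Bayes: a
variational Dirichlet λ over each topic-word row and a per-document
variational Dirichlet γ are optimized stochastically. Documents are
processed in chunks; each chunk's E-step iterates

    γ_k = α + Σ_w n_w φ̂_wk,   φ̂_wk ∝ exp(E[log θ_k] + E[log φ_kw]),

per document until the mean absolute change in γ falls below the
tolerance, expectations using the digamma-difference form
E[log θ_k] = ψ(γ_k) − ψ(Σ_j γ_j); the chunk's sufficient statistics give
a noisy full-data update λ̂ that is blended as
λ ← (1 − ρ_t) λ + ρ_t λ̂ with ρ_t = (τ0 + t)^(−κ), t counting chunk
updates across passes.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| α | 1/K | symmetric document-topic prior |
| η | 1/K | symmetric topic-word prior (configurable; the α convention applied to the word side) |
| passes | 20 | full sweeps over the corpus |
| chunksize | 1000 | documents per stochastic update |
| decay κ | 0.5 | learning-rate exponent; κ ∈ [0.5, 1] is required for convergence |
| offset τ0 | 64 | down-weights early updates |
| iterations | 1000 | E-step iteration cap per document |
| gamma_threshold | 0.001 | mean-absolute-change convergence tolerance for γ |

### Numerical and determinism choices

- λ is initialized from seeded Gamma(100, 1/100) noise; γ is initialized
  deterministically at α + n_d/K (the prior plus an even split of the
  document's mass), so inference needs no per-document randomness.
- Document order is never shuffled; with a fixed seed two fits are
  bitwise identical.
- φ̂ is never materialized: the γ update and the sufficient statistics
  use the standard factorized form with a 1e-100 floor on the per-word
  normalizer; λ entries are floored at 1e-12.
- An empty document converges immediately to γ = α·1, i.e. a uniform
  topic mixture.
- The per-pass training log records a per-token log-likelihood proxy
  (log of the mixture probability of each token under the current θ̂, φ̂),
  useful for eyeballing convergence, not a variational bound.

## Preprocessing

Tokens are split on non-alphanumeric boundaries, lowercased; purely
numeric tokens, stopwords (a vendored 179-word standard English list) and
tokens shorter than 4 characters are removed, in that order, before
Porter stemming — stopwords are matched on surface forms, so "having"
never survives as the stem "have". The Porter stemmer is the classic
1980 algorithm, implemented in-package and pinned by the published
reference pairs plus the stems that appear in forum-topic labels
("potti", "nappi", "birthdai", "pregnanc").

Bigrams use a count-threshold collocation score on adjacent pairs,

    score(a, b) = (count(a,b) − min_count) · N_tokens / (count(a)·count(b)),

merging pairs with score > threshold (defaults min_count = 5,
threshold = 10) in a single left-to-right pass — a token joins at most
one merge, so no recursive merging occurs. The vocabulary filter then
applies the collection-count (≥ 50 occurrences, counting total
occurrences rather than documents) and document-fraction (≤ 50%) rules to
the post-bigram corpus, so bigram tokens are eligible vocabulary entries.
Ids are assigned lexicographically, making the dictionary deterministic.

## C_v coherence and model selection

C_v is computed exactly as its components are usually described: boolean
sliding windows of width 110 (step 1) per document — documents shorter
than the window contribute a single whole-document window — define
occurrence probabilities p(w) and co-occurrence probabilities p(wi, wj)
as fractions of windows; NPMI(wi, wj) = log((p_ij + ε)/(p_i p_j)) /
(−log(p_ij + ε)) with ε = 1e-12 added inside the joint only; one-set
segmentation gives each topic word a context vector of NPMIs against the
topic's whole top-20 word set (the self-entry uses p(w,w) = p(w), which
makes it 1); the topic score is the mean cosine between each word vector
and the summed set vector, and the corpus score is the mean over topics.
A word absent from every window falls back to ε probabilities rather
than crashing. Degenerate cases behave sensibly: a pair present in half
of all windows and absent from the rest scores exactly 1, and a
single-word topic scores 1.

Topic-number selection refits the model from `repeats` random starts
(seed = base_seed + repeat) at each candidate K and picks the K with the
highest mean C_v, ties going to the smallest K. The default grid is 2–34
with step 1; the reference corpus for coherence is the training corpus
itself rather than a held-out split, since coherence here is a
descriptive, not predictive, criterion.

## Topic analysis

- **Assignment**: strict threshold — topic = argmax θ only when
  max θ > 0.75.
- **Labels**: words ranked by a = log φ + log(φ)/P, φ from the model's
  normalized λ row and P the empirical word frequency in the filtered
  bag-of-words corpus (φ and P must share a vocabulary, so P is computed
  post-preprocessing). The formula is implemented literally; because its
  second term is typographically suspect (log(φ)/P vs log(φ/P)), the
  "relevance" reading a = log φ + log(φ/P) is available behind
  `form="relevance"` and covered by tests. Both are monotone in φ at
  fixed P, and rank-invariant to rescaling λ rows. Ties break
  lexicographically.
- **Graph**: similarity edges use cosine > 0.4 between topic-word
  probability vectors (the natural reading of "word frequency
  distribution"); shared-word edges use intersecting top-10-by-probability
  lists. Association ranks only the 4-word names.
- **Projection**: classical multidimensional scaling (double-centered
  squared dissimilarities, top-2 eigenvectors) of the pairwise
  Jensen–Shannon distance between topic-word distributions, centered at
  the origin.
- **Source proportions**: cell (s, k) = assigned posts of source s in
  topic k divided by all assigned posts of source s, so rows sum to 1 and
  sources of very different sizes are comparable.

## Validation statistics

The 3-of-50 retention rule for coded concerns is justified by a
one-sample, one-sided proportion z test using the sample-proportion
(Wald) standard error: z = (p̂ − p0)/√(p̂(1−p̂)/n), confidence = Φ(z).
With x = 3, n = 50, p0 = 0.01 this gives 93.2% confidence (one-sided
p ≈ 0.068). The Wald form, not the null-SE form, is the one that yields
these values — the null-SE z test would give p ≈ 2×10⁻⁴ — so the Wald SE
is pinned by test. Prevalence intervals are Wald intervals
p̂ ± z_{(1+L)/2}·SE, clipped to [0, 1] and reported as percentages
*truncated* (not rounded) to one decimal: (3, 50) → 0.4–11.5 and
(20, 50) → 28.6–51.3. Truncation is deliberate — the untruncated lower
bound of (3, 50) is 0.4756%, which ordinary rounding would print as
0.5 — and the exact bounds are also exposed
(`proportion_ci_exact`). The one-sided test and the interval are dual:
p0 sits below the lower L-level bound exactly when confidence exceeds
(1 + L)/2, a property the test suite checks over a grid.

Human coding itself is ingested, never automated: concern codes are
tallied on exact string match after case-folding and whitespace
normalization, codes seen ≥ 3 times are retained, a category tagged on
more than half of a topic's coded posts becomes its majority category,
and the cross-topic table reports per-category proportions plus headline
counts (topics with a majority; topics where fewer than a quarter of
posts were attributable to any category; categories represented at all).
The 11 parenting-question category names ship as a fixed controlled
vocabulary.

## Synthetic corpora

The generator emulates the count statistics of a two-source forum
corpus, not its language. Each of K_true topics concentrates a
`topic_separation` fraction of its mass uniformly on a private
vocabulary block (blocks are disjoint, size ⌊V/K⌋) with the remainder
spread uniformly over the whole vocabulary; document mixtures are
Dirichlet(α_true) with an optional per-source multiplicative tilt on
selected topics; document lengths are 5 + NegativeBinomial with mean 60
and shape 5 (so short posts occur but empty ones are rare); planted
bigram pairs emit their second word adjacently at a configurable rate;
placeholder posts, single-token spam posts and inserted US spellings are
injected at configurable rates (defaults 3%, 2%, 5%). Word ids render as
deterministic consonant-vowel pseudo-words at least six characters long,
built from an alphabet chosen so tokenization, stopword removal, the
length filter and Porter stemming all pass them through unchanged —
corpora are therefore diffable across runs, and the token-level route
(`generate_token_docs`) agrees exactly with the full text round-trip on
clean posts.

The standard test corpus is K_true = 4, V = 400, 2000 documents,
separation 0.9, α_true = 0.2. The separation makes topics
well-identified; α_true = 0.2 keeps most documents dominated by one or
two topics, as forum posts usually are, which also means a substantial
fraction clears the 0.75 assignment threshold. On this corpus the fitted
topics match the planted ones to mean total-variation ≈ 0.05 and the
coherence scan over 2–6 selects K = 4: merged topics (K < 4) put
never-co-occurring word blocks in one top-word list and score low, while
surplus topics (K > 4) either duplicate a block or collect weakly
co-occurring background words and drag the mean down.

What passing these tests does **not** show: real forum posts have burstier
vocabularies, topic correlations, threads and quoting, spelling noise
beyond the US/UK axis, and no ground truth; recovery numbers on the
generator are an upper bound on what real data would give, and the
pipeline's value on real corpora rests on the human validation loop, not
on these simulations.

## Pipeline reproducibility

Every stage writes its artifacts plus a manifest entry (config hash with
path settings excluded, seed, content checksums of its inputs, post
counts in/out); a stage whose hash and input checksums are unchanged is
skipped on rerun. Manifests contain no timestamps or absolute paths, so
the same analysis run twice — even in different directories — produces
byte-identical manifests, labels and reports. The per-stage counts form
the collection-to-analysis flow ledger (posts loaded → after cleaning →
encoded → assigned), which can only decrease along the chain.

## Problem sizes

The test suite and the acceptance script run the full standard corpus
(2000 documents) for recovery and a 2–6 × 3-repeat coherence scan, and
smaller corpora (300–600 documents, V ≈ 100) for the cheaper
distributional checks; these sizes give stable results for the planted
effect sizes while keeping a complete run in the minutes range on one
CPU.

## Known limitations

- The online variational Bayes implementation is single-threaded dense
  numpy; corpora in the 10⁵-document range train in minutes-to-hours
  depending on K, not seconds.
- Priors are symmetric and fixed; no "auto" prior optimization,
  hierarchical or dynamic extensions.
- Bigrams only (no trigrams), no lemmatization, no language detection.
- The association formula is implemented as printed; see the labeling
  note above for the alternative reading.
- Inter-rater reliability of the human coding is out of scope; coded
  samples are taken at face value.
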