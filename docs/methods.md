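# Methods

`telerec` implements a self-adaptive, content-based recommendation method
for telemedicine specialists. The input is a consultation log (each event
links a patient's free-text EMR to the specialist who handled it), a set of
specialist profiles with expertise labels and a service rating, and a binary
specialist × attribute long-term knowledge matrix. The output is a ranked,
fully decomposed top-N list of specialists for a target patient's EMR. This
note records the model, the parameters that matter, the numerical choices,
and what the synthetic test world does and does not demonstrate.

## Pipeline

The method runs in four stages, each of which only ever adds to or
re-ranks the candidate pool; the stage log preserves the pool after every
stage so each final score is auditable.

### 1. Patient feature model

EMR text is normalized with a synonym dictionary (variant disease names →
canonical terms, longest match first in a single pass), tokenized with a
pluggable tokenizer (default: whitespace with greedy multi-word user-term
matching; a Chinese segmenter can be plugged in as a callable), and
filtered against a stop-word list; tokens without any alphabetic character
(bare numbers, punctuation) are dropped. Exact duplicate records — all
five fields equal — are removed; two patients sharing a diagnosis sentence
are deliberately kept as distinct documents.

Each document becomes the TF-IDF-weighted mean of the word vectors of its
f *distinct* feature words:

    d_i = (1/f) · Σ_k v_k · tfidf(w_k, d_i)

with tf(w, d) = count(w, d)/|d| and idf(w) = ln(N/df(w)), unsmoothed
(df ≥ 1 always holds for corpus tokens, so no guard is needed). Word
vectors come from a skip-gram negative-sampling (word2vec-family) model
trained in-package: single-threaded SGD with a dynamic window, a
unigram^0.75 negative table, linear learning-rate decay, and a seeded
RNG, so a fixed seed reproduces vectors bit-for-bit. Defaults: dimension
100, window 5, 5 negatives, 5 epochs, initial rate 0.025.

Similarity between EMRs is standard cosine. Each specialist's initial
recommendation index `ini_score` is the *maximum* similarity between the
target EMR and any EMR that specialist treated (negative cosines are
floored at 0, since an index is a [0, 1] quantity). No similarity
threshold is applied — telemedicine patients often present uncommon
conditions and a threshold would unduly restrict the pool — and the top 10
specialists by `ini_score` form the initial candidate set. Ties everywhere
break by specialist id ascending, for reproducibility.

### 2. Long-term knowledge and cold start

The long-term knowledge matrix holds binary expertise indicators with
possible missing cells. Missing cells are filled by column frequency: a
cell becomes 1 iff at least half of the *observed* cells in its column are
1. (Counting missing cells as zeros would bias filling toward 0,
defeating the fairness intent of frequency filling; a fully unobserved
column fills with 0 — no evidence of expertise.) Row similarity is the
weighted Jaccard coefficient Σ w·min / Σ w·max, which reduces to the plain
Jaccard coefficient under uniform weights (the default); an optional
rarity weighting w_p = ln(n/(1+Σ_j a_jp)) is available.

Newly registered specialists — fewer than three logged consultations —
with knowledge similarity ≥ 0.7 to a current candidate h receive

    ini_score'_j = ini_score_j + (1/q) · Σ_h ini_score_h · Sim(j, h)

over the q qualifying candidates, and join the pool. Existing members are
never removed or down-scored. Only newly registered specialists are
inserted this way; veterans outside the pool are reached by stage 3.

### 3. Short-term knowledge and semantic extension

Each specialist's recently diagnosed EMRs are concatenated into one
training document and modeled with LDA fitted by collapsed Gibbs
sampling (authored in-package; the sampler is a seeded, sequential numba
kernel, and parameter estimates use the final sweep's counts with
Dirichlet smoothing, so all φ and θ entries are positive and rows sum
to 1). Defaults: α = 50/K, β = 0.01, 500 iterations, K = 10. A specialist
with no diagnosed EMRs gets the symmetric prior mean — a uniform topic
distribution — rather than an error: with no data the posterior is the
prior.

Topic profiles are compared with the Jensen–Shannon divergence using
base-2 logarithms, so D_JS ∈ [0, 1], and similarity = 1 − D_JS (the
minimal monotone conversion onto [0, 1]). Pool members keep short_score
= 1; for each member, non-member specialists with similarity ≥ 0.8 (top
10 per seed member) are added with the seed's `ini_score` and the
similarity as `short_score`; a specialist reachable from several seeds
keeps the assignment maximizing ini_score × short_score.

**Topic-count selection.** The number of topics is chosen from the
training-perplexity curve over a K grid, where perplexity is
exp(−mean log P(w|d)) with P(w|d) = Σ_t P(w|t) P(t|d). Training
perplexity decreases (near-)monotonically in K — adding topics always
fits the training corpus at least slightly better — so the default rule
takes the curve's *elbow*: the grid point farthest above the chord joining
the curve's endpoints (the Kneedle construction, parameter-free). A plain
argmin rule is available as `method="min"` and is also the fallback for
grids with fewer than three points; exact ties resolve to the smaller K.
On synthetic corpora with 5 planted topics (V = 300, 500 documents, grid
2–10) the elbow rule recovers K* ± 1 in 10/10 seeds, while argmin always
returns the top of the grid.

### 4. Activity, preferences, QoS and fusion

Specialist activity is a time-decayed consultation share,

    AC_j = Σ_t N_j(t) · e^{−t} / N(t),    LAC_j = AC_j / AC_max,

with the period fixed to calendar months, t = whole months before the
newest record's month, and a 12-period horizon (the time base of the decay
is otherwise unspecified; e^{−t} uses the dimensionless period index). The
professional index is prof_score = LAC × ini_score × short_score.

Patients answer one five-category Likert item per strategy (Extremely
like … Extremely dislike → 4 … 0); the two numbers a, b give fusion
weights ω_p = a/(a+b), ω_q = b/(a+b), with (0.5, 0.5) as the 0/0
fallback so the constraint ω_p + ω_q = 1 always holds. Objective QoS is
the running mean of per-specialist service ratings on a 0–5 scale
(configurable), seeded from the profile's rating column and normalized by
the maximum over all specialists. The final ranking is

    compre_score = ω_p · prof_score' + ω_q · qos_score,

where prof_score' normalizes by the maximum professional score *within
the current candidate pool* (the fusion is applied to the list being
ranked, not the platform at large). If every pool member has zero
professional score the normalized value is defined as 0.

## Synthetic world

The generator produces a complete, seed-reproducible world with known
ground truth: a planted K* × V topic-word matrix φ* (Dirichlet rows,
concentration 0.08 over V = 300 words), per-specialist topic mixtures
(Dirichlet, concentration 0.15 over K* = 5 topics — mass concentrates on
one or two topics), and one consultation per patient whose text is drawn
token-by-token via topic-then-word draws from the specialist's mixture.
Default scale: 50 specialists, 1000 patients, 12 months. Documents average
30 tokens (Poisson, minimum 5), with stop-word symbols sprinkled at rate
0.08 and variant spellings of the first 10 vocabulary words at rate 0.5,
so the preprocessing stages have real work to do.

The knowledge attribute p corresponds to topic p: a_jp = 1 iff specialist
j's mixture mass on topic p is ≥ 0.2, with the dominant topic always
marked (so no row is all-zero); cells are then masked at the missing rate
(default 0.2). Every veteran receives at least one consultation, with
volumes beyond that drawn from skewed Dirichlet shares; a few specialists
(default 4) are newly registered with at most two consultations. With the
planted-match flag, one newcomer copies the knowledge row and mixture of
the strongest veteran for the target topic and receives *no*
consultations — long-term expertise without platform history, the pure
cold-start case — and the copied rows are excluded from masking so the
planted similarity is exactly 1. Ratings are clipped Gaussian draws
around a latent quality that is *independent* of topical relevance, which
is what makes the preference-weight sweep informative: leaning on QoS
cannot help topical precision.

The target patient's EMR is drawn from a single topic (one-hot mixture,
double length); the ground-truth best-match list contains the specialists
whose dominant topic is the target topic, and the broader label-based
relevant set (used as the retrieval universe for recall) contains every
specialist carrying the target disease label.

What passing tests on this world do **not** show: real clinical language
(synthetic symbol tokens sidestep segmentation, negation, abbreviation),
patient demographics or department structure, non-stationary specialist
interests, or rating dynamics; conclusions about real EMR corpora require
real data.

## Numerical and testing choices

- All stochastic components (embedding, Gibbs sampler, generator) are
  single-threaded and seeded; pipeline runs are bit-reproducible.
- Formula implementations (cosine, weighted Jaccard, JS divergence,
  activity, fusion, QoS arithmetic) are tested against independent
  oracles — SciPy distance routines, brute-force set enumeration, direct
  loop evaluation — on 1000 random instances each.
- Degenerate inputs are errors, not silent defaults: empty corpora, zero
  vectors, unnormalized distributions, out-of-scale ratings, unknown
  Likert categories, newcomers absent from the knowledge matrix.
- Statistical checks use fixed problem sizes chosen to keep the default
  suite desk-scale: topic recovery on 500-document corpora (3 seeds for
  φ* cosine recovery, 10 for topic-count selection), end-to-end recovery
  and the preference sweep on 20 seeded default worlds.
- The rank-priority score for human rationality ratings implements the
  printed prior (10−r)/45, which does not sum to 1 across ranks; a
  normalized variant (denominator Σ(10−r)) is available behind a flag.

## Known limitations

- The skip-gram and Gibbs kernels favor determinism over speed; corpora
  are expected to be desk-scale (thousands of documents), and no
  approximate nearest-neighbor search is attempted.
- Perplexity is computed on the training corpus; the elbow rule
  compensates for its monotone decrease in K, but a held-out/document-
  completion evaluation would be preferable at larger scales.
- Extension inherits the seed member's `ini_score`, which is a modeling
  choice (the fused score needs one); alternatives (e.g. discounting by
  similarity) are not explored.
- Waiting cost, scheduling, and online learning of the preference weights
  are out of scope.
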