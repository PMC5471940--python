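# Methods

## Model

`actopics` fits a three-facet admixture model to bibliographic records. The
latent structure is a set of K topics; observed facets are keyphrase tokens,
author lists, and one journal per paper. Generatively, each token of paper
*d* picks one of the paper's A_d authors uniformly, the author picks a topic
from their Dirichlet-multinomial topic distribution θ_a, and the topic emits
both the keyphrase (ψ_z over the V keyphrases) and the paper's journal (φ_z
over the J journals). The model is an author–conference–topic style model
with journals in the venue role and a bag-of-keyphrases in place of a
bag-of-words; keyphrases are opaque atomic units (no stemming or case
folding), which keeps topics interpretable as sets of controlled-vocabulary
phrases.

Two modeling consequences are worth stating explicitly:

* **Journal emission is token-level.** A paper has one observed journal, but
  every token's topic "re-emits" it, so each row of the topic×journal count
  table sums to that topic's token total. This keeps φ a topic×journal
  stochastic matrix and lets well-populated topics pin their journal profile
  sharply.
* **(z, x) are resampled jointly.** The collapsed full conditional for a
  token factorizes over the K × A_d candidate pairs as the product of three
  smoothed count ratios (see README). Sampling the pair jointly avoids the
  slow mixing of alternating z-then-x updates when an author and a topic are
  strongly coupled. Whether the original formulation of this model family
  sampled the pair jointly or sequentially is not documented; joint sampling
  is this package's choice.

The collapsed conditional was validated against brute-force enumeration of
all joint assignment configurations on tiny corpora (max absolute deviation
below 1e-10; see `tests/helpers.py` for the lgamma-based oracle).

## Hyperparameters and defaults

| parameter | default | meaning |
|---|---|---|
| K | 20 | topic count (10–50 is the usual scan range) |
| α | 50/K | author-topic Dirichlet concentration (standard heuristic) |
| β | 0.01 | topic-keyphrase concentration (sparse topics) |
| γ | 0.01 | topic-journal concentration |
| iterations | 1000 | Gibbs sweeps; no burn-in/thinning by default |

The point estimate is taken from the final sweep (matching single-run
reporting practice); `fit(average_last=S)` optionally averages the smoothed
estimates over the last S sweeps. Draws use numpy's PCG64 generator; the
categorical draw is inverse-CDF over (k, a) pairs in k-major order, so a run
is bit-reproducible given (corpus, hyperparameters, seed). The per-sweep
collapsed joint log-probability is logged; its trend (median of late sweeps ≥
median of early sweeps) is the convergence diagnostic used in tests.

Degenerate inputs: documents require ≥1 author; zero-keyphrase documents are
kept in corpus statistics but excluded from fitting (they carry no tokens);
an all-empty corpus is an error; K=1 collapses the sampler to author
resampling only.

## Held-out evaluation

Perplexity is exp(−mean log p(token)) over held-out tokens: 1 for a
perfectly certain model, V for the uniform model. Held-out documents are
scored by fold-in: ψ and φ frozen, 50 local sweeps (20 burn-in, both
configurable) estimate the document's author-topic counts, the post-burn-in
average local θ̂ is mixed uniformly over the document's authors, and
p(w|d) = Σ_k mix_k ψ[k,w]. Out-of-vocabulary tokens are dropped and counted
rather than smoothed — the conventional choice that keeps perplexities
comparable across models sharing a training vocabulary. A held-out journal
unseen in training multiplies every candidate topic by the same constant and
so cancels from the local conditional.

Topic similarity is the mean Pearson correlation over all C(K,2) pairs of ψ
rows — keyphrase profiles, not φ or θ, because "similarity between topics"
most naturally means what the topics are about. Zero-variance rows (possible
at K much larger than the effective topic count) are skipped and reported.
Run stability refits the model under seeds seed+0 … seed+r−1 and reports the
per-run similarity values, their mean and range; two invocations with the
same arguments return identical reports.

The period × K perplexity grid fits one model per (period, K) cell — α
follows 50/K as K varies — and scores a common held-out corpus, appending
average row and column. Absolute perplexity magnitudes depend strongly on
corpus and vocabulary size, so only within-grid comparisons are meaningful.

## Trend analysis

Per topic, keyphrases are ranked by ψ[k,·] and journals by φ[k,·]. Authors
need care: θ conditions on the author, so ranking authors *within* a topic
uses the Bayes inversion P(a|k) ∝ θ[a,k]·n(a). For n(a) the package uses the
expected token attribution Σ_{d ∋ a} N_d / A_d, which is computable from the
corpus alone (no sampler state) and equals the expected number of tokens the
uniform author-choice step hands to *a*. Ties anywhere break
lexicographically.

A journal's per-period topical mass is the φ column sum Σ_k φ[k,j] (masses
sum to K, so individual values may exceed 1 — which is why multi-period sums
in the point range of a few units are expected). Journals present in every
period enter the trajectory table with per-period values, sum, average =
sum/periods, gap = max − min, and a shape label:

* **rising** / **falling** — monotone non-decreasing / non-increasing;
* **peak** — rises to an interior maximum then falls; **dip** — the mirror
  image. The bibliometrics literature sometimes calls these shapes "convex"
  and "concave" respectively — the reverse of the mathematical convention —
  so this package uses the neutral labels (that usage's convex → peak,
  concave → dip);
* **other** — flat trajectories, gaps below `min_gap` (default 0: classify
  everything), and non-unimodal shapes.

With only two periods, only rising/falling/other are distinguishable and the
table degrades to that. Presence counts tally how often an entity occurs in
any top list per (period, topic) pair and per distinct period, with
multiplicity histograms that conserve the unique-entity total.

## Synthetic corpora

The generator draws θ, φ, ψ from symmetric Dirichlets (concentration 0.1 by
default — peaked, recoverable truths; ≥1 gives diffuse null truths) and
samples documents by the generative story above. One wrinkle: the model
emits a journal per token but a document observes one journal, so the
generator uses the *first token's* topic to draw it. This is simple and
reproducible but makes φ recovery noisier than ψ recovery — one journal draw
per document versus N_d keyphrase draws — which is why recovery expectations
are set lower for φ. Years are assigned round-robin over the configured
period-representative years, giving balanced period slices.

Label switching is resolved by greedy best-first matching of fitted to true
ψ rows on Pearson correlation; on small K the greedy match was verified to
sit within 0.02 mean correlation of the exhaustive-permutation optimum.

What the generator does **not** emulate: real keyphrase Zipf profiles,
author productivity skew, journal size imbalance, topic drift across
periods, or citation structure. Passing recovery tests therefore shows the
inference machinery is correct and well-calibrated on model-faithful data,
not that the model is adequate for any particular real corpus.

## Problem sizes used in the shipped analyses

The `analysis/` scripts use a four-period synthetic corpus of D=240
documents (K=5, V=120, A=30, J=8, 15–40 tokens per document, 300 sweeps per
period, 150 for the stability/perplexity refits) — large enough that matched
topic correlations reach ≈0.9 and the perplexity grid sits far below the
uniform score, small enough to run in a few minutes on one core. The
recovery benchmark in `scripts/acceptance.py` uses D=400, K=5, V=200,
N_d ~ U(30, 80), 500 sweeps, where mean matched ψ correlation ≈ 0.97 and φ
≈ 0.94 at seed 1.

## Known limitations

* Single-chain point estimates; no convergence diagnostics beyond the joint
  log-probability trend, and no hyperparameter optimization.
* Author identity is the exact normalized name string — no disambiguation,
  so homonyms merge and name variants split.
* The fold-in estimator mixes authors uniformly; documents whose authors
  have very different topic profiles are scored conservatively.
* Period models are fit independently (as in time-sliced topic analysis);
  topics are matched across periods only by their entity lists, not by any
  coupled prior, so cross-period topic identity is heuristic.
* Absolute perplexities are not comparable across corpora with different
  vocabularies or token counts.
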