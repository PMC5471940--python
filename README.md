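# actopics

Multi-faceted topic modeling of bibliographic corpora: one probabilistic
model that links **keyphrases, authors, and journals** through shared latent
topics, plus the evaluation and trend-analysis machinery needed to study how
a research field evolves over time.

The motivating use case is scientometrics of interdisciplinary fields such as
bioinformatics: given twenty years of PubMed records (PMID, authors, journal,
year, title, abstract, and a pre-extracted keyphrase list per paper), fit a
topic model per five-year period and ask *which topics rise or fall, which
authors lead them, and which journals carry them*.

## The model

Each paper *d* has authors **a**_d (A_d ≥ 1), one journal *j*, and N_d
keyphrase tokens (a bag-of-keyphrases: each multi-word phrase is a single
vocabulary unit). For every token:

1. an author *x* is drawn uniformly from **a**_d,
2. a topic *z* ~ Multinomial(θ_x) from that author's topic distribution,
3. the keyphrase *w* ~ Multinomial(ψ_z) and the paper's journal
   *j* ~ Multinomial(φ_z) are emitted by the topic.

θ (author×topic), φ (topic×journal), and ψ (topic×keyphrase) carry symmetric
Dirichlet priors α, γ, β (defaults α = 50/K, β = γ = 0.01). Inference is
collapsed Gibbs sampling: the Dirichlet parameters are integrated out and
each token's (z, x) pair is resampled jointly from

```
P(z=k, x=a | rest) ∝  (n_AT[a,k]+α)/(n_A[a]+Kα)
                    × (n_TW[k,w]+β)/(n_T[k]+Vβ)
                    × (n_TJ[k,j]+γ)/(n_T[k]+Jγ)
```

with count tables excluding the current token. Point estimates are the
smoothed, row-normalized counts.

Evaluation: held-out perplexity by fold-in (freeze ψ and φ, estimate each
held-out document's local author-topic mixture with short Gibbs runs) and
run-to-run stability (mean pairwise Pearson correlation of ψ rows, compared
across reseeded fits). Trend analysis: per-period top entities, per-journal
aggregate topical mass Σ_k φ[k,j] tracked across periods, max−min gaps, and
rising / falling / peak / dip trajectory shapes.

Because no public deposit of the original 46-journal corpus exists, the
package includes a generator that samples corpora from the model's own
generative process with known ground truth, so every stage is testable
offline (including topic-recovery checks after greedy label matching).

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
four-period corpus (outputs under `results/`, intermediate corpora under
`scratch/`):

```
python analysis/01_printed_tables.py   # bibliometric shares of the study tables
python analysis/02_simulate.py         # synthetic 4-period corpus + held-out set
python analysis/03_fit_periods.py      # collapsed Gibbs fit per period
python analysis/04_evaluate.py         # stability + perplexity grid
python analysis/05_trends.py           # trajectories, patterns, presence counts
```

`01` prints, from the tables shipped under `data/`:

```
collected papers: 241,569 across 46 journals
top journal: Biochemistry with 62,270 papers (25.78%)
20-year corpus: 170,099 papers
most productive year: 2014 (12,251 papers, 7.20%)
fourth period share: 31.46% (53,520 papers)
```

i.e. one journal alone contributes a quarter of the raw collection, and the
last five-year period is the most productive with 31.46% of the
abstract-filtered corpus. `03` reports, per period, the sampler's joint
log-probability climbing to a plateau and the mean matched-topic correlation
between fitted and generating keyphrase distributions (0.7–0.9 at these
60-document period sizes — the model recovers the truth it simulates from,
more sharply as the corpus grows). `04` prints each run's mean
pairwise topic correlation (a narrow band across seeds indicates stable
topics) and a period × K perplexity grid against the held-out sample, all far
below the uniform-model score (= vocabulary size). `05` classifies each
all-period journal's trajectory shape and counts recurring top entities.

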