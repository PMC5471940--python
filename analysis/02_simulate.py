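#!/usr/bin/env python
"""Generate the synthetic study corpus.

Draws a ground truth (K=5 topics over V=120 keyphrases, A=30 authors, J=8
journals, peaked Dirichlet concentration 0.1) and samples a four-period
corpus of 240 documents plus a disjoint held-out set in the role of a
later-year test sample, all from the same truth. Corpora (tabular dialect)
and the ground-truth matrices go to scratch/study/ for the downstream
scripts; a small summary lands in results/study/.
"""

from pathlib import Path

import pandas as pd

from actopics.corpus import corpus_statistics, write_tabular
from actopics.synthetic import GeneratorSettings, GroundTruth, sample_corpus, sample_ground_truth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
OUT = ROOT / "results" / "study"
SCRATCH.mkdir(parents=True, exist_ok=True)
OUT.mkdir(parents=True, exist_ok=True)

SETTINGS = GeneratorSettings(
    D=240, K=5, A=30, J=8, V=120,
    tokens_per_doc=(15, 40),
    concentration=0.1,
    years=(1996, 2001, 2006, 2011),  # one representative year per period
    seed=42,
)

truth = sample_ground_truth(SETTINGS)
corpus, _, _ = sample_corpus(truth)
write_tabular(corpus.documents, SCRATCH / "corpus.tsv")

heldout_settings = GeneratorSettings(
    D=40, K=5, A=30, J=8, V=120, tokens_per_doc=(15, 40),
    concentration=0.1, years=(2016,), seed=43,
)
heldout, _, _ = sample_corpus(
    GroundTruth(truth.theta_true, truth.phi_true, truth.psi_true, heldout_settings)
)
write_tabular(heldout.documents, SCRATCH / "heldout.tsv")

topics = [f"topic_{k}" for k in range(SETTINGS.K)]
pd.DataFrame(truth.theta_true, columns=topics).to_csv(SCRATCH / "theta_true.csv", index=False)
pd.DataFrame(truth.phi_true, index=topics).to_csv(SCRATCH / "phi_true.csv")
pd.DataFrame(truth.psi_true, index=topics).to_csv(SCRATCH / "psi_true.csv")

stats = corpus_statistics(corpus.documents, "period")
stats.to_csv(OUT / "synthetic_period_counts.csv", index=False)
print(f"study corpus: {corpus} -> {SCRATCH/'corpus.tsv'}")
print(f"held-out corpus: {heldout.n_documents} docs, {heldout.n_tokens} tokens")
print(stats.to_string(index=False))
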