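"""Independent oracles used by the model tests.

These recompute quantities from first principles (counts tallied directly
from assignment vectors, Dirichlet-multinomial joints via lgamma) without
touching the sampler's count tables, so they stay independent of the code
paths they check.
"""

from math import lgamma

import numpy as np

from actopics.corpus import Corpus
from actopics.model import Hyperparams


def tally_counts(corpus: Corpus, z_flat, x_flat, K: int):
    """Count tables recomputed by direct tally of per-token assignments."""
    nAT = np.zeros((corpus.A, K), dtype=int)
    nTW = np.zeros((K, corpus.V), dtype=int)
    nTJ = np.zeros((K, corpus.J), dtype=int)
    i = 0
    for d in range(corpus.n_documents):
        j = corpus.journal_id[d]
        for w in corpus.token_ids[d]:
            k, a = int(z_flat[i]), int(x_flat[i])
            nAT[a, k] += 1
            nTW[k, w] += 1
            nTJ[k, j] += 1
            i += 1
    return nAT, nTW, nTJ


def dirichlet_multinomial_log(counts: np.ndarray, conc: float) -> float:
    """log ∏_rows B(row + conc) / B(conc) for a symmetric Dirichlet prior."""
    out = 0.0
    n_cols = counts.shape[1]
    for row in counts:
        out += lgamma(n_cols * conc) - lgamma(row.sum() + n_cols * conc)
        for c in row:
            out += lgamma(c + conc) - lgamma(conc)
    return out


def collapsed_joint_log(corpus: Corpus, z_flat, x_flat, hp: Hyperparams) -> float:
    """Collapsed joint log-probability of a full assignment configuration."""
    nAT, nTW, nTJ = tally_counts(corpus, z_flat, x_flat, hp.K)
    return (
        dirichlet_multinomial_log(nAT, hp.alpha)
        + dirichlet_multinomial_log(nTW, hp.beta)
        + dirichlet_multinomial_log(nTJ, hp.gamma)
    )


def enumeration_conditional(
    corpus: Corpus, z_flat, x_flat, target: int, hp: Hyperparams
) -> np.ndarray:
    """Exact full conditional over (author, topic) for one token.

    Evaluates the collapsed joint at every candidate (z, x) value of the
    target token with all other assignments held fixed, then normalizes.
    Returns an A_d × K table ordered by the document's author list.
    """
    d = int(np.searchsorted(
        np.cumsum([len(t) for t in corpus.token_ids]), target, side="right"
    ))
    authors = corpus.author_ids[d]
    z = np.array(z_flat, dtype=int)
    x = np.array(x_flat, dtype=int)
    table = np.zeros((len(authors), hp.K))
    for ai, a in enumerate(authors):
        for k in range(hp.K):
            z[target] = k
            x[target] = a
            table[ai, k] = collapsed_joint_log(corpus, z, x, hp)
    table = np.exp(table - table.max())
    return table / table.sum()
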