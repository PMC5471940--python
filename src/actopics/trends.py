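"""Period-wise topic summaries, journal topical trajectories, and pattern
classification.

A fitted model yields, per topic, ranked keyphrases (by ψ), journals (by φ)
and authors; since θ conditions on the author, authors are ranked within a
topic by the Bayes inversion P(a|k) ∝ θ[a,k]·n(a), where n(a) is the
author's expected token attribution Σ_{d ∋ a} N_d / A_d computed from the
corpus alone.

Journal trajectories aggregate φ column mass per journal (Σ_k φ[k,j], so
values can exceed 1 and sum to K over journals) in each period, and classify
each all-period journal's trajectory shape as rising, falling, peak, dip, or
other. "Peak" and "dip" are neutral names for trajectories that rise then
fall, or fall then rise; in the bibliometrics literature these shapes are
sometimes called "convex" and "concave" respectively (the reverse of the
mathematical convention), which is why neutral labels are used here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .model import Posterior

__all__ = [
    "TopicSummary",
    "JournalTrajectory",
    "top_entities",
    "journal_topic_mass",
    "trajectory_table",
    "classify_pattern",
    "gap",
    "presence_counts",
]

PATTERNS = ("rising", "falling", "peak", "dip", "other")


@dataclass
class TopicSummary:
    """Ranked top entities of one topic in one period."""

    period: str
    topic: int
    keyphrases: list[tuple[str, float]]
    authors: list[tuple[str, float]]
    journals: list[tuple[str, float]]


@dataclass
class JournalTrajectory:
    """One journal's aggregate topical probability across periods."""

    journal: str
    values: list[float]
    sum: float = field(init=False)
    average: float = field(init=False)
    gap: float = field(init=False)
    pattern: str = field(init=False)

    def __post_init__(self) -> None:
        self.sum = float(np.sum(self.values))
        self.average = self.sum / len(self.values)
        self.gap = gap(self.values)
        self.pattern = _pattern_or_monotone(self.values)


def _ranked(labels: Sequence[str], values: np.ndarray, top_n: int) -> list[tuple[str, float]]:
    """Sort by value descending, ties lexicographic; truncate to top_n."""
    order = sorted(range(len(labels)), key=lambda i: (-values[i], labels[i]))
    return [(labels[i], float(values[i])) for i in order[:top_n]]


def author_token_mass(corpus: Corpus) -> np.ndarray:
    """Expected tokens attributed to each author: Σ_{d ∋ a} N_d / A_d."""
    mass = np.zeros(corpus.A)
    for d in range(corpus.n_documents):
        authors = corpus.author_ids[d]
        mass[authors] += len(corpus.token_ids[d]) / len(authors)
    return mass


def top_entities(
    posterior: Posterior, corpus: Corpus, top_n: int = 30, period: str = ""
) -> list[TopicSummary]:
    """Per-topic ranked keyphrase/author/journal lists.

    Author scores are the normalized P(a|k) ∝ θ[a,k]·n(a). Requesting more
    entries than a registry holds returns the full ranked list.
    """
    n_a = author_token_mass(corpus)
    summaries = []
    for k in range(posterior.K):
        author_score = posterior.theta[:, k] * n_a
        total = author_score.sum()
        if total > 0:
            author_score = author_score / total
        summaries.append(
            TopicSummary(
                period=period,
                topic=k,
                keyphrases=_ranked(posterior.vocab_labels, posterior.psi[k], top_n),
                authors=_ranked(posterior.author_labels, author_score, top_n),
                journals=_ranked(posterior.journal_labels, posterior.phi[k], top_n),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[TopicSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for kind, ranked in (
            ("keyphrase", s.keyphrases), ("author", s.authors), ("journal", s.journals)
        ):
            for rank, (label, val) in enumerate(ranked, start=1):
                rows.append((s.period, s.topic, kind, rank, label, val))
    return pd.DataFrame(
        rows, columns=["period", "topic", "kind", "rank", "entity", "probability"]
    )


def journal_topic_mass(posterior: Posterior) -> dict[str, float]:
    """Aggregate topical probability per journal: mass(j) = Σ_k φ[k,j].

    Masses sum to K over all journals (each φ row sums to one).
    """
    mass = posterior.phi.sum(axis=0)
    labels = posterior.journal_labels or [str(j) for j in range(len(mass))]
    return {lab: float(m) for lab, m in zip(labels, mass)}


def gap(values) -> float:
    """Range of a trajectory: max − min."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gap of empty sequence")
    return float(v.max() - v.min())


def classify_pattern(values, min_gap: float = 0.0) -> str:
    """Shape label for a per-period trajectory.

    Flat trajectories (or those with gap below ``min_gap``) are "other";
    otherwise: monotone non-decreasing → rising, non-increasing → falling,
    rise-then-fall around an interior maximum → peak, fall-then-rise around
    an interior minimum → dip, anything else → other.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("pattern classification needs at least 3 values")
    g = float(v.max() - v.min())
    if g == 0.0 or g < min_gap:
        return "other"
    diffs = np.diff(v)
    if (diffs >= 0).all():
        return "rising"
    if (diffs <= 0).all():
        return "falling"
    m = int(np.argmax(v))
    if 0 < m < v.size - 1 and (diffs[:m] >= 0).all() and (diffs[m:] <= 0).all():
        return "peak"
    m = int(np.argmin(v))
    if 0 < m < v.size - 1 and (diffs[:m] <= 0).all() and (diffs[m:] >= 0).all():
        return "dip"
    return "other"


def _pattern_or_monotone(values, min_gap: float = 0.0) -> str:
    """classify_pattern, degrading gracefully for 2-value trajectories
    (where only rising/falling/other are distinguishable)."""
    v = np.asarray(values, dtype=float)
    if v.size >= 3:
        return classify_pattern(v, min_gap=min_gap)
    g = float(v.max() - v.min())
    if g == 0.0 or g < min_gap:
        return "other"
    return "rising" if v[-1] > v[0] else "falling"


def trajectory_table(
    per_period_masses: Sequence[Mapping[str, float]],
    min_gap: float = 0.0,
) -> tuple[list[JournalTrajectory], list[str]]:
    """Trajectories for journals present in every period.

    A journal is "present" in a period when it appears in that period's mass
    map. Returns the all-period trajectories sorted by sum descending (ties
    alphabetical) and the list of journals excluded for missing a period.
    """
    if len(per_period_masses) < 2:
        raise ValueError("need at least 2 periods")
    seen: Counter[str] = Counter()
    for masses in per_period_masses:
        seen.update(masses.keys())
    n_periods = len(per_period_masses)
    everywhere = [j for j, c in seen.items() if c == n_periods]
    excluded = sorted(j for j, c in seen.items() if c < n_periods)
    rows = [
        JournalTrajectory(
            journal=j, values=[float(m[j]) for m in per_period_masses]
        )
        for j in everywhere
    ]
    for r in rows:
        r.pattern = _pattern_or_monotone(r.values, min_gap=min_gap)
    rows.sort(key=lambda r: (-r.sum, r.journal))
    return rows, excluded


def trajectories_to_frame(rows: Sequence[JournalTrajectory]) -> pd.DataFrame:
    n_periods = len(rows[0].values) if rows else 0
    data = {
        "journal": [r.journal for r in rows],
        **{
            f"period_{p + 1}": [r.values[p] for r in rows] for p in range(n_periods)
        },
        "sum_probability": [r.sum for r in rows],
        "average_probability": [r.average for r in rows],
        "gap": [r.gap for r in rows],
        "pattern": [r.pattern for r in rows],
    }
    return pd.DataFrame(data)


def presence_counts(
    summaries: Sequence[TopicSummary], entity_kind: str = "author"
) -> dict[str, pd.Series]:
    """How often each top-listed entity appears across topics and periods.

    An entity "appears" when it occurs in the top list of a (period, topic)
    pair. Returns topic-appearance counts, period-appearance counts (distinct
    periods), and histograms of both multiplicities (how many entities appear
    in exactly n topics / periods).
    """
    attr = {"author": "authors", "journal": "journals", "keyphrase": "keyphrases"}
    if entity_kind not in attr:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    topic_counts: Counter[str] = Counter()
    period_sets: dict[str, set[str]] = {}
    for s in summaries:
        for label, _ in getattr(s, attr[entity_kind]):
            topic_counts[label] += 1
            period_sets.setdefault(label, set()).add(s.period)
    topic_s = pd.Series(topic_counts, dtype=int).sort_values(ascending=False)
    period_s = pd.Series(
        {e: len(ps) for e, ps in period_sets.items()}, dtype=int
    ).sort_values(ascending=False)
    return {
        "topic_counts": topic_s,
        "period_counts": period_s,
        "topic_histogram": topic_s.value_counts().sort_index(),
        "period_histogram": period_s.value_counts().sort_index(),
    }
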