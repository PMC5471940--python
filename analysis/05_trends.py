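#!/usr/bin/env python
"""Topical trend analysis across periods.

From the per-period posteriors fitted by 03_fit_periods.py: aggregate each
journal's topical probability per period, keep the journals present in every
period, classify each trajectory's shape (rising / falling / peak / dip /
other) with its max–min gap, and count how often authors, journals, and
keyphrases recur across topics and periods. Tables go to results/study/.
"""

from pathlib import Path

import pandas as pd

from actopics.pipeline import load_posterior
from actopics.trends import (
    journal_topic_mass,
    presence_counts,
    trajectories_to_frame,
    trajectory_table,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "study"

period_dirs = sorted(OUT.glob("period_*"))
if not period_dirs:
    raise SystemExit("no fitted periods found: run 03_fit_periods.py first")

masses = [journal_topic_mass(load_posterior(p)) for p in period_dirs]
rows, excluded = trajectory_table(masses)
frame = trajectories_to_frame(rows)
frame.to_csv(OUT / "journal_trajectories.csv", index=False)
print(f"{len(rows)} journals present in all {len(period_dirs)} periods"
      + (f"; excluded: {', '.join(excluded)}" if excluded else ""))
print(frame.round(4).to_string(index=False))
print("\npattern counts:", frame["pattern"].value_counts().to_dict())

summaries = []
from actopics.trends import TopicSummary  # reconstruct from the saved CSVs

for pdir in period_dirs:
    t = pd.read_csv(pdir / "topic_summaries.csv")
    for (period, topic), grp in t.groupby(["period", "topic"]):
        by_kind = {
            kind: list(zip(g["entity"], g["probability"]))
            for kind, g in grp.groupby("kind")
        }
        summaries.append(TopicSummary(
            period=str(period), topic=int(topic),
            keyphrases=by_kind.get("keyphrase", []),
            authors=by_kind.get("author", []),
            journals=by_kind.get("journal", []),
        ))

for kind in ("author", "journal", "keyphrase"):
    pc = presence_counts(summaries, kind)
    pc["topic_counts"].rename("topic_count").rename_axis("entity").to_csv(
        OUT / f"presence_{kind}_topics.csv"
    )
    pc["period_counts"].rename("period_count").rename_axis("entity").to_csv(
        OUT / f"presence_{kind}_periods.csv"
    )
    uniq = len(pc["topic_counts"])
    multi = int((pc["period_counts"] > 1).sum())
    print(f"{kind}: {uniq} unique top-listed entities, {multi} appear in 2+ periods")
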