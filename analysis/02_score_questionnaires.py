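"""Score the simulated questionnaires: quadrant raw sums, normative
categories, signed axis scores (BR, T), derived quadrants,
highest-raw-score quadrants and personality axes.

Reads results/cohort/, writes results/scores.csv and prints the quadrant
classification cross-table.
"""

import argparse
from pathlib import Path

import pandas as pd

from sensory_axes import io as sio
from sensory_axes.epq import score_epq
from sensory_axes.profile import (
    QUADRANTS,
    axis_groups,
    axis_scores,
    categorize,
    derived_quadrant,
    highest_quadrant,
    score_quadrants,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/scores.csv"))
    args = ap.parse_args()

    item_map = sio.read_item_map(args.cohort / "item_map.csv")
    epq_map = sio.read_epq_map(args.cohort / "epq_map.csv")
    norms = sio.read_norms(args.cohort / "norms.yaml")
    responses = sio.read_responses(args.cohort / "responses.csv")
    epq = sio.read_epq_responses(args.cohort / "epq.csv")

    rows = []
    for resp in responses:
        raw = score_quadrants(resp, item_map)
        axes = axis_scores(resp, item_map)
        cats = categorize(raw, norms)
        hq = highest_quadrant(raw)
        row = {"participant_id": resp.participant_id}
        row.update({f"raw_{q}": raw[q] for q in QUADRANTS})
        row.update({f"cat_{q}": cats[q] for q in QUADRANTS})
        row["br"], row["t"] = axes.br, axes.t
        row["derived_quadrant"] = derived_quadrant(axes)
        row["highest_quadrant"] = hq.quadrant or ""
        row["tie_flag"] = hq.tie
        if not hq.tie:
            row["br_group"], row["t_group"] = axis_groups(hq.quadrant)
        e = score_epq(epq[resp.participant_id], epq_map)
        row["ie"], row["neuroticism"] = e.ie, e.neuroticism
        rows.append(row)

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"scored {len(df)} participants -> {args.out}")
    print(f"ties (excluded from quadrant analyses): {int(df['tie_flag'].sum())}")
    ok = df[~df["tie_flag"] & (df["derived_quadrant"] != "unclassified")]
    print("\nhighest-raw vs derived quadrant:")
    print(pd.crosstab(ok["highest_quadrant"], ok["derived_quadrant"]))


if __name__ == "__main__":
    main()
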