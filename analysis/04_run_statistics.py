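"""Run the full statistical battery on the scored cohort.

Assembles the cohort from results/cohort/ plus the ERP measures in
results/serp.csv and runs the analysis sequence: axis/quadrant agreement
(Fisher, chi-squared, Cramer's V), per-group ANOVAs of axis scores across
normative categories with Tukey post hoc, the introversion/extraversion
t-test, and the P50/gating comparisons and correlations.

Writes the report tables under results/report/ and prints the summary.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sensory_axes import io as sio
from sensory_axes.runner import CohortDataset, Participant, run_analysis
from sensory_axes.serp import GatingResult, P50Measurement, SerpResult


def serp_from_row(row) -> SerpResult:
    res = SerpResult()
    res.single = P50Measurement(
        amplitude=float(row["p50_amp_uV"]),
        latency_ms=float(row["p50_latency_ms"]),
        meets_criterion=bool(row["meets_criterion"]),
    )
    c_amp, t_amp = float(row["c_amp"]), float(row["t_amp"])
    valid = bool(row["valid"])
    res.gating = GatingResult(
        c_amplitude=c_amp, t_amplitude=t_amp,
        ratio=t_amp / c_amp if valid else None, valid=valid,
    )
    return res


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--serp", type=Path, default=Path("results/serp.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    ap.add_argument("--fisher-seed", type=int, default=1)
    args = ap.parse_args()

    item_map = sio.read_item_map(args.cohort / "item_map.csv")
    epq_map = sio.read_epq_map(args.cohort / "epq_map.csv")
    norms = sio.read_norms(args.cohort / "norms.yaml")
    responses = sio.read_responses(args.cohort / "responses.csv")
    epq = sio.read_epq_responses(args.cohort / "epq.csv")
    serp = pd.read_csv(args.serp).set_index("participant_id")

    participants = []
    for resp in responses:
        pid = resp.participant_id
        participants.append(
            Participant(
                participant_id=pid,
                responses=resp,
                epq=epq.get(pid),
                serp=serp_from_row(serp.loc[pid]) if pid in serp.index else None,
            )
        )
    data = CohortDataset(participants=participants, item_map=item_map, epq_map=epq_map)
    report = run_analysis(data, norms, fisher_seed=args.fisher_seed)
    report.to_csv(args.out)
    print(report.summary())
    print(f"\nreport tables written to {args.out}/")


if __name__ == "__main__":
    main()
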