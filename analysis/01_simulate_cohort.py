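"""Simulate the study cohort: questionnaire responses, personality
responses and per-participant EEG ground truth.

Writes, under results/cohort/:
  item_map.csv, epq_map.csv, norms.yaml   -- instrument configuration
  responses.csv, epq.csv                  -- simulated questionnaires
  truth.csv                               -- archetype, evoked amplitude and
                                             gating factor per participant
  eeg_manifest.csv                        -- per-participant simulation seeds
                                             (EEG is regenerated from these by
                                             03_erp_pipeline.py; continuous
                                             recordings are too large to keep)
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sensory_axes import io as sio
from sensory_axes.epq import default_epq_map
from sensory_axes.profile import default_item_map, default_norms
from sensory_axes.simulate import CohortSpec, simulate_epq_responses, simulate_responses


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=139, help="cohort size")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    item_map = default_item_map()
    epq_map = default_epq_map()
    norms = default_norms()
    spec = CohortSpec(n=args.n, seed=args.seed)
    rng = np.random.default_rng(args.seed)

    responses, labels = simulate_responses(spec, item_map, rng=rng)
    epq_ratings = simulate_epq_responses(labels, epq_map, spec, rng=rng)

    # per-participant ERP ground truth: sub-criterion median amplitude, so
    # only part of the cohort shows a measurable P50 (as with low-intensity
    # stimulation); one participant misses the EEG session
    amp = np.exp(np.log(0.45) + 0.7 * rng.standard_normal(args.n))
    gating = np.clip(rng.normal(0.77, 0.3, args.n), 0.05, 1.0)
    missing = rng.integers(args.n)
    seeds = rng.integers(2**31 - 2, size=args.n)

    sio.write_item_map(item_map, args.out / "item_map.csv")
    sio.write_epq_map(epq_map, args.out / "epq_map.csv")
    sio.write_norms(norms, args.out / "norms.yaml")
    sio.write_responses(responses, args.out / "responses.csv")
    sio.write_epq_responses(
        {r.participant_id: e for r, e in zip(responses, epq_ratings)},
        args.out / "epq.csv",
    )
    truth = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in responses],
            "archetype": labels,
            "amplitude_uv": amp,
            "gating": gating,
            "has_eeg": [i != missing for i in range(args.n)],
        }
    )
    truth.to_csv(args.out / "truth.csv", index=False)
    truth.assign(sim_seed=seeds)[["participant_id", "sim_seed", "amplitude_uv",
                                  "gating", "has_eeg"]].to_csv(
        args.out / "eeg_manifest.csv", index=False
    )
    counts = truth["archetype"].value_counts()
    print(f"simulated n = {args.n} participants (seed {args.seed})")
    print("archetype mixture:", dict(counts))
    print(f"P(true amplitude >= 0.5 uV) = {(amp >= 0.5).mean():.2f}")
    print(f"outputs in {args.out}/")


if __name__ == "__main__":
    main()
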