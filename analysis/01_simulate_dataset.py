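#!/usr/bin/env python
"""Generate the synthetic study dataset.

35 participants x 240 trials (12 identities x 5 emotions x 4 presentation
conditions), 3-s trials with 5-12 fixations each, emotion-specific fixation
hotspots, condition-specific refixation dynamics and confusion-structured
responses.  Writes fixations.csv, trials.csv and ground_truth.json under
results/data/.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from gazemark.core_data import write_dataset
from gazemark.synthetic_scanpaths import default_config, generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = default_config(seed=seed)
    fixations, trials, truth = generate_dataset(config)
    write_dataset(fixations, trials, OUT / "fixations.csv", OUT / "trials.csv")
    truth_dict = dataclasses.asdict(truth)
    truth_dict["accuracy"] = {f"{e}|{c}": v for (e, c), v in truth.accuracy.items()}
    (OUT / "ground_truth.json").write_text(json.dumps(truth_dict, indent=2))

    n_per = trials.groupby("participant_id").size()
    print(f"wrote {len(trials)} trials / {len(fixations)} fixations to {OUT}")
    print(f"trials per participant: {sorted(n_per.unique())}")
    print(f"overall response accuracy: {trials['correct'].mean():.3f}")
    print("accuracy by condition:")
    print(trials.groupby("condition")["correct"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
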