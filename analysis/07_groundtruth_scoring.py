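"""Score a synthetic ground-truthing matching exercise.

Simulates a validation panel (16 external experts, 9 students, up to 3
locations each) matching anonymised map colours to the five supergroups,
with externals more reliable than students, then scores accuracy per
supergroup and participant stratum. Writes results/groundtruth_scores.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ageplace.groundtruth import score_responses

ROOT = Path(__file__).resolve().parents[1] / "results"

P_CORRECT = {"external": 0.75, "student": 0.6}
SUPERGROUPS = ("1", "2", "3", "4", "5")
COLOURS = ("red", "blue", "green", "orange", "purple")


def main() -> None:
    rng = np.random.default_rng(0)
    # 56 locations; each shows all five supergroups under shuffled colours
    key_rows = []
    for loc in range(56):
        perm = rng.permutation(5)
        for colour, sg_idx in zip(COLOURS, perm):
            key_rows.append(
                {"location": f"L{loc:02d}", "colour": colour,
                 "supergroup": SUPERGROUPS[sg_idx]}
            )
    key = pd.DataFrame(key_rows)

    resp_rows = []
    participants = [(f"ext{i}", "external") for i in range(16)] + [
        (f"stu{i}", "student") for i in range(9)
    ]
    for pid, ptype in participants:
        locations = rng.choice(56, size=rng.integers(1, 4), replace=False)
        for loc in locations:
            loc_key = key[key["location"] == f"L{loc:02d}"]
            for _, row in loc_key.iterrows():
                if rng.random() < P_CORRECT[ptype]:
                    choice = row["supergroup"]
                else:
                    others = [s for s in SUPERGROUPS if s != row["supergroup"]]
                    choice = rng.choice(others)
                resp_rows.append(
                    {"participant_id": pid, "participant_type": ptype,
                     "location": row["location"], "colour": row["colour"],
                     "choice": choice}
                )
    responses = pd.DataFrame(resp_rows)

    scores = score_responses(responses, key)
    scores.round(1).to_csv(ROOT / "groundtruth_scores.csv")
    print(scores[["external", "student", "all"]].round(1).to_string())
    pooled = 100 * (
        scores["n_all"] * scores["all"] / 100
    ).sum() / scores["n_all"].sum()
    print(f"overall accuracy: {pooled:.1f}% over {scores['n_all'].sum()} matches")


if __name__ == "__main__":
    main()
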