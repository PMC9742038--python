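"""Pen-portrait z-score profiles and supergroup summaries.

Profiles supergroups against the all-area average and groups against
their parent supergroup, exports the salient top/bottom variables per
domain and the radar-chart table, and prints the supergroup summary
(size, 50+ population share, age structure).
Writes results/portraits_*.csv, results/summary.csv,
results/salient_variables.csv, results/radar_data.csv.
"""

from pathlib import Path

import pandas as pd

from ageplace.catalogue import variable_catalogue
from ageplace.profiles import (
    cluster_zscores,
    pen_portrait_export,
    radar_data,
    standardise,
    summary_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scaled = pd.read_csv(ROOT / "scaled_matrix.csv").set_index("area_id")
    assign = pd.read_csv(ROOT / "hierarchy.csv", dtype=str).set_index("area_id")
    pop = pd.read_csv(ROOT / "sources" / "population.csv")
    cat = variable_catalogue()

    X_std = standardise(scaled)
    super_z = cluster_zscores(X_std, assign["supergroup"])
    group_z = cluster_zscores(
        X_std, assign["group"], reference="parent",
        parent_labels=assign["supergroup"],
    )
    super_z.to_csv(ROOT / "portraits_supergroups.csv")
    group_z.to_csv(ROOT / "portraits_groups.csv")
    pen_portrait_export(super_z, cat, top_n=3).to_csv(
        ROOT / "salient_variables.csv", index=False
    )
    radar_data(super_z, cat).to_csv(ROOT / "radar_data.csv", index=False)

    class Hier:  # summary_table accepts anything exposing .assignments
        assignments = assign.reset_index()

    summary = summary_table(pop, Hier)
    summary.to_csv(ROOT / "summary.csv")
    print(summary.round(2).to_string())
    for code in summary.index:
        top = (
            super_z.loc[code].sort_values(ascending=False).index[0]
        )
        print(f"supergroup {code}: most distinctive variable {top} "
              f"(z = {super_z.loc[code].max():+.2f})")


if __name__ == "__main__":
    main()
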