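"""Pen-portrait profiles and supergroup summary statistics.

A cluster's pen portrait is the mean z-score of each input variable
over its member areas: 0 marks the all-area average (the *global*
reference frame), positive values above average. Second-tier groups are
profiled against their parent supergroup instead (*parent* frame:
columns re-standardised within the supergroup subset), so a group's
scores read as deviations from its parent's typical area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ageplace.catalogue import VariableCatalogue


def standardise(X: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores: (x - mean) / SD (ddof=0). Constant columns raise."""
    sd = X.std(ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"cannot standardise constant columns: {bad}")
    return (X - X.mean()) / sd


def cluster_zscores(
    X_std: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    reference: str = "global",
    parent_labels: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean z-score per cluster per variable (clusters x variables).

    ``reference="global"``: ``X_std`` must already be globally
    column-standardised; rows are grouped by ``labels`` and averaged.
    ``reference="parent"``: ``parent_labels`` assigns each area to a
    parent cluster; columns are re-standardised within each parent
    subset before averaging over ``labels`` (which must nest within the
    parents), so scores are in parent-SD units about the parent mean.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=X_std.index)
    if reference == "global":
        return X_std.groupby(labels).mean()
    if reference != "parent":
        raise ValueError("reference must be 'global' or 'parent'")
    if parent_labels is None:
        raise ValueError("parent frame requires parent_labels")
    parents = pd.Series(np.asarray(parent_labels, dtype=object), index=X_std.index)
    pieces = []
    for parent, sub in X_std.groupby(parents):
        pieces.append(standardise(sub).groupby(labels.loc[sub.index]).mean())
    return pd.concat(pieces).sort_index()


def older_person_ratio(population: pd.DataFrame) -> pd.Series:
    """Population 65+ relative to population 18-64, per area.

    Areas with ``pop_18_64 == 0`` get NaN (flagged missing), never an
    exception or infinity.
    """
    denom = population["pop_18_64"].to_numpy(dtype=float)
    num = population["pop_65_plus"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, num / denom, np.nan)
    return pd.Series(ratio, index=population["area_id"].to_numpy(), name="older_person_ratio")


def summary_table(population: pd.DataFrame, hierarchy) -> pd.DataFrame:
    """Supergroup summaries: size, share of 50+ population, age structure.

    Columns: ``n_areas``, ``pct_pop_50plus`` (share of the total 50+
    population living in the supergroup), ``mean_median_age`` (unweighted
    mean of area median ages) and ``mean_older_person_ratio``.
    """
    assign = hierarchy.assignments if hasattr(hierarchy, "assignments") else hierarchy
    pop = population.merge(assign[["area_id", "supergroup"]], on="area_id")
    if len(pop) != len(assign):
        raise ValueError("population and hierarchy do not share all area ids")
    opr = older_person_ratio(pop)
    pop = pop.assign(older_person_ratio=opr.to_numpy())
    total50 = pop["pop_50_plus"].sum()
    g = pop.groupby("supergroup")
    out = pd.DataFrame(
        {
            "n_areas": g.size(),
            "pct_pop_50plus": 100.0 * g["pop_50_plus"].sum() / total50,
            "mean_median_age": g["median_age"].mean(),
            "mean_older_person_ratio": g["older_person_ratio"].mean(),
        }
    )
    out.index.name = "supergroup"
    return out.sort_index(key=lambda ix: ix.astype(int))


def pen_portrait_export(
    portraits: pd.DataFrame,
    catalogue: VariableCatalogue,
    top_n: int = 3,
) -> pd.DataFrame:
    """Top and bottom ``top_n`` variables per domain per cluster.

    Ordering is deterministic: descending z-score, ties broken by
    lexical variable id. Returns a long table with columns ``cluster,
    domain, direction (top/bottom), rank, variable_id, z``.
    """
    domain_of = dict(
        zip(catalogue.table["variable_id"], catalogue.table["domain"])
    )
    rows = []
    for cluster, zrow in portraits.iterrows():
        frame = pd.DataFrame(
            {
                "variable_id": zrow.index,
                "z": zrow.to_numpy(dtype=float),
                "domain": [domain_of[v] for v in zrow.index],
            }
        )
        for domain, sub in frame.groupby("domain"):
            ordered = sub.sort_values(
                ["z", "variable_id"], ascending=[False, True]
            )
            for rank, (_, r) in enumerate(ordered.head(top_n).iterrows(), 1):
                rows.append((cluster, domain, "top", rank, r["variable_id"], r["z"]))
            bottom = ordered.tail(top_n).iloc[::-1]
            for rank, (_, r) in enumerate(bottom.iterrows(), 1):
                rows.append((cluster, domain, "bottom", rank, r["variable_id"], r["z"]))
    return pd.DataFrame(
        rows, columns=["cluster", "domain", "direction", "rank", "variable_id", "z"]
    )


def radar_data(portraits: pd.DataFrame, catalogue: VariableCatalogue) -> pd.DataFrame:
    """Long-form portrait table for radar/bar charts.

    One row per (cluster, variable): columns ``cluster, domain,
    variable_id, z``, with variables ranked within domain by z-score.
    """
    domain_of = dict(
        zip(catalogue.table["variable_id"], catalogue.table["domain"])
    )
    long = portraits.stack().rename("z").reset_index()
    long.columns = ["cluster", "variable_id", "z"]
    long["domain"] = long["variable_id"].map(domain_of)
    long["rank_in_domain"] = (
        long.groupby(["cluster", "domain"])["z"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    return long[["cluster", "domain", "variable_id", "z", "rank_in_domain"]]
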