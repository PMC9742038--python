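"""Clustergram diagnostics and the two-tier k-means hierarchy.

The top tier (*supergroups*) partitions all areas; each supergroup is
then clustered again on the same scaled variables to give nested
*groups* with codes ``"s.j"``. Cluster numbering at both tiers follows
descending member count so that runs are comparable. The clustergram —
per-k cluster centres projected on the first principal component, with
member flows between consecutive k — supports the (traditionally
visual) choice of k; :func:`suggest_k` automates it with the mean
Silhouette score while exposing the full diagnostics for a human
override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

#: Silhouette below which a suggested k is flagged as weak structure
#: (the Kaufman-Rousseeuw rule of thumb: under ~0.25 no substantial
#: structure has been found).
WEAK_SILHOUETTE = 0.25


def fit_kmeans(
    X: np.ndarray | pd.DataFrame,
    k: int,
    n_init: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` k-means; returns (labels, centres, inertia)."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


def pc1_scores(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """First-principal-component scores of the column-centred matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    # deterministic sign: largest-|loading| coordinate positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return Xc @ v


@dataclass
class Clustergram:
    """Per-k PC1 node positions, member counts, and inter-k flows."""

    nodes: pd.DataFrame        # k, cluster, pc1_mean, count
    transitions: pd.DataFrame  # k, from_cluster, to_cluster, count
    labels: dict[int, np.ndarray] = field(default_factory=dict)


def build_clustergram(
    X: np.ndarray | pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    n_init: int = 10,
    seed: int = 0,
) -> Clustergram:
    """Fit k-means over ``k_range`` and collect clustergram geometry.

    Node position of cluster c at a given k is the mean PC1 score of its
    members (PC1 computed once on the full column-centred matrix);
    transition counts tally areas moving between cluster assignments at
    consecutive k.
    """
    X = np.asarray(X, dtype=float)
    scores = pc1_scores(X)
    ks = list(k_range)
    labels: dict[int, np.ndarray] = {}
    node_rows = []
    for k in ks:
        lab, _, _ = fit_kmeans(X, k, n_init=n_init, seed=seed)
        labels[k] = lab
        for c in range(k):
            mask = lab == c
            node_rows.append(
                {
                    "k": k,
                    "cluster": c,
                    "pc1_mean": float(scores[mask].mean()) if mask.any() else np.nan,
                    "count": int(mask.sum()),
                }
            )
    trans_rows = []
    for k_prev, k_next in zip(ks[:-1], ks[1:]):
        tab = pd.crosstab(labels[k_prev], labels[k_next])
        for frm in tab.index:
            for to in tab.columns:
                n = int(tab.loc[frm, to])
                if n > 0:
                    trans_rows.append(
                        {"k": k_prev, "from_cluster": int(frm),
                         "to_cluster": int(to), "count": n}
                    )
    return Clustergram(
        nodes=pd.DataFrame(node_rows),
        transitions=pd.DataFrame(trans_rows),
        labels=labels,
    )


@dataclass
class KSelection:
    k: int
    diagnostics: pd.DataFrame  # k, silhouette, calinski_harabasz, davies_bouldin, inertia
    weak_structure: bool


def suggest_k(
    X: np.ndarray | pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    n_init: int = 10,
    seed: int = 0,
) -> KSelection:
    """Suggest k by maximum mean Silhouette (ties to the smaller k).

    Automates the visual clustergram inspection; the diagnostics table
    (Silhouette, Calinski-Harabasz, Davies-Bouldin, inertia per k) is
    returned so an analyst can override. A best Silhouette below
    ``WEAK_SILHOUETTE`` flags weak structure.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    best_k, best_sil = None, -np.inf
    for k in k_range:
        lab, _, inertia = fit_kmeans(X, k, n_init=n_init, seed=seed)
        sil = silhouette_score(X, lab)
        rows.append(
            {
                "k": k,
                "silhouette": sil,
                "calinski_harabasz": calinski_harabasz_score(X, lab),
                "davies_bouldin": davies_bouldin_score(X, lab),
                "inertia": inertia,
            }
        )
        if sil > best_sil:  # strict: first (smallest) k wins ties
            best_sil, best_k = sil, k
    return KSelection(
        k=int(best_k),
        diagnostics=pd.DataFrame(rows),
        weak_structure=bool(best_sil < WEAK_SILHOUETTE),
    )


@dataclass
class ClusterHierarchy:
    """Two-tier assignment plus fitted centres and reproducibility info."""

    assignments: pd.DataFrame            # area_id, supergroup, group
    centres_top: pd.DataFrame            # supergroup code -> centre
    centres_sub: dict[str, pd.DataFrame]  # supergroup code -> group centres
    seed: int = 0
    n_init: int = 100

    @property
    def supergroups(self) -> list[str]:
        return sorted(self.assignments["supergroup"].unique(), key=int)

    @property
    def groups(self) -> list[str]:
        return sorted(self.assignments["group"].unique())


def _relabel_by_size(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Map raw k-means labels to 1..k in descending member count.

    Ties break on the raw label for determinism. Returns (new_labels,
    order) where ``order[i]`` is the raw label ranked i-th.
    """
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    mapping = np.empty(k, dtype=int)
    mapping[order] = np.arange(1, k + 1)
    return mapping[labels], order


def fit_two_tier(
    X: pd.DataFrame,
    k_top: int = 5,
    k_sub: Sequence[int] | Mapping[str, int] = (3, 2, 2, 3, 3),
    n_init: int = 100,
    seed: int = 0,
) -> ClusterHierarchy:
    """Fit the supergroup tier, then re-cluster within each supergroup.

    ``X`` must be the range-scaled variable matrix indexed by area id.
    ``k_sub`` gives the second-tier k per supergroup code (a sequence
    aligned with codes "1".."k_top", or a mapping keyed by code). Codes:
    supergroups "1".."k_top" in descending size, groups "s.j" with j
    likewise descending within the supergroup.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame indexed by area id")
    if isinstance(k_sub, Mapping):
        sub_k = {str(c): int(k) for c, k in k_sub.items()}
    else:
        if len(k_sub) != k_top:
            raise ValueError("k_sub must provide one entry per supergroup")
        sub_k = {str(i + 1): int(k) for i, k in enumerate(k_sub)}
    missing = [str(i + 1) for i in range(k_top) if str(i + 1) not in sub_k]
    if missing:
        raise ValueError(f"k_sub missing supergroups: {missing}")

    raw_top, centres, _ = fit_kmeans(X, k_top, n_init=n_init, seed=seed)
    top, order = _relabel_by_size(raw_top, k_top)
    centres_top = pd.DataFrame(
        centres[order], index=[str(i) for i in range(1, k_top + 1)],
        columns=X.columns,
    )

    group = np.empty(len(X), dtype=object)
    centres_sub: dict[str, pd.DataFrame] = {}
    for s in range(1, k_top + 1):
        code = str(s)
        mask = top == s
        ks = sub_k[code]
        Xs = X.loc[mask]
        if ks == 1 or len(Xs) <= ks:
            sub_labels = np.zeros(int(mask.sum()), dtype=int)
            centres_s = Xs.mean().to_frame().T
            sub_new = sub_labels + 1
            centres_sub[code] = centres_s.set_axis([f"{code}.1"])
        else:
            raw_sub, c_sub, _ = fit_kmeans(Xs, ks, n_init=n_init, seed=seed)
            sub_new, sub_order = _relabel_by_size(raw_sub, ks)
            centres_sub[code] = pd.DataFrame(
                c_sub[sub_order],
                index=[f"{code}.{j}" for j in range(1, ks + 1)],
                columns=X.columns,
            )
        group[mask] = [f"{code}.{j}" for j in sub_new]

    assignments = pd.DataFrame(
        {
            "area_id": X.index,
            "supergroup": top.astype(str),
            "group": group,
        }
    ).reset_index(drop=True)
    return ClusterHierarchy(
        assignments=assignments,
        centres_top=centres_top,
        centres_sub=centres_sub,
        seed=seed,
        n_init=n_init,
    )
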