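"""Small-area estimation of digital engagement.

Two stages mirror the standard survey-to-small-area workflow:

1. *Spatial microsimulation*: iterative proportional fitting (IPF)
   reweights the survey so that, for each area, weighted category totals
   match that area's constraint marginals (age, gender, qualification,
   social grade, economic activity). Weighted outcome means then give
   per-area percentage estimates — but only areas with enough locally
   observed respondents yield trustworthy training targets.
2. *Supervised extension*: a gradient-boosted regressor (sample-weighted
   by observation counts) learns the map from area-level constraint
   shares to the microsimulated percentages on well-observed areas
   (>= 11 respondents) and predicts every area.

IPF updates depend on a respondent only through their constraint
categories, so respondents sharing an attribute cell always keep equal
weights. Internally the solver therefore iterates over the (at most a
few hundred) distinct cells and expands back to individuals, which is
exactly equivalent and orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ageplace.synth import CONSTRAINT_VARIABLES

OUTCOME_COLUMNS = ("broadband", "info", "shopbank", "social")
PCT_COLUMNS = ("pct_broadband", "pct_info", "pct_shopbank", "pct_social")


class InfeasibleConstraintError(ValueError):
    """A constraint category has positive target count but no survey support."""

    def __init__(self, empty_cells: list[tuple[str, str]]):
        self.empty_cells = empty_cells
        super().__init__(
            "no survey support for constraint cells: "
            + ", ".join(f"{v}={c}" for v, c in empty_cells)
        )


@dataclass
class IPFResult:
    """Converged (or capped) IPF weights for one area."""

    weights: np.ndarray            # one non-negative weight per survey row
    converged: bool
    n_iter: int
    max_rel_deviation: float       # max |marginal - target| / area_total
    redistributed: list[tuple[str, str]] = field(default_factory=list)


def constraints_for_area(constraints: pd.DataFrame, area_id: str) -> dict:
    """Extract one area's marginals as {variable: {category: count}}."""
    sub = constraints.loc[constraints["area_id"] == area_id]
    if sub.empty:
        raise KeyError(f"area {area_id!r} not in constraint table")
    out: dict[str, dict[str, float]] = {}
    for var, g in sub.groupby("variable"):
        out[str(var)] = dict(zip(g["category"], g["count"].astype(float)))
    return out


def _check_totals(area_constraints: Mapping[str, Mapping[str, float]],
                  tol: float) -> float:
    totals = {v: float(sum(c.values())) for v, c in area_constraints.items()}
    vals = np.array(list(totals.values()))
    if vals.max() - vals.min() > tol * max(vals.max(), 1.0):
        raise ValueError(
            f"constraint variables disagree on the area total: {totals}"
        )
    return float(vals.mean())


def _prepare_targets(
    survey: pd.DataFrame,
    area_constraints: Mapping[str, Mapping[str, float]],
    on_empty: str,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list[tuple[str, str]]]:
    """Category codes per variable + target vectors, handling empty cells.

    ``on_empty='redistribute'`` moves targets of unsupported categories
    onto the variable's supported categories proportionally to their
    targets; ``'error'`` raises :class:`InfeasibleConstraintError`.
    """
    codes: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    empties: list[tuple[str, str]] = []
    for var, cat_targets in area_constraints.items():
        if var not in survey.columns:
            raise KeyError(f"survey lacks constraint variable {var!r}")
        cats = list(cat_targets.keys())
        t = np.array([float(cat_targets[c]) for c in cats])
        code = pd.Categorical(survey[var], categories=cats).codes
        if (code < 0).any():
            bad = sorted(set(survey[var]) - set(cats))
            raise ValueError(f"survey has unknown {var} categories: {bad}")
        support = np.bincount(code, minlength=len(cats)) > 0
        empty = [(var, cats[j]) for j in range(len(cats))
                 if not support[j] and t[j] > 0]
        if empty:
            if on_empty == "error":
                raise InfeasibleConstraintError(empty)
            empties.extend(empty)
            lost = t[~support].sum()
            kept = t[support].sum()
            if kept <= 0:
                raise InfeasibleConstraintError(empty)
            t = np.where(support, t * (1.0 + lost / kept), 0.0)
        codes[var] = code
        targets[var] = t
    return codes, targets, empties


def ipf_reweight_area(
    survey: pd.DataFrame,
    area_constraints: Mapping[str, Mapping[str, float]],
    max_iter: int = 1000,
    tol: float = 1e-8,
    on_empty: str = "redistribute",
) -> IPFResult:
    """IPF-reweight the survey to one area's constraint marginals.

    Starting from uniform weights summing to the area total, each
    iteration rescales weights so one constraint variable's weighted
    category totals match its targets, cycling through all variables.
    Convergence: max absolute marginal deviation, relative to the area
    total, below ``tol``.
    """
    area_total = _check_totals(area_constraints, tol=1e-6)
    codes, targets, redistributed = _prepare_targets(
        survey, area_constraints, on_empty
    )
    n = len(survey)
    # collapse to joint cells: identical rows keep identical weights
    code_mat = np.column_stack([codes[v] for v in area_constraints])
    cells, cell_of = np.unique(code_mat, axis=0, return_inverse=True)
    cell_n = np.bincount(cell_of).astype(float)
    cell_codes = {v: cells[:, j] for j, v in enumerate(area_constraints)}

    w = np.full(len(cells), area_total / n) * cell_n  # cell total weights
    converged = False
    it = 0
    dev = np.inf
    for it in range(1, max_iter + 1):
        for var, t in targets.items():
            code = cell_codes[var]
            sums = np.bincount(code, weights=w, minlength=len(t))
            factor = np.ones_like(t)
            nz = sums > 0
            factor[nz] = np.where(t[nz] > 0, t[nz] / sums[nz], 0.0)
            w = w * factor[code]
        dev = max(
            np.abs(
                np.bincount(cell_codes[v], weights=w, minlength=len(t))
                - targets[v]
            ).max()
            for v, t in targets.items()
        ) / max(area_total, 1.0)
        if dev < tol:
            converged = True
            break
    weights = (w / cell_n)[cell_of]
    return IPFResult(
        weights=weights,
        converged=converged,
        n_iter=it,
        max_rel_deviation=float(dev),
        redistributed=redistributed,
    )


def estimate_area_percentages(
    weights_by_area: Mapping[str, np.ndarray],
    survey: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOME_COLUMNS,
) -> pd.DataFrame:
    """Weighted outcome percentages per area: 100 * sum(w*y) / sum(w)."""
    rows = []
    y = survey[list(outcomes)].to_numpy(dtype=float)
    for area_id, w in weights_by_area.items():
        w = np.asarray(w, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"area {area_id!r}: weights sum to zero")
        pct = 100.0 * (w @ y) / total
        rows.append({"area_id": area_id, **{
            f"pct_{o}": p for o, p in zip(outcomes, pct)
        }})
    return pd.DataFrame(rows)


def sms_estimates(
    survey: pd.DataFrame,
    constraints: pd.DataFrame,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """IPF + weighted means for every area in the constraint table.

    Returns per-area percentage estimates for the four outcomes plus a
    ``converged`` flag.
    """
    y = survey[list(OUTCOME_COLUMNS)].to_numpy(dtype=float)
    rows = []
    for area_id in constraints["area_id"].unique():
        cons = constraints_for_area(constraints, area_id)
        res = ipf_reweight_area(survey, cons, max_iter=max_iter, tol=tol)
        pct = 100.0 * (res.weights @ y) / res.weights.sum()
        rows.append(
            {
                "area_id": area_id,
                **{f"pct_{o}": p for o, p in zip(OUTCOME_COLUMNS, pct)},
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def select_training_areas(
    survey: pd.DataFrame, min_obs: int = 11
) -> tuple[list[str], pd.Series]:
    """Areas with at least ``min_obs`` geocoded respondents.

    Returns the qualifying area ids and the full per-area observation
    counts (used downstream as sample weights).
    """
    located = survey.dropna(subset=["area_id"])
    counts = located.groupby("area_id").size()
    training = counts.index[counts >= min_obs].tolist()
    return training, counts


def training_share(n_training: int, n_total: int) -> float:
    """Percentage of areas usable for supervised training."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_training / n_total


def constraint_features(constraints: pd.DataFrame) -> pd.DataFrame:
    """Area-level model features: each constraint category's share.

    One column per (variable, category): category count divided by the
    area total, the natural area-level representation of the marginals.
    """
    wide = constraints.pivot_table(
        index="area_id", columns=["variable", "category"], values="count",
        aggfunc="sum", fill_value=0.0,
    )
    totals = constraints.groupby(["area_id", "variable"])["count"].sum()
    area_total = totals.groupby("area_id").mean()
    shares = wide.div(area_total, axis=0)
    shares.columns = [f"{v}:{c}" for v, c in shares.columns]
    return shares


def _default_model_factory(seed: int) -> Callable[[], object]:
    from xgboost import XGBRegressor

    def make() -> object:
        return XGBRegressor(
            n_estimators=300,
            max_depth=3,
            learning_rate=0.1,
            subsample=0.9,
            colsample_bytree=0.9,
            n_jobs=1,
            random_state=seed,
        )

    return make


def fit_predict_sae(
    area_features: pd.DataFrame,
    sms_targets: pd.DataFrame,
    obs_counts: pd.Series,
    model_factory: Callable[[], object] | None = None,
    seed: int = 0,
    min_training_areas: int = 10,
) -> pd.DataFrame:
    """Train one sample-weighted regressor per outcome; predict all areas.

    ``sms_targets`` holds microsimulated percentages for the training
    areas only (index or ``area_id`` column). ``obs_counts`` are per-area
    respondent counts used as sample weights. Predictions are clipped to
    [0, 100] and produced for every row of ``area_features``.
    """
    if "area_id" in sms_targets.columns:
        sms_targets = sms_targets.set_index("area_id")
    train_ids = sms_targets.index.intersection(area_features.index)
    if len(train_ids) < min_training_areas:
        raise ValueError(
            f"only {len(train_ids)} training areas; need >= {min_training_areas}"
        )
    factory = model_factory or _default_model_factory(seed)
    X_train = area_features.loc[train_ids].to_numpy()
    X_all = area_features.to_numpy()
    w = obs_counts.reindex(train_ids).fillna(0.0).to_numpy(dtype=float)
    out = pd.DataFrame(index=area_features.index)
    for col in PCT_COLUMNS:
        model = factory()
        model.fit(X_train, sms_targets[col].to_numpy(), sample_weight=w)
        out[col] = np.clip(model.predict(X_all), 0.0, 100.0)
    return out.reset_index().rename(columns={"index": "area_id"})


def estimate_digital_engagement(
    survey: pd.DataFrame,
    constraints: pd.DataFrame,
    min_obs: int = 11,
    seed: int = 0,
    model_factory: Callable[[], object] | None = None,
) -> pd.DataFrame:
    """Full SAE chain: IPF microsimulation on training areas + model extension.

    Areas clearing the ``min_obs`` respondent filter provide the IPF
    targets; the regressor predicts all areas (model predictions are
    used everywhere, including training areas, for consistency).
    """
    training, counts = select_training_areas(survey, min_obs=min_obs)
    train_cons = constraints.loc[constraints["area_id"].isin(training)]
    targets = sms_estimates(survey, train_cons)
    features = constraint_features(constraints)
    return fit_predict_sae(
        features, targets, counts, model_factory=model_factory, seed=seed
    )
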