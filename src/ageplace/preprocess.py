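"""Variable screening, normalisation and standardisation.

The fixed order is: screen (descriptives, correlation flags, constant
detection) -> Box-Cox normalisation per variable (maximum-likelihood
lambda, with a shift to positivity where needed) -> range scaling to
[0, 1] so every variable contributes comparably to the clustering.
A drop-one-variable sensitivity analysis quantifies each variable's
effect on cluster quality; flagged variables are reported for human
review, never auto-dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats


@dataclass
class ScreenReport:
    stats: pd.DataFrame                       # per-variable descriptives
    high_correlation: pd.DataFrame            # pairs with |r| >= threshold
    constant: list[str] = field(default_factory=list)
    corr_threshold: float = 0.9


def screen_variables(matrix: pd.DataFrame, corr_threshold: float = 0.9) -> ScreenReport:
    """Descriptive screen: moments, quantiles, skewness, correlation flags.

    Flags every variable pair with |Pearson r| >= ``corr_threshold`` and
    every constant variable (zero variance; these must be removed before
    transformation).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two variables to screen")
    desc = pd.DataFrame(
        {
            "mean": matrix.mean(),
            "median": matrix.median(),
            "q25": matrix.quantile(0.25),
            "q75": matrix.quantile(0.75),
            "sd": matrix.std(ddof=1),
            "skewness": matrix.skew(),
        }
    )
    constant = desc.index[desc["sd"] == 0].tolist()
    corr = matrix.corr()
    pairs = []
    cols = list(matrix.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) >= corr_threshold:
                pairs.append((cols[i], cols[j], float(r)))
    high = pd.DataFrame(pairs, columns=["variable_a", "variable_b", "r"])
    return ScreenReport(
        stats=desc, high_correlation=high, constant=constant,
        corr_threshold=corr_threshold,
    )


#: Plausible lambda range. Unbounded ML estimates diverge on variables
#: with a large location and small relative spread (the power transform
#: then underflows to a numerically constant column), so the estimate is
#: confined to the conventional interval.
LAMBDA_BOUNDS = (-3.0, 3.0)


def box_cox(x: np.ndarray | pd.Series) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with ML lambda and automatic positivity shift.

    Returns ``(y, lambda, shift)`` where ``y = ((x+shift)**lam - 1)/lam``
    (``log(x+shift)`` at ``lam == 0``) and ``shift = 1 - min(x)`` when
    ``min(x) <= 0``, else 0. Lambda maximises the profile log-likelihood
    over ``LAMBDA_BOUNDS``.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("Box-Cox undefined for constant input")
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    z = x + shift
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, z),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    y = special.boxcox(z, lam)
    return y, lam, float(shift)


def box_cox_grid_lambda(
    x: np.ndarray, lo: float = -3.0, hi: float = 3.0, step: float = 0.001
) -> float:
    """Brute-force grid maximiser of the Box-Cox log-likelihood.

    Independent of :func:`box_cox` (which delegates to scipy's Brent
    optimiser); used as an oracle in the test-suite.
    """
    x = np.asarray(x, dtype=float)
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    z = x + shift
    logz = np.log(z)
    n = len(z)
    lams = np.arange(lo, hi + step / 2, step)
    best_lam, best_ll = lams[0], -np.inf
    sum_logz = logz.sum()
    for lam in lams:
        if abs(lam) < 1e-12:
            y = logz
        else:
            y = (np.exp(lam * logz) - 1.0) / lam
        var = y.var()
        if var <= 0:
            continue
        ll = (lam - 1.0) * sum_logz - 0.5 * n * np.log(var)
        if ll > best_ll:
            best_ll, best_lam = ll, lam
    return float(best_lam)


def range_scale(y: np.ndarray | pd.Series) -> tuple[np.ndarray, float, float]:
    """Affine map of ``y`` onto [0, 1]; returns ``(z, min, max)``."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("range_scale requires max > min (constant input)")
    return (y - lo) / (hi - lo), float(lo), float(hi)


@dataclass
class TransformSpec:
    """Replayable per-variable Box-Cox + range-scale parameters."""

    params: dict[str, dict[str, float]]  # var -> shift, lam, vmin, vmax

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in matrix.columns if v not in self.params]
        if missing:
            raise KeyError(f"no stored transform for: {missing}")
        out = {}
        for var in matrix.columns:  # preserve caller's column order
            p = self.params[var]
            x = matrix[var].to_numpy(dtype=float) + p["shift"]
            if np.any(x <= 0):
                raise ValueError(
                    f"{var}: shifted values not positive under stored shift"
                )
            lam = p["lam"]
            y = np.log(x) if abs(lam) < 1e-12 else (x**lam - 1.0) / lam
            out[var] = (y - p["vmin"]) / (p["vmax"] - p["vmin"])
        return pd.DataFrame(out, index=matrix.index)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"variables": self.params}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TransformSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(params=raw["variables"])


def fit_transform_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, TransformSpec]:
    """Box-Cox then range-scale every column; returns (scaled, spec).

    The returned matrix has column-wise minimum exactly 0 and maximum
    exactly 1. Constant columns raise; remove them at screening first.
    """
    params: dict[str, dict[str, float]] = {}
    cols = {}
    for var in matrix.columns:
        y, lam, shift = box_cox(matrix[var])
        z, vmin, vmax = range_scale(y)
        cols[var] = z
        params[var] = {
            "shift": shift, "lam": lam, "vmin": vmin, "vmax": vmax,
        }
    scaled = pd.DataFrame(cols, index=matrix.index)
    return scaled, TransformSpec(params=params)


def sensitivity_analysis(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Drop-one-variable deltas of three internal cluster-quality scores.

    For each variable v, k-means (fixed seed and restart count) is refit
    on the matrix without v and the change ``score(without v) -
    score(baseline)`` is reported for Silhouette and Calinski-Harabasz
    (higher = better) and Davies-Bouldin (lower = better). The matrix is
    expected to be normalised and range-scaled already.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    if k < 2:
        raise ValueError("sensitivity analysis needs k >= 2")

    def _scores(X: np.ndarray) -> tuple[float, float, float]:
        labels = KMeans(k, n_init=n_init, random_state=seed).fit_predict(X)
        return (
            silhouette_score(X, labels),
            calinski_harabasz_score(X, labels),
            davies_bouldin_score(X, labels),
        )

    base_sil, base_ch, base_db = _scores(matrix.to_numpy())
    rows = []
    for var in matrix.columns:
        X = matrix.drop(columns=var).to_numpy()
        sil, ch, db = _scores(X)
        rows.append(
            {
                "variable_id": var,
                "delta_silhouette": sil - base_sil,
                "delta_calinski_harabasz": ch - base_ch,
                "delta_davies_bouldin": db - base_db,
            }
        )
    out = pd.DataFrame(rows).set_index("variable_id")
    out.attrs["baseline"] = {
        "silhouette": base_sil,
        "calinski_harabasz": base_ch,
        "davies_bouldin": base_db,
    }
    return out
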