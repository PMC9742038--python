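"""Synthetic source-data generator with planted cluster structure.

Emulates every raw input the classification pipeline consumes — an area
population table with age/sex bands, survey microdata plus per-area
constraint marginals for five common variables, a monthly GP prescribing
ledger with practice-to-area registration counts — together with the
ground truth needed to test recovery: planted supergroup/group labels,
latent per-area prescribing rates, and latent digital-engagement
percentages implied by the survey outcome model.

The planted geometry: each supergroup shifts every direct catalogue
variable by ``separation`` (in within-cluster SD units) times a fixed
standard-normal draw; groups add offsets at half that scale. Derived
variables (prescribing rates, digital engagement) inherit cluster signal
through supergroup tilts on their latent models, so the assembled matrix
carries a consistent two-tier structure whose strength is controlled by
a single dial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ageplace.catalogue import variable_catalogue, DERIVED_VARIABLES
from ageplace.config import (
    GROUP_SPLITS,
    OUTCOME_COEFS,
    OUTCOME_NAMES,
    PRESCRIBING_BASE_RATE,
    SUPERGROUP_SHARES,
    SUPERGROUP_TILTS,
    ScenarioConfig,
)

AGE_BANDS = ("50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+")
GENDER_CATS = ("Male", "Female")
QUALIFICATION_CATS = ("none_other", "level_1_2_apprenticeship", "level_3_4_higher")
SOCIAL_GRADE_CATS = ("AB", "C1C2DE")
ECONOMIC_ACTIVITY_CATS = (
    "part_time",
    "full_time",
    "self_employed",
    "unemployed",
    "retired",
    "look_after_family",
    "long_term_disabled",
    "student",
    "not_working_other",
)

CONSTRAINT_VARIABLES = {
    "age": AGE_BANDS,
    "gender": GENDER_CATS,
    "qualification": QUALIFICATION_CATS,
    "social_grade": SOCIAL_GRADE_CATS,
    "economic_activity": ECONOMIC_ACTIVITY_CATS,
}

MONTHS = [(y, m) for y in range(2015, 2020) for m in range(1, 13)]  # 60 months


def _area_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"A{i:0{width}d}" for i in range(1, n + 1)]


def planted_assignments(config: ScenarioConfig) -> pd.DataFrame:
    """Planted (supergroup, group) label per area, deterministic in config.

    Returns a frame with ``area_id``, integer ``supergroup`` (1-based)
    and string ``group`` codes of the form ``"s.j"``.
    """
    rng = np.random.default_rng(config.substream("labels"))
    k = config.n_supergroups
    shares = np.asarray(SUPERGROUP_SHARES[:k], dtype=float)
    if len(shares) < k:  # more supergroups than the named defaults
        shares = np.ones(k)
    shares = shares / shares.sum()
    sg = rng.choice(np.arange(1, k + 1), size=config.n_areas, p=shares)
    groups = np.empty(config.n_areas, dtype=object)
    for s in range(1, k + 1):
        n_sub = config.groups_per_supergroup[s - 1]
        split = np.asarray(
            GROUP_SPLITS.get(n_sub, tuple([1.0 / n_sub] * n_sub)), dtype=float
        )
        split = split / split.sum()
        mask = sg == s
        sub = rng.choice(np.arange(1, n_sub + 1), size=int(mask.sum()), p=split)
        groups[mask] = [f"{s}.{j}" for j in sub]
    return pd.DataFrame(
        {"area_id": _area_ids(config.n_areas), "supergroup": sg, "group": groups}
    )


def _tilt(name: str, config: ScenarioConfig) -> np.ndarray:
    """Supergroup tilt vector, scaled by the separation dial.

    Tilts are calibrated at the default separation of 2.5 and scale
    linearly with it, so ``separation=0`` removes every planted signal
    (including demographic structure) and label recovery degrades to
    chance.
    """
    vals = SUPERGROUP_TILTS[name]
    if config.n_supergroups <= len(vals):
        out = np.asarray(vals[: config.n_supergroups], dtype=float)
    else:
        reps = -(-config.n_supergroups // len(vals))
        out = np.asarray((vals * reps)[: config.n_supergroups], dtype=float)
    return out * (config.separation / 2.5)


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Per-area population table with 50+ age bands and sex split.

    Totals are log-normal around 1,500 residents; band counts are
    multinomial draws so the seven-band sum equals ``pop_50_plus``
    exactly. Planted supergroups tilt the age structure (older or
    younger profiles), and a ``median_age`` column consistent with that
    structure is included for summary statistics.
    """
    rng = np.random.default_rng(config.substream("population"))
    labels = planted_assignments(config)
    n = config.n_areas
    sg_idx = labels["supergroup"].to_numpy() - 1
    age_tilt = _tilt("age", config)[sg_idx]

    total = np.maximum(
        200, np.rint(rng.lognormal(np.log(1500.0), 0.30, size=n)).astype(int)
    )
    share50 = np.clip(
        0.36 + 0.06 * age_tilt + rng.normal(0.0, 0.03, size=n), 0.15, 0.60
    )
    pop50 = np.maximum(10, np.rint(total * share50).astype(int))

    base_profile = np.array([0.20, 0.18, 0.16, 0.14, 0.12, 0.10, 0.10])
    band_counts = np.zeros((n, 7), dtype=int)
    idx = np.arange(7)
    for i in range(n):
        p = base_profile * np.exp(0.15 * age_tilt[i] * idx)
        p /= p.sum()
        alpha = 60.0 * p
        shares = rng.dirichlet(alpha)
        band_counts[i] = rng.multinomial(pop50[i], shares)

    pop65 = band_counts[:, 3:].sum(axis=1)
    under18_share = np.clip(
        0.21 - 0.03 * age_tilt + rng.normal(0.0, 0.02, size=n), 0.05, 0.40
    )
    under18 = np.rint(total * under18_share).astype(int)
    pop_18_64 = np.maximum(1, total - under18 - pop65)
    female = rng.binomial(pop50, 0.52)

    median_age = 25.0 + 40.0 * (pop50 / total) + rng.normal(0.0, 1.5, size=n)

    out = pd.DataFrame(
        {
            "area_id": labels["area_id"],
            "total_pop": total,
            "pop_50_plus": pop50,
            "pop_65_plus": pop65,
            "pop_18_64": pop_18_64,
            "pop_female_50plus": female,
            "pop_male_50plus": pop50 - female,
            "median_age": np.round(median_age, 2),
        }
    )
    for j, band in enumerate(AGE_BANDS):
        out[f"pop_{band}"] = band_counts[:, j]
    return out


# ---------------------------------------------------------------------------
# survey + constraints


def _area_category_proportions(
    config: ScenarioConfig, population: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-area category proportions for each constraint variable.

    Deterministic in (config, population): drawn from a dedicated
    substream so survey generation, constraint marginals and the latent
    outcome integration all see the same demographics.
    """
    rng = np.random.default_rng(config.substream("demographics"))
    labels = planted_assignments(config)
    n = config.n_areas
    sg_idx = labels["supergroup"].to_numpy() - 1
    edu_tilt = _tilt("education", config)[sg_idx]
    aff_tilt = _tilt("affluence", config)[sg_idx]

    band_cols = [f"pop_{b}" for b in AGE_BANDS]
    bands = population[band_cols].to_numpy(dtype=float)
    pop50 = population["pop_50_plus"].to_numpy(dtype=float)
    props: dict[str, np.ndarray] = {}
    props["age"] = bands / pop50[:, None]
    props["gender"] = np.column_stack(
        [
            population["pop_male_50plus"].to_numpy(dtype=float) / pop50,
            population["pop_female_50plus"].to_numpy(dtype=float) / pop50,
        ]
    )

    def _softmax_rows(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    qual_logits = np.column_stack(
        [
            0.2 - 0.5 * edu_tilt,
            np.zeros(n),
            -0.1 + 0.6 * edu_tilt,
        ]
    ) + rng.normal(0.0, 0.15, size=(n, 3))
    props["qualification"] = _softmax_rows(qual_logits)

    grade_logits = np.column_stack(
        [-0.5 + 0.7 * aff_tilt, np.zeros(n)]
    ) + rng.normal(0.0, 0.15, size=(n, 2))
    props["social_grade"] = _softmax_rows(grade_logits)

    # retired share tracks the 65+ fraction of the 50+ population
    old_frac = bands[:, 3:].sum(axis=1) / pop50
    econ_base = np.log(
        np.array([0.09, 0.18, 0.07, 0.04, 0.40, 0.05, 0.06, 0.01, 0.10])
    )
    econ_logits = np.tile(econ_base, (n, 1)) + rng.normal(0.0, 0.12, size=(n, 9))
    econ_logits[:, 4] += 1.8 * (old_frac - old_frac.mean())  # retired
    econ_logits[:, 1] += 0.4 * aff_tilt - 0.9 * (old_frac - old_frac.mean())
    econ_logits[:, 3] -= 0.5 * aff_tilt  # unemployed
    props["economic_activity"] = _softmax_rows(econ_logits)
    return props


def _digital_offsets(config: ScenarioConfig) -> np.ndarray:
    """Per-area logit offset shared by all four digital outcomes."""
    rng = np.random.default_rng(config.substream("digital_offsets"))
    labels = planted_assignments(config)
    sg_idx = labels["supergroup"].to_numpy() - 1
    tilt = _tilt("digital", config)[sg_idx]
    return 0.4 * tilt + rng.normal(0.0, 0.10, size=config.n_areas)


def _outcome_logit(coefs: dict, cats: dict[str, np.ndarray]) -> np.ndarray:
    """Linear predictor for one outcome given category index arrays."""
    eta = coefs["intercept"] + coefs["age"] * cats["age"]
    eta = eta + np.asarray(coefs["qualification"])[cats["qualification"]]
    eta = eta + np.asarray(coefs["social_grade"])[cats["social_grade"]]
    eta = eta + np.asarray(coefs["economic_activity"])[cats["economic_activity"]]
    return eta


def generate_survey_and_constraints(
    config: ScenarioConfig, population: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey microdata and per-area constraint marginals.

    Respondent counts per area are Poisson(``survey_obs_lambda``); any
    remaining respondents (up to ``n_survey``) carry no home area,
    emulating a national sample frame that cannot be geocoded. Each
    respondent draws the five constraint attributes from their home
    area's category proportions (national means for the unassigned) and
    four binary internet-use outcomes from a logistic model in which
    prevalence declines with age band.

    Constraint marginals are exact multinomial tabulations over each
    area's 50+ population, so every variable's categories sum to the
    same area total by construction.
    """
    rng = np.random.default_rng(config.substream("survey"))
    props = _area_category_proportions(config, population)
    offsets = _digital_offsets(config)
    n_areas = config.n_areas
    area_ids = population["area_id"].to_numpy()
    pop50 = population["pop_50_plus"].to_numpy()

    # --- constraint marginals (integer, consistent by construction)
    rows = []
    counts = {}
    for var, cats in CONSTRAINT_VARIABLES.items():
        if var == "age":
            mat = population[[f"pop_{b}" for b in AGE_BANDS]].to_numpy()
        elif var == "gender":
            mat = population[["pop_male_50plus", "pop_female_50plus"]].to_numpy()
        else:
            p = props[var]
            mat = np.vstack(
                [rng.multinomial(int(pop50[i]), p[i]) for i in range(n_areas)]
            )
        counts[var] = mat
        for j, cat in enumerate(cats):
            rows.append(
                pd.DataFrame(
                    {
                        "area_id": area_ids,
                        "variable": var,
                        "category": cat,
                        "count": mat[:, j],
                    }
                )
            )
    constraints = pd.concat(rows, ignore_index=True)

    # --- survey respondents
    per_area = rng.poisson(config.survey_obs_lambda, size=n_areas)
    overflow = per_area.sum() - config.n_survey
    if overflow > 0:  # trim from the end, deterministically
        for i in range(n_areas - 1, -1, -1):
            take = min(per_area[i], overflow)
            per_area[i] -= take
            overflow -= take
            if overflow == 0:
                break
    home = np.repeat(np.arange(n_areas), per_area)
    n_unassigned = config.n_survey - len(home)
    area_col = np.concatenate(
        [area_ids[home], np.full(n_unassigned, None, dtype=object)]
    )

    national = {
        var: counts[var].sum(axis=0) / counts[var].sum()
        for var in CONSTRAINT_VARIABLES
    }
    cats_idx: dict[str, np.ndarray] = {}
    for var, cat_names in CONSTRAINT_VARIABLES.items():
        k = len(cat_names)
        p_assigned = props[var][home] if var in ("age", "gender") else props[var][home]
        p_all = np.vstack([p_assigned, np.tile(national[var], (n_unassigned, 1))])
        u = rng.random(config.n_survey)
        cum = np.cumsum(p_all, axis=1)
        cum[:, -1] = 1.0
        cats_idx[var] = (u[:, None] > cum).sum(axis=1)

    survey = pd.DataFrame(
        {
            "individual_id": [f"P{i:06d}" for i in range(1, config.n_survey + 1)],
            "area_id": area_col,
        }
    )
    for var, cat_names in CONSTRAINT_VARIABLES.items():
        survey[var] = np.asarray(cat_names, dtype=object)[cats_idx[var]]

    ind_offset = np.concatenate([offsets[home], np.zeros(n_unassigned)])
    for name in OUTCOME_NAMES:
        eta = _outcome_logit(OUTCOME_COEFS[name], cats_idx) + ind_offset
        p = 1.0 / (1.0 + np.exp(-eta))
        survey[name] = rng.binomial(1, p)
    return survey, constraints


def latent_digital_percentages(
    config: ScenarioConfig, population: pd.DataFrame
) -> pd.DataFrame:
    """True per-area outcome percentages implied by the outcome model.

    Integrates the logistic model over each area's joint attribute
    distribution (independent across constraint variables, matching how
    respondents are drawn), enumerating all 756 attribute cells.
    """
    props = _area_category_proportions(config, population)
    offsets = _digital_offsets(config)
    shapes = [len(c) for c in CONSTRAINT_VARIABLES.values()]
    grids = np.meshgrid(*[np.arange(s) for s in shapes], indexing="ij")
    cells = {
        var: g.ravel()
        for var, g in zip(CONSTRAINT_VARIABLES.keys(), grids)
    }
    # cell probability per area: product of marginal proportions
    p_cell = np.ones((config.n_areas, len(cells["age"])))
    for var in CONSTRAINT_VARIABLES:
        p_cell *= props[var][:, cells[var]]
    out = {"area_id": population["area_id"].to_numpy()}
    for name in OUTCOME_NAMES:
        eta = _outcome_logit(OUTCOME_COEFS[name], cells)  # (n_cells,)
        prob = 1.0 / (1.0 + np.exp(-(eta[None, :] + offsets[:, None])))
        out[f"pct_{name}"] = 100.0 * (p_cell * prob).sum(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# prescribing


def generate_prescribing_sources(
    config: ScenarioConfig, population: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Monthly prescribing ledger, registration table, and latent rates.

    Practices sit at evenly spaced positions along the (ordered) area
    index; each area registers its residents with its two nearest
    practices, weighted towards the nearer one, so each practice serves
    a handful of neighbouring areas. Latent per-area annual log-rates
    combine the class base rate, a supergroup tilt on the prescribing
    environment, a spatially smooth field (correlation length well
    beyond a practice catchment — prescribing environments vary at the
    scale of health systems, not single areas) and small area-level
    noise; monthly practice items are Poisson around the rate implied by
    the practice's registered population. Registration counts are
    constant over the 60 months (one row per practice-month-area).
    """
    rng = np.random.default_rng(config.substream("prescribing"))
    labels = planted_assignments(config)
    sg_idx = labels["supergroup"].to_numpy() - 1
    rx_tilt = _tilt("health_rx", config)[sg_idx]
    n_areas, n_prac = config.n_areas, config.n_practices
    area_ids = population["area_id"].to_numpy()
    total_pop = population["total_pop"].to_numpy()
    pop50 = population["pop_50_plus"].to_numpy(dtype=float)

    practice_ids = [f"G{p:04d}" for p in range(1, n_prac + 1)]
    centres = (np.arange(n_prac) + 0.5) * n_areas / n_prac
    pos = np.arange(n_areas) + 0.5
    d = np.abs(pos[:, None] - centres[None, :])  # (areas, practices)
    nearest2 = np.argsort(d, axis=1)[:, :2]
    w_near = rng.uniform(0.7, 0.9, size=n_areas)

    # patients[a, j] for j in the two practices serving area a
    patients = np.zeros((n_areas, 2), dtype=int)
    for i in range(n_areas):
        patients[i] = rng.multinomial(int(total_pop[i]), [w_near[i], 1 - w_near[i]])

    reg_rows = {"practice_id": [], "area_id": [], "patients": []}
    for i in range(n_areas):
        for j in range(2):
            if patients[i, j] > 0:
                reg_rows["practice_id"].append(practice_ids[nearest2[i, j]])
                reg_rows["area_id"].append(area_ids[i])
                reg_rows["patients"].append(patients[i, j])
    reg_base = pd.DataFrame(reg_rows)
    months = pd.DataFrame(MONTHS, columns=["year", "month"])
    registration = months.merge(reg_base, how="cross")[
        ["practice_id", "year", "month", "area_id", "patients"]
    ]

    # latent annual rates and monthly practice intensities
    # smooth spatial field along the area index (Gaussian kernel, unit SD)
    def _spatial_field(width: float = 12.0) -> np.ndarray:
        raw = rng.standard_normal(n_areas)
        half = int(3 * width)
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
        k /= k.sum()
        smooth = np.convolve(raw, k, mode="same")
        sd = smooth.std()
        return smooth / sd if sd > 0 else smooth

    latent_rows = []
    ledger_frames = []
    for cls, base in PRESCRIBING_BASE_RATE.items():
        log_rate = (
            np.log(base)
            + 0.25 * rx_tilt
            + 0.25 * _spatial_field()
            + rng.normal(0.0, 0.05, size=n_areas)
        )
        rate = np.exp(log_rate)
        latent_rows.append(
            pd.DataFrame(
                {"area_id": area_ids, "chemical_class": cls, "annual_rate": rate}
            )
        )
        # monthly expected items contributed by each area, split by share
        monthly_area = rate * pop50 / 12.0
        lam = np.zeros(n_prac)
        share = patients / patients.sum(axis=1, keepdims=True)
        for j in range(2):
            np.add.at(lam, nearest2[:, j], monthly_area * share[:, j])
        items = rng.poisson(lam[None, :].repeat(60, axis=0))  # (60, n_prac)
        frame = pd.DataFrame(
            {
                "practice_id": np.tile(practice_ids, 60),
                "year": np.repeat([y for y, _ in MONTHS], n_prac),
                "month": np.repeat([m for _, m in MONTHS], n_prac),
                "chemical_class": cls,
                "items": items.ravel(),
            }
        )
        ledger_frames.append(frame)
    ledger = pd.concat(ledger_frames, ignore_index=True)
    latent = pd.concat(latent_rows, ignore_index=True)
    return ledger, registration, latent


# ---------------------------------------------------------------------------
# final matrix


def assemble_variable_matrix(
    config: ScenarioConfig,
    population: pd.DataFrame,
    prescribing_rates: pd.DataFrame | None = None,
    digital_percentages: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the area x 71-variable matrix plus planted labels.

    Direct catalogue variables follow the planted two-tier Gaussian
    model (supergroup offsets at ``separation`` within-SD units, group
    offsets at half that), mapped onto plausible per-variable location
    and scale. Derived columns must be supplied: ``prescribing_rates``
    with columns (area_id, chemical_class, rate or annual_rate) fills
    ``achei_rate``/``memantine_rate``; ``digital_percentages`` with
    ``pct_broadband``..``pct_social`` fills the digital estimates.

    Raises ``ValueError`` naming the missing columns if a derived table
    is absent or incomplete.
    """
    cat = variable_catalogue()
    missing: list[str] = []
    if prescribing_rates is None:
        missing += ["achei_rate", "memantine_rate"]
    if digital_percentages is None:
        missing += ["pct_broadband", "pct_info", "pct_shopbank", "pct_social"]
    if missing:
        raise ValueError(
            "missing derived tables for columns: " + ", ".join(missing)
        )

    rng = np.random.default_rng(config.substream("matrix"))
    labels = planted_assignments(config)
    n = config.n_areas
    direct = cat.direct_ids
    n_direct = len(direct)

    # fixed standard-normal effect draws scaled by the separation dial
    eff_rng = np.random.default_rng(config.substream("effects"))
    sg_z = eff_rng.standard_normal((config.n_supergroups, n_direct))
    grp_codes = sorted(
        {f"{s + 1}.{j + 1}" for s in range(config.n_supergroups)
         for j in range(config.groups_per_supergroup[s])}
    )
    grp_z = {
        g: eff_rng.standard_normal(n_direct) for g in grp_codes
    }

    sg_idx = labels["supergroup"].to_numpy() - 1
    raw = rng.standard_normal((n, n_direct))
    raw += config.separation * sg_z[sg_idx]
    grp_offsets = np.vstack([grp_z[g] for g in labels["group"]])
    raw += 0.5 * config.separation * grp_offsets

    base = rng.uniform(15.0, 60.0, size=n_direct)
    unit = rng.uniform(2.0, 5.0, size=n_direct)
    data = base[None, :] + unit[None, :] * raw

    matrix = pd.DataFrame(data, columns=direct)
    matrix.insert(0, "area_id", labels["area_id"])
    matrix = matrix.set_index("area_id")

    # splice in derived columns
    rate_col = "rate" if "rate" in prescribing_rates.columns else "annual_rate"
    wide = prescribing_rates.pivot_table(
        index="area_id", columns="chemical_class", values=rate_col
    )
    for cls, col in (("AChEI", "achei_rate"), ("Memantine", "memantine_rate")):
        if cls not in wide.columns:
            raise ValueError(f"missing derived tables for columns: {col}")
        matrix[col] = wide[cls].reindex(matrix.index)
    dig = digital_percentages.set_index("area_id")
    for col in ("pct_broadband", "pct_info", "pct_shopbank", "pct_social"):
        if col not in dig.columns:
            raise ValueError(f"missing derived tables for columns: {col}")
        matrix[col] = dig[col].reindex(matrix.index)

    matrix = matrix[cat.variable_ids]  # catalogue order
    if matrix.isna().any().any():
        bad = matrix.columns[matrix.isna().any()].tolist()
        raise ValueError(f"derived tables left missing values in: {bad}")
    return matrix, labels
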