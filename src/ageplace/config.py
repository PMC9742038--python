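"""Scenario configuration for the synthetic study population.

The defaults define the study conditions used throughout the test-suite
and the acceptance analysis: 2,000 areas (mean population ~1,500, the
LSOA design target), a five-supergroup / thirteen-group planted
hierarchy, one GP practice per ~5 areas, and a survey whose Poisson(7)
respondents-per-area allocation leaves roughly one area in ten with the
11+ observations needed for supervised training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Planted supergroup population shares (largest to smallest follows the
#: typical shape of national classifications: three large, two small tiers).
SUPERGROUP_SHARES = (0.23, 0.12, 0.27, 0.25, 0.13)

#: Within-supergroup group shares for 2- and 3-way splits.
GROUP_SPLITS = {1: (1.0,), 2: (0.6, 0.4), 3: (0.45, 0.33, 0.22)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic classification scenario.

    Parameters
    ----------
    n_areas:
        Number of small areas to simulate.
    n_supergroups:
        Planted top-tier cluster count.
    groups_per_supergroup:
        Planted second-tier split per supergroup; the total group count
        is ``sum(groups_per_supergroup)``.
    separation:
        Between-supergroup distance of planted variable means, in units
        of the within-cluster standard deviation. Second-tier offsets
        use half this value. 0 removes all planted signal.
    n_practices:
        Number of GP practices issuing prescriptions.
    n_survey:
        Total survey respondents. Respondents are allocated to home
        areas with per-area Poisson(``survey_obs_lambda``) counts; any
        remainder has no recorded home area (a national-sample tail).
    survey_obs_lambda:
        Mean survey respondents per area.
    seed:
        Root seed; every generator derives an independent substream.
    """

    n_areas: int = 2000
    n_supergroups: int = 5
    groups_per_supergroup: Sequence[int] = (3, 2, 2, 3, 3)
    separation: float = 2.5
    n_practices: int = 400
    n_survey: int = 16000
    survey_obs_lambda: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 1 or self.n_practices < 1 or self.n_survey < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_supergroups < 1:
            raise ValueError("n_supergroups must be >= 1")
        if len(self.groups_per_supergroup) != self.n_supergroups:
            raise ValueError(
                "groups_per_supergroup must have one entry per supergroup "
                f"(got {len(self.groups_per_supergroup)} for "
                f"{self.n_supergroups} supergroups)"
            )
        if any(g < 1 for g in self.groups_per_supergroup):
            raise ValueError("each supergroup needs >= 1 group")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.survey_obs_lambda <= 0:
            raise ValueError("survey_obs_lambda must be positive")
        # freeze the sequence so configs hash / compare cleanly
        object.__setattr__(
            self, "groups_per_supergroup", tuple(self.groups_per_supergroup)
        )

    @property
    def n_groups(self) -> int:
        return int(sum(self.groups_per_supergroup))

    def substream(self, name: str) -> list[int]:
        """Seed sequence for an independent, named random substream."""
        tag = sum(ord(c) * 31**i for i, c in enumerate(name)) % (2**31 - 1)
        return [self.seed % (2**31 - 1), tag]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# Outcome model coefficients for the four digital-engagement outcomes
# (broadband at home, information seeking, shopping/banking, social use).
# Log-odds are linear in the constraint attributes; age is the dominant,
# negative gradient so prevalence falls across age bands.
OUTCOME_NAMES = ("broadband", "info", "shopbank", "social")

OUTCOME_COEFS = {
    # intercept, per-age-band step (7 bands), qualification steps (3 cats),
    # social-grade step (2 cats), economic-activity offsets (9 cats)
    "broadband": {
        "intercept": 2.0,
        "age": -0.35,
        "qualification": (0.0, 0.5, 1.0),
        "social_grade": (0.5, 0.0),
        "economic_activity": (0.3, 0.4, 0.4, -0.2, 0.0, 0.0, -0.4, 0.2, -0.2),
    },
    "info": {
        "intercept": 1.5,
        "age": -0.40,
        "qualification": (0.0, 0.6, 1.2),
        "social_grade": (0.5, 0.0),
        "economic_activity": (0.3, 0.4, 0.5, -0.1, 0.0, 0.0, -0.3, 0.3, -0.2),
    },
    "shopbank": {
        "intercept": 1.0,
        "age": -0.45,
        "qualification": (0.0, 0.5, 1.0),
        "social_grade": (0.6, 0.0),
        "economic_activity": (0.4, 0.5, 0.5, -0.2, 0.0, 0.1, -0.4, 0.2, -0.3),
    },
    "social": {
        "intercept": 0.8,
        "age": -0.30,
        "qualification": (0.0, 0.4, 0.8),
        "social_grade": (0.3, 0.0),
        "economic_activity": (0.2, 0.2, 0.3, 0.0, 0.0, 0.2, -0.2, 0.4, -0.1),
    },
}

#: Supergroup tilts (z-style, unitless) steering the demographic realism
#: of the planted clusters: age structure, education, affluence, digital
#: engagement and dementia-prescribing environment. Index = supergroup - 1.
SUPERGROUP_TILTS = {
    "age": (-0.2, -1.0, 1.0, 0.8, -0.6),
    "education": (-0.8, -0.4, 0.5, 0.1, 1.0),
    "affluence": (-1.0, -0.6, 0.8, 0.3, 0.9),
    "digital": (-0.8, -0.3, 0.6, 0.0, 1.0),
    "health_rx": (0.8, 0.2, -0.4, -0.2, 0.4),
}

#: Baseline annual prescribing rates, items per person aged 50+ per year.
PRESCRIBING_BASE_RATE = {"AChEI": 0.35, "Memantine": 0.12}
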