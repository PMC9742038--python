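"""Generate the synthetic source tables for the default study scenario.

Writes the area population table, survey microdata with constraint
marginals, the 60-month prescribing ledger with practice registrations,
and the planted ground truth (labels, latent rates, latent digital
percentages) under results/sources/.
"""

from pathlib import Path

from ageplace import synth
from ageplace.config import ScenarioConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "sources"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ScenarioConfig(seed=0)
    cfg.to_yaml(OUT / "scenario.yaml")

    pop = synth.generate_population(cfg)
    survey, cons = synth.generate_survey_and_constraints(cfg, pop)
    ledger, reg, latent_rates = synth.generate_prescribing_sources(cfg, pop)
    latent_digital = synth.latent_digital_percentages(cfg, pop)
    labels = synth.planted_assignments(cfg)

    pop.to_csv(OUT / "population.csv", index=False)
    survey.to_csv(OUT / "survey.csv", index=False)
    cons.to_csv(OUT / "constraints.csv", index=False)
    ledger.to_csv(OUT / "ledger.csv", index=False)
    reg.to_csv(OUT / "registration.csv", index=False)
    latent_rates.to_csv(OUT / "latent_rates.csv", index=False)
    latent_digital.to_csv(OUT / "latent_digital.csv", index=False)
    labels.to_csv(OUT / "planted_labels.csv", index=False)

    located = survey.dropna(subset=["area_id"])
    print(f"areas: {len(pop)}, mean population {pop['total_pop'].mean():.0f}")
    print(
        f"survey: {len(survey)} respondents, "
        f"{located['area_id'].nunique()} areas with >=1 geocoded respondent"
    )
    print(
        f"ledger: {len(ledger)} practice-month-class rows over "
        f"{ledger[['year', 'month']].drop_duplicates().shape[0]} months"
    )
    print(f"planted hierarchy: {labels['supergroup'].nunique()} supergroups, "
          f"{labels['group'].nunique()} groups")


if __name__ == "__main__":
    main()
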