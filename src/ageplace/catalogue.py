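"""The packaged variable catalogue: 71 measures across nine domains.

The catalogue is a synthetic-representative stand-in for the full input
measure list of a national ageing classification: variable names and
domain placement follow the pen-portrait vocabulary of such products
(tenure mix, household composition, deprivation, digital engagement,
dementia prescribing, access and civic assets), with denominators taken
over the population aged 50+ wherever that is the natural base. Six
variables are *derived* by upstream pipeline stages (four small-area
digital-engagement estimates, two prescribing rates); the remaining 65
are direct area measures.

Direction hints are ``+`` (higher value reads as more advantage or
amenity), ``-`` (more constraint or deprivation), ``.`` (neutral /
compositional).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DOMAINS = (
    "People",
    "Housing",
    "Work and Education",
    "Mobility",
    "Financial Security",
    "Digital",
    "Health",
    "Outdoor Space and Living Environment",
    "Civic Participation",
)

#: Variables filled in by upstream pipeline stages rather than drawn
#: directly from source tables.
DERIVED_VARIABLES = (
    "pct_broadband",
    "pct_info",
    "pct_shopbank",
    "pct_social",
    "achei_rate",
    "memantine_rate",
)

# (variable_id, human name, domain, direction hint)
_CATALOGUE = [
    # People (10)
    ("pct_female_50plus", "% female among aged 50+", "People", "."),
    ("pct_aged_80plus", "% aged 80+ among aged 50+", "People", "."),
    ("pct_aged_50_64", "% aged 50-64 among aged 50+", "People", "."),
    ("pct_single_person_hh", "% single-person households (50+)", "People", "-"),
    ("pct_married_couple", "% married or cohabiting (50+)", "People", "+"),
    ("pct_ethnic_minority", "% ethnic minority (50+)", "People", "."),
    ("pct_born_overseas", "% born outside the UK (50+)", "People", "."),
    ("pct_low_english", "% with low English proficiency (50+)", "People", "-"),
    ("pct_living_with_children", "% living with dependent children (50+)", "People", "."),
    ("pct_recent_movers", "% resident under 2 years (residential churn)", "People", "."),
    # Housing (10)
    ("pct_owned_outright", "% owning home outright (50+)", "Housing", "+"),
    ("pct_mortgage_shared", "% with mortgage or shared ownership (50+)", "Housing", "."),
    ("pct_social_rented", "% in social rented housing (50+)", "Housing", "-"),
    ("pct_private_rented", "% in private rented housing (50+)", "Housing", "."),
    ("pct_detached_semi", "% in detached or semi-detached housing", "Housing", "+"),
    ("pct_terraced", "% in terraced housing", "Housing", "."),
    ("pct_flats", "% in flats or apartments", "Housing", "."),
    ("pct_no_central_heating", "% households without central heating", "Housing", "-"),
    ("pct_spare_bedrooms", "% households with 2+ spare bedrooms (50+)", "Housing", "+"),
    ("pct_overcrowded", "% households overcrowded", "Housing", "-"),
    # Work and Education (9)
    ("pct_retired", "% retired (50+)", "Work and Education", "."),
    ("pct_full_time", "% in full-time employment (50+)", "Work and Education", "."),
    ("pct_part_time", "% in part-time employment (50+)", "Work and Education", "."),
    ("pct_self_employed", "% self-employed (50+)", "Work and Education", "."),
    ("pct_unemployed", "% unemployed (50+)", "Work and Education", "-"),
    ("pct_no_qualifications", "% with no or other qualifications (50+)", "Work and Education", "-"),
    ("pct_mid_qualifications", "% with level 1/2/apprenticeship (50+)", "Work and Education", "."),
    ("pct_high_qualifications", "% with level 3/4+ qualifications (50+)", "Work and Education", "+"),
    ("pct_home_carers", "% looking after home or family (50+)", "Work and Education", "."),
    # Mobility (7)
    ("pct_no_car", "% households with no car or van (50+)", "Mobility", "-"),
    ("pct_two_plus_cars", "% households with 2+ cars (50+)", "Mobility", "+"),
    ("dist_gp_km", "mean road distance to nearest GP (km)", "Mobility", "-"),
    ("dist_hospital_km", "mean road distance to nearest hospital (km)", "Mobility", "-"),
    ("dist_shops_km", "mean road distance to food shops (km)", "Mobility", "-"),
    ("public_transport_score", "public transport accessibility score", "Mobility", "+"),
    ("pct_active_travel", "% travelling by foot or cycle", "Mobility", "+"),
    # Financial Security (7)
    ("income_deprivation_older", "income deprivation affecting older people score", "Financial Security", "-"),
    ("pension_credit_rate", "pension credit claim rate (65+)", "Financial Security", "-"),
    ("fuel_poverty_rate", "% households in fuel poverty", "Financial Security", "-"),
    ("median_house_price", "median house price (GBP 1000s)", "Financial Security", "+"),
    ("affordability_ratio", "house price to earnings affordability ratio", "Financial Security", "."),
    ("pct_income_deprived_hh", "% income-deprived households", "Financial Security", "-"),
    ("benefit_claim_rate", "working-age benefit claim rate (50-64)", "Financial Security", "-"),
    # Digital (6) — four derived small-area estimates + two infrastructure
    ("pct_broadband", "% aged 50+ with broadband at home (estimated)", "Digital", "+"),
    ("pct_info", "% aged 50+ using internet for information seeking (estimated)", "Digital", "+"),
    ("pct_shopbank", "% aged 50+ using internet for shopping/banking (estimated)", "Digital", "+"),
    ("pct_social", "% aged 50+ using internet for social purposes (estimated)", "Digital", "+"),
    ("mean_download_mbps", "mean fixed-line download speed (Mbit/s)", "Digital", "+"),
    ("pct_premises_superfast", "% premises with superfast broadband", "Digital", "+"),
    # Health (8) — two derived prescribing rates + six direct
    ("achei_rate", "acetylcholinesterase-inhibitor items per person 50+ per year", "Health", "."),
    ("memantine_rate", "memantine items per person 50+ per year", "Health", "."),
    ("pct_good_health", "% in good or very good health (50+)", "Health", "+"),
    ("pct_limiting_illness", "% with limiting long-term illness (50+)", "Health", "-"),
    ("pct_disability", "% with a disability (50+)", "Health", "-"),
    ("pct_unpaid_care_low", "% providing 1-19 h unpaid care weekly (50+)", "Health", "."),
    ("pct_unpaid_care_high", "% providing 20+ h unpaid care weekly (50+)", "Health", "-"),
    ("emergency_admission_rate", "emergency hospital admissions per 1000 (65+)", "Health", "-"),
    # Outdoor Space and Living Environment (8)
    ("no2_index", "annual mean NO2 pollution index", "Outdoor Space and Living Environment", "-"),
    ("pm10_index", "annual mean PM10 pollution index", "Outdoor Space and Living Environment", "-"),
    ("green_space_score", "access to green space score", "Outdoor Space and Living Environment", "+"),
    ("pct_private_outdoor", "% addresses with private outdoor space", "Outdoor Space and Living Environment", "+"),
    ("crime_rate_index", "recorded crime rate index", "Outdoor Space and Living Environment", "-"),
    ("traffic_noise_index", "road traffic noise exposure index", "Outdoor Space and Living Environment", "-"),
    ("flood_risk_score", "residential flood risk score", "Outdoor Space and Living Environment", "-"),
    ("pct_overheat_risk", "% dwellings at summer overheating risk", "Outdoor Space and Living Environment", "-"),
    # Civic Participation (6)
    ("civic_assets_per_1000", "civic assets within 1 km per 1000 residents", "Civic Participation", "+"),
    ("community_centres_per_1000", "community centres per 1000 residents", "Civic Participation", "+"),
    ("library_access_score", "public library accessibility score", "Civic Participation", "+"),
    ("worship_places_per_1000", "places of worship per 1000 residents", "Civic Participation", "."),
    ("volunteering_rate", "estimated regular volunteering rate (50+)", "Civic Participation", "+"),
    ("electoral_turnout", "local electoral turnout rate", "Civic Participation", "+"),
]


@dataclass(frozen=True)
class VariableCatalogue:
    """Immutable catalogue of classification input variables."""

    table: pd.DataFrame

    @property
    def variable_ids(self) -> list[str]:
        return list(self.table["variable_id"])

    @property
    def domains(self) -> list[str]:
        return sorted(self.table["domain"].unique())

    @property
    def direct_ids(self) -> list[str]:
        return [v for v in self.variable_ids if v not in DERIVED_VARIABLES]

    def domain_of(self, variable_id: str) -> str:
        row = self.table.loc[self.table["variable_id"] == variable_id]
        if row.empty:
            raise KeyError(variable_id)
        return str(row["domain"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)


_TABLE = pd.DataFrame(
    _CATALOGUE, columns=["variable_id", "name", "domain", "direction"]
)


def variable_catalogue() -> VariableCatalogue:
    """Return the packaged 71-variable, nine-domain catalogue.

    The same object contents are returned on every call; callers must
    not mutate the table in place.
    """
    return VariableCatalogue(table=_TABLE.copy())
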