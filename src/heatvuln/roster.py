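"""County demographic and socioeconomic variable roster.

The 30-variable roster standard in county-level heat-vulnerability work:
age structure, sex, race/ethnicity, employment and occupation mix, wealth,
education, housing, one-parent families, and urbanicity.  Most variables
come from ACS five-year estimates; the nursing-facility and rural-block
shares come from the Decennial Census.

``COLLINEAR_DROPS`` lists the twelve variables conventionally removed
before regression because their pairwise Pearson correlation with another
roster variable exceeds 0.7, leaving 18 predictors to enter stepwise
selection.
"""

from __future__ import annotations

#: (name, unit) for the full county covariate roster.
SDOH_ROSTER: tuple[tuple[str, str], ...] = (
    ("median_age", "year"),
    ("under_5_years", "percent"),
    ("over_65_years", "percent"),
    ("over_65_nursing_facilities", "percent"),
    ("female", "percent"),
    ("nonhispanic_white", "percent"),
    ("nonhispanic_black", "percent"),
    ("nonhispanic_other_races", "percent"),
    ("hispanic", "percent"),
    ("labor_force", "percent"),
    ("unemployment_rate", "percent"),
    ("farming_fishing_mining_forestry", "percent"),
    ("construction_extraction", "percent"),
    ("installation_maintenance_repair", "percent"),
    ("services", "percent"),
    ("per_capita_income", "1000 dollars"),
    ("median_household_income", "1000 dollars"),
    ("median_gross_rent", "1000 dollars"),
    ("median_house_value", "1000 dollars"),
    ("households_under_10k", "percent"),
    ("households_over_200k", "percent"),
    ("food_stamps_snap", "percent"),
    ("below_poverty_level", "percent"),
    ("no_automobile", "percent"),
    ("less_than_high_school", "percent"),
    ("limited_english", "percent"),
    ("median_year_built", "year"),
    ("mobile_homes", "percent"),
    ("one_parent_families", "percent"),
    ("rural_block_groups", "percent"),
)

#: Variables removed for |r| > 0.7 collinearity with another roster member.
COLLINEAR_DROPS: tuple[str, ...] = (
    "median_age",
    "nonhispanic_white",
    "median_household_income",
    "median_gross_rent",
    "median_house_value",
    "households_over_200k",
    "food_stamps_snap",
    "below_poverty_level",
    "less_than_high_school",
    "limited_english",
    "mobile_homes",
    "rural_block_groups",
)


def roster_names() -> list[str]:
    return [name for name, _ in SDOH_ROSTER]


def stepwise_candidates() -> list[str]:
    """Roster variables surviving the conventional collinearity drop."""
    drops = set(COLLINEAR_DROPS)
    unknown = drops - set(roster_names())
    if unknown:  # pragma: no cover - guards roster edits
        raise ValueError(f"drop list names unknown variables: {sorted(unknown)}")
    return [name for name in roster_names() if name not in drops]
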