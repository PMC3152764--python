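"""The bundled mortality fixture: a calibrated synthetic life table.

The model needs an age/sex all-cause mortality table as the competing risk.
This package ships a Gompertz-Makeham stand-in whose remaining life
expectancy at 70 is calibrated per sex; this script generates it, verifies
the calibration, and writes it as delimited text so a real census table can
be dropped in with the same format.
"""

from adscreensim import (
    DEFAULT_FIXTURE_SPEC,
    default_life_table,
    life_expectancy,
    analytic_ad_free_years,
    SimulationConfig,
)
from adscreensim.lifetables import write_life_table_csv

table = default_life_table()
for sex in ("male", "female"):
    target = DEFAULT_FIXTURE_SPEC.calibration_target[sex]
    e70 = life_expectancy(table, sex, 70.0)
    print(f"{sex:6s}: remaining life expectancy at 70 = {e70:.2f} y (target {target})")

adfy = analytic_ad_free_years(SimulationConfig(cohort_size=1))
print(f"analytic no-screening AD-free expectancy from 70 (46% male): {adfy:.3f} y/person")

write_life_table_csv(table, "life_table.csv")
print("wrote life_table.csv (age, q_male, q_female; ages 50-99, open age 100)")

# Reading: the fixture reproduces the published per-person AD-free-years
# scale (~13.68 y from age 70) by construction; swap in a real period life
# table via the same CSV format to remove the stand-in.
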