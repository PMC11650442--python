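import pandas as pd
import pytest

import swedgi as sg


@pytest.fixture(scope="session")
def toy():
    return sg.make_toy_fixture()


@pytest.fixture(scope="session")
def specs():
    return sg.load_guidelines("swedgi_2015")


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort exercising every pipeline stage quickly."""
    cfg = sg.SimConfig(
        n_participants=600, seed=42, n_species=60, reads_per_sample_range=(4000, 6000)
    )
    return sg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table, _ = sg.build_analysis_table(small_cohort, depth=3000, seed=42)
    return table.assign(mets=table.mets.astype(float))


def best_diet(specs, pid="best", energy=2000.0) -> pd.DataFrame:
    """A diet reaching every recommendation: all 12 components score 4."""
    row = {"pid": pid, "energy": energy, "juice": 0.0, "fibre": 30.0,
           "sucrose": 0.0, "fructose": 0.0, "glucose": 0.0}
    for s in specs:
        if s.derived or s.scoring == "salt_composite":
            continue
        row[s.source_fields[0]] = s.recommended_level if s.direction == "encourage" else 0.0
    salt = next(s for s in specs if s.scoring == "salt_composite")
    row["salt"] = 0.5 * salt.recommended_level * energy * sg.KCAL_TO_MJ
    row["salts_at_table"] = False
    return pd.DataFrame([row])


def worst_diet(specs, pid="worst", energy=2000.0) -> pd.DataFrame:
    """A diet missing every recommendation by >=75 %: all components score 0."""
    row = {"pid": pid, "energy": energy, "juice": 0.0, "fibre": 5.0,
           "fructose": 0.0, "glucose": 0.0}
    for s in specs:
        if s.derived or s.scoring == "salt_composite":
            continue
        row[s.source_fields[0]] = 0.0 if s.direction == "encourage" else 2.0 * s.recommended_level
    sugar = next(s for s in specs if s.derived == "added_sugar")
    row["sucrose"] = 2.0 * sugar.recommended_level  # no fruit/veg/juice to subtract
    salt = next(s for s in specs if s.scoring == "salt_composite")
    row["salt"] = 2.0 * salt.recommended_level * energy * sg.KCAL_TO_MJ
    row["salts_at_table"] = True
    return pd.DataFrame([row])
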