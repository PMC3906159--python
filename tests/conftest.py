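import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thermoshift import SurveyDataset

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def build_survey(rows) -> SurveyDataset:
    """rows: (transect_id, habitat, year, visit, species_id, count) tuples."""
    return SurveyDataset(pd.DataFrame(
        rows, columns=["transect_id", "habitat", "year", "visit", "species_id", "count"]
    ))


@pytest.fixture
def two_year_survey() -> SurveyDataset:
    """4 transects x 2 habitats x 2 years x 2 visits, 3 species."""
    rows = []
    base = {"spA": 6, "spB": 3, "spC": 1}
    for t, h in [("t1", "h1"), ("t2", "h1"), ("t3", "h2"), ("t4", "h2")]:
        for year in (1998, 2011):
            for visit in (1, 2):
                for sp, c in base.items():
                    bump = 2 if (year == 2011 and sp == "spA") else 0
                    rows.append((t, h, year, visit, sp, c + bump))
    return build_survey(rows)
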