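import numpy as np
import pytest
from hypothesis import settings

from emergepi import (
    AdmissionRecord,
    GroundTruthLaw,
    SimulationConfig,
)
from emergepi.frequency_analysis import ProfileEntry, RankedProfile

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

YEARS = list(range(2015, 2021))
POPULATIONS = {y: 315_000.0 for y in YEARS}

# 10 admissions, 2 of them Z-chapter (non-emergencies), hand-checkable.
HANDWRITTEN_ROWS = [
    ("P01", "I21.0", 2015),
    ("P02", "I21.1", 2015),
    ("P03", "Z03.8", 2015),
    ("P04", "G40.9", 2016),
    ("P05", "i63.4", 2016),
    ("P06", "S72.00", 2016),
    ("P07", "A09", 2017),
    ("P08", "B15.9", 2017),
    ("P09", "Z76.1", 2017),
    ("P10", "K35.8", 2017),
]


@pytest.fixture
def handwritten_records():
    return [AdmissionRecord(pid, code, year) for pid, code, year in HANDWRITTEN_ROWS]


@pytest.fixture
def handwritten_csv(tmp_path):
    path = tmp_path / "admissions.csv"
    lines = ["patient_id,icd10_code,year"]
    lines += [f"{pid},{code},{year}" for pid, code, year in HANDWRITTEN_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def six_year_exponential_config():
    """Six-year Poisson stream under the canonical exponential law."""
    law = GroundTruthLaw(family="exponential", n_categories=50, b0=1000.0, b1=0.1)
    return SimulationConfig(
        law=law,
        years=YEARS,
        population_per_year=POPULATIONS,
        z_fraction=0.027,
        noise="poisson",
        seed=42,
    )


def profile_from_values(values, n_years=2, scale="per_100k"):
    """Ranked profile straight from mean frequencies (sorted descending)."""
    vals = np.sort(np.asarray(values, dtype=float))[::-1]
    entries = tuple(
        ProfileEntry(
            category=f"X{i:02d}",
            chapter_group="X",
            mean=float(v),
            pi_lower=float(v),
            pi_upper=float(v),
            mean_count=float(v),
        )
        for i, v in enumerate(vals)
    )
    return RankedProfile(entries=entries, n_years=n_years, scale=scale)
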