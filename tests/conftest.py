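import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pvsignal import faers_io, pipeline, synthetic
from pvsignal.vocab import DrugVocabulary, EventHierarchy

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def drug_vocab() -> DrugVocabulary:
    return DrugVocabulary.from_yaml()


@pytest.fixture(scope="session")
def hierarchy() -> EventHierarchy:
    return EventHierarchy.from_csv()


@pytest.fixture(scope="session")
def small_case_data():
    """A linked, normalized CaseData from a 5,000-report synthetic draw with
    one injected gabapentin-osteopenia signal."""
    cfg = synthetic.SyntheticConfig(
        n_reports=5000,
        seed=20240915,
        signal_multipliers=(synthetic.Multiplier("GABAPENTIN", "OSTEOPENIA", 8.0),),
    )
    ds = synthetic.generate(cfg)
    cd, _ = faers_io.ingest_tables(
        ds.frames["demo"], ds.frames["drug"], ds.frames["reac"], ds.frames["outc"]
    )
    cd = pipeline.normalize_case_drugs(cd, DrugVocabulary.from_yaml())
    return cd


def toy_case_data() -> faers_io.CaseData:
    """Six hand-built cases: 2 with (DRUGX & EVENTY), 1 DRUGX only,
    1 EVENTY only, 2 with neither -> contingency (2, 1, 1, 2)."""
    cases = pd.DataFrame(
        {
            "primaryid": [f"P{i}" for i in range(1, 7)],
            "caseid": [f"C{i}" for i in range(1, 7)],
            "fda_dt": [20200101.0] * 6,
            "sex": ["F", "M", "F", "M", "F", "UNK"],
            "age_years": [30.0, 70.0, np.nan, 50.0, 61.0, 40.0],
        }
    )
    drugs = pd.DataFrame(
        {
            "primaryid": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "drugname": ["DRUGX"] * 3 + ["DRUGZ"] * 3,
            "role_cod": ["PS"] * 6,
            "canonical": ["DRUGX"] * 3 + ["DRUGZ"] * 3,
        }
    )
    reactions = pd.DataFrame(
        {
            "primaryid": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "pt": ["EVENTY", "EVENTY", "OTHERPT", "EVENTY", "OTHERPT", "OTHERPT"],
        }
    )
    outcomes = pd.DataFrame({"primaryid": ["P1"], "outc_cod": ["HO"]})
    return faers_io.CaseData(cases=cases, drugs=drugs, reactions=reactions,
                             outcomes=outcomes)


@pytest.fixture()
def toy_cases() -> faers_io.CaseData:
    return toy_case_data()
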