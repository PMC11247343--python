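import pytest

from faers_signal.model import CaseReport, DrugEntry, ReportSet
from faers_signal.simulate import default_config, generate


def make_report(
    case_id,
    drugs,
    reactions,
    *,
    version="2020Q1-1",
    year=2020,
    outcomes=(),
    sex="unknown",
    age=None,
    country=None,
):
    """Terse CaseReport factory: drugs as (name, role) pairs or bare names (PS)."""
    entries = tuple(
        DrugEntry(name=d, role_code="PS") if isinstance(d, str) else DrugEntry(*d)
        for d in drugs
    )
    return CaseReport(
        case_id=case_id,
        version_key=version,
        report_year=year,
        drugs=entries,
        reactions=tuple(sorted(set(reactions))),
        outcomes=frozenset(outcomes),
        sex=sex,
        age_years=age,
        country=country,
    )


@pytest.fixture
def mk():
    return make_report


@pytest.fixture
def toy_reports():
    """Four single-PT reports forming a balanced drug x PT 2x2 universe."""
    return ReportSet(
        [
            make_report("c1", ["drugx"], ["pty"]),
            make_report("c2", ["drugx"], ["ptz"]),
            make_report("c3", ["drugw"], ["pty"]),
            make_report("c4", ["drugw"], ["ptz"]),
        ]
    )


@pytest.fixture(scope="session")
def sim_small():
    """A 400-report synthetic database with its ground truth (fixed seed)."""
    config = default_config(n_reports=400, seed=11)
    reports, truth = generate(config)
    return config, reports, truth


@pytest.fixture(scope="session")
def sim_medium():
    """A 2000-report synthetic database for counting oracles."""
    config = default_config(n_reports=2000, seed=17)
    reports, truth = generate(config)
    return config, reports, truth
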