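from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from faerspv.faers_io import CaseReport

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_case(primaryid="1001", caseid="1", fda_dt=date(2023, 1, 1),
              drugs=(("crizotinib", "PS"),), pts=("nausea",), **kw) -> CaseReport:
    return CaseReport(
        primaryid=primaryid, caseid=caseid, fda_dt=fda_dt,
        drugs=list(drugs), pts=set(pts), **kw,
    )


@pytest.fixture
def case_factory():
    return make_case


@pytest.fixture(scope="session")
def one_pt_config():
    """A one-PT-per-report scenario with a single injected signal, for
    which the generator's closed-form expected cells are exact."""
    from faerspv import synthetic

    events = [("target event", 0.02, "")] + [
        (f"filler {i}", 0.98 / 20, "") for i in range(20)
    ]
    return synthetic.SimulationConfig(
        n_reports=100_000,
        drug_vocab=[("drug x", 0.01, ["drug x", "BRAND X"])],
        event_vocab=events,
        signals=[synthetic.SignalSpec("drug x", "target event", 5.0)],
        pts_per_report=1.0,
        seed=20,
    )
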