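"""Shared fixtures: the packaged inputs, default curves and scenario runs."""

from __future__ import annotations

import pytest
from hypothesis import settings

import renalbudget as rb

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inputs() -> rb.ModelInputs:
    return rb.default_inputs()


@pytest.fixture(scope="session")
def curves(inputs):
    return rb.make_default_curves(inputs.survival)


@pytest.fixture(scope="session")
def all_results(inputs, curves):
    """Reference plus all five scenarios, run once per session."""
    return rb.run_all_scenarios(inputs, curves)


@pytest.fixture(scope="session")
def reference_result(all_results):
    return all_results["reference"]


@pytest.fixture(scope="session")
def microsim_reference(inputs, curves):
    """Large-n microsimulation of the reference scenario for oracle checks."""
    return rb.simulate_patients(
        50_000, 1234, inputs.scenarios["reference"], inputs, curves
    )


def zeroed_costs_dict(inputs: rb.ModelInputs) -> dict:
    """Config dict with every unit cost set to zero."""
    doc = inputs.to_dict()
    for key, val in doc["costs"].items():
        if isinstance(val, dict) and "point" in val:
            val.update(point=0.0, low=0.0, high=0.0)
    for key in ("hd", "pd"):
        doc["hospitalisation"]["event_cost"][key].update(point=0.0, low=0.0, high=0.0)
    return doc


def zeroed_transitions_dict(inputs: rb.ModelInputs) -> dict:
    """Config dict with every movement probability set to zero."""
    doc = inputs.to_dict()
    tr = doc["transitions"]
    tr["transplant_rate"].update(point=0.0, low=0.0, high=0.0)
    tr["graft_failure"].update(point=0.0, low=0.0, high=0.0)
    tr["home_hd_to_ichd"].update(point=0.0, low=0.0, high=0.0)
    for block in ("ichd_to_home_hd", "hd_to_pd", "pd_to_hd"):
        for val in tr[block].values():
            val.update(point=0.0, low=0.0, high=0.0)
    return doc


@pytest.fixture()
def immortal_curves():
    """Survivor functions identically one (no deaths)."""
    return {
        "dialysis": rb.SurvivalCurve("exponential", (0.0,), "dialysis"),
        "transplant": rb.SurvivalCurve("exponential", (0.0,), "transplant"),
    }
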