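"""Shared fixtures: bundled networks and cached pipeline results.

The heavier pipelines (toggle switch, insulin cascade) are solved once per
session and reused across tests.
"""

from __future__ import annotations

import pytest
import sympy as sp

import crnsteady as cs


@pytest.fixture(scope="session")
def methods_crn():
    return cs.load_fixture("methods_example")


@pytest.fixture(scope="session")
def fig1_crn():
    return cs.load_fixture("fig1_example")


@pytest.fixture(scope="session")
def crispri_crn():
    return cs.load_fixture("crispri")


@pytest.fixture(scope="session")
def insulin_crn():
    return cs.load_fixture("insulin")


@pytest.fixture(scope="session")
def methods_result(methods_crn):
    return cs.solve_crn(methods_crn)


@pytest.fixture(scope="session")
def fig1_result(fig1_crn):
    return cs.solve_crn(fig1_crn)


@pytest.fixture(scope="session")
def crispri_result(crispri_crn):
    return cs.solve_crn(crispri_crn)


@pytest.fixture(scope="session")
def insulin_result(insulin_crn):
    return cs.solve_crn(insulin_crn)


@pytest.fixture(scope="session")
def crispri_resolved(crispri_result):
    return cs.resolve_with_conservation(crispri_result.merged, crispri_result.laws)


@pytest.fixture(scope="session")
def insulin_resolved(insulin_crn, insulin_result):
    rates = {r.rate_symbol: 1 for r in insulin_crn.reactions}
    return cs.resolve_with_conservation(
        insulin_result.merged, insulin_result.laws, rate_values=rates
    )


@pytest.fixture(scope="session")
def insulin_acr(insulin_resolved, insulin_result):
    return cs.acr_report(insulin_resolved, insulin_result.laws)


def k(i: int) -> sp.Symbol:
    return sp.Symbol(f"k{i}", positive=True)
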