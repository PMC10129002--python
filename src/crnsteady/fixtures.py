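"""Bundled example networks, loaded from the plain-text reaction lists."""

from __future__ import annotations

from importlib import resources

from .core import CRN, parse_network

__all__ = ["fixture_text", "load_fixture", "FIXTURES"]

FIXTURES = ("methods_example", "fig1_example", "crispri", "insulin")


def fixture_text(name: str) -> str:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return (resources.files("crnsteady.data") / f"{name}.crn").read_text()


def load_fixture(name: str) -> CRN:
    return parse_network(fixture_text(name))
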