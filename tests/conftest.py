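"""Shared fixtures.

Terminal-cycle runs are the expensive unit of work (~2 s each), so they are
computed once per session and memoized by regimen label.
"""

import functools

import pytest

import lipbpk as L


@pytest.fixture(scope="session")
def params():
    """Baseline physiology (first-trimester pregnancy)."""
    return L.default_params()


@pytest.fixture(scope="session")
def terminal_summary(params):
    """Memoized terminal-cycle summaries for preset regimens under the
    baseline physiology and default solver options."""

    @functools.lru_cache(maxsize=None)
    def get(name: str) -> L.CycleSummary:
        return L.find_terminal_cycle(params, L.get_preset(name))

    return get


@pytest.fixture(scope="session")
def reference(terminal_summary):
    """Pathological (450/900) fetal reference levels, from the cached run."""
    fetal = terminal_summary("450/900").compartments["fetus"]
    return L.ReferenceLevels(
        max_fetal_peak=fetal.peak,
        max_fetal_average=fetal.average,
        provenance="450/900",
    )
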