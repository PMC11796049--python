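"""Shared fixtures: simulated traces, vendor fixture files, converted datasets.

Everything is generated at test time from the simulator; session scope
keeps the finite-difference runs to one per suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from cvflow.convert import Trace, assemble_cycles, segment_sweeps
from cvflow.pipeline import analyze_dataset, convert_file
from cvflow.simulate import REVERSIBLE_PRESET, fixture_header, simulate_cv, write_fixture


def make_triangle(
    n_cycles: int = 2,
    scan_rate: float = 0.1,
    e_low: float = 0.0,
    e_high: float = 0.5,
    dt: float = 0.1,
) -> Trace:
    """Ideal triangular potential program with a flat unit current."""
    step = scan_rate * dt
    up = np.arange(e_low, e_high + step / 2, step)
    down = up[::-1][1:]
    one = np.concatenate([up, down])
    E = np.concatenate([one[:-1]] * n_cycles + [np.array([e_low])])
    t = np.arange(len(E)) * dt
    I = np.full(len(E), 1e-6)
    return Trace(t, E, I)


@pytest.fixture(scope="session")
def reversible_trace() -> Trace:
    return simulate_cv(REVERSIBLE_PRESET)


@pytest.fixture(scope="session")
def reversible_cycles(reversible_trace):
    return assemble_cycles(segment_sweeps(reversible_trace))


@pytest.fixture(scope="session")
def gamry_fixture(tmp_path_factory, reversible_trace):
    path = tmp_path_factory.mktemp("fixtures") / "run01.DTA"
    header = fixture_header(REVERSIBLE_PRESET, "gamry-dta", "run01")
    write_fixture(reversible_trace, header, "gamry-dta", path)
    return path


@pytest.fixture(scope="session")
def palmsens_fixture(tmp_path_factory, reversible_trace):
    path = tmp_path_factory.mktemp("fixtures") / "run02.csv"
    header = fixture_header(REVERSIBLE_PRESET, "palmsens-csv", "run02")
    write_fixture(reversible_trace, header, "palmsens-csv", path)
    return path


@pytest.fixture(scope="session")
def analyzed_dataset(tmp_path_factory, gamry_fixture):
    """A converted + analyzed dataset directory (3 cycles)."""
    workdir = tmp_path_factory.mktemp("work")
    result = convert_file(gamry_fixture, workdir=workdir)
    analyze_dataset(result.dataset_dir)
    return result
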