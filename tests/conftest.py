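import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsqcscreen import Assignment, AssignmentTable
from hsqcscreen.synth import make_ccl28_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_assign() -> AssignmentTable:
    """24 well-separated amide peaks, including two histidines.

    Large enough that a handful of perturbed residues can clear a
    mean + 2·SD significance threshold computed over all residues.
    """
    rows = [
        (5, "A", 8.10, 110.0), (11, "C", 8.60, 118.0), (20, "S", 7.60, 114.0),
        (25, "E", 9.10, 122.0), (31, "H", 7.90, 126.0), (40, "T", 8.90, 108.0),
        (53, "I", 9.40, 129.0), (66, "M", 7.30, 120.5), (72, "H", 8.35, 131.0),
        (80, "K", 9.75, 116.5),
    ]
    rng = np.random.default_rng(20)
    taken = {(h, n) for _, _, h, n in rows}
    idx = 81
    while len(rows) < 24:
        h = float(rng.uniform(6.6, 10.4))
        n = float(rng.uniform(103.0, 134.0))
        if all(np.hypot(h - h0, 0.2 * (n - n0)) > 0.3 for _, _, h0, n0 in rows):
            rows.append((idx, "G", h, n))
            idx += 1
    entries = [Assignment(i, c, h, n, height=1.0) for i, c, h, n in rows]
    return AssignmentTable(entries, name="mini")


@pytest.fixture(scope="session")
def ccl28_fixture():
    """The packaged 2,678-fragment fixture at seed 1."""
    return make_ccl28_fixture(1)


@pytest.fixture(scope="session")
def frag_map(ccl28_fixture):
    _, fragments, _ = ccl28_fixture
    return {f.fragment_id: f for f in fragments}
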