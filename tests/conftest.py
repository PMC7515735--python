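import numpy as np
import pytest

import triplexkit as tk


@pytest.fixture(scope="session")
def py_a_spec():
    return tk.parse_label("pY(a)")


@pytest.fixture(scope="session")
def pr_a_spec():
    return tk.parse_label("pR(a)")


@pytest.fixture(scope="session")
def py_a_model(py_a_spec):
    return tk.build_triplex(py_a_spec)


@pytest.fixture(scope="session")
def pr_a_model(pr_a_spec):
    return tk.build_triplex(pr_a_spec)


@pytest.fixture(scope="session")
def b_duplex():
    return tk.build_duplex("GAA" * 3, "B")


@pytest.fixture(scope="session")
def a_duplex():
    return tk.build_duplex("GAA" * 3, "A")


@pytest.fixture()
def rigid_motion():
    """A fixed, non-trivial rotation + translation."""
    from triplexkit.geometry import rotation_about_axis

    R = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 73.0)
    t = np.array([11.0, -7.0, 4.5])
    return R, t
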