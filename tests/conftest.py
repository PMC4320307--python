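import pytest

from retiform import HamiltonLoop, Permutation, load_default_modes

#: The 24-operator sequence tracing one quadrivalent Hamilton loop:
#: N1 N2 N3 N2 N3 N2 N1 N2, repeated three times, from start 1234.
QUADRIVALENT_LOOP_OPS = (1, 2, 3, 2, 3, 2, 1, 2) * 3


@pytest.fixture
def quadrivalent_loop() -> HamiltonLoop:
    return HamiltonLoop(start=Permutation((1, 2, 3, 4)), ops=QUADRIVALENT_LOOP_OPS)


@pytest.fixture
def hexagon_loop() -> HamiltonLoop:
    return HamiltonLoop(start=Permutation((1, 2, 3)), ops=(1, 2, 1, 2, 1, 2))


@pytest.fixture
def invalid_loop() -> HamiltonLoop:
    # N1 applied twice revisits the start immediately
    return HamiltonLoop(start=Permutation((1, 2, 3, 4)), ops=(1,) * 24)


@pytest.fixture(scope="session")
def default_repertoire():
    return load_default_modes()
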