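import numpy as np
import pytest

from promotif import PWM

TRANSFAC_TWO_MATRICES = """\
AC  M00001
XX
ID  I$TEST_01
XX
NA  testA
XX
P0      A      C      G      T
01      0      0      9      1      G
02      9      1      0      0      A
03      1      0      9      0      G
04      0      0      0     10      T
05      0     10      0      0      C
06      9      0      1      0      A
XX
//
AC  M00002
XX
ID  I$TEST_02
XX
NA  testB
XX
PO      A      C      G      T
01     10      0      0      0      A
02      0     10      0      0      C
03      0      0     10      0      G
04      0      0      0     10      T
05     10      0      0      0      A
XX
//
"""


@pytest.fixture
def transfac_text():
    return TRANSFAC_TWO_MATRICES


@pytest.fixture
def consensus_pwm():
    """Deterministic matrix: consensus GACGTT with probability 1 per column."""
    counts = np.zeros((6, 4))
    for i, base in enumerate("GACGTT"):
        counts[i, "ACGT".index(base)] = 10.0
    return PWM(matrix_id="consensus", counts=counts)


@pytest.fixture
def palindrome_pwm():
    """Consensus GAATTC, its own reverse complement."""
    counts = np.zeros((6, 4))
    for i, base in enumerate("GAATTC"):
        counts[i, "ACGT".index(base)] = 10.0
    return PWM(matrix_id="palindrome", counts=counts)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
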