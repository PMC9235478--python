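import numpy as np
import pytest

from polarpleio import SimDesign, builtin_curve


@pytest.fixture(scope="session")
def curve_p2():
    return builtin_curve(2)


@pytest.fixture(scope="session")
def curve_p3():
    return builtin_curve(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale two-trait design used by several tests."""
    return SimDesign(m_total=10_000, p=2, rho=0.8, n_replicates=3, seed=99)


def write_sumstats_file(path, rows, header="snp chr pos ea oa beta se"):
    """Write a tiny whitespace-delimited summary-statistics file."""
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(" ".join(str(x) for x in row) + "\n")
    return path
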