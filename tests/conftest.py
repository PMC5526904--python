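import numpy as np
import pytest

from wgdtrace.codonml import CodonFrequencies, CodonModelSpec
from wgdtrace.core_io import read_newick


def ladder_newick(prefix: str, n: int, tip: float = 0.3,
                  internal: float = 0.15) -> str:
    """Caterpillar tree string with uniform branch lengths."""
    tips = [f"{prefix}{i}:{tip}" for i in range(1, n + 1)]
    s = tips[0]
    for t in tips[1:]:
        s = f"({s},{t}):{internal}"
    return s.rsplit(":", 1)[0] + ";"


@pytest.fixture(scope="session")
def uniform_freqs():
    return CodonFrequencies.uniform()


@pytest.fixture(scope="session")
def tree6():
    """Six-taxon tree with a two-leaf foreground clade (class 1)."""
    return read_newick(
        "((a:0.1,b:0.15) #1 :0.05,(c:0.12,d:0.08):0.07,(e:0.1,f:0.2):0.06);"
    )


@pytest.fixture(scope="session")
def tree8_marked():
    """Eight-taxon tree whose left four-leaf clade is foreground."""
    return read_newick(
        "(((a:0.1,b:0.15):0.1,(c:0.12,d:0.08):0.07) $1 :0.05,"
        "((e:0.1,f:0.2):0.06,(g:0.1,h:0.1):0.1):0.05);"
    )


@pytest.fixture(scope="session")
def m0_spec(uniform_freqs):
    return CodonModelSpec.m0(kappa=2.0, omega=0.2, frequencies=uniform_freqs)
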