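import numpy as np
import pytest

from rapa import build_energy_table, make_structure


@pytest.fixture(scope="session")
def table():
    return build_energy_table()


@pytest.fixture
def asn_ser():
    return make_structure("asn_ser")


@pytest.fixture
def asn_asn():
    return make_structure("asn_asn")


def brute_force_edges(sites, threshold):
    """Independent all-pairs distance filter (input positions only)."""
    out = set()
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if sites[i].residue_key == sites[j].residue_key:
                continue
            d = float(np.linalg.norm(sites[i].position - sites[j].position))
            if d <= threshold:
                out.add((i, j))
    return out
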