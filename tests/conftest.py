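import numpy as np
import pandas as pd
import pytest

from tundradiv import PlotRecord, SimulationConfig, build_matrix, simulate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One full-design synthetic survey shared across tests."""
    return simulate_survey(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_matrix(default_survey):
    return default_survey.matrix()


@pytest.fixture
def hand_records():
    """Two stations whose plots are internally identical but mutually distinct."""
    recs = []
    for si, sp in (("S1", {"a", "b", "c"}), ("S2", {"d", "e"})):
        for pi in range(5):
            recs.append(
                PlotRecord(
                    mountain="M1", transect="T1", station=si, plot=f"P{pi+1}",
                    altitude=800.0 + (0.0 if si == "S1" else 1.0),
                    cover=0.5, species=frozenset(sp),
                )
            )
    return recs


@pytest.fixture
def staircase():
    """Perfectly nested 4x4 matrix: each row a subset of the one above."""
    return np.array(
        [[1, 1, 1, 1],
         [1, 1, 1, 0],
         [1, 1, 0, 0],
         [1, 0, 0, 0]], dtype=np.int8
    )


@pytest.fixture
def two_block():
    """Block-diagonal two-module matrix with Q = 0.5 under the true partition."""
    return np.array(
        [[1, 1, 0, 0],
         [1, 1, 0, 0],
         [0, 0, 1, 1],
         [0, 0, 1, 1]], dtype=np.int8
    )


def make_community_matrix(incidence, altitudes=None):
    """Wrap a bare incidence array in a CommunityMatrix with stub metadata."""
    from tundradiv import CommunityMatrix

    n = incidence.shape[0]
    if altitudes is None:
        altitudes = np.linspace(750.0, 1400.0, n)
    meta = pd.DataFrame(
        {
            "mountain": ["M1"] * n,
            "transect": ["T1"] * n,
            "station": [f"S{i+1}" for i in range(n)],
            "plot": [f"P{i+1}" for i in range(n)],
            "altitude_m": altitudes,
        }
    )
    species = [f"sp{j+1}" for j in range(incidence.shape[1])]
    return CommunityMatrix(incidence, meta, species)
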