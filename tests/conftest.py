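import pytest

from phytonet.adme import CompoundRecord
from phytonet.fishing import InteractionRecord
from phytonet.network import PPINetwork, build_bipartite
from phytonet.synthetic_study import build_study_fixture


@pytest.fixture
def toy_compounds():
    """Five compounds straddling the OB/DL thresholds; exactly 2 pass."""
    scores = [(35, 0.2), (30, 0.18), (29.9, 0.5), (60, 0.17), (10, 0.05)]
    return [
        CompoundRecord(f"c{i}", name=f"toy-{i}", ob=ob, dl=dl)
        for i, (ob, dl) in enumerate(scores, start=1)
    ]


@pytest.fixture
def k23_network():
    """Complete bipartite K2,3: 2 compounds x 3 targets, 6 edges."""
    edges = [
        InteractionRecord(c, t, 0.9, 0.9)
        for c in ("c1", "c2")
        for t in ("TA", "TB", "TC")
    ]
    return build_bipartite(["c1", "c2"], edges)


@pytest.fixture
def star_ppi():
    """Star K1,9: hub of degree 9, mean degree 1.8, hub threshold 3.6."""
    conf = {("HUB", f"L{i}") if "HUB" < f"L{i}" else (f"L{i}", "HUB"): 0.9 for i in range(9)}
    return PPINetwork(confidences=conf)


@pytest.fixture(scope="session")
def study_fixture():
    """Synthetic study-shaped tables (built once per session)."""
    return build_study_fixture(seed=0)
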