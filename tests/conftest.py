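import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hubcog.connectome import Connectome, NodeSet, SubjectMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Normalized 3-node connectome with edge weights 0.2 / 0.3 / 0.5."""
    nodes = NodeSet(("lh.a", "lh.b", "rh.c"))
    w = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.3], [0.5, 0.3, 0.0]])
    return Connectome("tri", "control", nodes, w, normalized=True)


def make_connectome(w, subject_id="s", group="control", normalized=True,
                    removed=None, streamline_total=None):
    n = w.shape[0]
    nodes = NodeSet(tuple(f"lh.n{i}" for i in range(n)))
    return Connectome(subject_id, group, nodes, np.asarray(w, float),
                      removed=removed or {}, normalized=normalized,
                      streamline_total=streamline_total or 10_000_000)


@pytest.fixture
def make():
    return make_connectome
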