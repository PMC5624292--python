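import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from landgen.seqio import Alignment, PatchTable
from landgen.synthetic import Polyline, Rect, ScenarioConfig


def make_alignment(seqs, patches=None, ids=None) -> Alignment:
    n = len(seqs)
    ids = ids or [f"s{i}" for i in range(n)]
    patches = patches or ["P1"] * n
    return Alignment(ids, patches, np.array([list(s) for s in seqs]))


def make_patch_table(labels, coords=None) -> PatchTable:
    coords = coords or [(i * 0.01, -39.0) for i in range(len(labels))]
    table = pd.DataFrame(coords, columns=["lon", "lat"],
                         index=pd.Index(labels))
    return PatchTable(table, {lab: [] for lab in labels})


@pytest.fixture
def toy_alignment() -> Alignment:
    """The 3 x 4 toy: pairwise diffs (1 + 2 + 1)/3 sites / 4 = 1/3."""
    return make_alignment(["ACGT", "ACGA", "ACTA"])


@pytest.fixture
def two_patch_alignment() -> Alignment:
    """Two internally identical, mutually distinct groups (Snn = 1)."""
    return make_alignment(["AAAA"] * 4 + ["TTTT"] * 4,
                          patches=["P1"] * 4 + ["P2"] * 4)


def tiny_scenario(seed=0, **overrides) -> ScenarioConfig:
    """A 20 x 20 three-patch scenario small enough for replicate loops."""
    params = dict(
        nrows=20, ncols=20, dx=0.002, dy=0.002, xll=-73.0, yll=-39.9,
        legend={1: "forest", 2: "shrub", 3: "farm"},
        background=3,
        shapes=[Rect(1, 2, 2, 4, 4), Rect(1, 2, 15, 4, 17),
                Rect(1, 15, 8, 17, 10),
                Polyline(1, ((3, 5), (3, 14))),
                Polyline(2, ((5, 3), (14, 9)))],
        patch_cells=[(3, 3), (3, 16), (16, 9)],
        patch_labels=["A", "B", "C"],
        conductance={1: 1.0, 2: 0.5, 3: 0.05},
        n_per_patch=[8, 8, 8],
        deme_size=30, mu=1e-4, seq_length=120, lam=None,
        mig_rate=0.05, generations=200, seed=seed)
    params.update(overrides)
    return ScenarioConfig(**params)


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    return tiny_scenario()
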