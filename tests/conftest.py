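import numpy as np
import pandas as pd
import pytest

from caniuc.de import vst
from caniuc.io import CountMatrix
from caniuc.simulate import SimulationDesign, simulate_counts


@pytest.fixture(scope="session")
def small_planted():
    """A small two-cluster dataset: 8+7 tumors, 5 normals, 10% of 2000
    genes carry a mut-only |log2FC| = 2 effect."""
    design = SimulationDesign(
        n_genes=2000,
        n_tumors_mut=8,
        n_tumors_wt=7,
        n_normals=5,
        frac_de_shared=0.0,
        frac_de_mut_only=0.1,
        frac_de_wt_only=0.0,
        frac_opposite=0.0,
        dispersion=0.1,
        effect_log2fc=2.0,
        seed=42,
        hotspots=[],
    )
    counts, samples, truth = simulate_counts(design)
    return design, counts, samples, truth


@pytest.fixture(scope="session")
def small_planted_vst(small_planted):
    _, counts, samples, _ = small_planted
    return vst(counts), samples


@pytest.fixture()
def tiny_counts():
    frame = pd.DataFrame(
        {"s1": [10, 3, 0, 25], "s2": [20, 6, 0, 50], "s3": [10, 3, 1, 25]},
        index=["g1", "g2", "g3", "g4"],
    )
    return CountMatrix(frame)


def relabel_accuracy(assignments: pd.Series, planted: dict[str, str]) -> float:
    """Best label-matching accuracy of a 2-cluster assignment against the
    planted mut/wt labels."""
    truth = pd.Series(planted)
    pred = assignments[truth.index]
    a = ((pred == 1) == (truth == "mut")).mean()
    b = ((pred == 2) == (truth == "mut")).mean()
    return float(max(a, b))
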