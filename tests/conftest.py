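import numpy as np
import pandas as pd
import pytest

from cocktailnet import MolecularNetwork


@pytest.fixture
def path_net():
    """A-B-C path."""
    return MolecularNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net():
    """Center A with leaves B, C, D."""
    return MolecularNetwork.from_edges([("A", "B"), ("A", "C"), ("A", "D")])


@pytest.fixture
def tiny_meta():
    """One batch, one MCF7 case with two controls, plus a second drug so the
    batch survives the single-perturbagen filter."""
    return pd.DataFrame({
        "sample_id": ["c1", "c2", "case1", "case2"],
        "batch_id": ["1"] * 4,
        "cell_line": ["MCF7"] * 4,
        "perturbagen": ["CONTROL", "CONTROL", "DRUGX", "DRUGY"],
        "dose": [0.0, 0.0, 10.0, 10.0],
        "control_ids": [[], [], ["c1", "c2"], ["c1", "c2"]],
    })


def make_gene_matrix(values: dict[str, list[float]], genes: list[str]) -> pd.DataFrame:
    return pd.DataFrame(values, index=genes)
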