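import numpy as np
import pandas as pd
import pytest

from comira.expression import ExpressionMatrix


def make_matrix(values, genes=None, samples=None, scale="fpkm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )


@pytest.fixture
def small_fpkm():
    return make_matrix([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0], [5.0, 3.0, 0.2]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_gmt(tmp_path):
    """Five small gene sets over a 30-gene universe, GMT on disk."""
    lines = [
        "set01\tCell cycle-like\tG00\tG01\tG02\tG03\tG04",
        "set02\tSignaling-like\tG05\tG06\tG07",
        "set03\tMetabolism-like\tG08\tG09\tG10\tG11\tG12\tG13\tG14\tG15",
        "set04\tAdhesion-like\tG16\tG17\tG18\tG19",
        "set05\tTransport-like\tG20\tG21\tG22\tG23\tG24\tG25",
    ]
    path = tmp_path / "toy.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def universe_30():
    return {f"G{i:02d}" for i in range(30)}
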