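import numpy as np
import pandas as pd
import pytest

from reprank import ExpressionDataset, RankedDrugList


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """6 genes x 8 samples, gene G0 strongly up in cases, G1 strongly down."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    matrix = 8.0 + 0.3 * rng.standard_normal((6, 8))
    matrix[0, :4] += 3.0
    matrix[1, :4] -= 3.0
    groups = pd.Series(["case"] * 4 + ["control"] * 4, index=samples)
    return ExpressionDataset(
        matrix=pd.DataFrame(matrix, index=genes, columns=samples),
        groups=groups, stage="MM", dataset_id="toy",
    )


def make_list(items: list[str], tool_id: str = "t1", dataset_id: str = "DS1",
              stage: str = "MM") -> RankedDrugList:
    """Reverser-first list: first item gets the most negative score."""
    n = len(items)
    entries = [(item, -float(n - i)) for i, item in enumerate(items)]
    return RankedDrugList(entries=entries, tool_id=tool_id, dataset_id=dataset_id, stage=stage)


@pytest.fixture
def make_ranked_list():
    return make_list
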