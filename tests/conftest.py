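import numpy as np
import pandas as pd
import pytest

from kdapipe import ExpressionMatrix, MetaboliteTable


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """3 genes x 4 samples, two groups, log2 scale."""
    values = pd.DataFrame(
        [[8.0, 8.2, 9.1, 9.0],
         [7.5, 7.4, 7.6, 7.5],
         [10.0, 10.1, 9.2, 9.1]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "t1", "t2"],
    )
    groups = {"c1": "FA", "c2": "FA", "t1": "DE", "t2": "DE"}
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def small_metabolome() -> MetaboliteTable:
    abund = pd.DataFrame(
        [[100.0, 110.0, 350.0, 330.0],
         [50.0, np.nan, 55.0, 52.0],
         [9.0, 8.0, 7.5, 8.5]],
        index=["m1", "m2", "m3"],
        columns=["c1", "c2", "t1", "t2"],
    )
    ann = pd.DataFrame(
        {"super_pathway": ["Carbohydrate", "Lipid", "unknown"],
         "sub_pathway": ["Glycogen", "TAG", "unknown"]},
        index=["m1", "m2", "m3"],
    )
    groups = {"c1": "FA", "c2": "FA", "t1": "DE", "t2": "DE"}
    return MetaboliteTable(abundances=abund, annotations=ann, groups=groups)
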