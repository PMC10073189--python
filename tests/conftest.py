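import numpy as np
import pandas as pd
import pytest

from sigmr.io import SignatureMatrix
from sigmr.signatures import ExpressionSignature


def make_matrix(values, gene_ids=None, column_ids=None, landmark=None, cell_line="HA1E"):
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(n_g)]
    column_ids = column_ids or [f"C{i:03d}" for i in range(n_c)]
    landmark = np.ones(n_g, dtype=bool) if landmark is None else np.asarray(landmark, bool)
    meta = pd.DataFrame(
        {
            "compound_id": [c.split(":")[0] for c in column_ids],
            "compound_name": [c.split(":")[0] for c in column_ids],
            "cell_line": cell_line,
            "dose": "10 uM",
            "time": "24 h",
        },
        index=pd.Index(column_ids, name="column_id"),
    )
    return SignatureMatrix(
        gene_ids=gene_ids,
        gene_is_landmark=landmark,
        column_ids=column_ids,
        column_meta=meta,
        values=values,
    )


def make_signature(z, gene_ids=None, landmark=None, **meta):
    z = np.asarray(z, dtype=float)
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(len(z))]
    landmark = np.ones(len(z), dtype=bool) if landmark is None else np.asarray(landmark, bool)
    meta.setdefault("column_id", "sig")
    return ExpressionSignature(gene_ids=gene_ids, z=z, is_landmark=landmark, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.standard_normal((20, 5)))
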