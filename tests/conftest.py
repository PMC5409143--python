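import numpy as np
import pandas as pd
import pytest

from drugcorr.panel_io import (
    ExpressionMatrix,
    LineageAnnotation,
    ResponseTable,
    harmonize,
)


def make_panel(expr_dict, response_rows, lineage_of, tag="fixture"):
    """Build a HarmonizedPanel from plain dict/list literals."""
    expr = ExpressionMatrix(pd.DataFrame(expr_dict).T)
    resp = ResponseTable(
        pd.DataFrame(response_rows, columns=["cell_line", "drug", "metric", "value"])
    )
    ann = LineageAnnotation(dict(lineage_of))
    return harmonize(expr, resp, ann, tag=tag)


@pytest.fixture
def small_panel():
    """Two genes x six cell lines across two lineages, one drug.

    GENEUP rises with IC50 within each lineage (resistance marker);
    GENEDN falls with it (sensitizing marker).
    """
    lines = [f"L{i}" for i in range(1, 7)]
    expr = {
        "GENEUP": dict(zip(lines, [1.0, 2.0, 3.0, 1.5, 2.5, 3.5])),
        "GENEDN": dict(zip(lines, [3.0, 2.0, 1.0, 3.5, 2.5, 1.5])),
    }
    resp = [(c, "DRUG1", "IC50", v) for c, v in zip(lines, [0.1, 1.0, 10.0, 0.2, 2.0, 20.0])]
    lineage_of = {c: ("lung" if i < 3 else "skin") for i, c in enumerate(lines)}
    return make_panel(expr, resp, lineage_of)
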