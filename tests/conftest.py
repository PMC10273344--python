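import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stabbench import ScoreTable, SourceMeta

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(columns: dict[str, list[float]], gene: str = "GENE1") -> ScoreTable:
    """Build a fully-observed ScoreTable from per-source value lists.

    NaN entries mark missing (variant, source) pairs and are dropped.
    Variants are L{i}P substitutions at consecutive positions.
    """
    rows = []
    for source, values in columns.items():
        for i, v in enumerate(values):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            rows.append((gene, i + 1, "L", "P", source, float(v)))
    return ScoreTable(
        pd.DataFrame(rows, columns=["gene", "position", "wt", "mut", "source", "value"])
    )


@pytest.fixture
def predictor_meta():
    def _make(source_id, direction=1, units="kcal_per_mol"):
        return SourceMeta(source_id, "predictor", direction, units,
                          structure_context="monomer")
    return _make


@pytest.fixture
def dms_meta():
    def _make(source_id, direction=1, assay_class="abundance", wt_reference=None):
        return SourceMeta(source_id, "dms", direction, "unitless",
                          assay_class=assay_class, wt_reference=wt_reference)
    return _make
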