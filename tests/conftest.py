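import pandas as pd
import pytest

from arealink.core import AggregatedTable, TransitionMatrix, VarMeta
from arealink.crosswalk import build_mapping_table
from arealink.synthgeo import GeographyParams, generate_geography


def make_matrix(links, k=1, source_level=None, target_level=None):
    return TransitionMatrix(
        index=k,
        links=frozenset(links),
        source_level=source_level if source_level is not None else k,
        target_level=target_level if target_level is not None else k + 1,
    )


def make_table(values, kind="count", var="births", level="eco", tag=None, weights=None):
    data = {var: pd.Series(values)}
    meta = {var: VarMeta(kind=kind, tag=tag)}
    if weights is not None:
        data["w"] = pd.Series(weights)
        meta["w"] = VarMeta(kind="continuous")
    df = pd.DataFrame(data)
    df.index = df.index.astype(str)
    df.index.name = "id"
    return AggregatedTable(data=df, var_meta=meta, level=level)


@pytest.fixture(scope="session")
def mixed_geography():
    """A seeded geography exercising all equivalence situations."""
    params = GeographyParams(
        seed=42,
        overlap_rate=0.2,
        frac_split=0.05,
        frac_one_to_one=0.1,
        fragmentation_rate=0.2,
    )
    return generate_geography(params)


@pytest.fixture(scope="session")
def mixed_mapping(mixed_geography):
    table, census = build_mapping_table([mixed_geography.m1, mixed_geography.m2])
    return table, census
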