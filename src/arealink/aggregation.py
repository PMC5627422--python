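"""Aggregate variables from an original spatial level to the analysis level.

Count variables only admit a sum (events are additive); continuous
variables and proportions admit mean, median or weighted mean.  Missing
member values are excluded from mean-like aggregates; for a sum they flag
the analysis unit's total as *incomplete* rather than silently lowering it
— undercounting is exactly what the validation step must be able to see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AggregatedTable, ConfigError, DataError, VarMeta
from .crosswalk import MappingTable

__all__ = ["AggregationSpec", "aggregate"]

_METHODS = ("sum", "mean", "median", "weighted_mean")


@dataclass(frozen=True)
class AggregationSpec:
    """How one variable is carried to the analysis level."""

    variable: str
    method: str
    weight_var: str | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(
                f"unknown aggregation method {self.method!r} for {self.variable!r}"
            )
        if self.method == "weighted_mean" and not self.weight_var:
            raise ConfigError(
                f"weighted_mean for {self.variable!r} requires a weight_var"
            )


def _resolve_level(table: AggregatedTable, mapping: MappingTable) -> dict[str, str]:
    """Pick the mapping side (eco or medical) whose IDs match the table."""
    ids = set(table.ids)
    eco_hits = len(ids & set(mapping.eco_to_analysis))
    med_hits = len(ids & set(mapping.medical_to_analysis))
    if eco_hits == 0 and med_hits == 0:
        raise DataError("no table id appears in the mapping table")
    return mapping.eco_to_analysis if eco_hits >= med_hits else mapping.medical_to_analysis


def aggregate(
    table: AggregatedTable,
    mapping: MappingTable,
    specs: list[AggregationSpec],
) -> tuple[AggregatedTable, dict]:
    """Aggregate ``table`` onto the analysis units through ``mapping``.

    Returns the analysis-level table and a completeness report listing
    unmapped input units and, per variable, analysis units whose sum is
    incomplete because a member value was missing.
    """
    id_to_analysis = _resolve_level(table, mapping)
    report: dict = {"unmapped_ids": [], "incomplete": {}, "missing_members": {}}

    df = table.data
    mapped_mask = df.index.to_series().isin(id_to_analysis)
    report["unmapped_ids"] = sorted(df.index[~mapped_mask])
    df = df[mapped_mask]
    groups = df.groupby(df.index.map(id_to_analysis))

    out: dict[str, pd.Series] = {}
    out_meta: dict[str, VarMeta] = {}
    for spec in specs:
        var = spec.variable
        if var not in table.data.columns:
            raise ConfigError(f"variable {var!r} absent from the table")
        meta = table.var_meta.get(var, VarMeta())
        if meta.kind == "count" and spec.method != "sum":
            raise ConfigError(
                f"count variable {var!r} only allows sum, not {spec.method!r}"
            )
        if meta.kind == "proportion" and spec.method == "sum":
            raise ConfigError(f"sum requested on proportion variable {var!r}")

        if spec.method == "sum":
            agg = groups[var].sum(min_count=1)
            incomplete = sorted(
                aid for aid, grp in groups if grp[var].isna().any()
            )
            if incomplete:
                report["incomplete"][var] = incomplete
        elif spec.method == "mean":
            agg = groups[var].mean()
        elif spec.method == "median":
            agg = groups[var].median()
        else:  # weighted_mean
            wvar = spec.weight_var
            if wvar not in table.data.columns:
                raise ConfigError(
                    f"weight variable {wvar!r} for {var!r} absent from the table"
                )
            vals = {}
            for aid, grp in groups:
                ok = grp[var].notna() & grp[wvar].notna()
                w = grp.loc[ok, wvar]
                if float(w.sum()) == 0.0:
                    raise DataError(
                        f"weighted_mean of {var!r}: zero total weight in unit {aid!r}"
                    )
                vals[aid] = float((grp.loc[ok, var] * w).sum() / w.sum())
            agg = pd.Series(vals)

        n_missing = int(table.data[var].isna().sum())
        if n_missing:
            report["missing_members"][var] = n_missing
        out[var] = agg
        # a sum of proportions is forbidden above, so kinds carry over
        out_meta[var] = meta

    result = pd.DataFrame(out)
    result.index.name = "id"
    # keep every analysis unit the mapping defines, even value-less ones
    result = result.reindex(sorted(mapping.analysis_units))
    return (
        AggregatedTable(data=result, var_meta=out_meta, level="analysis"),
        report,
    )
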