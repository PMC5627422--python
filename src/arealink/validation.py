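"""Statistical validation of the mapping table.

The mapping table is validated by comparing a variable recorded in BOTH
databases (for the French birth application, the annual number of live
births) at the analysis scale: for each analysis unit the relative
difference

    r_i = 100 * (eco_i - med_i) / med_i

is computed with the MEDICAL count as the denominator, and summarised as a
median [IQR].  Units with a zero medical count are excluded from the
quantiles and counted.  Both signed and absolute versions are reported;
the headline uses the signed one unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AggregatedTable, DataError, VarMeta

__all__ = ["ComparisonReport", "compare_common_variable", "select_common_variables"]


@dataclass
class ComparisonReport:
    variable: str
    per_unit: pd.Series  # signed r_i (%) per analysis unit with med_i > 0
    median_pct: float
    iqr_pct: tuple[float, float]
    abs_median_pct: float
    abs_iqr_pct: tuple[float, float]
    total_eco: float
    total_med: float
    total_difference: float
    n_units: int
    n_excluded: int  # zero-medical-denominator units

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "median_pct": self.median_pct,
            "iqr_pct": list(self.iqr_pct),
            "abs_median_pct": self.abs_median_pct,
            "abs_iqr_pct": list(self.abs_iqr_pct),
            "total_eco": self.total_eco,
            "total_med": self.total_med,
            "total_difference": self.total_difference,
            "n_units": self.n_units,
            "n_excluded": self.n_excluded,
        }

    def summary(self, signed: bool = True) -> str:
        med = self.median_pct if signed else self.abs_median_pct
        q1, q3 = self.iqr_pct if signed else self.abs_iqr_pct
        return (
            f"{self.variable}: median relative difference "
            f"{med:.1f}% [{q1:.1f}; {q3:.1f}] over {self.n_units} analysis units "
            f"({self.n_excluded} excluded); totals eco={self.total_eco:g} "
            f"med={self.total_med:g} difference={self.total_difference:g}"
        )


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics (R type 7)
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def compare_common_variable(
    eco_agg: AggregatedTable,
    med_agg: AggregatedTable,
    variable: str,
) -> ComparisonReport:
    """Compare a shared variable between the two databases at analysis scale."""
    for tab, name in ((eco_agg, "ecological"), (med_agg, "medical")):
        if variable not in tab.data.columns:
            raise DataError(f"variable {variable!r} absent from the {name} table")
    eco = eco_agg.data[variable]
    med = med_agg.data[variable]
    common = eco.index.intersection(med.index)
    eco, med = eco.loc[common], med.loc[common]
    both = eco.notna() & med.notna()
    eco, med = eco[both], med[both]
    if len(eco) == 0:
        raise DataError("empty comparison: no overlapping analysis units")

    total_eco = float(eco.sum())
    total_med = float(med.sum())
    nonzero = med > 0
    r = 100.0 * (eco[nonzero] - med[nonzero]) / med[nonzero]
    if len(r) == 0:
        raise DataError("empty comparison: all medical denominators are zero")
    q1, q2, q3 = _quartiles(r.to_numpy())
    a1, a2, a3 = _quartiles(np.abs(r.to_numpy()))
    return ComparisonReport(
        variable=variable,
        per_unit=r,
        median_pct=q2,
        iqr_pct=(q1, q3),
        abs_median_pct=a2,
        abs_iqr_pct=(a1, a3),
        total_eco=total_eco,
        total_med=total_med,
        total_difference=total_eco - total_med,
        n_units=int(len(r)),
        n_excluded=int((~nonzero).sum()),
    )


def select_common_variables(
    eco_meta: dict[str, VarMeta],
    med_meta: dict[str, VarMeta],
    eco_table: AggregatedTable | None = None,
    med_table: AggregatedTable | None = None,
) -> list[tuple[str, str]]:
    """Variables shared by the two databases, matched by semantic tag.

    Returns ``(eco_variable, medical_variable)`` pairs ranked by the lesser
    of the two completeness fractions (units carrying a value), best first.
    An empty result means validation must be skipped.
    """
    eco_by_tag = {m.tag: v for v, m in eco_meta.items() if m.tag}
    med_by_tag = {m.tag: v for v, m in med_meta.items() if m.tag}
    shared = set(eco_by_tag) & set(med_by_tag)

    def completeness(pair: tuple[str, str]) -> float:
        ev, mv = pair
        ec = eco_table.completeness(ev) if eco_table is not None else 1.0
        mc = med_table.completeness(mv) if med_table is not None else 1.0
        return min(ec, mc)

    pairs = [(eco_by_tag[t], med_by_tag[t]) for t in sorted(shared)]
    return sorted(pairs, key=lambda p: (-completeness(p), p))
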