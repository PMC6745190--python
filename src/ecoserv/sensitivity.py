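"""Elasticity of the total ESV to value-coefficient perturbation.

Because benefit-transfer coefficients are transferred from a global model,
their local accuracy is uncertain. The standard check perturbs one class's
entire coefficient row by +/-50% and measures the elasticity of the total —
the coefficient of sensitivity:

    CS = ((ESV_adj - ESV) / ESV) / ((VC_adj - VC) / VC)

CS > 1 means the total is elastic (coefficient errors are amplified);
CS < 1 means the estimate is robust to coefficient error. Under the linear
valuation model CS reduces to the class's share of the total, ESV_k / ESV,
independent of the perturbation size — a property the tests verify
numerically rather than assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classes import CLASSES
from .raster import AreaTable
from .valuation import ValueCoefficientTable, total_esv

__all__ = ["SensitivityResult", "adjust_vc", "coefficient_of_sensitivity", "sensitivity_table"]


@dataclass(frozen=True)
class SensitivityResult:
    """Response of the total ESV to one class's coefficient perturbation."""

    class_name: str
    delta: float
    pct_change_total: float  # % change of the total under the perturbation
    cs: float  # coefficient of sensitivity (elasticity)

    @property
    def elastic(self) -> bool:
        return self.cs > 1.0


def adjust_vc(vc: ValueCoefficientTable, class_name: str, factor: float) -> ValueCoefficientTable:
    """Scale one class's coefficient row by ``factor`` (1.5 for +50%)."""
    if not 0 < factor <= 2:
        raise ValueError("factor must lie in (0, 2] (+/-100% at most)")
    return vc.scale_class(class_name, factor)


def coefficient_of_sensitivity(
    areas_ha: pd.Series,
    vc: ValueCoefficientTable,
    class_name: str,
    delta: float = 0.5,
) -> SensitivityResult:
    """CS of the total ESV to a relative coefficient change ``delta``.

    ``delta`` is the signed fractional adjustment (+0.5 for +50%). For a
    class whose coefficients are all zero the perturbation changes nothing
    and the formula degenerates to 0/0; CS is defined as 0 there.
    """
    if class_name not in CLASSES:
        raise KeyError(f"unknown land-cover class {class_name!r}")
    if delta == 0:
        raise ValueError("delta must be nonzero")
    base = total_esv(areas_ha, vc)
    if base <= 0:
        raise ValueError("total ESV must be positive for a sensitivity analysis")
    if float(vc.class_totals()[class_name]) == 0.0:
        return SensitivityResult(class_name, delta, 0.0, 0.0)
    adjusted = total_esv(areas_ha, adjust_vc(vc, class_name, 1.0 + delta))
    rel_change = (adjusted - base) / base
    cs = rel_change / delta
    return SensitivityResult(class_name, delta, 100.0 * abs(rel_change), cs)


def sensitivity_table(
    areas: AreaTable,
    vc: ValueCoefficientTable,
    delta: float = 0.5,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Percent change and CS for every class and year (report layout).

    Rows are classes, columns a two-level (year, {pct_change, cs}) header;
    values rounded to ``decimals`` (None for full precision).
    """
    cols = {}
    for year in areas.years:
        row = areas.row(year)
        results = [coefficient_of_sensitivity(row, vc, c, delta) for c in CLASSES]
        cols[(year, "pct_change")] = [r.pct_change_total for r in results]
        cols[(year, "cs")] = [r.cs for r in results]
    df = pd.DataFrame(cols, index=list(CLASSES))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["year", "measure"])
    df.index.name = "class"
    if decimals is not None:
        df = df.round(decimals)
    return df
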