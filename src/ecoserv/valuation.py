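"""Benefit-transfer valuation of land-cover areas.

Ecosystem service values are obtained by multiplying each class's area by a
per-hectare value coefficient and summing:

    ESV_k = sum_f A_k VC_kf        (value of land class k)
    ESV_f = sum_k A_k VC_kf        (value of service function f)
    ESV   = sum_k sum_f A_k VC_kf  (total)

with A_k the class area in hectares and VC_kf the coefficient in US$ per
hectare per year. The two partial sums are different margins of the same
matrix product, so sum_k ESV_k == sum_f ESV_f == ESV holds by construction
— a useful accounting identity for report validation. Change between years
is expressed as ESV_cr = 100 (ESV_t2 - ESV_t1) / ESV_t1.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASSES, FUNCTIONS
from .raster import AreaTable, CategoricalRaster

__all__ = [
    "ValueCoefficientTable",
    "esv_by_class",
    "esv_by_function",
    "total_esv",
    "esv_change_rate",
    "zonal_esv",
]

BILLION = 1e9


class ValueCoefficientTable:
    """Per-class, per-function value coefficients (US$ ha^-1 yr^-1).

    Wraps a ``class x function`` DataFrame in canonical order. The packaged
    default is the published Central Asia matrix derived from the de Groot
    et al. global unit values; any table with the same schema can be
    substituted.
    """

    def __init__(self, vc: pd.DataFrame):
        missing_c = [c for c in CLASSES if c not in vc.index]
        missing_f = [f for f in FUNCTIONS if f not in vc.columns]
        if missing_c or missing_f:
            raise ValueError(f"coefficient table misses classes {missing_c} / functions {missing_f}")
        df = vc.loc[list(CLASSES), list(FUNCTIONS)].astype(float)
        if (df.values < 0).any():
            raise ValueError("value coefficients must be nonnegative")
        self._df = df

    @classmethod
    def default(cls) -> "ValueCoefficientTable":
        """The packaged Central Asia coefficient matrix."""
        with resources.files("ecoserv.data").joinpath("value_coefficients_central_asia.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ValueCoefficientTable":
        df = pd.read_csv(path_or_buf, comment="#", index_col="class")
        return cls(df)

    def to_csv(self, path: str | Path) -> Path:
        self._df.to_csv(path, index_label="class")
        return Path(path)

    @property
    def matrix(self) -> pd.DataFrame:
        return self._df.copy()

    def class_totals(self) -> pd.Series:
        """Per-class coefficient totals (sum over the nine functions)."""
        totals = self._df.sum(axis=1)
        totals.name = "total_vc"
        return totals

    def scale_class(self, class_name: str, factor: float) -> "ValueCoefficientTable":
        """Copy with one class's entire coefficient row scaled by ``factor``."""
        if class_name not in CLASSES:
            raise KeyError(f"unknown land-cover class {class_name!r}")
        if not np.isfinite(factor) or factor < 0:
            raise ValueError("scale factor must be finite and nonnegative")
        df = self._df.copy()
        df.loc[class_name] *= factor
        return ValueCoefficientTable(df)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, ValueCoefficientTable) and self._df.equals(other._df)


def _check_row(areas_ha: pd.Series) -> pd.Series:
    a = areas_ha.reindex(list(CLASSES))
    if a.isna().any():
        raise ValueError(f"area row misses classes {list(a.index[a.isna()])}")
    return a.astype(float)


def esv_by_class(areas_ha: pd.Series, vc: ValueCoefficientTable) -> pd.Series:
    """ESV_k = A_k x (sum over functions of VC_kf), in US$."""
    a = _check_row(areas_ha)
    out = a * vc.class_totals()
    out.name = "esv_usd"
    return out


def esv_by_function(areas_ha: pd.Series, vc: ValueCoefficientTable) -> pd.Series:
    """ESV_f = sum over classes of A_k x VC_kf, in US$."""
    a = _check_row(areas_ha)
    out = vc.matrix.mul(a, axis=0).sum(axis=0)
    out.name = "esv_usd"
    return out


def total_esv(areas_ha: pd.Series, vc: ValueCoefficientTable) -> float:
    """Total ESV in US$; equals both margins' sums."""
    return float(esv_by_class(areas_ha, vc).sum())


def esv_change_rate(esv_t1: float, esv_t2: float) -> float:
    """Change rate 100 x (ESV_t2 - ESV_t1) / ESV_t1, %.

    A zero baseline yields NaN with a warning (undefined, not 0)."""
    if esv_t1 == 0:
        warnings.warn("change rate undefined for zero baseline ESV", stacklevel=2)
        return float("nan")
    return 100.0 * (esv_t2 - esv_t1) / esv_t1


def zonal_esv(
    raster: CategoricalRaster,
    zones: CategoricalRaster | np.ndarray,
    vc: ValueCoefficientTable,
) -> pd.Series:
    """Total ESV per zone of a co-registered integer zone raster.

    Zones partition the landscape, so the per-zone values sum to the global
    total over the common mask.
    """
    zvals = zones.values if isinstance(zones, CategoricalRaster) else np.asarray(zones)
    if zvals.shape != raster.shape:
        raise ValueError(f"zone grid shape {zvals.shape} != landscape {raster.shape}")
    valid = raster.mask
    if isinstance(zones, CategoricalRaster):
        valid = valid & zones.mask
    totals_vc = vc.class_totals().to_numpy()
    weights = raster.area_weights()[valid]
    cls = raster.values[valid]
    zone_ids = np.unique(zvals[valid])
    out = {}
    for z in zone_ids:
        sel = zvals[valid] == z
        area_by_class = np.bincount(cls[sel], weights=weights[sel], minlength=len(CLASSES))
        out[int(z)] = float(area_by_class @ totals_vc)
    s = pd.Series(out, name="esv_usd")
    s.index.name = "zone"
    return s


def esv_table(areas: AreaTable, vc: ValueCoefficientTable) -> dict[str, pd.DataFrame]:
    """Per-class, per-function and total ESV for every year of an area table.

    Returns a dict with DataFrames ``by_class`` (years x classes, US$),
    ``by_function`` (years x functions, US$) and Series ``total`` (US$).
    """
    by_class = pd.DataFrame(
        {y: esv_by_class(areas.row(y), vc) for y in areas.years}
    ).T
    by_function = pd.DataFrame(
        {y: esv_by_function(areas.row(y), vc) for y in areas.years}
    ).T
    total = by_class.sum(axis=1)
    total.name = "esv_usd"
    for df in (by_class, by_function):
        df.index.name = "year"
    return {"by_class": by_class, "by_function": by_function, "total": total}
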