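"""Categorical land-cover rasters: I/O, legend remapping and area accounting.

The in-memory model is deliberately small: a :class:`CategoricalRaster` is an
integer grid of class indices (``-1`` marks nodata) plus the metadata needed
for area accounting (hectares per cell) and georeferencing (origin, cell
size, CRS label, epoch year). Two on-disk forms are supported:

* single-band integer TIFF (via :mod:`tifffile`), with the geo-metadata
  carried as a JSON document in the TIFF ImageDescription tag;
* ESRI ASCII grid (``.asc``), a plain-text raster format convenient for
  fixtures and hand inspection.

Areas are always computed in full-precision hectares; only rendered tables
use the conventional 10^4 ha, 2-decimal presentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASSES, NODATA

__all__ = [
    "ClassLegend",
    "CategoricalRaster",
    "AreaTable",
    "LegendCoverageError",
    "load_raster",
    "write_raster",
    "tabulate_areas",
    "area_change_pct",
]


class LegendCoverageError(ValueError):
    """A raster contains raw codes the legend does not map."""


@dataclass(frozen=True)
class ClassLegend:
    """Mapping from raw raster codes to the canonical 7-class scheme.

    Parameters
    ----------
    mapping
        ``raw_code -> class name``; every class name must be one of
        :data:`ecoserv.classes.CLASSES`.
    nodata_codes
        Raw codes treated as nodata (in addition to the raster's own
        declared nodata value).
    """

    mapping: dict[int, str]
    nodata_codes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = sorted(set(self.mapping.values()) - set(CLASSES))
        if bad:
            raise ValueError(f"legend maps to unknown classes {bad}; expected {CLASSES}")
        overlap = set(self.mapping) & set(self.nodata_codes)
        if overlap:
            raise ValueError(f"codes {sorted(overlap)} are both mapped and declared nodata")

    @classmethod
    def identity(cls) -> "ClassLegend":
        """Codes 1..7 map to the canonical classes in order; 0 is nodata."""
        return cls({i + 1: name for i, name in enumerate(CLASSES)}, frozenset({0}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassLegend":
        """Read a two-column ``raw_code,class_name`` table; ``nodata`` rows
        become nodata codes. Lines starting with ``#`` are comments."""
        df = pd.read_csv(path, comment="#")
        if not {"raw_code", "class_name"} <= set(df.columns):
            raise ValueError("legend CSV needs columns raw_code, class_name")
        nodata = frozenset(int(c) for c, n in zip(df.raw_code, df.class_name) if str(n).lower() == "nodata")
        mapping = {int(c): str(n) for c, n in zip(df.raw_code, df.class_name) if str(n).lower() != "nodata"}
        return cls(mapping, nodata)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassLegend":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            {int(k): str(v) for k, v in doc.get("mapping", {}).items()},
            frozenset(int(c) for c in doc.get("nodata_codes", [])),
        )

    def remap(self, raw: np.ndarray, raster_nodata: int | None = None) -> np.ndarray:
        """Remap a raw integer grid to class indices (nodata -> -1).

        Raises :class:`LegendCoverageError` naming any unmapped code — codes
        are never silently dropped.
        """
        raw = np.asarray(raw)
        if not np.issubdtype(raw.dtype, np.integer):
            if np.issubdtype(raw.dtype, np.floating) and np.all(np.mod(raw[np.isfinite(raw)], 1) == 0):
                raw = raw.astype(np.int64)
            else:
                raise TypeError(f"raster band is not integer-valued (dtype {raw.dtype})")
        nodata = set(self.nodata_codes)
        if raster_nodata is not None:
            nodata.add(int(raster_nodata))
        present = set(np.unique(raw).tolist())
        unmapped = sorted(present - set(self.mapping) - nodata)
        if unmapped:
            raise LegendCoverageError(
                f"raw codes {unmapped} present in raster are not covered by the legend"
            )
        out = np.full(raw.shape, NODATA, dtype=np.int16)
        for code, name in self.mapping.items():
            out[raw == code] = CLASSES.index(name)
        return out


@dataclass
class CategoricalRaster:
    """A single-epoch categorical land-cover grid.

    ``values`` holds canonical class indices (0..6) with ``-1`` for nodata.
    ``cell_area_ha`` is either a scalar (equal-area approximation) or a grid
    of per-cell hectare weights matching ``values`` in shape.
    """

    values: np.ndarray
    cell_area_ha: float | np.ndarray = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    crs: str = "local"
    year: int | None = None
    classes: tuple[str, ...] = field(default=CLASSES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        n = len(self.classes)
        bad = self.values[(self.values != NODATA) & ((self.values < 0) | (self.values >= n))]
        if bad.size:
            raise ValueError(f"illegal class indices present: {sorted(set(bad.tolist()))}")
        if np.ndim(self.cell_area_ha) == 0:
            if float(self.cell_area_ha) <= 0:
                raise ValueError("cell_area_ha must be positive")
        else:
            self.cell_area_ha = np.asarray(self.cell_area_ha, dtype=float)
            if self.cell_area_ha.shape != self.values.shape:
                raise ValueError("per-cell area grid must match raster shape")
            if np.any(self.cell_area_ha <= 0):
                raise ValueError("cell_area_ha must be strictly positive")

    # -- basic views ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell carries a class."""
        return self.values != NODATA

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def area_weights(self) -> np.ndarray:
        """Per-cell hectare weights as a full grid (scalar broadcast)."""
        if np.ndim(self.cell_area_ha) == 0:
            return np.full(self.shape, float(self.cell_area_ha))
        return self.cell_area_ha

    def class_counts(self) -> pd.Series:
        counts = np.bincount(self.values[self.mask], minlength=len(self.classes))
        return pd.Series(counts, index=list(self.classes), name="cells")

    def class_areas_ha(self) -> pd.Series:
        """Per-class area in hectares (nodata excluded)."""
        w = self.area_weights()[self.mask]
        v = self.values[self.mask]
        areas = np.bincount(v, weights=w, minlength=len(self.classes))
        return pd.Series(areas, index=list(self.classes), name="area_ha")

    def with_values(self, values: np.ndarray, year: int | None = None) -> "CategoricalRaster":
        return replace(self, values=np.asarray(values, dtype=np.int16), year=year if year is not None else self.year)

    # -- mask harmonization ---------------------------------------------
    @staticmethod
    def harmonize(
        r1: "CategoricalRaster", r2: "CategoricalRaster"
    ) -> tuple["CategoricalRaster", "CategoricalRaster"]:
        """Apply the union of nodata masks to both rasters.

        Cross-tabulation and map comparison are only meaningful over the
        common support, so any cell that is nodata in either epoch becomes
        nodata in both.
        """
        if r1.shape != r2.shape:
            raise ValueError(f"raster shapes differ: {r1.shape} vs {r2.shape}")
        common = r1.mask & r2.mask
        if not common.any():
            raise ValueError("rasters share no valid cells after mask harmonization")
        v1 = np.where(common, r1.values, NODATA).astype(np.int16)
        v2 = np.where(common, r2.values, NODATA).astype(np.int16)
        return r1.with_values(v1), r2.with_values(v2)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("cell_area_ha", "origin", "cell_size", "crs", "year", "nodata")


def load_raster(
    path: str | Path,
    legend: ClassLegend | None = None,
    *,
    cell_area_ha: float | None = None,
    year: int | None = None,
) -> CategoricalRaster:
    """Read a single-band integer raster and remap it to the 7-class scheme.

    ``legend=None`` assumes the file already stores canonical class indices
    (as written by :func:`write_raster`). TIFF (``.tif``/``.tiff``) and ESRI
    ASCII grid (``.asc``) formats are recognised by suffix.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw, meta = _read_tiff(path)
    elif path.suffix.lower() == ".asc":
        raw, meta = _read_ascii_grid(path)
    else:
        raise ValueError(f"unrecognised raster format {path.suffix!r} (expected .tif or .asc)")

    nodata = meta.get("nodata")
    if legend is not None:
        values = legend.remap(raw, raster_nodata=nodata)
    else:
        values = np.asarray(raw, dtype=np.int16)
        if nodata is not None:
            values = np.where(values == int(nodata), NODATA, values).astype(np.int16)
        out_of_range = values[(values != NODATA) & ((values < 0) | (values >= len(CLASSES)))]
        if out_of_range.size:
            raise LegendCoverageError(
                f"raster stores codes {sorted(set(out_of_range.tolist()))} but no legend was given"
            )
    return CategoricalRaster(
        values,
        cell_area_ha=cell_area_ha if cell_area_ha is not None else meta.get("cell_area_ha", 1.0),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        cell_size=float(meta.get("cell_size", 1.0)),
        crs=str(meta.get("crs", "local")),
        year=year if year is not None else meta.get("year"),
    )


def write_raster(raster: CategoricalRaster, path: str | Path, *, nodata: int = -9999) -> Path:
    """Write class indices to TIFF or ASCII grid (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_tiff(raster, path)
    elif path.suffix.lower() == ".asc":
        _write_ascii_grid(raster, path, nodata=nodata)
    else:
        raise ValueError(f"unrecognised raster format {path.suffix!r} (expected .tif or .asc)")
    return path


def _read_tiff(path: Path) -> tuple[np.ndarray, dict]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        raw = page.asarray()
        meta: dict = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                doc = json.loads(desc.value)
                if isinstance(doc, dict):
                    meta = {k: doc[k] for k in _META_KEYS if k in doc}
            except (json.JSONDecodeError, TypeError):
                pass
    if raw.ndim == 3:
        if raw.shape[0] == 1:
            raw = raw[0]
        elif raw.shape[-1] == 1:
            raw = raw[..., 0]
        else:
            raise ValueError("expected a single-band raster")
    if not np.issubdtype(raw.dtype, np.integer):
        raise TypeError(f"TIFF band is not integer ({raw.dtype})")
    return raw, meta


def _write_tiff(raster: CategoricalRaster, path: Path) -> None:
    import tifffile

    meta = {
        "cell_area_ha": (
            float(raster.cell_area_ha) if np.ndim(raster.cell_area_ha) == 0 else "per-cell"
        ),
        "origin": list(raster.origin),
        "cell_size": raster.cell_size,
        "crs": raster.crs,
        "year": raster.year,
        "nodata": NODATA,
        "classes": list(raster.classes),
    }
    tifffile.imwrite(path, raster.values.astype(np.int16), description=json.dumps(meta))


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[1].replace(".", "").replace("-", "").isdigit():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(0)
        data = np.loadtxt(fh, skiprows=len(header))
    data = np.atleast_2d(data)
    if not np.all(np.mod(data[np.isfinite(data)], 1) == 0):
        raise TypeError("ASCII grid holds non-integer values")
    meta = {
        "origin": (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        "cell_size": header.get("cellsize", 1.0),
        "nodata": int(header["nodata_value"]) if "nodata_value" in header else None,
    }
    return data.astype(np.int64), meta


def _write_ascii_grid(raster: CategoricalRaster, path: Path, *, nodata: int) -> None:
    rows, cols = raster.shape
    out = np.where(raster.mask, raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, out, fmt="%d")


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------


class AreaTable:
    """Per-year, per-class areas in hectares.

    Thin wrapper around a ``year x class`` DataFrame that fixes units
    (internal hectares, rendered 10^4 ha) and the canonical class order.
    """

    def __init__(self, areas_ha: pd.DataFrame):
        df = areas_ha.copy()
        missing = [c for c in CLASSES if c not in df.columns]
        if missing:
            raise ValueError(f"area table misses classes {missing}")
        df = df.loc[:, list(CLASSES)].astype(float)
        if (df.values < 0).any():
            raise ValueError("areas must be nonnegative")
        df.index = df.index.astype(int)
        df.index.name = "year"
        self._df = df.sort_index()

    @classmethod
    def from_rows(cls, rows: dict[int, pd.Series]) -> "AreaTable":
        return cls(pd.DataFrame({y: s for y, s in rows.items()}).T)

    @classmethod
    def from_rasters(cls, rasters: dict[int, CategoricalRaster]) -> "AreaTable":
        return cls.from_rows({y: tabulate_areas(r) for y, r in rasters.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaTable":
        """Long-format CSV with columns ``year, class, area_1e4_ha``."""
        df = pd.read_csv(path, comment="#")
        need = {"year", "class", "area_1e4_ha"}
        if not need <= set(df.columns):
            raise ValueError(f"area CSV needs columns {sorted(need)}")
        wide = df.pivot(index="year", columns="class", values="area_1e4_ha") * 1e4
        return cls(wide)

    def to_csv(self, path: str | Path) -> Path:
        long = (
            (self._df / 1e4)
            .round(2)
            .reset_index()
            .melt(id_vars="year", var_name="class", value_name="area_1e4_ha")
            .sort_values(["year", "class"], key=_class_sort_key)
        )
        long.to_csv(path, index=False)
        return Path(path)

    # -- access ---------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return list(self._df.index)

    @property
    def areas_ha(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def areas_1e4_ha(self) -> pd.DataFrame:
        """Rendered view in 10^4 ha at 2 decimals."""
        return (self._df / 1e4).round(2)

    def row(self, year: int) -> pd.Series:
        if year not in self._df.index:
            raise KeyError(f"year {year} not in area table (have {self.years})")
        return self._df.loc[year].copy()

    def totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def add_row(self, year: int, areas_ha: pd.Series) -> "AreaTable":
        df = self._df.copy()
        df.loc[int(year)] = areas_ha.reindex(list(CLASSES)).values
        return AreaTable(df)

    def change_pct(self, y1: int, y2: int) -> pd.Series:
        return area_change_pct(self, y1, y2)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AreaTable(years={self.years})\n{self.areas_1e4_ha}"


def _class_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "class":
        order = {c: i for i, c in enumerate(CLASSES)}
        return col.map(order)
    return col


def tabulate_areas(raster: CategoricalRaster) -> pd.Series:
    """Per-class areas (ha) of one raster epoch: cell counts x cell area."""
    return raster.class_areas_ha()


def area_change_pct(areas: AreaTable, y1: int, y2: int) -> pd.Series:
    """Relative area change 100 x (A(y2) - A(y1)) / A(y1), per class.

    Classes with zero baseline area get NaN and a warning rather than a
    silent 0 or infinity; the set of affected classes is recorded in
    ``result.attrs['undefined']``.
    """
    a1, a2 = areas.row(y1), areas.row(y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a2 - a1) / a1
    undefined = [c for c in CLASSES if a1[c] == 0]
    if undefined:
        warnings.warn(
            f"change rate undefined for zero-baseline classes {undefined}", stacklevel=2
        )
        pct[undefined] = np.nan
    pct.name = f"change_pct_{y1}_{y2}"
    pct.attrs["undefined"] = undefined
    return pct
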