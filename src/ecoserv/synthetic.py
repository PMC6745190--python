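"""Synthetic landscapes with known composition and transition dynamics.

No public archive carries the co-registered multi-epoch rasters behind the
packaged Central Asia area table, so every spatial stage is exercised on
neutral-landscape surrogates instead: categorical grids with controlled
class proportions, controlled spatial clustering, and drift generated by a
known transition matrix — which makes transition-matrix recovery, CA
allocation and kappa validation all testable against ground truth.

Construction is quantile thresholding of a smoothed Gaussian random field:
cells are ranked by the field value and the sorted ranks are cut at the
cumulative class proportions, so realized composition matches the request
to the cell. Smoothing radius 0 gives spatially independent noise (salt-
and-pepper); larger radii give contiguous patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .ca import neighborhood_suitability
from .classes import CLASSES
from .markov import TransitionMatrix
from .raster import AreaTable, CategoricalRaster

__all__ = [
    "LandscapeSpec",
    "generate_initial",
    "evolve",
    "central_asia_area_table",
    "central_asia_coefficients",
    "central_asia_proportions",
    "default_legend",
    "reference_transition",
]

#: 1995 Central Asia class shares (grassland ~51.4%, bare ~23.9%, cropland
#: ~19.0%), the default composition for synthetic landscapes.
_DEFAULT_PROPORTIONS: tuple[float, ...] | None = None


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one synthetic categorical landscape.

    ``patchiness`` is the Gaussian smoothing radius in cells (0 = spatially
    independent noise); ``proportions`` default to the packaged 1995
    Central Asia shares.
    """

    rows: int = 200
    cols: int = 200
    proportions: tuple[float, ...] | None = None
    patchiness: float = 3.0
    cell_area_ha: float = 9.0  # a 300 m cell
    seed: int = 0
    year: int | None = None
    classes: tuple[str, ...] = field(default=CLASSES)

    def resolved_proportions(self) -> np.ndarray:
        p = self.proportions
        if p is None:
            p = central_asia_proportions(1995).to_numpy()
        p = np.asarray(p, dtype=float)
        if len(p) != len(self.classes):
            raise ValueError(f"need {len(self.classes)} proportions, got {len(p)}")
        if (p < 0).any():
            raise ValueError("proportions must be nonnegative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"proportions sum to {total}, expected 1")
        return p / total

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.patchiness < 0:
            raise ValueError("patchiness must be >= 0")
        if self.patchiness > 0 and (self.rows < 10 or self.cols < 10):
            raise ValueError("patchy landscapes need a grid of at least 10x10")
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")


def generate_initial(spec: LandscapeSpec) -> CategoricalRaster:
    """Neutral landscape with the requested composition.

    A standard-normal field is smoothed with a Gaussian kernel of radius
    ``patchiness``; ranking the field and cutting the ranks at cumulative
    proportion quantiles assigns classes, so realized shares deviate from
    the request by at most one cell regardless of patchiness. Deterministic
    for a fixed seed.
    """
    p = spec.resolved_proportions()
    rng = np.random.default_rng(spec.seed)
    fld = rng.standard_normal((spec.rows, spec.cols))
    if spec.patchiness > 0:
        fld = ndimage.gaussian_filter(fld, sigma=spec.patchiness, mode="wrap")
        # tiny jitter breaks plateau ties deterministically
        fld = fld + rng.normal(scale=1e-9, size=fld.shape)
    n = fld.size
    order = np.argsort(fld, axis=None, kind="stable")
    cuts = np.round(np.cumsum(p) * n).astype(np.int64)
    values = np.empty(n, dtype=np.int16)
    start = 0
    for k, stop in enumerate(cuts):
        values[order[start:stop]] = k
        start = stop
    values[order[start:]] = len(p) - 1
    return CategoricalRaster(
        values.reshape(spec.rows, spec.cols),
        cell_area_ha=spec.cell_area_ha,
        year=spec.year,
    )


def evolve(
    raster: CategoricalRaster,
    A: TransitionMatrix,
    seed: int = 0,
    clustered: bool = False,
    window: int = 5,
    year: int | None = None,
) -> CategoricalRaster:
    """Advance a landscape one interval under transition matrix ``A``.

    Unclustered mode draws each cell's next class independently from its
    row of A — the exact generative inverse of
    :func:`ecoserv.markov.estimate_transition`, which makes recovery tests
    possible. Clustered mode draws per-(source, destination) flip *counts*
    from the same multinomial law but assigns the flips to the cells whose
    neighborhood suitability most favors the destination, so change arrives
    spatially aggregated while composition stays multinomially faithful.
    """
    rng = np.random.default_rng(seed)
    values = raster.values.copy()
    mask = raster.mask
    nclasses = A.n
    if not clustered:
        u = rng.random(values.shape)
        cum = np.cumsum(A.probs, axis=1)
        new = values.copy()
        src = values[mask]
        draw = u[mask]
        # vectorised inverse-CDF draw per source class
        idx = (draw[:, None] > cum[src]).sum(axis=1)
        new[mask] = np.minimum(idx, nclasses - 1).astype(np.int16)
        return raster.with_values(np.where(mask, new, values), year=year)

    stack = neighborhood_suitability(raster, window=window).values
    shuffle_key = rng.permutation(values.size)
    orig = raster.values
    flat = values.ravel()
    for i in range(nclasses):
        cells = np.flatnonzero((orig == i) & mask)
        if cells.size == 0:
            continue
        counts = rng.multinomial(cells.size, A.probs[i])
        assigned = np.zeros(cells.size, dtype=bool)
        # place movers (j != i) first, most suitable cells first
        for j in np.argsort(-counts, kind="stable"):
            if j == i or counts[j] == 0:
                continue
            rr, cc = np.unravel_index(cells, values.shape)
            score = stack[j, rr, cc]
            order = np.lexsort((cells, shuffle_key[cells], -score))
            order = order[~assigned[order]]
            take = order[: counts[j]]
            flat[cells[take]] = j
            assigned[take] = True
    return raster.with_values(flat.reshape(values.shape), year=year)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def central_asia_area_table() -> AreaTable:
    """The packaged 1995-2035 Central Asia per-class area table (stored to
    the published precision: 10^4 ha, 2 decimals)."""
    with resources.files("ecoserv.data").joinpath("areas_central_asia_1995_2035.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    wide = df.pivot(index="year", columns="class", values="area_1e4_ha") * 1e4
    return AreaTable(wide)


def central_asia_coefficients():
    """The packaged Central Asia value-coefficient matrix."""
    from .valuation import ValueCoefficientTable

    return ValueCoefficientTable.default()


def central_asia_proportions(year: int = 1995) -> pd.Series:
    """Class shares for one year of the packaged area table."""
    row = central_asia_area_table().row(year)
    return row / row.sum()


def default_legend():
    """Packaged CCI-LC-style legend (documented best-effort stand-in)."""
    from .raster import ClassLegend

    with resources.as_file(resources.files("ecoserv.data").joinpath("cci_lc_legend.csv")) as p:
        return ClassLegend.from_csv(p)


def reference_transition(seed: int | None = None) -> TransitionMatrix:
    """A plausible decadal transition matrix for scenario generation.

    Strong diagonal persistence with cropland and urban expanding at the
    expense of grassland and bare land, and water shrinking — the drift
    pattern of the packaged area table. Not estimated from data; a fixture
    for synthetic scenarios.
    """
    P = np.array(
        [
            # cropland forest grass  wet   urban  bare   water
            [0.960, 0.002, 0.020, 0.001, 0.010, 0.006, 0.001],  # cropland
            [0.010, 0.970, 0.015, 0.002, 0.001, 0.001, 0.001],  # forestland
            [0.050, 0.003, 0.920, 0.002, 0.004, 0.020, 0.001],  # grassland
            [0.010, 0.002, 0.020, 0.940, 0.002, 0.006, 0.020],  # wetland
            [0.001, 0.000, 0.004, 0.000, 0.994, 0.001, 0.000],  # urban
            [0.030, 0.001, 0.030, 0.001, 0.003, 0.930, 0.005],  # bare
            [0.010, 0.001, 0.010, 0.030, 0.001, 0.060, 0.888],  # water
        ]
    )
    return TransitionMatrix(P)
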