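"""Cellular-automata allocation and kappa validation of categorical maps.

The Markov stage (:mod:`ecoserv.markov`) fixes *how much* area each class
must gain or lose over an interval; this module decides *where*. Each cell
carries a per-class suitability score derived from its neighborhood — the
fraction of same-class cells within a square contiguity window — and demand
is satisfied by flipping the cells whose suitability most favors the gaining
class over their current class. Agreement between simulated and observed
maps is scored with Cohen's kappa,

    kappa = (p0 - pc) / (1 - pc),

with p0 the observed proportion agreement and pc the chance agreement from
the two maps' marginal class frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import CLASSES, NODATA
from .markov import TransitionMatrix
from .raster import CategoricalRaster

__all__ = [
    "SuitabilityStack",
    "KappaResult",
    "AllocationReport",
    "neighborhood_suitability",
    "allocate",
    "cohens_kappa",
]


@dataclass
class SuitabilityStack:
    """Per-class suitability grids in [0, 1], aligned with a landscape."""

    values: np.ndarray  # (n_classes, rows, cols)
    provenance: str = "neighborhood-density"
    window: int = 5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != len(CLASSES):
            raise ValueError(f"expected ({len(CLASSES)}, rows, cols) stack, got {v.shape}")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability scores must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


def neighborhood_suitability(raster: CategoricalRaster, window: int = 5) -> SuitabilityStack:
    """Class density in a square window around each cell.

    ``suitability[k, r, c]`` is the fraction of *valid* cells of class k in
    the ``window x window`` neighborhood centered on (r, c); edge cells use
    the truncated window. At every valid cell the scores across classes sum
    to 1 (they partition the neighborhood). Nodata cells get NaN.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    mask = raster.mask.astype(float)
    # uniform_filter computes window means with zero padding; multiplying by
    # the window size recovers windowed sums with truncated edges.
    scale = float(window * window)
    valid_in_window = ndimage.uniform_filter(mask, size=window, mode="constant", cval=0.0) * scale
    stack = np.empty((len(CLASSES), *raster.shape), dtype=float)
    for k in range(len(CLASSES)):
        onehot = ((raster.values == k) & raster.mask).astype(float)
        hits = ndimage.uniform_filter(onehot, size=window, mode="constant", cval=0.0) * scale
        with np.errstate(invalid="ignore", divide="ignore"):
            stack[k] = hits / valid_in_window
    stack[:, ~raster.mask] = np.nan
    return SuitabilityStack(np.nan_to_num(stack, nan=0.0) * raster.mask + np.where(raster.mask, 0.0, np.nan), window=window)


@dataclass(frozen=True)
class AllocationReport:
    """Outcome of one CA allocation: iterations used and the residual demand."""

    iterations: int
    residual_cells: int
    residual_fraction: float
    converged: bool


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` cells by the largest-remainder rule."""
    raw = proportions * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def allocate(
    baseline: CategoricalRaster,
    targets: pd.Series,
    suitability: SuitabilityStack | None = None,
    *,
    transition: TransitionMatrix | None = None,
    window: int = 5,
    max_iter: int = 10,
    seed: int = 0,
    tol: float = 0.005,
) -> tuple[CategoricalRaster, AllocationReport]:
    """Reassign cells of ``baseline`` so class areas meet ``targets`` (ha).

    Demand-driven greedy reassignment: per-class cell quotas are derived
    from the target areas (largest-remainder apportionment, conserving the
    valid-cell count exactly); classes above quota donate cells to classes
    below quota, highest gain in neighborhood suitability first, ties broken
    by a seeded shuffle and then stable cell index. A transition matrix, if
    given, forbids flips i -> j with A_ij = 0. Suitability is taken from the
    argument on the first sweep and recomputed from the evolving map on
    later sweeps, so growth stays attached to existing patches.

    Returns the new raster and an :class:`AllocationReport`; a residual
    above ``tol`` (fraction of valid cells) after ``max_iter`` sweeps is
    reported with a warning, not an exception.
    """
    t = targets.reindex(list(CLASSES)).to_numpy(dtype=float)
    if np.any(t < 0) or not np.isfinite(t).all():
        raise ValueError("targets must be finite and nonnegative")
    masked_area = float(baseline.class_areas_ha().sum())
    if masked_area <= 0:
        raise ValueError("baseline has no valid cells")
    if abs(t.sum() - masked_area) > 1e-3 * masked_area:
        raise ValueError(
            f"target total {t.sum():.1f} ha differs from masked area {masked_area:.1f} ha by >0.1%"
        )
    n = len(CLASSES)
    n_valid = baseline.n_valid
    quota = _largest_remainder(t / t.sum(), n_valid)

    values = baseline.values.copy()
    mask = baseline.mask
    flat_valid = np.flatnonzero(mask.ravel())
    rng = np.random.default_rng(seed)
    shuffle_key = rng.permutation(values.size)

    counts = np.bincount(values[mask], minlength=n)
    allowed = None if transition is None else transition.probs > 0

    it = 0
    for it in range(1, max_iter + 1):
        deficit = quota - counts
        residual = int(np.abs(deficit).sum()) // 2
        if residual == 0:
            it -= 1
            break
        if it == 1 and suitability is not None:
            stack = suitability.values
        else:
            stack = neighborhood_suitability(
                baseline.with_values(values), window=window
            ).values
        moved = np.zeros(values.size, dtype=bool)
        progress = 0
        for j in np.argsort(-deficit, kind="stable"):
            need = quota[j] - counts[j]
            if need <= 0:
                continue
            surplus = counts - quota
            donor = surplus > 0
            if allowed is not None:
                donor = donor & allowed[:, j]
            donor[j] = False
            cur = values.ravel()[flat_valid]
            cand = flat_valid[donor[cur] & ~moved[flat_valid]]
            if cand.size == 0:
                continue
            rr, cc = np.unravel_index(cand, values.shape)
            gain = stack[j, rr, cc] - stack[values.ravel()[cand], rr, cc]
            order = np.lexsort((cand, shuffle_key[cand], -gain))
            budget = surplus.copy()
            for idx in order:
                if need == 0:
                    break
                cell = cand[idx]
                src = values.ravel()[cell]
                if budget[src] <= 0:
                    continue
                values.ravel()[cell] = j
                moved[cell] = True
                budget[src] -= 1
                counts[src] -= 1
                counts[j] += 1
                need -= 1
                progress += 1
        if progress == 0:
            break

    deficit = quota - counts
    residual = int(np.abs(deficit).sum()) // 2
    frac = residual / n_valid
    converged = frac <= tol
    if not converged:
        warnings.warn(
            f"allocation did not converge in {max_iter} sweeps: residual "
            f"{residual} cells ({frac:.2%} of valid area)",
            stacklevel=2,
        )
    out = baseline.with_values(values)
    return out, AllocationReport(it, residual, frac, converged)


# ---------------------------------------------------------------------------
# Kappa agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa between two categorical maps over their common support."""

    kappa: float
    p0: float
    pc: float
    confusion: pd.DataFrame = field(repr=False)
    undefined: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "kappa": None if self.undefined else self.kappa,
                "p0": self.p0,
                "pc": self.pc,
                "undefined": self.undefined,
                "confusion": {
                    "classes": list(self.confusion.index),
                    "counts": self.confusion.to_numpy().tolist(),
                },
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc


def cohens_kappa(observed: CategoricalRaster, simulated: CategoricalRaster) -> KappaResult:
    """Chance-corrected agreement between observed and simulated maps.

    The confusion matrix is tabulated over the harmonized (common) mask;
    p0 is the diagonal fraction, pc the product of marginals summed over
    classes. When pc = 1 (both maps constant with identical marginals)
    kappa is undefined and flagged rather than silently 0 or 1.
    """
    r1, r2 = CategoricalRaster.harmonize(observed, simulated)
    common = r1.mask
    nclasses = len(CLASSES)
    i = r1.values[common].astype(np.int64)
    j = r2.values[common].astype(np.int64)
    conf = np.bincount(i * nclasses + j, minlength=nclasses * nclasses).reshape(nclasses, nclasses)
    total = conf.sum()
    p0 = float(np.trace(conf)) / total
    pc = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    confusion = pd.DataFrame(conf, index=list(CLASSES), columns=list(CLASSES))
    if abs(1.0 - pc) < 1e-12:
        warnings.warn("kappa undefined: chance agreement is 1 (both maps constant)", stacklevel=2)
        return KappaResult(float("nan"), p0, pc, confusion, undefined=True)
    kappa = (p0 - pc) / (1.0 - pc)
    return KappaResult(float(kappa), p0, pc, confusion)
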