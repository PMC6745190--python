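"""Markov-chain estimation and projection of land-cover composition.

The first-order Markov model of land change treats the landscape composition
as a probability vector s(t) over classes and advances it with a row-
stochastic transition matrix A estimated by cross-tabulating two epochs:

    s(t+1) = s(t) A,        A_ij = n_ij / sum_j n_ij,

where n_ij counts cells (or sums cell areas, in area-weighted mode) that
were class i at t and class j at t+1. One Markov step corresponds to one
inter-epoch interval; multi-interval projection is a matrix power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASSES
from .raster import CategoricalRaster

__all__ = ["StateVector", "TransitionMatrix", "estimate_transition", "project_state", "target_areas"]

_ATOL = 1e-9


@dataclass(frozen=True)
class StateVector:
    """Per-class composition of the landscape (proportions summing to 1)."""

    proportions: np.ndarray
    epoch: int | str | None = None
    classes: tuple[str, ...] = field(default=CLASSES)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if p.ndim != 1 or len(p) != len(self.classes):
            raise ValueError(f"state vector must have {len(self.classes)} entries")
        if (p < -_ATOL).any():
            raise ValueError("state proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"state proportions sum to {p.sum():.12f}, expected 1")

    @classmethod
    def from_areas(cls, areas: pd.Series, epoch: int | None = None) -> "StateVector":
        v = areas.reindex(list(CLASSES)).to_numpy(dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError("cannot build a state vector from zero total area")
        return cls(v / total, epoch=epoch)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.classes), name=self.epoch)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic class-transition probabilities with their counts.

    ``probs[i, j]`` is the probability that a cell of class i at the start
    of the interval is class j at the end; ``counts`` holds the underlying
    cross-tabulation (cells, or hectares in area-weighted mode). Rows whose
    source class is absent are identity rows: an absent class cannot be a
    source, and the convention keeps the matrix stochastic without
    inventing transitions.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    interval: tuple[int, int] | None = None
    classes: tuple[str, ...] = field(default=CLASSES)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        n = len(self.classes)
        if p.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}, got {p.shape}")
        if (p < -_ATOL).any():
            raise ValueError("transition probabilities must be nonnegative")
        rowsums = p.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(f"rows must sum to 1 (got {rowsums})")
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=float)
            if c.shape != (n, n):
                raise ValueError("counts shape must match probs")
            object.__setattr__(self, "counts", c)

    @classmethod
    def identity(cls, interval: tuple[int, int] | None = None) -> "TransitionMatrix":
        n = len(CLASSES)
        return cls(np.eye(n), np.zeros((n, n)), interval)

    @property
    def n(self) -> int:
        return len(self.classes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.classes), columns=list(self.classes))

    def power(self, steps: int) -> np.ndarray:
        if steps < 1:
            raise ValueError("steps must be a positive integer")
        return np.linalg.matrix_power(self.probs, steps)

    def to_csv(self, path: str | Path) -> Path:
        self.as_frame().round(6).to_csv(path, index_label="from_class")
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path, interval: tuple[int, int] | None = None) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        df = df.loc[list(CLASSES), list(CLASSES)]
        return cls(df.to_numpy(dtype=float), interval=interval)


def estimate_transition(
    r1: CategoricalRaster,
    r2: CategoricalRaster,
    *,
    area_weighted: bool = False,
) -> TransitionMatrix:
    """Cross-tabulate two co-registered epochs into a transition matrix.

    Masks are harmonized (union of nodata) before counting, so the
    cross-tabulation runs over the common support only. With
    ``area_weighted=True`` each cell contributes its hectare weight instead
    of 1, which matters only for per-cell (latitude-corrected) area grids.
    """
    r1, r2 = CategoricalRaster.harmonize(r1, r2)
    common = r1.mask
    n = len(CLASSES)
    i = r1.values[common].astype(np.int64)
    j = r2.values[common].astype(np.int64)
    weights = r1.area_weights()[common] if area_weighted else None
    counts = np.bincount(i * n + j, weights=weights, minlength=n * n).reshape(n, n).astype(float)
    probs = counts.copy()
    rowsum = counts.sum(axis=1)
    nonzero = rowsum > 0
    probs[nonzero] /= rowsum[nonzero, None]
    probs[~nonzero] = np.eye(n)[~nonzero]
    interval = None
    if r1.year is not None and r2.year is not None:
        interval = (int(r1.year), int(r2.year))
    return TransitionMatrix(probs, counts, interval)


def project_state(s: StateVector, A: TransitionMatrix, steps: int = 1) -> StateVector:
    """Advance a composition vector by ``steps`` intervals: s A^steps.

    The result is renormalised only against accumulated floating-point
    round-off; it is a valid probability vector by construction.
    """
    if len(s.proportions) != A.n:
        raise ValueError("state and transition matrix dimensions disagree")
    out = s.proportions @ A.power(steps)
    out = np.clip(out, 0.0, None)
    out = out / out.sum()
    epoch = None
    if isinstance(s.epoch, int) and A.interval is not None:
        epoch = s.epoch + steps * (A.interval[1] - A.interval[0])
    return StateVector(out, epoch=epoch)


def target_areas(areas_t: pd.Series, A: TransitionMatrix, steps: int = 1) -> pd.Series:
    """Project per-class areas (ha) forward, conserving the total exactly."""
    total = float(areas_t.reindex(list(CLASSES)).sum())
    if total <= 0:
        raise ValueError("total area must be positive")
    s = StateVector.from_areas(areas_t)
    s_next = project_state(s, A, steps)
    out = pd.Series(s_next.proportions * total, index=list(CLASSES))
    out.name = areas_t.name
    return out
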