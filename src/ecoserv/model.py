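"""Model / Results front-ends for land-change projection and valuation.

Two fitted-model pairs organise the library in the familiar
construct-fit-inspect style:

* :class:`LandChangeModel` — built from two (or more) co-registered raster
  epochs; ``fit()`` estimates the Markov transition matrix and returns a
  :class:`LandChangeResults` that projects composition, allocates it in
  space with the CA rule, and validates hindcasts with Cohen's kappa.
* :class:`BenefitTransferModel` — built from an area table and a value-
  coefficient matrix; ``fit()`` returns :class:`ValuationResults` holding
  the per-class / per-function / total ESV tables, change rates and the
  coefficient-of-sensitivity analysis, with ``summary()`` and ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ca, markov, sensitivity, valuation
from .classes import CLASS_LABELS, CLASSES, FUNCTION_LABELS, FUNCTIONS
from .raster import AreaTable, CategoricalRaster
from .valuation import BILLION, ValueCoefficientTable

__all__ = ["LandChangeModel", "LandChangeResults", "BenefitTransferModel", "ValuationResults"]


class LandChangeModel:
    """First-order Markov + CA land-change model estimated from raster epochs.

    Parameters
    ----------
    epochs
        Mapping ``year -> CategoricalRaster`` with at least two entries;
        the transition matrix is estimated from the last two epochs unless
        an explicit ``interval`` pair is requested at fit time.
    area_weighted
        Cross-tabulate hectares instead of cells (matters only with
        per-cell area grids).
    """

    def __init__(self, epochs: dict[int, CategoricalRaster], *, area_weighted: bool = False):
        if len(epochs) < 2:
            raise ValueError("need at least two raster epochs")
        self.epochs = {int(y): r for y, r in sorted(epochs.items())}
        self.area_weighted = area_weighted

    @classmethod
    def from_files(cls, paths: dict[int, str], legend=None, *, cell_area_ha: float | None = None, **kw):
        from .raster import load_raster

        return cls(
            {y: load_raster(p, legend, cell_area_ha=cell_area_ha, year=y) for y, p in paths.items()},
            **kw,
        )

    def fit(self, interval: tuple[int, int] | None = None) -> "LandChangeResults":
        years = list(self.epochs)
        if interval is None:
            interval = (years[-2], years[-1])
        y1, y2 = interval
        if y1 not in self.epochs or y2 not in self.epochs:
            raise KeyError(f"interval {interval} not among epochs {years}")
        A = markov.estimate_transition(
            self.epochs[y1], self.epochs[y2], area_weighted=self.area_weighted
        )
        return LandChangeResults(self, A, baseline_year=y2)


@dataclass
class LandChangeResults:
    """Fitted transition matrix plus projection/allocation/validation."""

    model: LandChangeModel
    transition: markov.TransitionMatrix
    baseline_year: int

    @property
    def baseline(self) -> CategoricalRaster:
        return self.model.epochs[self.baseline_year]

    @property
    def interval_years(self) -> int:
        i = self.transition.interval
        return (i[1] - i[0]) if i else 1

    def project(self, steps: int = 1) -> pd.Series:
        """Markov-projected class areas (ha) after ``steps`` intervals."""
        return markov.target_areas(self.baseline.class_areas_ha(), self.transition, steps)

    def simulate(
        self,
        steps: int = 1,
        *,
        window: int = 5,
        max_iter: int = 10,
        seed: int = 0,
    ) -> tuple[CategoricalRaster, ca.AllocationReport]:
        """CA allocation of the ``steps``-interval Markov demand onto the grid."""
        targets = self.project(steps)
        suit = ca.neighborhood_suitability(self.baseline, window=window)
        out, report = ca.allocate(
            self.baseline,
            targets,
            suit,
            transition=self.transition,
            window=window,
            max_iter=max_iter,
            seed=seed,
        )
        out.year = self.baseline_year + steps * self.interval_years
        return out, report

    def validate(self, observed: CategoricalRaster, simulated: CategoricalRaster) -> ca.KappaResult:
        """Cohen's kappa of a hindcast against the held-out observed epoch."""
        return ca.cohens_kappa(observed, simulated)

    def summary(self) -> str:
        A = self.transition.as_frame().round(4)
        lines = [
            "Land-change model (Markov + CA)",
            "=" * 47,
            f"epochs fitted:        {self.transition.interval or 'n/a'}",
            f"baseline year:        {self.baseline_year}",
            f"valid cells:          {self.baseline.n_valid}",
            "",
            "Transition probability matrix (rows = from):",
            A.to_string(),
        ]
        return "\n".join(lines)


class BenefitTransferModel:
    """Benefit-transfer valuation of an area table under a coefficient matrix."""

    def __init__(self, areas: AreaTable, coefficients: ValueCoefficientTable | None = None):
        self.areas = areas
        self.vc = coefficients if coefficients is not None else ValueCoefficientTable.default()

    @classmethod
    def from_dataframe(cls, areas_ha: pd.DataFrame, coefficients=None) -> "BenefitTransferModel":
        return cls(AreaTable(areas_ha), coefficients)

    def fit(self, sensitivity_delta: float = 0.5) -> "ValuationResults":
        tables = valuation.esv_table(self.areas, self.vc)
        sens = sensitivity.sensitivity_table(self.areas, self.vc, sensitivity_delta, decimals=None)
        return ValuationResults(
            self, tables["by_class"], tables["by_function"], tables["total"], sens, sensitivity_delta
        )


@dataclass
class ValuationResults:
    """ESV estimates, change rates and sensitivity for every year."""

    model: BenefitTransferModel
    esv_by_class: pd.DataFrame  # years x classes, US$
    esv_by_function: pd.DataFrame  # years x functions, US$
    total: pd.Series  # per year, US$
    sensitivity_full: pd.DataFrame  # classes x (year, measure)
    sensitivity_delta: float

    # -- rendered views (billions, 2 decimals) --------------------------
    @property
    def esv_by_class_billion(self) -> pd.DataFrame:
        return (self.esv_by_class / BILLION).round(2)

    @property
    def esv_by_function_billion(self) -> pd.DataFrame:
        return (self.esv_by_function / BILLION).round(2)

    @property
    def total_billion(self) -> pd.Series:
        return (self.total / BILLION).round(2)

    def sensitivity(self, decimals: int | None = 2) -> pd.DataFrame:
        return self.sensitivity_full if decimals is None else self.sensitivity_full.round(decimals)

    def change_rates(self, pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
        """Per-class and total ESV change rates (%) for year pairs."""
        years = list(self.total.index)
        if pairs is None:
            pairs = [(years[i], years[i + 1]) for i in range(len(years) - 1)]
            if len(years) > 2:
                pairs.append((years[0], years[-1]))
        out = {}
        for y1, y2 in pairs:
            with np.errstate(divide="ignore", invalid="ignore"):
                per_class = 100.0 * (self.esv_by_class.loc[y2] - self.esv_by_class.loc[y1]) / self.esv_by_class.loc[y1]
            per_class = per_class.where(self.esv_by_class.loc[y1] != 0, np.nan)
            per_class["total"] = valuation.esv_change_rate(self.total[y1], self.total[y2])
            out[f"{y1}-{y2}"] = per_class
        df = pd.DataFrame(out)
        df.index.name = "class"
        return df

    def summary(self) -> str:
        byc = self.esv_by_class_billion.rename(columns=CLASS_LABELS)
        byf = self.esv_by_function_billion.rename(columns=FUNCTION_LABELS)
        sens = self.sensitivity().rename(index=CLASS_LABELS)
        lines = [
            "Benefit-transfer ecosystem service valuation",
            "=" * 60,
            f"years: {list(self.total.index)}   classes: {len(CLASSES)}   functions: {len(FUNCTIONS)}",
            "",
            "Total ESV (billion US$ / yr):",
            self.total_billion.round(2).to_string(),
            "",
            "ESV by land-cover class (billion US$ / yr):",
            byc.to_string(),
            "",
            "ESV by service function (billion US$ / yr):",
            byf.to_string(),
            "",
            f"Sensitivity to +/-{self.sensitivity_delta:.0%} coefficient adjustment"
            " (% change of total, CS):",
            sens.to_string(),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Stacked per-class ESV trajectory (billion US$ per year)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        data = self.esv_by_class / BILLION
        ax.stackplot(
            data.index,
            [data[c] for c in CLASSES],
            labels=[CLASS_LABELS[c] for c in CLASSES],
        )
        ax.set_xlabel("year")
        ax.set_ylabel("ESV (billion US$ / yr)")
        ax.legend(loc="upper left", fontsize=7, ncols=2)
        return ax
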