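"""CA suitability, demand allocation and kappa map agreement."""

import numpy as np
import pytest

from ecoserv import (
    TransitionMatrix,
    allocate,
    cohens_kappa,
    estimate_transition,
    neighborhood_suitability,
    reference_transition,
    target_areas,
)
from ecoserv import LandscapeSpec, generate_initial
from ecoserv.classes import CLASSES, NODATA

from conftest import make_raster

CROP = CLASSES.index("cropland")
GRASS = CLASSES.index("grassland")
URBAN = CLASSES.index("urban")


class TestNeighborhoodSuitability:
    def test_uniform_raster_scores_one_for_its_class(self):
        r = make_raster(np.full((6, 6), GRASS))
        stack = neighborhood_suitability(r, window=3).values
        assert np.allclose(stack[GRASS], 1.0)
        assert np.allclose(np.delete(stack, GRASS, axis=0), 0.0)

    def test_isolated_cell_fraction_of_window(self):
        vals = np.full((7, 7), GRASS)
        vals[3, 3] = CROP
        stack = neighborhood_suitability(make_raster(vals), window=3).values
        assert stack[CROP, 3, 3] == pytest.approx(1 / 9)
        assert stack[GRASS, 3, 3] == pytest.approx(8 / 9)
        # edge cells use the truncated window: corner sees a 2x2 neighborhood
        assert stack[GRASS, 0, 0] == pytest.approx(1.0)

    def test_scores_partition_the_window(self):
        r = generate_initial(LandscapeSpec(rows=30, cols=30, patchiness=1.5, seed=4))
        stack = neighborhood_suitability(r, window=5).values
        assert np.allclose(stack.sum(axis=0), 1.0, atol=1e-9)

    def test_nodata_cells_are_nan_and_excluded(self):
        vals = np.full((5, 5), GRASS)
        vals[2, 2] = NODATA
        stack = neighborhood_suitability(make_raster(vals), window=3).values
        assert np.isnan(stack[GRASS, 2, 2])
        # neighbors of the hole normalise over the 8 valid cells in window
        assert stack[GRASS, 1, 2] == pytest.approx(1.0)

    def test_even_window_rejected(self, checkerboard):
        with pytest.raises(ValueError, match="odd"):
            neighborhood_suitability(checkerboard, window=4)


class TestAllocation:
    def test_no_net_demand_returns_baseline(self, checkerboard):
        targets = checkerboard.class_areas_ha()
        out, report = allocate(checkerboard, targets, seed=0)
        assert np.array_equal(out.values, checkerboard.values)
        assert report.residual_cells == 0

    def test_single_class_target_converts_everything(self, checkerboard):
        targets = checkerboard.class_areas_ha() * 0.0
        targets["urban"] = checkerboard.class_areas_ha().sum()
        out, report = allocate(checkerboard, targets, seed=0)
        assert (out.values[out.mask] == URBAN).all()
        assert report.converged

    def test_markov_demand_met_within_half_percent(self):
        r = generate_initial(LandscapeSpec(rows=200, cols=200, patchiness=2.0, seed=7, cell_area_ha=9.0))
        A = reference_transition()
        targets = target_areas(r.class_areas_ha(), A)
        out, report = allocate(r, targets, transition=A, seed=3)
        err = (out.class_areas_ha() - targets).abs()
        assert (err <= 0.005 * targets.sum()).all()
        assert report.residual_fraction <= 0.005

    def test_valid_cell_count_conserved(self):
        vals = np.full((20, 20), GRASS)
        vals[0, :5] = NODATA
        r = make_raster(vals)
        targets = r.class_areas_ha()
        targets["grassland"] -= 50
        targets["cropland"] += 50
        out, _ = allocate(r, targets, seed=0)
        assert out.n_valid == r.n_valid
        assert (out.mask == r.mask).all()

    def test_forbidden_transitions_never_occur(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([CROP, GRASS, CLASSES.index("water")], size=(40, 40))
        r = make_raster(vals)
        # only grassland may become cropland; everything else persists
        P = np.eye(len(CLASSES))
        P[GRASS, GRASS], P[GRASS, CROP] = 0.8, 0.2
        A = TransitionMatrix(P)
        targets = r.class_areas_ha()
        targets["cropland"] += 100
        targets["grassland"] -= 100
        out, _ = allocate(r, targets, transition=A, seed=1)
        flips = (out.values != r.values) & r.mask
        assert set(r.values[flips].tolist()) <= {GRASS}
        assert set(out.values[flips].tolist()) <= {CROP}

    def test_blocked_demand_reports_residual(self):
        vals = np.full((10, 10), GRASS)
        r = make_raster(vals)
        A = TransitionMatrix.identity()  # nothing may change class
        targets = r.class_areas_ha()
        targets["grassland"] -= 30
        targets["urban"] += 30
        with pytest.warns(UserWarning, match="did not converge"):
            out, report = allocate(r, targets, transition=A, seed=0, max_iter=3)
        assert not report.converged
        assert report.residual_cells == 30
        assert np.array_equal(out.values, r.values)

    def test_deterministic_for_fixed_seed(self):
        r = generate_initial(LandscapeSpec(rows=60, cols=60, patchiness=1.0, seed=9))
        A = reference_transition()
        targets = target_areas(r.class_areas_ha(), A)
        out1, _ = allocate(r, targets, transition=A, seed=42)
        out2, _ = allocate(r, targets, transition=A, seed=42)
        assert np.array_equal(out1.values, out2.values)

    def test_infeasible_target_total_rejected(self, checkerboard):
        targets = checkerboard.class_areas_ha() * 2
        with pytest.raises(ValueError, match="differs from masked area"):
            allocate(checkerboard, targets, seed=0)


class TestCohensKappa:
    def test_identical_maps_score_one(self, checkerboard):
        res = cohens_kappa(checkerboard, checkerboard)
        assert res.kappa == pytest.approx(1.0)
        assert res.p0 == 1.0

    def test_hand_confusion_matrix(self):
        """40/10 // 10/40 confusion: p0=0.8, pc=0.5, kappa=0.6."""
        obs = np.concatenate([np.full(50, CROP), np.full(50, GRASS)])
        sim = obs.copy()
        sim[40:50] = GRASS
        sim[50:60] = CROP
        res = cohens_kappa(make_raster(obs.reshape(10, 10)), make_raster(sim.reshape(10, 10)))
        assert res.p0 == pytest.approx(0.8)
        assert res.pc == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)
        assert res.confusion.loc["cropland", "grassland"] == 10

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = make_raster(rng.integers(0, 7, size=(30, 30)))
        b = make_raster(rng.integers(0, 7, size=(30, 30)))
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_independent_maps_score_near_zero(self):
        rng = np.random.default_rng(17)
        a = make_raster(rng.integers(0, 7, size=(300, 300)))
        b = make_raster(rng.integers(0, 7, size=(300, 300)))
        assert abs(cohens_kappa(a, b).kappa) < 0.02

    def test_matches_sklearn_oracle(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        base = rng.integers(0, 7, size=(50, 50))
        noisy = np.where(rng.random((50, 50)) < 0.3, rng.integers(0, 7, size=(50, 50)), base)
        ours = cohens_kappa(make_raster(base), make_raster(noisy)).kappa
        theirs = sklearn_metrics.cohen_kappa_score(base.ravel(), noisy.ravel())
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_constant_identical_maps_flagged_undefined(self):
        r = make_raster(np.full((5, 5), GRASS))
        with pytest.warns(UserWarning, match="undefined"):
            res = cohens_kappa(r, r)
        assert res.undefined
        assert np.isnan(res.kappa)

    def test_kappa_formula_identity(self):
        rng = np.random.default_rng(31)
        a = make_raster(rng.integers(0, 4, size=(40, 40)))
        b = make_raster(rng.integers(0, 4, size=(40, 40)))
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx((res.p0 - res.pc) / (1 - res.pc))
        assert -1.0 <= res.kappa <= 1.0

    def test_json_serialization(self, tmp_path, checkerboard):
        import json

        res = cohens_kappa(checkerboard, checkerboard)
        doc = json.loads(res.to_json(tmp_path / "kappa.json"))
        assert doc["kappa"] == pytest.approx(1.0)
        assert len(doc["confusion"]["counts"]) == len(CLASSES)
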