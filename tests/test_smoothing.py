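import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mycogeo as mg
from mycogeo.errors import BandwidthSelectionError, InvalidInputError
from mycogeo.smoothing import _kernel_rows

from conftest import random_instance
from oracles import bf_gcv, bf_kernel_weights, bf_smooth

C = mg.GeoCoordinate


class TestKernelWeights:
    def test_single_source_gets_all_mass(self):
        w = mg.kernel_weights(C(40, -100), [C(10, 10)], rho=50.0)
        assert w.weights == pytest.approx([1.0])

    def test_equidistant_sources_split_evenly(self):
        target = C(0.0, 0.0)
        w = mg.kernel_weights(target, [C(0.0, 1.0), C(0.0, -1.0)], rho=200.0)
        assert w.weights == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_half_kernel_distance_gives_two_thirds_one_third(self):
        # second source at d = rho*sqrt(2 ln 2), where the kernel halves:
        # weights proportional to (1, 1/2) -> (2/3, 1/3)
        rho = 100.0
        d = rho * math.sqrt(2 * math.log(2))
        dlat = math.degrees(d / mg.EARTH_RADIUS_KM)
        w = mg.kernel_weights(C(0.0, 0.0), [C(0.0, 0.0), C(dlat, 0.0)], rho=rho)
        assert w.weights == pytest.approx([2 / 3, 1 / 3], abs=1e-9)

    def test_underflow_falls_back_to_nearest_point_mass(self):
        w = mg.kernel_weights(C(0.0, 0.0), [C(20.0, 0.0), C(10.0, 0.0)], rho=0.01)
        assert w.underflow
        assert w.weights == pytest.approx([0.0, 1.0])

    def test_invalid_args(self):
        with pytest.raises(InvalidInputError):
            mg.kernel_weights(C(0, 0), [], 10.0)
        with pytest.raises(InvalidInputError):
            mg.kernel_weights(C(0, 0), [C(1, 1)], 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_weights_always_sum_to_one(self, seed):
        inst = random_instance(np.random.default_rng(seed))
        w = mg.kernel_weights(
            C(inst["glats"][0], inst["glons"][0]), inst["sources"], inst["rho"]
        )
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (w.weights >= 0).all()


class TestSmoothOccurrence:
    def test_constant_presence_gives_constant_surface(self, us_grid):
        sources = [C(30, -100), C(40, -90), C(45, -120)]
        ones = mg.smooth_occurrence(np.ones(3), sources, 300.0, us_grid)
        zeros = mg.smooth_occurrence(np.zeros(3), sources, 300.0, us_grid)
        assert ones.probs == pytest.approx(np.ones(us_grid.n_cells), abs=1e-12)
        assert zeros.probs == pytest.approx(np.zeros(us_grid.n_cells), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        inst = random_instance(rng, n_max=10, n_cells_max=5)
        grid = mg.SpatialGrid(inst["glats"], inst["glons"], 1.0, 1.0)
        got = mg.smooth_occurrence(inst["Y"][:, 0], inst["sources"], 100.0, grid)
        want = bf_smooth(
            inst["Y"][:, 0].tolist(),
            list(zip(inst["lats"], inst["lons"])),
            100.0,
            inst["grid_points"],
        )
        assert got.probs == pytest.approx(want, abs=1e-12)

    def test_monotone_in_presence(self, us_grid):
        rng = np.random.default_rng(4)
        inst = random_instance(rng, n_max=15)
        y = inst["Y"][:, 0].astype(float)
        base = mg.smooth_occurrence(y, inst["sources"], 250.0, us_grid).probs
        flip = np.flatnonzero(y == 0)
        if flip.size:
            y2 = y.copy()
            y2[flip[0]] = 1.0
            more = mg.smooth_occurrence(y2, inst["sources"], 250.0, us_grid).probs
            assert (more >= base - 1e-12).all()

    def test_large_rho_limit_is_prevalence_fraction(self, us_grid):
        rng = np.random.default_rng(5)
        inst = random_instance(rng)
        y = inst["Y"][:, 0].astype(float)
        surf = mg.smooth_occurrence(y, inst["sources"], 1e7, us_grid)
        assert surf.probs == pytest.approx(np.full(us_grid.n_cells, y.mean()), abs=1e-6)


class TestGCV:
    def test_two_point_large_rho_closed_form(self):
        # all weights 1/2: yhat = (.5, .5), rss = .25, tr/n = .5, score = 1
        d = mg.gcv_score(np.array([1, 0]), [C(40, -100), C(40, -99)], rho=1e6)
        assert d.trace_ratio == pytest.approx(0.5, abs=1e-9)
        assert d.rss == pytest.approx(0.25, abs=1e-9)
        assert d.score == pytest.approx(1.0, abs=1e-8)

    def test_perfect_fit_scores_zero(self):
        # constant y: yhat == y for any weights, so score == 0
        d = mg.gcv_score(np.ones(5), [C(30 + i, -100) for i in range(5)], rho=500.0)
        assert d.score == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            inst = random_instance(rng)
            got = mg.gcv_score(inst["Y"][:, 0], inst["sources"], inst["rho"])
            score, tr, rss = bf_gcv(
                inst["Y"][:, 0].tolist(),
                list(zip(inst["lats"], inst["lons"])),
                inst["rho"],
            )
            assert got.score == pytest.approx(score, abs=1e-12, rel=1e-9)
            assert got.trace_ratio == pytest.approx(tr, abs=1e-12)
            assert got.rss == pytest.approx(rss, abs=1e-12)

    def test_diagnostics_invariant(self):
        rng = np.random.default_rng(7)
        inst = random_instance(rng)
        d = mg.gcv_score(inst["Y"][:, 0], inst["sources"], 300.0)
        assert d.score == pytest.approx(d.rss / (1 - d.trace_ratio) ** 2)


class TestSelectBandwidth:
    def test_constant_presence_picks_largest_candidate(self):
        cfg = mg.FitConfig(bandwidth_candidates=[100.0, 300.0, 900.0])
        sources = [C(30 + 3 * i, -100 + 2 * i) for i in range(6)]
        rho, diags = mg.select_bandwidth(np.ones(6), sources, cfg)
        assert rho == 900.0
        assert all(d.rss == pytest.approx(0.0, abs=1e-20) for d in diags)

    def test_singleton_candidate_returned(self):
        cfg = mg.FitConfig(bandwidth_candidates=[400.0])
        sources = [C(30 + 3 * i, -100 + 2 * i) for i in range(6)]
        rho, _ = mg.select_bandwidth(np.array([1, 0, 1, 0, 1, 0]), sources, cfg)
        assert rho == 400.0

    def test_all_degenerate_raises(self):
        cfg = mg.FitConfig(bandwidth_candidates=[1.0], max_trace_ratio=0.5)
        sources = [C(30, -100), C(45, -80)]  # isolated: W ~ identity
        with pytest.raises(BandwidthSelectionError):
            mg.select_bandwidth(np.array([1, 0]), sources, cfg, taxon_id="t")

    def test_tracks_fine_grid_minimizer_on_single_bump(self, us_grid):
        # one endemic taxon (sigma = 300 km), n = 200: the selected rho should
        # sit at the coarse-grid GCV minimum, bracketing the fine-grid minimizer
        world = mg.TrueWorld(
            domain=mg.DEFAULT_DOMAIN,
            species=[
                mg.SpeciesField(
                    "bump", "endemic", (C(38.0, -95.0),), 300.0, 0.9, 0.02
                )
            ],
            seed=0,
        )
        samples = mg.simulate_samples(world, 200, seed=1)
        cfg = mg.FitConfig()
        rho, _ = mg.select_bandwidth(samples.Y[:, 0], samples.locations, cfg)
        fine = np.geomspace(10, 3000, 200)
        scores = [
            mg.gcv_score(samples.Y[:, 0], samples.locations, r, cfg.max_trace_ratio)
            for r in fine
        ]
        ok = [s for s in scores if not s.degenerate]
        fine_best = min(ok, key=lambda s: s.score).rho
        # within one coarse-grid step of the dense-grid minimizer
        step = np.log(3000 / 10) / 24
        assert abs(np.log(rho) - np.log(fine_best)) <= step + 1e-9


class TestFitAtlas:
    def test_all_present_taxon_gets_constant_one_surface(self, us_grid):
        table = mg.SampleTable(
            sample_ids=["a", "b"],
            lats=[30.0, 40.0],
            lons=[-100.0, -90.0],
            taxon_ids=["t"],
            Y=np.ones((2, 1), dtype=int),
        )
        atlas = mg.fit_atlas(table, us_grid)
        assert atlas.surfaces[0].probs == pytest.approx(np.ones(us_grid.n_cells))
        assert math.isnan(atlas.surfaces[0].rho)  # prevalence filter sentinel

    def test_matches_per_taxon_pipeline(self, us_grid):
        rng = np.random.default_rng(8)
        lats = rng.uniform(30, 45, 10)
        lons = rng.uniform(-115, -80, 10)
        Y = rng.integers(0, 2, (10, 2)).astype(np.int8)
        Y[:, 0] = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        Y[0, 1], Y[1, 1] = 1, 0  # keep both taxa past the prevalence filter
        table = mg.SampleTable(
            sample_ids=[f"s{i}" for i in range(10)],
            lats=lats, lons=lons, taxon_ids=["t0", "t1"], Y=Y,
        )
        cfg = mg.FitConfig(max_trace_ratio=0.9)
        atlas = mg.fit_atlas(table, us_grid, cfg)
        for j in range(2):
            rho_j, _ = mg.select_bandwidth(Y[:, j], table.locations, cfg)
            assert atlas.surfaces[j].rho == rho_j
            want = mg.smooth_occurrence(Y[:, j], table.locations, rho_j, us_grid)
            assert atlas.surfaces[j].probs == pytest.approx(want.probs, abs=1e-12)

    def test_surfaces_within_unit_interval(self, small_atlas):
        P = small_atlas.prob_matrix()
        assert (P >= 0).all() and (P <= 1).all()

    def test_roundtrip_persistence_bit_exact(self, small_atlas, tmp_path):
        small_atlas.save(tmp_path / "atlas")
        back = mg.OccurrenceAtlas.load(tmp_path / "atlas")
        assert back.taxon_ids == small_atlas.taxon_ids
        assert np.array_equal(back.prob_matrix(), small_atlas.prob_matrix())
        got = [s.rho for s in back.surfaces]
        want = [s.rho for s in small_atlas.surfaces]
        assert got == pytest.approx(want, nan_ok=True)
        assert back.fit_config.clip_epsilon == small_atlas.fit_config.clip_epsilon

    def test_kernel_rows_match_bruteforce(self):
        rng = np.random.default_rng(9)
        inst = random_instance(rng, n_max=8, n_cells_max=4)
        D = mg.geometry.pairwise_distances(
            inst["glats"], inst["glons"], inst["lats"], inst["lons"]
        )
        W, _ = _kernel_rows(D, inst["rho"])
        for k, t in enumerate(inst["grid_points"]):
            want = bf_kernel_weights(t, list(zip(inst["lats"], inst["lons"])), inst["rho"])
            assert W[k] == pytest.approx(want, abs=1e-12)
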