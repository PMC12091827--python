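"""Synthetic-data generator: determinism, gradients, Yule trees, niche
evolution with planted events, and occurrence sampling."""

import numpy as np
import pytest

from barniche.errors import InvalidSpecError, NoHabitatError
from barniche.synthetic_data import (
    TrueNiche,
    evolve_true_niches,
    sample_occurrences,
    simulate_env_grid,
    simulate_yule_tree,
    verify_truth_consistency,
)


class TestEnvGrid:
    def test_noise_free_gradient_row_means(self):
        g = simulate_env_grid(11, 6, ("ns", 0.0, 10.0), 0.0, seed=1)
        np.testing.assert_array_equal(g.values.mean(axis=1), np.arange(11.0))

    def test_we_gradient_runs_along_columns(self):
        g = simulate_env_grid(4, 5, ("we", 2.0, 6.0), 0.0, seed=1)
        np.testing.assert_allclose(g.values.mean(axis=0), np.linspace(2, 6, 5))

    def test_same_seed_bitwise_identical(self):
        a = simulate_env_grid(30, 30, ("ns", 0.0, 5.0), 0.7, seed=42)
        b = simulate_env_grid(30, 30, ("ns", 0.0, 5.0), 0.7, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        a = simulate_env_grid(30, 30, ("ns", 0.0, 5.0), 0.7, seed=1)
        b = simulate_env_grid(30, 30, ("ns", 0.0, 5.0), 0.7, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_detrended_sd_matches_request(self):
        # brute-force: remove the row-wise gradient, measure what is left
        g = simulate_env_grid(100, 100, ("ns", 0.0, 10.0), 0.5, seed=1)
        detrended = g.values - g.values.mean(axis=1, keepdims=True)
        assert abs(detrended.std() - 0.5) < 0.1  # within 20%

    def test_nodata_mask_respected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        g = simulate_env_grid(5, 5, ("ns", 0, 1), 0.0, seed=0, nodata_mask=mask)
        assert np.isnan(g.values[0, 0]) and g.nodata_mask[0, 0]
        assert np.isfinite(g.values[~g.nodata_mask]).all()

    @pytest.mark.parametrize(
        "spec", [("ns", np.inf, 1.0), ("ns", 0.0, np.nan), ("up", 0.0, 1.0)]
    )
    def test_invalid_gradient_spec_rejected(self, spec):
        with pytest.raises(InvalidSpecError):
            simulate_env_grid(5, 5, spec, 0.0, seed=0)


class TestYuleTree:
    def test_two_tips_forced_topology(self):
        t = simulate_yule_tree(2, 5.0, seed=3)
        assert t.n_tips == 2
        assert t.depth == pytest.approx(5.0)
        assert all(t.nodes[i].age == pytest.approx(0.0) for i in t.tips())

    @pytest.mark.parametrize("seed", range(10))
    def test_ultrametric_by_construction(self, seed):
        t = simulate_yule_tree(15, 6.12, seed=seed)
        assert t.root_to_tip_variance() < 1e-9

    def test_binary_rooted_internal_node_count(self):
        # a rooted binary tree on n tips has exactly n-1 internal nodes
        for seed in range(200):
            t = simulate_yule_tree(40, 6.12, seed=seed)
            assert len(t.internal_ids()) == 39

    def test_tip_labels_unique(self):
        t = simulate_yule_tree(25, 1.0, seed=0)
        labels = t.tip_labels()
        assert len(set(labels)) == 25

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidSpecError):
            simulate_yule_tree(1, 5.0, seed=0)


class TestNicheEvolution:
    def test_no_events_means_root_niche_everywhere(self):
        t = simulate_yule_tree(10, 6.0, seed=1)
        evo = evolve_true_niches(t, (5.0, 9.0), 0.0, 1.0, seed=2)
        assert evo.events == []
        for niche in evo.niches.values():
            assert (niche.low, niche.high) == (5.0, 9.0)

    def test_forced_expansion_high_definition(self):
        t = simulate_yule_tree(4, 6.0, seed=1)
        tip = t.tip_id("sp01")
        evo = evolve_true_niches(
            t, (5.0, 9.0), 0.0, 1.0, seed=2, forced_events={tip: ("expansion_high", 3.0)}
        )
        assert evo.niches[tip].high == pytest.approx(12.0)
        assert evo.niches[tip].low == pytest.approx(5.0)
        assert len(evo.events) == 1
        assert evo.events[0].event == "expansion_high"

    def test_event_frequency_matches_rate(self):
        # binomial check over replicates: per-branch event probability
        rate, n_rep = 0.3, 500
        t = simulate_yule_tree(12, 6.0, seed=7)
        n_branches = len(t.nodes) - 1
        count = 0
        for seed in range(n_rep):
            evo = evolve_true_niches(t, (5.0, 25.0), rate, 0.5, seed=seed)
            count += len(evo.events)
        freq = count / (n_rep * n_branches)
        se = np.sqrt(rate * (1 - rate) / (n_rep * n_branches))
        assert abs(freq - rate) < 3 * se

    def test_truth_consistency_checked_each_run(self):
        t = simulate_yule_tree(12, 6.0, seed=3)
        evo = evolve_true_niches(t, (5.0, 25.0), 0.5, 1.0, seed=4)
        # re-verify explicitly: child interval = parent interval + event
        verify_truth_consistency(t, evo.niches, evo.events, evo.clamped)

    def test_clamping_recorded_not_evented(self):
        t = simulate_yule_tree(4, 6.0, seed=1)
        tip = t.tip_id("sp01")
        evo = evolve_true_niches(
            t, (5.0, 9.0), 0.0, 1.0, seed=2,
            grid_range=(0.0, 10.0),
            forced_events={tip: ("expansion_high", 5.0)},
        )
        assert evo.niches[tip].high == pytest.approx(10.0)  # clamped
        assert (tip, "high") in evo.clamped
        assert len(evo.events) == 1  # clamping itself is not an event

    def test_root_interval_outside_grid_rejected(self):
        t = simulate_yule_tree(4, 6.0, seed=1)
        with pytest.raises(InvalidSpecError):
            evolve_true_niches(t, (5.0, 9.0), 0.0, 1.0, seed=0, grid_range=(6.0, 20.0))


class TestOccurrenceSampling:
    def _grids(self):
        return [
            simulate_env_grid(30, 30, ("ns", 0.0, 30.0), 0.0, seed=0, variable="temperature"),
            simulate_env_grid(30, 30, ("we", 0.0, 1500.0), 0.0, seed=1, variable="precipitation"),
        ]

    def _niches(self):
        return {
            "temperature": TrueNiche("sp", "temperature", 10.0, 20.0),
            "precipitation": TrueNiche("sp", "precipitation", 400.0, 1100.0),
        }

    def test_samples_respect_all_intervals(self):
        grids = self._grids()
        occ = sample_occurrences(grids, self._niches(), k=25, seed=5, species="sp")
        assert len(occ) == 25
        for lon, lat in occ.points:
            assert 10.0 <= grids[0].value_at(lon, lat) <= 20.0
            assert 400.0 <= grids[1].value_at(lon, lat) <= 1100.0

    @pytest.mark.parametrize("k", [54, 2])
    def test_requested_count_returned(self, k):
        # the study's per-species extremes: 54 and 2 records
        occ = sample_occurrences(self._grids(), self._niches(), k=k, seed=1, species="sp")
        assert len(occ) == k

    def test_sampling_without_replacement(self):
        occ = sample_occurrences(self._grids(), self._niches(), k=30, seed=2, species="sp")
        assert len(set(occ.points)) == 30

    def test_insufficient_habitat_raises(self):
        grids = [simulate_env_grid(5, 5, ("ns", 0.0, 24.0), 0.0, seed=0, variable="t")]
        # exactly one row (5 cells) inside [0,1); narrow further to 1 cell
        niche = {"t": TrueNiche("sp", "t", -0.5, 0.5)}
        occ = sample_occurrences(grids, niche, k=3, seed=0, species="sp")
        assert len(occ) == 3
        with pytest.raises(NoHabitatError, match="sp"):
            sample_occurrences(grids, niche, k=6, seed=0, species="sp")

    def test_no_habitat_names_species(self):
        grids = [simulate_env_grid(5, 5, ("ns", 0.0, 24.0), 0.0, seed=0, variable="t")]
        with pytest.raises(NoHabitatError, match="hermit"):
            sample_occurrences(
                grids, {"t": TrueNiche("hermit", "t", 100.0, 101.0)}, k=1, seed=0,
                species="hermit",
            )

    def test_never_on_nodata(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, :] = True
        g = simulate_env_grid(
            20, 20, ("ns", 0.0, 30.0), 0.0, seed=0, variable="t", nodata_mask=mask
        )
        occ = sample_occurrences(
            [g], {"t": TrueNiche("sp", "t", 0.0, 30.0)}, k=40, seed=3, species="sp"
        )
        for lon, lat in occ.points:
            r, c = g.cell_of(lon, lat)
            assert not g.nodata_mask[r, c]

    def test_range_coverage_mode_pins_extremes(self):
        grids = self._grids()
        occ = sample_occurrences(
            grids, self._niches(), k=10, seed=4, species="sp", ensure_range_coverage=True
        )
        vals = [grids[0].value_at(*p) for p in occ.points]
        ok = (grids[0].values >= 10.0) & (grids[0].values <= 20.0)
        ok &= (grids[1].values >= 400.0) & (grids[1].values <= 1100.0)
        assert max(vals) == pytest.approx(np.nanmax(grids[0].values[ok]))
        assert min(vals) == pytest.approx(np.nanmin(grids[0].values[ok]))
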