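"""Branching simulator, raster embedding, correlated sizes, SSE injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avalanches import (
    AvalancheCatalog,
    BinningSpec,
    BranchingConfig,
    detect_sse,
    embed_catalog_as_raster,
    extract_avalanches,
    generate_correlated_sizes,
    inject_sse,
    simulate_branching_avalanches,
)
from avalanches.errors import InvalidParameterError, PlacementError


class TestBranchingSimulator:
    def test_no_propagation_when_offspring_is_zero(self):
        truth = simulate_branching_avalanches(
            BranchingConfig(m=0.0, n_avalanches=500, offspring_law="binomial", seed=1)
        )
        assert np.all(truth.catalog.sizes == 1)
        assert np.all(truth.catalog.durations == 1)

    def test_subcritical_mean_size_closed_form(self):
        # mean total progeny of a subcritical GW process is 1/(1-m)
        m = 0.5
        truth = simulate_branching_avalanches(
            BranchingConfig(m=m, n_avalanches=10_000, seed=7)
        )
        sizes = truth.catalog.sizes
        expected = 1.0 / (1.0 - m)
        se = sizes.std(ddof=1) / np.sqrt(sizes.size)
        assert abs(sizes.mean() - expected) < 3 * se

    def test_subcritical_mean_matches_generation_enumeration(self):
        # cross-check the closed form by direct summation of expected
        # generation sizes: sum_g m^g
        m = 0.5
        assert sum(m**g for g in range(200)) == pytest.approx(1.0 / (1.0 - m))

    def test_size_at_least_duration(self, critical_catalog):
        assert np.all(critical_catalog.sizes >= critical_catalog.durations)

    def test_cap_flags_runaway_cascades(self):
        truth = simulate_branching_avalanches(
            BranchingConfig(m=1.5, n_avalanches=300, size_cap=1000, seed=3)
        )
        cat = truth.catalog
        assert cat.capped.any()
        assert np.all(cat.sizes[cat.capped] >= 1000)
        assert not cat.fit_mask[cat.capped].any()

    def test_fixed_seed_bit_identical(self):
        cfg = BranchingConfig(m=1.0, n_avalanches=2000, seed=99)
        a = simulate_branching_avalanches(cfg).catalog
        b = simulate_branching_avalanches(cfg).catalog
        assert np.array_equal(a.sizes, b.sizes)
        assert np.array_equal(a.durations, b.durations)

    def test_mean_field_truth_only_at_critical_point(self):
        crit = simulate_branching_avalanches(BranchingConfig(m=1.0, n_avalanches=10, seed=0))
        sub = simulate_branching_avalanches(BranchingConfig(m=0.5, n_avalanches=10, seed=0))
        assert (crit.true_tau, crit.true_alpha, crit.true_gamma) == (1.5, 2.0, 0.5)
        assert sub.true_tau is None

    @pytest.mark.parametrize(
        "kwargs",
        [dict(m=-1.0, n_avalanches=10), dict(m=1.0, n_avalanches=0),
         dict(m=1.0, n_avalanches=10, size_cap=0),
         dict(m=2.5, n_avalanches=10, offspring_law="binomial")],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            BranchingConfig(**kwargs)


class TestEmbedding:
    def test_trivial_two_avalanche_pattern(self):
        cat = AvalancheCatalog(sizes=[3, 1], durations=[2, 1])
        raster = embed_catalog_as_raster(cat, n_neurons=4, bin_dt=0.03, gap_law=1, seed=0)
        bins = np.floor(raster.times_s / 0.03).astype(int)
        counts = np.bincount(bins, minlength=4)
        assert counts[2] == 0 and counts[3] == 1
        assert tuple(counts[:2]) in {(2, 1), (1, 2)}

    def test_empty_catalog_gives_empty_raster(self):
        cat = AvalancheCatalog(sizes=np.empty(0, int), durations=np.empty(0, int))
        raster = embed_catalog_as_raster(cat, n_neurons=3, bin_dt=0.03)
        assert raster.n_spikes == 0

    def test_catalog_rejects_infeasible_avalanche(self):
        with pytest.raises(InvalidParameterError):
            AvalancheCatalog(sizes=[2], durations=[3])  # S < T cannot exist

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_round_trip_is_identity_on_size_duration(self, data):
        n = data.draw(st.integers(1, 30), label="n_avalanches")
        durations = data.draw(
            st.lists(st.integers(1, 8), min_size=n, max_size=n), label="T"
        )
        extra = data.draw(
            st.lists(st.integers(0, 10), min_size=n, max_size=n), label="S-T"
        )
        sizes = [t + e for t, e in zip(durations, extra)]
        gap = data.draw(st.sampled_from([1, 2, ("geometric", 0.5)]), label="gap")
        seed = data.draw(st.integers(0, 2**16), label="seed")
        cat = AvalancheCatalog(sizes=sizes, durations=durations)
        raster = embed_catalog_as_raster(cat, n_neurons=5, bin_dt=0.03,
                                         gap_law=gap, seed=seed)
        binning = BinningSpec(isi=0.03, bin_width_frames=1, bin_dt=0.03)
        out = extract_avalanches(raster, binning)
        assert list(out.sizes) == sizes
        assert list(out.durations) == durations

    def test_round_trip_on_critical_catalog(self, critical_catalog):
        from avalanches.extraction import replace_catalog
        sub = replace_catalog(
            critical_catalog,
            sizes=critical_catalog.sizes[:500], durations=critical_catalog.durations[:500],
            capped=None, start_bins=None, participations=None, sse_flags=None,
        )
        raster = embed_catalog_as_raster(sub, n_neurons=50, bin_dt=0.03, seed=5)
        out = extract_avalanches(raster, BinningSpec(0.03, 1, 0.03))
        assert np.array_equal(out.sizes, sub.sizes)
        assert np.array_equal(out.durations, sub.durations)


class TestCorrelatedSizes:
    def test_zero_persistence_is_iid_from_marginal(self):
        a = generate_correlated_sizes(5000, persist_prob=0.0, seed=11)
        assert a.min() >= 1
        # no repeats beyond chance: lag-1 equal-value rate stays near the
        # marginal collision probability (well below the persistent case)
        rep = np.mean(a[1:] == a[:-1])
        b = generate_correlated_sizes(5000, persist_prob=0.8, seed=11)
        rep_b = np.mean(np.abs(np.log(b[1:] / b[:-1])) < np.log(1.5) + 1e-9)
        assert rep_b > rep

    def test_single_element_sequence_valid(self):
        assert generate_correlated_sizes(1, seed=0).shape == (1,)

    def test_reproducible(self):
        x = generate_correlated_sizes(200, persist_prob=0.3, seed=42)
        y = generate_correlated_sizes(200, persist_prob=0.3, seed=42)
        assert np.array_equal(x, y)

    def test_invalid_persist_prob(self):
        with pytest.raises(InvalidParameterError):
            generate_correlated_sizes(10, persist_prob=1.0)


class TestInjectSse:
    def _sparse_raster(self):
        cat = AvalancheCatalog(sizes=np.ones(30, int), durations=np.ones(30, int))
        return embed_catalog_as_raster(cat, n_neurons=20, bin_dt=0.03,
                                       gap_law=8, seed=8)

    def test_zero_events_unchanged(self):
        raster = self._sparse_raster()
        out = inject_sse(raster, n_events=0)
        assert np.array_equal(out.times, raster.times)

    def test_injected_bursts_detected_by_screening(self):
        raster = self._sparse_raster()
        out = inject_sse(raster, n_events=5, participation=1.0, duration_bins=2, seed=4)
        cat = extract_avalanches(out, BinningSpec(0.03, 1, 0.03))
        cat = detect_sse(cat, participation_threshold=0.75, min_events=5)
        assert cat.sse_flags.sum() >= 5
        assert cat.recording_has_sse

    def test_sse_occupy_large_size_short_duration_corner(self):
        raster = self._sparse_raster()
        out = inject_sse(raster, n_events=5, participation=1.0, duration_bins=2, seed=4)
        cat = detect_sse(
            extract_avalanches(out, BinningSpec(0.03, 1, 0.03)), 0.75, min_events=5
        )
        sse = cat.sse_flags.astype(bool)
        # separated from the background cloud: larger sizes, no longer durations
        assert cat.sizes[sse].min() > cat.sizes[~sse].max()
        assert cat.durations[sse].max() <= 2

    def test_placement_error_when_no_room(self):
        # back-to-back avalanches leave no stretch for a long window
        cat = AvalancheCatalog(sizes=np.ones(5, int), durations=np.ones(5, int))
        raster = embed_catalog_as_raster(cat, n_neurons=4, bin_dt=0.03, gap_law=1, seed=0)
        with pytest.raises(PlacementError):
            inject_sse(raster, n_events=50, participation=1.0, duration_bins=400,
                       seed=0, bin_dt=0.03)
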