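import numpy as np
import pytest

from fmg import (
    ConfigError,
    GenerationConfig,
    build_study_set,
    check_feasibility,
    generate_lists,
    select_lures_distributed,
    select_lures_random,
)
from fmg.generation import solve_bin_ratio
from conftest import brute_force_ranking


def roles(drm):
    return list(drm.studied) + list(drm.critical_lures) + list(drm.unrelated_lures)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, fragment",
        [
            (dict(close_space_size=15, n_studied=15, n_critical=1), "sum of Studied"),
            (dict(n_targets=20, n_studied=15), "Target Items"),
            (dict(n_lists=0), "Number of Lists"),
            (dict(n_unrelated=-1), "Unrelated Lures"),
            (dict(method="nearest"), "method"),
        ],
    )
    def test_violations_name_the_parameter(self, kw, fragment):
        cfg = GenerationConfig(**{"n_lists": 2, **kw})
        with pytest.raises(ConfigError, match=fragment):
            cfg.validate()

    def test_valid_config_passes(self, small_config):
        small_config.validate()

    def test_zero_unrelated_lures_is_allowed(self):
        GenerationConfig(n_lists=1, n_unrelated=0).validate()


class TestBuildStudySet:
    def test_farthest_studied_sits_at_rank_ncs_by_brute_force(
        self, clustered, small_config
    ):
        space = clustered.space
        p = build_study_set(
            space, space.labels[0], small_config, np.random.default_rng(1)
        )
        oracle = brute_force_ranking(space, p.centroid, excluded=p.build_excluded)
        ranks = {l: i + 1 for i, (_, l) in enumerate(oracle)}
        assert max(ranks[l] for l in p.studied) == small_config.close_space_size
        assert len(p.studied) == small_config.n_studied
        assert len(p.close_space) == small_config.close_space_size
        assert set(p.studied) <= set(p.close_space)
        # the reported radius is the rank-N_CS distance
        assert p.close_radius == pytest.approx(
            oracle[small_config.close_space_size - 1][0], abs=1e-12
        )

    def test_close_space_exactly_filled_by_studied_items(self, clustered):
        # boundary configuration: N_CS == N_S, classical selection off
        cfg = GenerationConfig(
            n_lists=1, close_space_size=15, n_studied=15,
            n_targets=6, classical_critical_lure=False,
        )
        space = clustered.space
        p = build_study_set(space, space.labels[3], cfg, np.random.default_rng(2))
        assert sorted(p.studied) == sorted(p.close_space)

    def test_classical_flag_keeps_rank_one_unstudied(self, clustered, small_config):
        space = clustered.space
        p = build_study_set(
            space, space.labels[160], small_config, np.random.default_rng(3)
        )
        oracle = brute_force_ranking(space, p.centroid, excluded=p.build_excluded)
        assert oracle[0][1] == p.nearest_neighbor
        assert p.nearest_neighbor not in set(p.studied)

    def test_deterministic_per_rng_state(self, clustered, small_config):
        space = clustered.space
        a = build_study_set(space, space.labels[5], small_config,
                            np.random.default_rng(4))
        b = build_study_set(space, space.labels[5], small_config,
                            np.random.default_rng(4))
        assert a.studied == b.studied
        assert np.array_equal(a.centroid, b.centroid)

    def test_studied_ordered_by_ascending_centroid_distance(
        self, clustered, small_config
    ):
        space = clustered.space
        p = build_study_set(space, space.labels[8], small_config,
                            np.random.default_rng(5))
        d = [p.distance(space, l) for l in p.studied]
        assert d == sorted(d)


class TestRandomLures:
    def test_forced_selection_when_close_space_has_no_slack(self, clustered):
        # N_CS = N_S + N_CL: critical lures are exactly the non-studied items
        cfg = GenerationConfig(
            n_lists=1, close_space_size=18, n_studied=15, n_targets=6,
            n_critical=3, n_unrelated=2, classical_critical_lure=False,
        )
        space = clustered.space
        p = build_study_set(space, space.labels[20], cfg, np.random.default_rng(6))
        crit, unrel = select_lures_random(space, p, cfg, np.random.default_rng(7))
        assert sorted(crit) == sorted(set(p.close_space) - set(p.studied))
        assert len(unrel) == 2

    def test_unrelated_lures_beyond_all_studied_items(self, clustered, small_config):
        space = clustered.space
        p = build_study_set(space, space.labels[40], small_config,
                            np.random.default_rng(8))
        crit, unrel = select_lures_random(space, p, small_config,
                                          np.random.default_rng(9))
        oracle = dict((l, d) for d, l in brute_force_ranking(space, p.centroid))
        for l in crit:
            assert oracle[l] <= p.close_radius
        for l in unrel:
            assert oracle[l] > p.close_radius

    def test_classical_single_critical_is_the_first_neighbor(
        self, clustered, small_config
    ):
        # the classical-DRM configuration: one critical lure, forced closest
        space = clustered.space
        p = build_study_set(space, space.labels[60], small_config,
                            np.random.default_rng(10))
        crit, _ = select_lures_random(space, p, small_config,
                                      np.random.default_rng(11))
        assert crit == [p.nearest_neighbor]


class TestDistributedLures:
    def test_single_bins_cover_each_region(self, clustered):
        cfg = GenerationConfig(
            n_lists=1, close_space_size=50, n_studied=15, n_targets=6,
            n_critical=1, n_unrelated=1, method="distributed",
            classical_critical_lure=False,
        )
        space = clustered.space
        p = build_study_set(space, space.labels[80], cfg, np.random.default_rng(12))
        crit, unrel, edges, ratio = select_lures_distributed(
            space, p, cfg, np.random.default_rng(13)
        )
        assert len(crit) == 1 and len(unrel) == 1
        assert edges[1] == pytest.approx(p.close_radius)
        cand_d = [p.distance(space, l) for l in p.close_space
                  if l not in set(p.studied)]
        assert edges[0] == pytest.approx(min(cand_d))

    def test_bin_widths_form_a_single_geometric_progression(self, clustered):
        cfg = GenerationConfig(
            n_lists=1, close_space_size=50, n_studied=15, n_targets=6,
            n_critical=3, n_unrelated=3, method="distributed",
        )
        space = clustered.space
        p = build_study_set(space, space.labels[100], cfg, np.random.default_rng(14))
        *_, edges, ratio = select_lures_distributed(
            space, p, cfg, np.random.default_rng(15)
        )
        widths = np.diff(edges)
        consecutive = widths[1:] / widths[:-1]
        assert np.allclose(consecutive, ratio, rtol=1e-9)
        assert edges[cfg.n_critical] == pytest.approx(p.close_radius, abs=1e-12)

    def test_three_criticals_occupy_three_distinct_close_bins(self, clustered):
        cfg = GenerationConfig(
            n_lists=1, close_space_size=50, n_studied=15, n_targets=6,
            n_critical=3, n_unrelated=3, method="distributed",
        )
        space = clustered.space
        p = build_study_set(space, space.labels[120], cfg, np.random.default_rng(16))
        crit, unrel, edges, _ = select_lures_distributed(
            space, p, cfg, np.random.default_rng(17)
        )
        assert len(crit) == 3 and len(unrel) == 3
        close_edges = edges[: cfg.n_critical + 1]
        bins = set()
        for l in crit:
            d = p.distance(space, l)
            b = int(np.searchsorted(close_edges[1:], d, side="left"))
            bins.add(b)
        assert bins == {0, 1, 2}

    @pytest.mark.parametrize(
        "close_span, far_span, n_close, n_far",
        [(0.3, 0.9, 3, 3), (0.3, 0.3, 3, 3), (0.5, 0.2, 2, 4), (0.1, 1.4, 1, 5)],
    )
    def test_ratio_solver_satisfies_both_tilings(
        self, close_span, far_span, n_close, n_far
    ):
        r = solve_bin_ratio(close_span, far_span, n_close, n_far)
        w = (close_span * (r - 1) / (r**n_close - 1) if r != 1.0
             else close_span / n_close)
        widths = w * r ** np.arange(n_close + n_far)
        assert widths[:n_close].sum() == pytest.approx(close_span, rel=1e-9)
        assert widths[n_close:].sum() == pytest.approx(far_span, rel=1e-9)

    def test_balanced_spans_yield_uniform_bins(self):
        assert solve_bin_ratio(0.2, 0.4, 2, 4) == 1.0


class TestGenerateLists:
    def test_no_item_appears_in_two_lists(self, clustered, small_config):
        lists = generate_lists(clustered.space, small_config)
        all_roles = [l for p in lists for l in roles(p)]
        assert len(all_roles) == len(set(all_roles))
        per_list = small_config.n_studied + small_config.n_critical \
            + small_config.n_unrelated
        assert len(all_roles) == small_config.n_lists * per_list

    def test_targets_are_a_studied_subset_of_requested_size(
        self, clustered, small_config
    ):
        lists = generate_lists(clustered.space, small_config)
        for p in lists:
            assert len(p.targets) == small_config.n_targets
            assert set(p.targets) <= set(p.studied)

    def test_same_seed_reproduces_every_list(self, clustered, small_config):
        a = generate_lists(clustered.space, small_config)
        b = generate_lists(clustered.space, small_config)
        for x, y in zip(a, b):
            assert roles(x) == roles(y) and x.targets == y.targets

    def test_studied_sets_are_mono_cluster_on_well_separated_space(
        self, well_separated
    ):
        space, truth, _ = well_separated
        cfg = GenerationConfig(n_lists=12, seed=21)
        lists = generate_lists(space, cfg)
        studied_clusters = []
        for p in lists:
            clusters = {truth[l] for l in p.studied}
            assert len(clusters) == 1
            studied_clusters.append(clusters.pop())
        assert len(set(studied_clusters)) == 12

    def test_invalid_config_raises_before_any_work(self, clustered):
        cfg = GenerationConfig(n_lists=2, n_targets=99)
        with pytest.raises(ConfigError, match="Target Items"):
            generate_lists(clustered.space, cfg)


class TestFeasibility:
    def test_small_vocabulary_is_infeasible_for_both_methods(self, clustered):
        cfg = GenerationConfig(n_lists=100, close_space_size=50, seed=1)
        reports = check_feasibility(clustered.space, cfg)
        for rep in reports.values():
            assert not rep.feasible
            assert "vocabulary" in rep.limiting_constraint
            assert rep.suggested_edits

    def test_structural_violation_reported_not_raised(self, clustered):
        cfg = GenerationConfig(n_lists=2, close_space_size=10, n_studied=15)
        reports = check_feasibility(clustered.space, cfg)
        for rep in reports.values():
            assert not rep.feasible
            assert "sum of Studied" in rep.limiting_constraint
            assert rep.suggested_edits["close_space_items"] >= 16

    def test_generous_space_feasible_for_both_methods(self, clustered):
        cfg = GenerationConfig(n_lists=3, n_critical=3, n_unrelated=3, seed=2)
        reports = check_feasibility(clustered.space, cfg)
        assert all(rep.feasible for rep in reports.values())

    def test_trial_does_not_perturb_the_real_run(self, clustered, small_config):
        before = generate_lists(clustered.space, small_config)
        check_feasibility(clustered.space, small_config)
        after = generate_lists(clustered.space, small_config)
        for x, y in zip(before, after):
            assert roles(x) == roles(y)
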