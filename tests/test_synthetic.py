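"""Synthetic multi-site generators and the parity harness."""

import numpy as np
import pytest

from conftest import make_plan

from fedstar.collaborator import LogisticAdapter, SegmentationAdapter
from fedstar.synthetic import (
    SiteConfig,
    expected_foreground_fraction,
    generate_segmentation_sites,
    generate_tabular_sites,
    generate_tabular_task,
    load_site_fixtures,
    pool_sites,
    run_simulation,
    train_centralized_reference,
    write_site_fixtures,
)


def _cfg(**kw):
    base = dict(n_sites=4, sizes=[50, 100, 150, 200], feature_dim=8, seed=3)
    base.update(kw)
    return SiteConfig(**base)


class TestTabularGenerator:
    def test_sizes_respected(self):
        sites = generate_tabular_sites(_cfg())
        assert [s.declared_size for s in sites] == [50, 100, 150, 200]
        assert sites[0].features.shape == (50, 8)

    def test_reproducible_from_seed(self):
        a = generate_tabular_sites(_cfg())
        b = generate_tabular_sites(_cfg())
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.features, sb.features)
            assert np.array_equal(sa.labels, sb.labels)

    def test_different_seed_differs(self):
        a = generate_tabular_sites(_cfg(seed=3))
        b = generate_tabular_sites(_cfg(seed=4))
        assert not np.array_equal(a[0].features, b[0].features)

    def test_zero_shift_is_homogeneous(self):
        # per-site feature means within 4 standard errors of the global mean
        cfg = _cfg(sizes=[500] * 4, site_shift=0.0, seed=9)
        sites = generate_tabular_sites(cfg)
        pooled = np.concatenate([s.features for s in sites])
        global_mean = pooled.mean(axis=0)
        for s in sites:
            se = s.features.std(axis=0, ddof=1) / np.sqrt(len(s.features))
            assert np.all(np.abs(s.features.mean(axis=0) - global_mean) < 4 * se)

    def test_shift_separates_site_means(self):
        sites = generate_tabular_sites(_cfg(sizes=[500] * 4, site_shift=3.0))
        means = np.stack([s.features.mean(axis=0) for s in sites])
        dists = np.linalg.norm(means - means.mean(axis=0), axis=1)
        assert np.all(dists > 1.0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(sizes=[0, 100, 150, 200]),
            dict(class_balance=0.0),
            dict(class_balance=1.0),
            dict(noise_sd=0.0),
            dict(site_shift=-1.0),
        ],
    )
    def test_degenerate_config_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_tabular_sites(_cfg(**bad))

    def test_holdout_pooled_and_disjoint_draw(self):
        sites, holdout = generate_tabular_task(_cfg(), n_holdout=200)
        assert holdout.declared_size == 200
        # holdout must not replicate any training row
        train = np.concatenate([s.features for s in sites])
        assert not any((train == row).all(axis=1).any() for row in holdout.features[:10])


class TestSegmentationGenerator:
    def test_shapes_and_binary_masks(self):
        cfg = SiteConfig(n_sites=2, sizes=[20, 20], image_shape=(32, 32), seed=5)
        sites = generate_segmentation_sites(cfg)
        assert sites[0].features.shape == (20, 32, 32)
        assert set(np.unique(sites[0].labels)) <= {0.0, 1.0}

    def test_reproducible_from_seed(self):
        cfg = SiteConfig(n_sites=1, sizes=[5], image_shape=(16, 16), seed=2)
        a = generate_segmentation_sites(cfg)[0]
        b = generate_segmentation_sites(cfg)[0]
        assert np.array_equal(a.features, b.features)

    def test_foreground_fraction_in_analytic_band(self):
        cfg = SiteConfig(n_sites=1, sizes=[200], image_shape=(32, 32), seed=7)
        site = generate_segmentation_sites(cfg)[0]
        lo, hi = expected_foreground_fraction(cfg)
        assert lo < site.labels.mean() < hi

    def test_small_image_rejected(self):
        cfg = SiteConfig(n_sites=1, sizes=[5], image_shape=(4, 16), seed=0)
        with pytest.raises(ValueError, match="8x8"):
            generate_segmentation_sites(cfg)


class TestCentralizedReference:
    def test_pooled_size_is_sum(self):
        sites = generate_tabular_sites(_cfg())
        assert pool_sites(sites).declared_size == 500

    def test_deterministic(self):
        sites = generate_tabular_sites(_cfg())
        pooled = pool_sites(sites)
        task = make_plan().tasks["train"]
        states = []
        for _ in range(2):
            ad = LogisticAdapter(8)
            state, _ = train_centralized_reference(pooled, task, ad, rounds=3, seed=11)
            states.append(state)
        assert all(np.array_equal(states[0][k], states[1][k]) for k in states[0])

    def test_full_batch_loss_monotone(self):
        sites = generate_tabular_sites(_cfg())
        pooled = pool_sites(sites)
        task = make_plan(lr=0.1).tasks["train"]
        ad = LogisticAdapter(8)
        losses = [
            train_centralized_reference(pooled, task, ad, rounds=1, seed=0)[1]
            for _ in range(8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestSimulation:
    def test_single_collaborator_matches_centralized_oracle(self):
        sites, holdout = generate_tabular_task(
            SiteConfig(n_sites=1, sizes=[300], feature_dim=8, seed=21), n_holdout=200
        )
        plan = make_plan(rounds=4, collaborators=["solo"], seed=5)
        factory = lambda: LogisticAdapter(8)  # noqa: E731
        report = run_simulation(plan, sites, factory, factory().get_state(), holdout=holdout)
        ad = factory()
        oracle, _ = train_centralized_reference(
            sites[0], plan.tasks["train"], ad, rounds=4, seed=5, origin="solo"
        )
        assert all(
            np.array_equal(report.final_consensus[k], oracle[k]) for k in oracle
        )
        assert report.gap == pytest.approx(0.0, abs=1e-12)
        assert report.rounds_completed == 4

    def test_consensus_beats_worst_single_site_under_shift(self):
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            sites, holdout = generate_tabular_task(
                SiteConfig(
                    n_sites=3, sizes=[100, 200, 400], feature_dim=8,
                    site_shift=2.0, seed=100 + seed,
                ),
                n_holdout=400,
            )
            plan = make_plan(
                rounds=10, collaborators=["s0", "s1", "s2"], seed=seed, lr=0.5
            )
            factory = lambda: LogisticAdapter(8)  # noqa: E731
            rep = run_simulation(plan, sites, factory, factory().get_state(), holdout=holdout)
            if rep.trajectory[-1] >= min(rep.single_site_metrics):
                wins += 1
        assert wins >= n_seeds - 1

    def test_straggler_halt_propagates_with_round(self):
        from fedstar.errors import FedstarError

        sites = generate_tabular_sites(_cfg(n_sites=2, sizes=[50, 50]))
        plan = make_plan(
            rounds=2, collaborators=["a", "b", "c"], min_fraction=0.9, cutoff=1.0
        )
        factory = lambda: LogisticAdapter(8)  # noqa: E731
        with pytest.raises((ValueError, FedstarError)):
            run_simulation(plan, sites, factory, factory().get_state())

    def test_fixture_roundtrip(self, tmp_path):
        sites = generate_tabular_sites(_cfg(n_sites=2, sizes=[30, 40]))
        write_site_fixtures(sites, tmp_path, site_ids=["s0", "s1"])
        loaded = load_site_fixtures(tmp_path)
        assert set(loaded) == {"s0", "s1"}
        assert np.array_equal(loaded["s0"].features, sites[0].features)
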