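"""Simulator contracts: determinism, conservation, selection dynamics and the
three observation models."""

import numpy as np
import pandas as pd
import pytest

from preneo import cna
from preneo.sim import (
    CloneCapExceeded,
    SimulationConfig,
    simulate_evolution,
    sample_barcode_reads,
    sample_scrna,
    sample_swgs,
)


def _fitness_multiplier(s: float, base: float = 0.35) -> float:
    """Per-event coefficient giving a per-day log growth-rate advantage s."""
    return (np.exp(s) * (1 + base) - 1) / base


class TestBranchingProcess:
    def test_no_mutation_keeps_every_karyotype_diploid(self, neutral_history):
        h = neutral_history
        assert all((c.arm_cn == 2).all() and not c.focal for c in h.clones.values())
        cov = sample_swgs(h, 60, mean_coverage=2.0, replicate=0, seed=0)
        profile = cna.call_profile(cov, h.genome)
        assert cna.compute_fga(profile) == 0.0

    def test_sizes_conserved_and_bottleneck_exact(self, neutral_history):
        h = neutral_history
        cfg = h.config
        census = h.census_table()
        assert len(census) > 0
        for phase, df in h.sizes.items():
            totals = df.sum(axis=0)
            for day, total in totals.items():
                assert total > 0
                # the day after a passage the population restarts from the bottleneck
                if (
                    day % cfg.passage_interval_days == 0
                    and ((census["phase"] == phase) & (census["day"] == day)).any()
                ):
                    assert total == cfg.bottleneck_size

    def test_same_seed_gives_identical_history(self, genome):
        cfg = dict(genome=genome, n_founder=30, n_days=40, barcoding_day=10,
                   split_day=17, seed=7)
        h1 = simulate_evolution(SimulationConfig(**cfg))
        h2 = simulate_evolution(SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(h1.clones_table(), h2.clones_table())
        assert h1.sizes.keys() == h2.sizes.keys()
        for k in h1.sizes:
            pd.testing.assert_frame_equal(h1.sizes[k], h2.sizes[k])
        assert h1.extinct == h2.extinct
        assert h1.barcode_silenced == h2.barcode_silenced

    def test_mutation_children_strictly_extend_parent_events(self, genome):
        cfg = SimulationConfig(genome=genome, n_days=120, seed=3)
        h = simulate_evolution(cfg)
        mutated = [c for c in h.clones.values()
                   if c.parent_id is not None and len(c.events) > 0]
        assert mutated, "expected mutation events at the default rates"
        for c in mutated:
            parent = h.clones[c.parent_id]
            assert c.events[: len(parent.events)] == parent.events
            assert len(c.events) >= len(parent.events)

    def test_every_cell_at_barcoding_has_unique_barcode(self, neutral_history):
        h = neutral_history
        day0 = h.sizes["parental"][0]
        barcoded = [h.clones[cid] for cid in day0.index[day0 > 0]]
        bcs = [c.barcode_id for c in barcoded]
        assert None not in bcs and len(set(bcs)) == len(bcs)
        assert (day0[day0 > 0] == 1).all()

    def test_two_clone_logistic_limit(self, genome):
        """Mean mutant frequency over 200 mutation-free runs matches the
        closed-form logistic f(t) = f0 e^{st} / (1 + f0 (e^{st} - 1))."""
        s, f0, t_end = 0.1, 0.01, 60
        w = _fitness_multiplier(s)
        expected = f0 * np.exp(s * t_end) / (1 + f0 * (np.exp(s * t_end) - 1))
        finals = []
        for seed in range(200):
            cfg = SimulationConfig(
                genome=genome, n_founder=100_000,
                founder_clones=[((), 99_000), (("9p-",), 1_000)],
                fitness_table={"9p-": w}, contingency_table={},
                missegregation_rate=0.0, focal_deletion_rate=0.0,
                carrying_capacity=10**18, passage_interval_days=1_000,
                bottleneck_size=10**18 - 1, barcoding_day=None,
                n_replicates=1, n_days=t_end, seed=seed,
            )
            h = simulate_evolution(cfg)
            f = h.event_frequencies(t_end, None)["9p-"]
            finals.append(float(f))
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 1.96 * se + 1e-4
        assert abs(expected - 0.80) < 0.01  # the closed form itself

    def test_extinction_is_a_result_not_an_exception(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=5, base_growth_rate=0.01, death_rate=0.6,
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=50, n_days=60, seed=0,
        )
        h = simulate_evolution(cfg)
        assert "parental" in h.extinct
        assert h.extinct["parental"] < 50

    def test_clone_cap_error_names_cap(self, genome):
        cfg = SimulationConfig(genome=genome, n_founder=50, max_clones=10,
                               barcoding_day=0, split_day=5, n_days=10, seed=0)
        with pytest.raises(CloneCapExceeded, match="max_clones=10"):
            simulate_evolution(cfg)

    def test_invalid_rates_rejected(self, genome):
        with pytest.raises(ValueError, match="missegregation_rate"):
            SimulationConfig(genome=genome, missegregation_rate=1.5).validate()
        with pytest.raises(ValueError, match="bottleneck_size"):
            SimulationConfig(genome=genome, bottleneck_size=10**9).validate()
        with pytest.raises(ValueError, match="fitness"):
            SimulationConfig(genome=genome, fitness_table={"9p-": 0.0}).validate()


class TestShallowWGS:
    def test_diploid_population_flat_expectations(self, neutral_history):
        cn = neutral_history.bin_copy_number(30, 0)
        assert np.allclose(cn, 2.0)
        cov = sample_swgs(neutral_history, 30, mean_coverage=0.2, replicate=0, seed=1)
        # Poisson mean test: genome-wide mean ~ 0.2x * 1 Mb bins / 100 bp reads
        expected = 0.2 * neutral_history.genome.bin_size / 100
        assert abs(cov.counts.mean() - expected) / expected < 0.05

    def test_half_population_one_copy_loss_gives_075_ratio(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=1000,
            founder_clones=[((), 500), (("5q-",), 500)],
            fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=None, n_days=20, passage_interval_days=1_000,
            carrying_capacity=10**9, bottleneck_size=10**9 - 1, seed=0,
        )
        h = simulate_evolution(cfg)
        cn = h.bin_copy_number(0, None)
        arm_mask = (genome.bins["arm"] == "5q").to_numpy()
        assert np.allclose(cn[arm_mask], 1.5)  # (2*0.5 + 1*0.5)
        assert np.allclose(cn[~arm_mask], 2.0)
        cov = sample_swgs(h, 0, mean_coverage=30.0, seed=0)
        ratio = cov.counts[arm_mask].mean() / cov.counts[~arm_mask].mean()
        assert abs(ratio - 0.75) < 0.02

    def test_segment_mean_recovered_after_calling(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=1000,
            founder_clones=[((), 500), (("5q-",), 500)],
            fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=None, n_days=10, passage_interval_days=1_000,
            carrying_capacity=10**9, bottleneck_size=10**9 - 1, seed=0,
        )
        h = simulate_evolution(cfg)
        cov = sample_swgs(h, 0, mean_coverage=30.0, seed=0)
        profile = cna.call_profile(cov, genome)
        arm_mask = (genome.bins["arm"] == "5q").to_numpy()
        states = profile.bin_states()
        seg_mean = np.zeros(genome.n_bins)
        for _, seg in profile.segments.iterrows():
            seg_mean[int(seg.start_bin): int(seg.end_bin)] = seg["mean"]
        assert abs(seg_mean[arm_mask].mean() - np.log2(0.75)) < 0.05
        assert (states[arm_mask] == -1).all()

    def test_day_outside_range_raises(self, neutral_history):
        with pytest.raises(ValueError, match="day"):
            sample_swgs(neutral_history, 10_000, seed=0)


class TestBarcodeReads:
    def test_single_surviving_barcode_has_frequency_one(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=1, fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=0, split_day=7, n_replicates=1, n_days=14, seed=0,
        )
        h = simulate_evolution(cfg)
        reads = sample_barcode_reads(h, 0, 14, total_reads=1_000, seed=0)
        assert len(reads) == 1 and reads.iloc[0] == 1_000

    def test_zero_overdispersion_matches_multinomial_variance(self, neutral_history):
        h = neutral_history
        true = h.barcode_frequencies(30, 0)
        n_reads = 2_000
        draws = np.stack(
            [
                sample_barcode_reads(h, 0, 30, total_reads=n_reads, seed=s)
                .reindex(true.index, fill_value=0).to_numpy()
                for s in range(300)
            ]
        )
        p = true.to_numpy()
        expected_var = n_reads * p * (1 - p)
        observed_var = draws.var(axis=0, ddof=1)
        big = expected_var > 20
        ratio = observed_var[big] / expected_var[big]
        assert 0.8 < ratio.mean() < 1.2

    def test_overdispersion_inflates_variance(self, neutral_history):
        h = neutral_history
        true = h.barcode_frequencies(30, 0)
        top = true.idxmax()
        n_reads = 2_000
        counts = {
            od: np.array(
                [
                    sample_barcode_reads(h, 0, 30, n_reads, overdispersion=od, seed=s)
                    .get(top, 0)
                    for s in range(200)
                ]
            )
            for od in (0.0, 0.05)
        }
        assert counts[0.05].var() > 2 * counts[0.0].var()

    def test_depth_1e5_estimates_within_001(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=4, founder_clones=[((), 4)],
            fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=0, split_day=3, n_replicates=1, n_days=10, seed=5,
        )
        h = simulate_evolution(cfg)
        true = h.barcode_frequencies(10, 0)
        est = sample_barcode_reads(h, 0, 10, total_reads=100_000, seed=1)
        est = est / est.sum()
        assert (est.reindex(true.index, fill_value=0) - true).abs().max() < 0.01

    def test_day_before_barcoding_raises(self, genome):
        cfg = SimulationConfig(genome=genome, n_founder=10, barcoding_day=20,
                               missegregation_rate=0, focal_deletion_rate=0,
                               fitness_table={}, contingency_table={},
                               n_days=40, seed=0)
        h = simulate_evolution(cfg)
        with pytest.raises(ValueError, match="barcoding_day"):
            sample_barcode_reads(h, 0, 5, seed=0)

    def test_dropout_silences_lineages(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=50, fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=0, split_day=7, n_replicates=1, n_days=60,
            barcode_dropout_rate=0.2, seed=11,
        )
        h = simulate_evolution(cfg)
        assert h.barcode_silenced, "expected silenced lineages at 20%/passage"
        day = 60
        readable = set(sample_barcode_reads(h, 0, day, 10_000, seed=0).index)
        for bc, silenced_day in h.barcode_silenced.items():
            if silenced_day <= day:
                assert bc not in readable


class TestSingleCellSampling:
    def test_diploid_clone_unit_dosage(self, neutral_history):
        adata = sample_scrna(neutral_history, 30, n_cells=150, replicate=0, seed=0)
        ref_adata = sample_scrna(neutral_history, 30, n_cells=150, replicate=0, seed=0)
        assert adata.shape[0] == 150
        assert (adata.obs["barcode_id"] >= 0).all()
        # same seed, same call -> identical draw (determinism)
        assert (adata.X != ref_adata.X).nnz == 0

    def test_trisomy_arm_mean_ratio_near_1p5(self, genome):
        cfg = SimulationConfig(
            genome=genome, n_founder=400,
            founder_clones=[((), 200), (("7q+",), 200)],
            fitness_table={}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            barcoding_day=10, n_days=10, seed=0,
        )
        h = simulate_evolution(cfg)
        adata = sample_scrna(h, 5, n_cells=400, genes_per_arm=40, seed=0)
        arm_genes = adata.var_names[adata.var["arm"] == "7q"]
        tri = adata.obs["clone_id"].isin(
            [c.clone_id for c in h.clones.values() if "7q+" in c.events]
        ).to_numpy()
        assert tri.sum() >= 150
        X = adata[:, arm_genes].X.toarray()
        depth = np.asarray(adata.X.sum(axis=1)).ravel()
        mean_tri = (X[tri] / depth[tri, None]).sum(axis=1).mean()
        mean_dip = (X[~tri] / depth[~tri, None]).sum(axis=1).mean()
        ratio = mean_tri / mean_dip
        assert abs(np.log2(ratio) - np.log2(1.5)) < 0.15

    def test_zero_cells_gives_empty_matrix_with_headers(self, neutral_history):
        adata = sample_scrna(neutral_history, 30, n_cells=0, replicate=0, seed=0)
        assert adata.shape[0] == 0
        assert list(adata.obs.columns) == [
            "sample_id", "day", "clone_id", "barcode_id", "low_quality"
        ]
        assert adata.shape[1] > 0

    def test_oversampling_raises(self, neutral_history):
        n = neutral_history.population_size(30, 0)
        with pytest.raises(ValueError, match="exceeds"):
            sample_scrna(neutral_history, 30, n_cells=n + 1, replicate=0, seed=0)
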