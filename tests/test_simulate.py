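"""Generator correctness: determinism, planted structure, marginal moments."""

import numpy as np
import pandas as pd
import pytest

import agecog as ac


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"nb_dispersion": 0.0}, "nb_dispersion"),
            ({"ttc_sd": -1.0}, "ttc_sd"),
            ({"frac_age_up": 1.5}, "frac_age_up"),
            ({"frac_aged_impaired": -0.1}, "frac_aged_impaired"),
            ({"behavior_r": 1.0}, "behavior_r"),
            ({"libsize_spread": -0.2}, "libsize_spread"),
            ({"n_genes": 100, "n_age_de": 80, "n_behavior_genes": 30}, "n_age_de"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        cfg = ac.SimulationConfig(**kwargs)
        with pytest.raises(ValueError, match=field):
            cfg.validate()


class TestDeterminism:
    def test_equal_seeds_identical(self):
        cfg = ac.SimulationConfig(n_genes=300, n_age_de=20, n_behavior_genes=20, seed=7)
        m1, s1, t1 = ac.generate_counts(cfg)
        m2, s2, t2 = ac.generate_counts(cfg)
        assert m1 == m2
        pd.testing.assert_frame_equal(s1, s2)
        assert t1.age_de_genes == t2.age_de_genes

    def test_distinct_seeds_differ(self):
        cfg = ac.SimulationConfig(
            n_genes=300, n_age_de=20, n_behavior_genes=20, seed=7
        )
        m1, _, _ = ac.generate_counts(cfg)
        m2, _, _ = ac.generate_counts(cfg.replace(seed=8))
        assert not m1.counts.equals(m2.counts)

    def test_behavior_table_consistent_with_counts_call(self):
        cfg = ac.SimulationConfig(
            n_genes=100, n_age_de=10, n_behavior_genes=10, seed=3
        )
        _, samples, _ = ac.generate_counts(cfg)
        alone = ac.generate_behavior(cfg)
        pd.testing.assert_frame_equal(samples, alone)


class TestPlantedStructure:
    def test_planted_sets_disjoint_and_sized(self, small_dataset):
        cfg, _, _, truth = small_dataset
        assert len(truth.age_de_genes) == cfg.n_age_de
        assert len(truth.behavior_genes) == cfg.n_behavior_genes
        assert not set(truth.age_de_genes) & set(truth.behavior_genes)

    def test_age_lfc_on_log2_scale(self):
        cfg = ac.SimulationConfig(
            n_genes=400, n_age_de=100, n_behavior_genes=0, age_lfc=2.0,
            frac_age_up=1.0, libsize_spread=0.0, mean_log_expr=7.0, seed=5,
        )
        matrix, samples, truth = ac.generate_counts(cfg)
        young = samples.loc[samples.age_group == "young", "sample_id"]
        aged = samples.loc[samples.age_group == "aged", "sample_id"]
        planted = list(truth.age_de_genes)
        ratio = (
            matrix.counts.loc[planted, aged].mean(axis=1)
            / matrix.counts.loc[planted, young].mean(axis=1)
        )
        # planted 4-fold shift recovered in expectation
        assert np.median(np.log2(ratio)) == pytest.approx(2.0, abs=0.15)

    def test_zero_lfc_plants_nothing(self):
        cfg = ac.SimulationConfig(
            n_genes=500, n_age_de=100, n_behavior_genes=0, age_lfc=0.0, seed=2
        )
        matrix, samples, truth = ac.generate_counts(cfg)
        nm = ac.normalize(ac.filter_low_counts(matrix))
        res = ac.age_screen(nm, samples, alpha=0.025)
        planted = [g for g in truth.age_de_genes if g in res.index]
        # indistinguishable from null: hit rate near alpha, far below power levels
        assert res.loc[planted, "significant"].mean() < 0.12

    def test_overdispersion(self):
        cfg = ac.SimulationConfig(
            n_genes=800, n_age_de=0, n_behavior_genes=0, libsize_spread=0.0,
            nb_dispersion=0.3, seed=9,
        )
        matrix, _, _ = ac.generate_counts(cfg)
        mean = matrix.counts.mean(axis=1)
        var = matrix.counts.var(axis=1, ddof=1)
        high = mean > 20
        assert (var[high] > mean[high]).mean() > 0.95

    def test_true_size_factors_recovered(self):
        cfg = ac.SimulationConfig(
            n_genes=3000, n_age_de=0, n_behavior_genes=0, libsize_spread=0.4, seed=4
        )
        matrix, _, truth = ac.generate_counts(cfg)
        est = ac.size_factors(ac.filter_low_counts(matrix))
        r = np.corrcoef(np.log(est), np.log(truth.true_size_factors))[0, 1]
        assert r > 0.95


class TestBehavior:
    def test_no_impaired_equal_means(self):
        cfg = ac.SimulationConfig(
            n_young=200, n_aged=200, frac_aged_impaired=0.0,
            ttc_young_mean=30.0, ttc_au_mean=30.0, seed=1,
        )
        table = ac.generate_behavior(cfg)
        young = table.loc[table.age_group == "young", "set_shift_ttc"]
        aged = table.loc[table.age_group == "aged", "set_shift_ttc"]
        assert abs(young.mean() - aged.mean()) < 2.5

    def test_all_impaired_shifts_mean(self):
        cfg = ac.SimulationConfig(
            n_young=300, n_aged=300, frac_aged_impaired=1.0,
            ttc_young_mean=25.0, ttc_ai_mean=80.0, ttc_sd=5.0, seed=1,
        )
        table = ac.generate_behavior(cfg)
        diff = (
            table.loc[table.age_group == "aged", "set_shift_ttc"].mean()
            - table.loc[table.age_group == "young", "set_shift_ttc"].mean()
        )
        assert diff == pytest.approx(55.0, abs=2.0)

    def test_ttc_floor(self):
        cfg = ac.SimulationConfig(
            n_young=200, n_aged=200, ttc_young_mean=10.0, ttc_sd=10.0, seed=3
        )
        table = ac.generate_behavior(cfg)
        assert (table["set_shift_ttc"] >= 8).all()

    def test_mean_split_recovers_latent_labels(self):
        """Mean-split accuracy approaches the two-Gaussian Bayes rate.

        Oracle: Monte-Carlo Bayes accuracy with the known means/SD and
        the optimal likelihood boundary.
        """
        cfg = ac.SimulationConfig(n_aged=2000, seed=6)
        rng = np.random.default_rng(123)
        n = 200_000
        impaired = rng.random(n) < cfg.frac_aged_impaired
        draws = rng.normal(
            np.where(impaired, cfg.ttc_ai_mean, cfg.ttc_au_mean), cfg.ttc_sd
        )
        # optimal boundary for equal-variance Gaussians incl. prior odds
        mid = (cfg.ttc_ai_mean + cfg.ttc_au_mean) / 2 + (
            cfg.ttc_sd**2
            / (cfg.ttc_ai_mean - cfg.ttc_au_mean)
            * np.log((1 - cfg.frac_aged_impaired) / cfg.frac_aged_impaired)
        )
        bayes = ((draws > mid) == impaired).mean()

        table = ac.generate_behavior(cfg)
        aged = table.loc[table.age_group == "aged"].set_index("sample_id")
        labels = ac.mean_split(aged["set_shift_ttc"])
        accuracy = (labels["label"] == aged["ttc_class"]).mean()
        assert accuracy > 0.5  # above chance
        assert accuracy > bayes - 0.1  # near the Bayes ceiling

    def test_discrimination_index_in_range(self):
        table = ac.generate_behavior(ac.SimulationConfig(seed=0))
        di = table["discrimination_index"]
        assert ((di >= -1) & (di <= 1)).all()


class TestSpikeIn:
    def test_zero_noise_perfectly_linear(self):
        table = ac.generate_spikein(n_transcripts=92, noise_sd=0.0, seed=0)
        report = ac.spikein_qc(table)
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)
        assert report.passed

    def test_r2_decreases_with_noise(self):
        """R^2 of the QC fit falls monotonically as log-scale noise grows."""
        levels = [0.0, 0.2, 0.5, 1.0]
        mean_r2 = []
        for noise in levels:
            r2 = [
                ac.spikein_qc(ac.generate_spikein(92, noise, seed)).r_squared
                for seed in range(10)
            ]
            mean_r2.append(np.mean(r2))
        assert all(a > b for a, b in zip(mean_r2, mean_r2[1:]))

    def test_single_transcript_fails_gate(self):
        table = ac.generate_spikein(n_transcripts=1, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            ac.spikein_qc(table)


class TestQpcrGenerator:
    def test_zero_noise_exact_cycle_shift(self):
        ct = ac.generate_qpcr({"Arc": 2.0, "Gapdh": 1.0}, ct_sd=0.0, seed=0)
        arc = ct.loc[ct.gene == "Arc"]
        shift = (
            arc.loc[arc.group == "control", "ct"].mean()
            - arc.loc[arc.group == "treated", "ct"].mean()
        )
        assert shift == pytest.approx(1.0, abs=1e-12)

    def test_unit_folds_recover_one(self):
        ct = ac.generate_qpcr({"Arc": 1.0, "Fos": 1.0, "Gapdh": 1.0}, ct_sd=0.0, seed=0)
        rel = ac.delta_delta_ct(ct, control_group="control")
        assert rel["fold"].to_numpy() == pytest.approx(np.ones(len(rel)), abs=1e-12)

    def test_planted_fold_recovered(self):
        """Recovered Arc fold within 5% of the planted 1.89 over 100 seeds."""
        folds = []
        for seed in range(100):
            ct = ac.generate_qpcr(
                {"Arc": 1.89, "Gapdh": 1.0}, n_per_group=6, ct_sd=0.05, seed=seed
            )
            rel = ac.delta_delta_ct(ct, control_group="control")
            folds.append(rel.loc[rel.group == "treated", "fold"].mean())
        assert np.mean(folds) == pytest.approx(1.89, rel=0.05)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ac.generate_qpcr({"Arc": -2.0, "Gapdh": 1.0}, seed=0)
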