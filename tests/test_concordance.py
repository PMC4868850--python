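"""Cross-study concordance: matching, chi-square, directed tests, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import agecog as ac


def _nm(values: pd.DataFrame, log=True):
    return ac.NormalizedMatrix(
        values, pd.Series(1.0, index=values.columns), log_transformed=log
    )


def _two_group_samples(n_young, n_aged):
    ids = [f"y{i}" for i in range(n_young)] + [f"a{i}" for i in range(n_aged)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "age_group": ["young"] * n_young + ["aged"] * n_aged,
        }
    )


class TestMatchGenes:
    def test_case_insensitive_match(self, toy_counts):
        prior = ac.DirectionSet.from_pairs("human", [("G1", 1), ("G3", -1), ("ZZZ", 1)])
        matched = ac.match_genes(prior, toy_counts)
        assert len(matched) == 2
        assert matched.display["g1"] == "g1"  # data's own identifier kept

    def test_absent_symbols_excluded(self, toy_counts):
        prior = ac.DirectionSet.from_pairs("x", [("nope", 1)])
        assert len(ac.match_genes(prior, toy_counts)) == 0

    def test_T_is_matched_count(self, normalized):
        nm, _ = normalized
        symbols = nm.gene_ids[:30] + ["missing1", "missing2"]
        prior = ac.DirectionSet.from_pairs("x", [(s, 1) for s in symbols])
        assert len(ac.match_genes(prior, nm)) == 30


class TestDirectionAgreement:
    def test_all_planted_agree(self):
        samples = _two_group_samples(4, 4)
        values = pd.DataFrame(
            {s: ([1.0, 5.0] if g == "young" else [2.0, 3.0])
             for s, g in zip(samples.sample_id, samples.age_group)},
            index=["up_gene", "down_gene"],
        )
        nm = _nm(values, log=False)
        prior = ac.DirectionSet.from_pairs("x", [("up_gene", 1), ("down_gene", -1)])
        n_same, percent = ac.direction_agreement(prior, nm, samples)
        assert (n_same, percent) == (2, 100)

    def test_printed_percent(self):
        # 203 of 318 concordant genes is 64% to the nearest integer
        assert round(100 * 203 / 318) == 64

    def test_equal_means_count_as_disagreement(self):
        samples = _two_group_samples(3, 3)
        values = pd.DataFrame(
            {s: [4.0] for s in samples.sample_id}, index=["flat"]
        )
        prior = ac.DirectionSet.from_pairs("x", [("flat", 1)])
        n_same, _ = ac.direction_agreement(prior, _nm(values, log=False), samples)
        assert n_same == 0

    def test_random_directions_near_half(self, normalized):
        nm, samples = normalized
        rng = np.random.default_rng(3)
        genes = list(rng.choice(nm.gene_ids, 400, replace=False))
        prior = ac.DirectionSet.from_pairs(
            "null", [(g, int(d)) for g, d in zip(genes, rng.choice([-1, 1], 400))]
        )
        _, percent = ac.direction_agreement(prior, nm, samples)
        assert 40 <= percent <= 60


class TestChiSquareDirection:
    def test_even_split_is_zero(self):
        chi2, p = ac.chi_square_direction(100, 200)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_printed_scale_example(self):
        chi2, p = ac.chi_square_direction(203, 318)
        assert chi2 == pytest.approx(24.35, abs=0.005)
        assert p < 0.001

    def test_total_agreement_equals_T(self):
        for T in (10, 25, 318):
            chi2, _ = ac.chi_square_direction(T, T)
            assert chi2 == pytest.approx(T)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_closed_form(self, data):
        T = data.draw(st.integers(min_value=1, max_value=5000))
        n_same = data.draw(st.integers(min_value=0, max_value=T))
        chi2, p = ac.chi_square_direction(n_same, T)
        assert chi2 == pytest.approx(2 * (n_same - T / 2) ** 2 / (T / 2), rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_direction_of_evidence_matches_binomial(self):
        """On every small instance the chi-square and the exact binomial
        rank departures from 50:50 the same way (enumeration oracle)."""
        for T in range(1, 31):
            binom_p = [stats.binomtest(k, T, 0.5).pvalue for k in range(T + 1)]
            chi2_vals = [ac.chi_square_direction(k, T)[0] for k in range(T + 1)]
            # larger chi2 <=> smaller (or equal) binomial p
            order = np.argsort(chi2_vals)
            ranked_p = np.array(binom_p)[order]
            assert all(
                ranked_p[i] >= ranked_p[i + 1] - 1e-12 for i in range(T)
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ac.chi_square_direction(1, 0)
        with pytest.raises(ValueError):
            ac.chi_square_direction(5, 4)


class TestExpectedDirectionFdr:
    @pytest.mark.parametrize(
        "T, alpha, n_sig, expected",
        [(318, 0.05, 60, 0.27), (26, 0.05, 16, 0.08)],
    )
    def test_worked_examples(self, T, alpha, n_sig, expected):
        assert round(ac.expected_direction_fdr(T, alpha, n_sig), 2) == expected

    def test_zero_sig_undefined(self):
        assert np.isnan(ac.expected_direction_fdr(100, 0.05, 0))

    def test_strictly_decreasing_in_n_sig(self):
        values = [ac.expected_direction_fdr(318, 0.05, k) for k in range(1, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_unity_at_expected_count(self):
        assert ac.expected_direction_fdr(200, 0.05, 10) == pytest.approx(1.0)


class TestDirectedTests:
    def test_one_tailed_p_complementarity(self, normalized):
        """p(predicted up) + p(predicted down) = 1 for the t statistic."""
        nm, samples = normalized
        genes = nm.gene_ids[:20]
        up = ac.DirectionSet.from_pairs("up", [(g, 1) for g in genes])
        down = ac.DirectionSet.from_pairs("down", [(g, -1) for g in genes])
        rep_up = ac.directed_tests(up, nm, samples)
        rep_down = ac.directed_tests(down, nm, samples)
        # recover per-gene p values from both runs via a fresh computation
        log_values = nm.log2()
        young = samples.loc[samples.age_group == "young", "sample_id"]
        aged = samples.loc[samples.age_group == "aged", "sample_id"]
        for gene in genes:
            t_stat, _ = stats.ttest_ind(
                log_values.loc[gene, aged], log_values.loc[gene, young], equal_var=True
            )
            df = len(young) + len(aged) - 2
            p_up = stats.t.sf(t_stat, df)
            p_down = stats.t.cdf(t_stat, df)
            assert p_up + p_down == pytest.approx(1.0, abs=1e-12)

    def test_report_arithmetic_consistency(self, normalized, small_dataset):
        _, _, _, truth = small_dataset
        nm, samples = normalized
        planted = [g for g in truth.age_de_genes if g in nm.values.index]
        prior = ac.DirectionSet.from_pairs(
            "truth", [(g, truth.age_de_genes[g]) for g in planted]
        )
        report = ac.directed_tests(prior, nm, samples, alpha=0.05)
        assert report.T == len(planted)
        assert report.n_sig_up + report.n_sig_down == report.n_sig
        assert report.n_same <= report.T
        assert report.expected_sig == pytest.approx(report.T * 0.05)
        assert report.fdr == pytest.approx(report.expected_sig / report.n_sig)
        # planted true directions: most genes significant, FDR far below 1
        assert report.n_sig / report.T > 0.8
        assert report.fdr < 0.1
        assert len(report.sig_genes) == report.n_sig

    def test_null_prior_fdr_near_one(self):
        cfg = ac.SimulationConfig(n_genes=2000, n_age_de=0, n_behavior_genes=0, seed=12)
        matrix, samples, _ = ac.generate_counts(cfg)
        nm = ac.normalize(ac.filter_low_counts(matrix))
        rng = np.random.default_rng(0)
        genes = list(rng.choice(nm.gene_ids, 800, replace=False))
        prior = ac.DirectionSet.from_pairs(
            "null", [(g, int(d)) for g, d in zip(genes, rng.choice([-1, 1], 800))]
        )
        report = ac.directed_tests(prior, nm, samples, alpha=0.05)
        # E[n_sig] = T * alpha, so the FDR concentrates near 1
        assert report.n_sig == pytest.approx(report.T * 0.05, abs=3 * np.sqrt(800 * 0.05 * 0.95))
        assert 0.6 < report.fdr < 1.7
        assert 40 <= report.percent_same <= 60

    def test_untestable_gene_stays_in_T(self):
        samples = _two_group_samples(3, 3)
        values = pd.DataFrame(
            {
                s: ([4.0, 1.0 + i] if g == "aged" else [4.0, 5.0 + i])
                for i, (s, g) in enumerate(zip(samples.sample_id, samples.age_group))
            },
            index=["flat", "varies"],
        )
        prior = ac.DirectionSet.from_pairs("x", [("flat", 1), ("varies", -1)])
        report = ac.directed_tests(prior, _nm(values, log=False), samples)
        assert report.T == 2  # untestable gene retained in the denominator count
        assert report.n_sig <= 1

    def test_zero_sig_fdr_nan(self):
        samples = _two_group_samples(3, 3)
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(5, 0.1, size=(4, 6)),
            index=[f"g{i}" for i in range(4)],
            columns=samples.sample_id,
        )
        prior = ac.DirectionSet.from_pairs("x", [(f"g{i}", 1) for i in range(4)])
        report = ac.directed_tests(prior, _nm(values), samples, alpha=1e-6)
        assert report.n_sig == 0 and np.isnan(report.fdr)
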