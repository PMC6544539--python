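import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from brainmosaic import enrichment


def binom_tail_oracle(k, n, p):
    """Upper-tail summation from log-gammas, independent of scipy.stats."""
    ks = np.arange(k, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
        + ks * np.log(p) + (n - ks) * np.log1p(-p)
    )
    return float(np.exp(logpmf).sum())


class TestMethylationBackground:
    def test_published_genome_totals(self):
        frac = enrichment.methylation_background(476_286_624, 3_095_693_981)
        assert round(100 * frac, 1) == 15.4

    def test_zero_methylated(self):
        assert enrichment.methylation_background(0, 100) == 0.0

    def test_planted_fraction_recovered_exactly(self):
        flags = np.zeros(1000, dtype=bool)
        flags[:300] = True
        assert enrichment.methylation_background_from_flags(flags) == 0.30

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment.methylation_background(0, 0)


class TestBinomialEnrichment:
    def test_matches_oracle_on_validated_counts(self):
        got = enrichment.binomial_enrichment(6, 22, 0.154, sided="greater")
        assert got == pytest.approx(binom_tail_oracle(6, 22, 0.154), abs=1e-12)

    def test_expected_count_not_significant(self):
        n = 100
        p = enrichment.binomial_enrichment(round(n * 0.154), n, 0.154)
        assert p > 0.4

    def test_all_successes_closed_form(self):
        assert enrichment.binomial_enrichment(22, 22, 0.154) == pytest.approx(
            0.154**22, rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enrichment.binomial_enrichment(5, 3, 0.1)
        with pytest.raises(ValueError):
            enrichment.binomial_enrichment(1, 3, 0.0)


class TestExpressionEnrichment:
    def test_validated_brain_expressed_aggregate(self, table1):
        coding = table1[table1["consequence"].isin(["nonsynonymous", "start_loss"])]
        out = enrichment.expression_enrichment(coding["expression_class"])
        brain = out[out["class"] == "brain_expressed"].iloc[0]
        assert brain["observed"] == 10
        assert len(coding) == 17
        assert brain["observed"] / len(coding) == pytest.approx(0.588, abs=0.001)

    def test_degenerate_background_single_class(self):
        props = {c: 0.0 for c in enrichment.EXPRESSION_CLASSES}
        props["expressed_all"] = 1.0
        out = enrichment.expression_enrichment(["expressed_all"] * 5, props)
        row = out[out["class"] == "expressed_all"].iloc[0]
        assert row["p"] == 1.0

    def test_planted_enrichment_detected(self):
        # 100 genes, 90 in expressed_all (background 0.45) -> strong signal
        out = enrichment.expression_enrichment(
            ["expressed_all"] * 90 + ["not_detected"] * 10
        )
        row = out[out["class"] == "expressed_all"].iloc[0]
        assert row["p"] < 1e-10

    def test_aggregate_equals_aggregated_background_test(self, table1):
        coding = table1[table1["consequence"].isin(["nonsynonymous", "start_loss"])]
        out = enrichment.expression_enrichment(coding["expression_class"])
        brain = out[out["class"] == "brain_expressed"].iloc[0]
        p_brain = sum(
            enrichment.BackgroundModel().expression_class_proportions[c]
            for c in enrichment.BRAIN_EXPRESSED
        )
        direct = enrichment.binomial_enrichment(10, 17, p_brain, sided="two")
        assert brain["p"] == pytest.approx(direct)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            enrichment.expression_enrichment(["brainy"])


class TestConstraintQuartiles:
    def test_validated_quartiles_uniformity_not_rejected(self, table1):
        coding = table1[table1["consequence"].isin(["nonsynonymous", "start_loss"])]
        qs = coding["constraint_quartile"].dropna().astype(int)
        out = enrichment.constraint_quartile_test(qs)
        assert (out["p"] > 0.05).all()

    def test_extreme_concentration_rejected(self):
        out = enrichment.constraint_quartile_test([4] * 20)
        row = out[out["quartile"] == 4].iloc[0]
        assert row["p"] == pytest.approx(0.25**20, rel=1e-6)

    def test_simulated_uniform_counts_balanced(self):
        rng = np.random.default_rng(8)
        qs = rng.integers(1, 5, size=1000)
        out = enrichment.constraint_quartile_test(qs)
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        assert (np.abs(out["observed"] - 250) <= 3 * sigma).all()


class TestCohortProbability:
    def test_prior_returned_for_empty_cohort(self):
        assert enrichment.cohort_variant_probability(0, 0)["mean"] == 0.5

    def test_published_cohort_posterior_mean(self):
        out = enrichment.cohort_variant_probability(46, 1461)
        assert out["mean"] == pytest.approx(47 / 1463)
        assert round(100 * out["mean"], 1) == 3.2
        assert out["ci_low"] < 46 / 1461 < out["ci_high"]

    def test_single_success_closed_form(self):
        assert enrichment.cohort_variant_probability(1, 1)["mean"] == pytest.approx(2 / 3)

    def test_interval_coverage_near_nominal(self):
        rng = np.random.default_rng(99)
        true_p, n, reps = 0.03, 1461, 400
        covered = 0
        for _ in range(reps):
            carriers = rng.binomial(n, true_p)
            out = enrichment.cohort_variant_probability(carriers, n)
            covered += out["ci_low"] <= true_p <= out["ci_high"]
        assert 0.92 <= covered / reps <= 0.985


class TestRegionBias:
    def fisher_oracle(self, table):
        """Two-sided Fisher p by hypergeometric enumeration."""
        (a, b), (c, d) = table
        n, r1, c1 = a + b + c + d, a + b, a + c
        ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
        logp = (
            gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
            + gammaln(n - r1 + 1) - gammaln(c1 - ks + 1)
            - gammaln(n - r1 - c1 + ks + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )
        probs = np.exp(logp)
        p_obs = probs[ks == a][0]
        return float(probs[probs <= p_obs * (1 + 1e-7)].sum())

    def test_matches_enumeration_oracle(self):
        table = [[3, 1], [1, 3]]
        out = enrichment.region_bias_test(table)
        assert out["p"] == pytest.approx(self.fisher_oracle(table), abs=1e-12)

    def test_identical_proportions_uninformative(self):
        assert enrichment.region_bias_test([[5, 5], [5, 5]])["p"] == pytest.approx(1.0)

    def test_zero_margin_reported_not_raised(self):
        out = enrichment.region_bias_test([[0, 0], [3, 4]])
        assert out["p"] == 1.0 and out["note"] == "zero margin"

    def test_random_tables_against_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            table = rng.integers(0, 40, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            out = enrichment.region_bias_test(table.tolist())
            assert out["p"] == pytest.approx(
                self.fisher_oracle(table.tolist()), abs=1e-10
            )
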