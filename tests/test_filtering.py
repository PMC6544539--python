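import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import brainmosaic as bm
from brainmosaic import filtering


def toy_sites(n, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1),
            "ref": ["C"] * n,
            "alt": ["T"] * n,
        }
    )


class TestRegionMask:
    def test_low_depth_in_any_sample_excludes_site(self):
        sites = toy_sites(1)
        depth = np.array([[31], [30], [29]])
        mask = filtering.build_region_mask(sites, depth)
        assert mask.callable_bp == 0

    def test_all_clear_keeps_everything(self):
        sites = toy_sites(5)
        depth = np.full((3, 5), 30)
        mask = filtering.build_region_mask(sites, depth)
        assert mask.callable_bp == 5
        assert mask.callable_sites.all()

    def test_ten_site_toy_enumeration(self):
        # blacklist covers the first three sites (0-based [0,3)); one sample
        # has depth 10 at the eighth site (0-based index 7) -> 6 callable
        sites = toy_sites(10)
        depth = np.full((2, 10), 50)
        depth[0, 7] = 10
        blacklist = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [3]})
        mask = filtering.build_region_mask(sites, depth, blacklist=blacklist)
        assert mask.callable_bp == 6
        assert list(np.nonzero(~mask.callable_sites)[0]) == [0, 1, 2, 7]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            filtering.build_region_mask(
                toy_sites(2),
                np.full((1, 2), 50),
                blacklist=pd.DataFrame(
                    {"chrom": ["chr1"], "start": [5], "end": [5]}
                ),
            )


class TestVafWindow:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(0.52, False), (0.08, False), (0.25, True), (0.10, True), (0.50, True)],
    )
    def test_boundaries_closed(self, vaf, expected):
        assert filtering.vaf_window_filter(vaf) == expected

    def test_no_coverage_fails(self):
        assert not filtering.vaf_window_filter(0.0, depth=0)


class TestHetBinomialTest:
    def test_null_mode_not_significant(self):
        p = filtering.het_binomial_test(47, 100)
        assert p > 0.9

    def test_zero_alt_closed_form(self):
        p = filtering.het_binomial_test(0, 40)
        assert p == pytest.approx(2 * 0.53**40, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        # independent oracle: cumulative sums of the exact pmf
        k = np.arange(201)
        pmf = stats.binom.pmf(k, 200, 0.47)
        lower = np.cumsum(pmf)
        upper = np.cumsum(pmf[::-1])[::-1]
        oracle = np.minimum(1.0, 2 * np.minimum(lower, upper))
        assert filtering.het_binomial_test(30, 200) == pytest.approx(
            oracle[30], abs=1e-12
        )

    def test_exhaustive_oracle_all_depths_to_300(self):
        for n in range(1, 301):
            k = np.arange(n + 1)
            pmf = stats.binom.pmf(k, n, 0.47)
            lower = np.cumsum(pmf)
            upper = np.cumsum(pmf[::-1])[::-1]
            oracle = np.minimum(1.0, 2 * np.minimum(lower, upper))
            got = filtering.het_binomial_test(k, np.full(n + 1, n))
            assert np.max(np.abs(got - oracle)) < 1e-12

    def test_monotone_within_lower_tail(self):
        n = 120
        mode = round(0.47 * n)
        p = filtering.het_binomial_test(np.arange(0, mode + 1), np.full(mode + 1, n))
        assert (np.diff(p) >= -1e-15).all()

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(1, 300), st.data())
    def test_valid_probability_and_mirror_symmetry(self, n, data):
        # reflecting the count and the null probability gives the same
        # two-sided p-value, and every p lies in (0, 1]
        k = data.draw(st.integers(0, n))
        p = filtering.het_binomial_test(k, n, p0=0.47)
        mirrored = filtering.het_binomial_test(n - k, n, p0=0.53)
        assert 0 < p <= 1
        assert p == pytest.approx(mirrored, rel=1e-9)

    def test_minlike_convention_available(self):
        p = filtering.het_binomial_test(30, 200, method="minlike")
        assert p == pytest.approx(stats.binomtest(30, 200, 0.47).pvalue)


class TestRecurrenceFilter:
    def make(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
        )

    def test_shared_variant_removed_everywhere(self):
        df = self.make([("a", "chr1", 5, "C", "T"), ("b", "chr1", 5, "C", "T")])
        assert not filtering.recurrence_filter(df).any()

    def test_unique_variant_survives(self):
        df = self.make([("a", "chr1", 5, "C", "T")])
        assert filtering.recurrence_filter(df).all()

    def test_keyed_by_alt_allele(self):
        df = self.make(
            [
                ("a", "chr1", 9, "A", "T"),
                ("b", "chr1", 9, "A", "T"),
                ("c", "chr1", 9, "A", "T"),
                ("d", "chr1", 9, "A", "G"),
            ]
        )
        keep = filtering.recurrence_filter(df)
        assert list(keep) == [False, False, False, True]

    def test_two_samples_same_individual_count_once(self):
        df = self.make([("a1", "chr1", 5, "C", "T"), ("a2", "chr1", 5, "C", "T")])
        keep = filtering.recurrence_filter(df, individual_of={"a1": "A", "a2": "A"})
        assert keep.all()


class TestPopulationFilter:
    def make_pop(self):
        return pd.DataFrame(
            {
                "chrom": ["chr11", "chr1"],
                "pos": [104905100, 10],
                "ref": ["T", "C"],
                "alt": ["G", "T"],
                "maf": [4.10e-3, 0.02],
            }
        )

    def test_rare_common_and_absent(self):
        cands = pd.DataFrame(
            {
                "sample_id": ["s"] * 3,
                "chrom": ["chr11", "chr1", "chr2"],
                "pos": [104905100, 10, 99],
                "ref": ["T", "C", "G"],
                "alt": ["G", "T", "A"],
            }
        )
        keep = filtering.population_frequency_filter(cands, self.make_pop())
        assert list(keep) == [True, False, True]


class TestRunDiscovery:
    def test_empty_cohort_yields_empty_output(self):
        cfg = bm.SimulationConfig(
            n_samples=5, n_sites=50,
            het_density=0, somatic_rate_per_division=0, error_rate_mean=0, seed=0,
        )
        c = bm.simulate_cohort(cfg)
        surv, audit, _ = bm.run_discovery(
            c.sites, c.depth, c.alt_count, c.sample_ids
        )
        assert len(surv) == 0 and len(audit) == 0

    def test_het_only_cohort_yields_no_candidates(self):
        cfg = bm.SimulationConfig(
            n_samples=50, n_sites=500, het_density=0.003,
            somatic_rate_per_division=0, error_rate_mean=0, seed=5,
        )
        c = bm.simulate_cohort(cfg)
        surv, audit, _ = bm.run_discovery(
            c.sites, c.depth, c.alt_count, c.sample_ids
        )
        # nominal false-positive allowance at p < 1e-5
        n_tested = int(audit["pass_vaf"].sum())
        assert len(surv) <= stats.poisson.ppf(0.999, 1e-5 * n_tested)

    def test_inconsistent_sample_set_rejected(self, default_cohort):
        c = default_cohort
        with pytest.raises(ValueError):
            bm.run_discovery(c.sites, c.depth, c.alt_count, c.sample_ids[:-1])

    def test_survivors_satisfy_all_thresholds(self, default_discovery):
        surv, audit, mask = default_discovery
        if len(surv):
            assert ((surv["vaf"] >= 0.10) & (surv["vaf"] <= 0.50)).all()
            assert (surv["het_p"] < 1e-5).all()
            assert (surv["panel_p"] < 1e-3).all()
            site_pos = set(np.nonzero(mask.callable_sites)[0] + 1)
            assert set(surv["pos"]).issubset(site_pos)

    def test_recurrence_population_order_independent(self, default_discovery):
        surv, audit, _ = default_discovery
        pool = audit[audit["pass_panel"]]
        rec = filtering.recurrence_filter(pool)
        pop = filtering.population_frequency_filter(pool, None)
        final_rp = set(pool[rec & pop].index)
        final_pr = set(pool[pop & rec].index)
        assert final_rp == final_pr == set(
            audit.index[audit["passed"]]
        )

    def test_stage_counts_monotone_nonincreasing(self, default_discovery):
        _, audit, _ = default_discovery
        counts = filtering.stage_counts(audit)
        chain = [counts[k] for k in ("entered", "snv", "mask", "vaf", "het",
                                     "panel", "recurrence", "population")]
        assert all(a >= b for a, b in zip(chain, chain[1:]))

    def test_stage1_recovery_high_at_high_depth(self):
        # the het-binomial stage needs ~170x to separate VAF 0.25 from a
        # het at 0.47 with p < 1e-5; at 200x mean depth the chain recovers
        # most planted first-division variants
        cfg = bm.SimulationConfig(
            n_samples=80, n_sites=600, depth_mean=200, depth_sd=12.9,
            depth_site_sd=10.9, somatic_rate_per_division=5e-3, seed=9,
        )
        c = bm.simulate_cohort(cfg)
        surv, _, mask = bm.run_discovery(
            c.sites, c.depth, c.alt_count, c.sample_ids,
            blacklist=c.blacklist, cnv=c.cnv, popfreq=c.popfreq, seed=2,
        )
        t1 = c.truth[c.truth["kind"] == "somatic_stage1"]
        idx = {s: i for i, s in enumerate(c.sample_ids)}
        survived = set(zip(surv["sample_id"], surv["pos"]))
        eligible = [
            r for r in t1.itertuples()
            if mask.callable_sites[r.site_index]
        ]
        got = sum((r.sample_id, r.pos) in survived for r in eligible)
        assert len(eligible) >= 20
        assert got / len(eligible) >= 0.8
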