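"""Gene-discovery harmonization filters, Fisher tests and meta-analysis."""

import math
from fractions import Fraction
from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rvburden.discovery import (
    combine_control_counts,
    count_tests,
    direction_filter,
    gene_fisher,
    haldane_odds_ratio,
    high_confidence_mask,
    run_autosomal_discovery,
    run_x_discovery,
    synonymous_calibration_filter,
    weighted_z_meta,
)
from rvburden.simulate import simulate_gene_counts


def fisher_oracle(a, b, c, d):
    """Exhaustive two-tailed Fisher p: enumerate all tables with the
    observed margins using exact rational hypergeometric probabilities
    and sum those no more probable than the observed table."""
    row1, row2, col1 = a + b, c + d, a + c

    def comb(n, k):
        return Fraction(math.comb(n, k))

    denom = comb(row1 + row2, col1)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    probs = {x: comb(row1, x) * comb(row2, col1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestCoverageMask:
    def test_both_above_threshold_retained(self):
        retained, _ = high_confidence_mask({"g": 0.95}, {"g": 0.92})
        assert retained == {"g"}

    def test_boundary_inclusive(self):
        retained, _ = high_confidence_mask({"g": 0.80}, {"g": 0.80})
        assert retained == {"g"}

    def test_one_dataset_below_excludes(self):
        retained, _ = high_confidence_mask({"g": 0.95}, {"g": 0.79})
        assert retained == set()

    def test_unmatched_regions_excluded_and_reported(self):
        retained, unmatched = high_confidence_mask({"g": 0.9, "h": 0.9}, {"g": 0.9})
        assert retained == {"g"} and unmatched == ["h"]


class TestCalibrationFilter:
    def test_control_higher_rate_retained(self, toy_gene_counts):
        kept, excluded = synonymous_calibration_filter(toy_gene_counts, 100, 100)
        assert set(kept["gene_id"]) == {"GA", "GB", "GC"}
        assert set(excluded["gene_id"]) == {"GD"}  # equal rates excluded

    def test_study_scale_arithmetic(self):
        """18,866 genes with 3,263 planted case-higher-or-equal
        synonymous rates leave exactly 15,603."""
        n = 18_866
        bad = 3_263
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "case_synonymous": [5] * bad + [2] * (n - bad),
                "control_synonymous": [5] * bad + [4] * (n - bad),
            }
        )
        kept, excluded = synonymous_calibration_filter(genes, 100, 100)
        assert len(kept) == 15_603 and len(excluded) == bad

    def test_direction_filter_strict_and_dual(self, toy_gene_counts):
        sets = direction_filter(toy_gene_counts, 100, 100)
        ids = toy_gene_counts["gene_id"]
        assert list(ids[sets["class_I"]]) == ["GA", "GD"]
        assert list(ids[sets["class_II"]]) == ["GA", "GD"]
        assert list(ids[sets["dual"]]) == ["GA", "GD"]
        # GC has equal class-I rates -> excluded from the class-I set
        assert "GC" not in set(ids[sets["class_I"]])


class TestGeneFisher:
    def test_empty_table(self):
        res = gene_fisher(0, 0, 100, 100)
        assert res.p_value == 1.0 and res.empty and math.isnan(res.odds_ratio)

    def test_matches_enumeration_oracle_carriers(self):
        res = gene_fisher(8, 1, 100, 100, unit="carriers")
        assert res.p_value == pytest.approx(fisher_oracle(8, 92, 1, 99), rel=1e-9)
        assert res.odds_ratio == pytest.approx((8 * 99) / (92 * 1), rel=1e-12)

    def test_zero_control_cell_gives_infinite_or(self):
        res = gene_fisher(3, 0, 50, 50)
        assert math.isinf(res.odds_ratio) and res.p_value < 1

    def test_allele_unit_exposure_is_2n(self):
        res = gene_fisher(2, 2, 10, 10, unit="alleles")
        assert res.table == (2, 18, 2, 18)

    def test_count_above_exposure_rejected(self):
        with pytest.raises(ValueError):
            gene_fisher(21, 0, 10, 10, unit="carriers")

    def test_one_sided_p_monotone_in_case_cell(self):
        """With margins fixed, shifting a count from control to case
        never increases the one-sided enrichment p."""
        from scipy import stats

        last = 1.0
        for a in range(0, 11):
            p = stats.fisher_exact([[a, 40 - a], [10 - a, 30 + a]], alternative="greater")[1]
            assert p <= last + 1e-12
            last = p

    def test_haldane_or_finite_on_zero_cells(self):
        assert np.isfinite(haldane_odds_ratio((3, 10, 0, 13)))


class TestWeightedZMeta:
    def test_equal_inputs_combine_to_sqrt2_z(self):
        p = 0.01
        z = NormalDist().inv_cdf(1 - p / 2)
        expected = 1 - NormalDist().cdf(z * math.sqrt(2))
        assert weighted_z_meta(p, p, 1.0, 1.0) == pytest.approx(expected, rel=1e-9)
        assert weighted_z_meta(p, p, 1.0, 1.0) < p

    @settings(derandomize=True, max_examples=50)
    @given(
        p1=st.floats(1e-10, 1, exclude_max=False),
        p2=st.floats(1e-10, 1),
        w1=st.floats(0.1, 5),
        w2=st.floats(0.1, 5),
    )
    def test_symmetric_under_swap(self, p1, p2, w1, w2):
        assert weighted_z_meta(p1, p2, w1, w2) == pytest.approx(
            weighted_z_meta(p2, p1, w2, w1), rel=1e-9
        )

    def test_matches_independent_normal_oracle(self):
        """Stdlib NormalDist recomputes the same combination."""
        p1, p2, w1, w2 = 0.01, 0.04, 1.0, 0.55
        nd = NormalDist()
        z1, z2 = nd.inv_cdf(1 - p1 / 2), nd.inv_cdf(1 - p2 / 2)
        expected = 1 - nd.cdf((w1 * z1 + w2 * z2) / math.sqrt(w1**2 + w2**2))
        assert weighted_z_meta(p1, p2, w1, w2) == pytest.approx(expected, rel=1e-9)

    def test_vanishing_weight_recovers_single_test(self):
        p1 = 0.003
        one_sided = 1 - NormalDist().cdf(NormalDist().inv_cdf(1 - p1 / 2))
        assert weighted_z_meta(p1, 0.5, 1.0, 1e-9) == pytest.approx(one_sided, rel=1e-6)


class TestTestCounting:
    @pytest.mark.parametrize(
        "n_genes,n_dual,expected_tests",
        [(15_603, 347, 16_297), (10, 0, 10), (10, 10, 30)],
    )
    def test_autosomal_accounting(self, n_genes, n_dual, expected_tests):
        n_tests, alpha = count_tests(n_genes, n_dual)
        assert n_tests == expected_tests
        assert alpha == pytest.approx(0.05 / expected_tests)

    def test_study_scale_threshold(self):
        _, alpha = count_tests(15_603, 347)
        assert alpha == pytest.approx(3.07e-6, rel=5e-3)


class TestAutosomalDiscovery:
    def test_dual_gene_reported_once_at_min_p(self, toy_gene_counts):
        kept, _ = synonymous_calibration_filter(toy_gene_counts, 100, 100)
        ranked, info = run_autosomal_discovery(kept, 100, 100, unit="carriers")
        ga = ranked[ranked["gene_id"] == "GA"].iloc[0]
        tests = [r for r in info["all_tests"] if r.gene_id == "GA"]
        assert len(tests) == 3  # class I, class II, meta
        assert ga["p_value"] == pytest.approx(min(t.p_value for t in tests))
        assert ga["n_tests_gene"] == 3

    def test_excluded_genes_never_reported(self):
        genes = simulate_gene_counts(500, 500, 300, seed=0, synonymous_perturbation=1.3)
        kept, excluded = synonymous_calibration_filter(genes, 500, 500)
        ranked, _ = run_autosomal_discovery(kept, 500, 500)
        assert set(ranked["gene_id"]).isdisjoint(set(excluded["gene_id"]))
        sets = direction_filter(kept, 500, 500)
        allowed = set(kept.loc[sets["class_I"], "gene_id"]) | set(
            kept.loc[sets["class_II"], "gene_id"]
        )
        assert set(ranked["gene_id"]) <= allowed

    def test_null_cohort_has_no_bonferroni_hits(self):
        """Under the null, Bonferroni keeps the expected number of
        significant genes near zero."""
        genes = simulate_gene_counts(
            2000, 2000, 4000,
            baseline_rates={"class_I": 5e-3, "class_II": 5e-3, "synonymous": 5e-3},
            seed=11,
        )
        kept, _ = synonymous_calibration_filter(genes, 2000, 2000)
        ranked, _ = run_autosomal_discovery(kept, 2000, 2000)
        assert int(ranked["significant"].sum()) <= 1

    def test_external_counts_added_to_controls(self, toy_gene_counts):
        ext = pd.DataFrame(
            {
                "gene_id": ["GA"],
                "control_class_I": [7],
                "control_class_II": [0],
                "control_synonymous": [3],
            }
        )
        combined = combine_control_counts(toy_gene_counts, ext, 100, 900)
        row = combined[combined["gene_id"] == "GA"].iloc[0]
        assert row["control_class_I"] == 8 and row["control_synonymous"] == 9
        assert combined.attrs["n_control"] == 1000


def make_x_carriers(n_class_I=78, n_class_II=44, n_dual=6, seed=0):
    """Carrier table with the requested per-class gene counts; dual
    genes appear in both classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n_cls in (("class_I", n_class_I), ("class_II", n_class_II)):
        for i in range(n_cls):
            gid = f"XD{i:03d}" if i < n_dual else f"X{cls}{i:03d}"
            rows.append(
                {
                    "gene_id": gid,
                    "test_class": cls,
                    "case_female": int(rng.integers(1, 5)),
                    "case_male": int(rng.integers(1, 6)),
                    "control_female": int(rng.integers(0, 3)),
                    "control_male": int(rng.integers(0, 3)),
                }
            )
    return pd.DataFrame(rows)


class TestXDiscovery:
    def test_study_scale_test_count_and_alpha(self):
        carriers = make_x_carriers(78, 44, 6)
        _, info = run_x_discovery(
            carriers,
            {"female": 2265, "male": 6630},
            {"female": 23653, "male": 30127},
        )
        assert info["n_tests"] == 372
        assert info["alpha"] == pytest.approx(1.34e-4, rel=5e-3)
        assert info["weight_class_II"] == 0.55

    def test_three_strata_per_gene_class(self):
        carriers = make_x_carriers(3, 2, 1)
        results, info = run_x_discovery(
            carriers, {"female": 100, "male": 200}, {"female": 300, "male": 400}
        )
        gene_rows = results[results["test_class"] != "meta"]
        assert set(gene_rows["stratum"]) == {"female", "male", "combined"}
        assert info["n_tests"] == 3 * 3 + 3 * 2 + 1
        assert (results["test_class"] == "meta").sum() == 1
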