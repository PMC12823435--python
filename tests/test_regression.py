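"""Burden regressions, outcome models and the joint PGS analysis."""

import numpy as np
import pandas as pd
import pytest

from rvburden.regression import (
    burden_logistic,
    firth_logistic,
    geneset_comorbidity_scan,
    iq_linear,
    joint_pgs_analysis,
    outcome_association,
    pentile_bins,
    per_person_count,
)
from rvburden.simulate import SimulationConfig, simulate_clinical_iq, simulate_cohort


def make_counts(rows):
    return pd.DataFrame(rows, columns=["individual_id", "gene_id", "vclass", "count", "zone"])


class TestPerPersonCount:
    individuals = pd.DataFrame(
        {"individual_id": ["i1", "i2", "i3"], "sex": ["male", "female", "male"]}
    )

    def test_no_variants_gives_zero(self):
        counts = make_counts([("i2", "g1", "class_I", 1, "autosome")])
        out = per_person_count(counts, self.individuals, ["g1"], "class_I")
        assert out["i1"] == 0 and out["i3"] == 0

    def test_allele_counts_summed(self):
        counts = make_counts(
            [("i1", "g1", "class_I", 1, "autosome"), ("i1", "g2", "class_I", 1, "autosome")]
        )
        out = per_person_count(counts, self.individuals, ["g1", "g2"], "class_I")
        assert out["i1"] == 2

    def test_male_x_nonpar_doubled(self):
        counts = make_counts(
            [("i1", "gx", "class_I", 1, "x_nonpar"), ("i2", "gx", "class_I", 1, "x_nonpar")]
        )
        out = per_person_count(counts, self.individuals, ["gx"], "class_I")
        assert out["i1"] == 2  # male hemizygote counted as two alleles
        assert out["i2"] == 1

    def test_unknown_gene_warned_and_ignored(self):
        counts = make_counts([("i1", "g1", "class_I", 1, "autosome")])
        with pytest.warns(UserWarning):
            out = per_person_count(
                counts, self.individuals, ["g1", "gz"], "class_I", known_genes=["g1"]
            )
        assert out["i1"] == 1


class TestBurdenLogistic:
    def test_recovers_planted_log_odds(self):
        rng = np.random.default_rng(0)
        n = 8000
        x = rng.poisson(0.5, n)
        logit = -0.2 + np.log(1.6) * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = burden_logistic(y.astype(int), x)
        assert res.ci_low < 1.6 < res.ci_high
        assert res.odds_ratio == pytest.approx(1.6, rel=0.12)

    def test_orthogonal_covariate_leaves_estimate_unchanged(self):
        """Mirror every observation with covariate +1/-1: the covariate
        is exactly orthogonal and the exposure estimate must not move."""
        rng = np.random.default_rng(1)
        n = 500
        x = rng.poisson(0.4, n)
        y = (rng.random(n) < 0.4).astype(int)
        base = burden_logistic(np.tile(y, 2), np.tile(x, 2))
        z = np.concatenate([np.ones(n), -np.ones(n)])
        with_cov = burden_logistic(np.tile(y, 2), np.tile(x, 2), pd.DataFrame({"z": z}))
        assert with_cov.beta == pytest.approx(base.beta, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            burden_logistic([1, 1, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            burden_logistic([0, 1, 0], [1, 1, 1])

    def test_separation_falls_back_to_firth(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.array([0] * 20 + [1] * 20)  # complete separation
        res = burden_logistic(y, x)
        assert res.method == "firth"
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        assert res.odds_ratio > 1

    def test_firth_shrinks_toward_null_on_balanced_data(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        x = rng.poisson(0.5, 60)
        beta, cov = firth_logistic(y.astype(float), np.column_stack([np.ones(60), x]))
        assert np.all(np.isfinite(beta)) and cov.shape == (2, 2)


class TestIQLinear:
    def test_recovers_planted_decline(self):
        df = simulate_clinical_iq(n=5000, beta=-2.25, seed=0)
        res = iq_linear(df, "ultra_rare_class_I")
        assert res.ci_low < -2.25 < res.ci_high
        assert res.method == "ols"

    def test_null_effect_ci_covers_zero(self):
        df = simulate_clinical_iq(n=3000, beta=0.0, seed=1)
        res = iq_linear(df, "ultra_rare_class_I")
        assert res.ci_low < 0 < res.ci_high

    def test_constant_exposure_rejected(self):
        df = simulate_clinical_iq(n=100, seed=2)
        df["ultra_rare_class_I"] = 1
        with pytest.raises(ValueError):
            iq_linear(df, "ultra_rare_class_I")


class TestOutcomeAssociation:
    def make_cohort(self, or_=1.25, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        carrier = rng.random(n) < 0.15
        p = 1 / (1 + np.exp(-(0.0 + np.log(or_) * carrier)))
        return pd.DataFrame(
            {
                "carrier_count": carrier.astype(int),
                "outcome_low": (rng.random(n) < p).astype(int),
                "sex": rng.integers(0, 2, n),
                "birth_year": rng.integers(1981, 2009, n),
            }
        )

    def test_planted_outcome_or_recovered(self):
        cohort = self.make_cohort(or_=1.25)
        logit, fisher = outcome_association(cohort, "carrier_count", "outcome_low")
        assert logit.ci_low < 1.25 < logit.ci_high
        assert fisher["p_value"] < 0.05

    def test_fisher_and_logistic_agree_in_direction(self):
        cohort = self.make_cohort(or_=1.6, seed=3)
        logit, fisher = outcome_association(cohort, "carrier_count", "outcome_low")
        assert (logit.odds_ratio > 1) == (fisher["odds_ratio"] > 1)

    def test_independent_exposure_gives_null_or(self):
        cohort = self.make_cohort(or_=1.0, seed=4)
        logit, _ = outcome_association(cohort, "carrier_count", "outcome_low")
        assert logit.ci_low < 1.0 < logit.ci_high


class TestPentiles:
    def test_bin_sizes_differ_by_at_most_one(self):
        s = pd.Series(np.random.default_rng(0).normal(size=1003))
        sizes = pentile_bins(s).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_assignment_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=500).round(1))  # many ties
        bins = pentile_bins(s)
        perm = rng.permutation(500)
        bins_perm = pentile_bins(s.iloc[perm]).sort_index()
        assert (bins_perm == bins).all()


@pytest.fixture(scope="module")
def pgs_cohort():
    """Additive liability: case odds rise with PGS and carrier status."""
    rng = np.random.default_rng(10)
    n = 40_000
    pgs = rng.normal(0, 1, n)
    carrier = (rng.random(n) < 0.2).astype(int)
    logit = -1.2 + 0.5 * pgs + np.log(1.8) * carrier
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return pd.DataFrame(
        {"status": y, "pgs": pgs, "class_I_constrained": carrier,
         "sex": rng.integers(0, 2, n), "birth_year": rng.integers(1981, 2009, n)}
    )


class TestJointPGS:
    def test_reference_stratum_or_is_one(self, pgs_cohort):
        table = joint_pgs_analysis(pgs_cohort)
        ref = table[(table.pentile == 1) & (table.carrier == 0)].iloc[0]
        assert ref["odds_ratio"] == 1.0 and ref["reference"]

    def test_monotone_risk_across_bins(self, pgs_cohort):
        table = joint_pgs_analysis(pgs_cohort)
        for c in (0, 1):
            ors = table[table.carrier == c].sort_values("pentile")["odds_ratio"].to_numpy()
            assert (np.diff(ors) > 0).all()

    def test_carrier_curve_above_noncarrier(self, pgs_cohort):
        table = joint_pgs_analysis(pgs_cohort)
        for b in range(1, 6):
            or_car = table[(table.pentile == b) & (table.carrier == 1)]["odds_ratio"].iloc[0]
            or_non = table[(table.pentile == b) & (table.carrier == 0)]["odds_ratio"].iloc[0]
            assert or_car > or_non


class TestComorbidityScan:
    def test_enrichment_detected_only_in_comorbid_contrast(self):
        """A gene set enriched only in the comorbid subgroup shows up in
        that contrast and not in the complement-class scan."""
        cfg = SimulationConfig(
            n_cases=3000,
            n_controls=1000,
            n_genes=100,
            gene_sets={"NDD": list(range(20))},
            baseline_rates={"class_I": 5e-3, "class_II": 5e-3, "synonymous": 1e-2},
            comorbidity_model={"ID": (0.3, {"NDD": 3.0}), "ASD": (0.3, {})},
            seed=21,
        )
        ds = simulate_cohort(cfg)
        coh = ds.cohort.copy()
        coh["sex"] = (coh["sex"] == "male").astype(int)
        cases = coh.status == 1
        contrasts = [
            ("with_ID_vs_without", cases & (coh.ID == 1), cases & (coh.ID == 0)),
            ("with_ASD_vs_without", cases & (coh.ASD == 1) & (coh.ID == 0),
             cases & (coh.ASD == 0) & (coh.ID == 0)),
        ]
        table = geneset_comorbidity_scan(coh, ["NDD"], ["class_I", "synonymous"], contrasts)
        id_row = table[(table.contrast == "with_ID_vs_without") & (table.vclass == "class_I")]
        asd_row = table[(table.contrast == "with_ASD_vs_without") & (table.vclass == "class_I")]
        syn_row = table[(table.contrast == "with_ID_vs_without") & (table.vclass == "synonymous")]
        assert bool(id_row["significant"].iloc[0])
        assert not bool(asd_row["significant"].iloc[0])
        assert not bool(syn_row["significant"].iloc[0])  # synonymous sanity check

    def test_small_subgroup_skipped(self):
        rng = np.random.default_rng(0)
        coh = pd.DataFrame(
            {"status": 1, "SCZ": [1] * 10 + [0] * 200, "NDD_class_I": rng.poisson(0.5, 210),
             "sex": rng.integers(0, 2, 210)}
        )
        cases = coh.status == 1
        table = geneset_comorbidity_scan(
            coh, ["NDD"], ["class_I"],
            [("scz", cases & (coh.SCZ == 1), cases & (coh.SCZ == 0))],
        )
        assert table["status"].iloc[0] == "skipped_small_subgroup"
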