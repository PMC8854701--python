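"""Poisson dN/dS selection inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from glandevo.dnds import (
    CONSEQUENCE_CLASSES,
    bh_fdr,
    count_site_opportunities,
    driver_fraction,
    estimate_context_rates,
    estimate_omega,
    expected_counts,
    gene_set_dnds,
    per_gene_selection,
)
from glandevo.synthetic import random_gene_model, simulate_selection_catalog


def brute_force_opportunities(flanked_cds: str):
    """Independent enumeration oracle using Biopython's translator."""
    from Bio.Seq import Seq

    cds = flanked_cds[1:-1]
    totals = {"missense": 0, "nonsense": 0, "synonymous": 0}
    for p in range(len(cds)):
        ref = cds[p]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutant = cds[:p] + alt + cds[p + 1 :]
            c = 3 * (p // 3)
            aa = str(Seq(cds[c : c + 3]).translate())
            new_aa = str(Seq(mutant[c : c + 3]).translate())
            if new_aa == aa:
                totals["synonymous"] += 1
            elif new_aa == "*":
                totals["nonsense"] += 1
            else:
                totals["missense"] += 1
    return totals


class TestSiteOpportunities:
    def test_methionine_codon_has_no_synonymous_change(self):
        model = count_site_opportunities("ATG", "AATGC")
        sums = {c: int(model.L[c].sum()) for c in CONSEQUENCE_CLASSES}
        assert sums == {"missense": 9, "nonsense": 0, "synonymous": 0}

    def test_tryptophan_codon_admits_two_stops(self):
        model = count_site_opportunities("TGG", "ATGGC")
        sums = {c: int(model.L[c].sum()) for c in CONSEQUENCE_CLASSES}
        assert sums == {"missense": 7, "nonsense": 2, "synonymous": 0}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_translation_oracle(self, seed):
        model = random_gene_model(f"G{seed}", n_codons=30, seed=seed)
        oracle = brute_force_opportunities(model.flanked_cds)
        got = {c: int(model.L[c].sum()) for c in CONSEQUENCE_CLASSES}
        assert got == oracle

    def test_conservation_sum_is_three_per_site(self):
        model = random_gene_model("G", n_codons=100, seed=1)
        assert model.total_opportunities() == 3 * model.cds_length

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            count_site_opportunities("bad", "A" + "ATGTAAATG" + "C")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            count_site_opportunities("bad", "AATNC")


class TestContextRates:
    def test_uniform_counts_give_unit_rates(self):
        model = random_gene_model("G", 50, seed=0)
        rates = estimate_context_rates(
            np.full(96, 100.0), [model], observed_total=10.0
        )
        np.testing.assert_allclose(rates.r, 1.0)

    def test_zero_observed_total_gives_t_zero(self):
        model = random_gene_model("G", 50, seed=0)
        rates = estimate_context_rates(np.full(96, 1.0), [model], 0.0)
        assert rates.t == 0.0

    def test_scale_invariance_of_relative_rates(self, rng):
        counts = rng.poisson(50, 96).astype(float) + 1
        model = random_gene_model("G", 50, seed=0)
        r1 = estimate_context_rates(counts, [model], 5.0).r
        r2 = estimate_context_rates(2 * counts, [model], 5.0).r
        np.testing.assert_allclose(r1, r2)

    def test_calibration_total_expected_equals_observed(self, rng):
        counts = rng.poisson(50, 96).astype(float) + 1
        models = [random_gene_model(f"G{i}", 60, seed=i) for i in range(3)]
        rates = estimate_context_rates(counts, models, observed_total=123.0)
        exp = expected_counts(rates, models)
        assert exp.to_numpy().sum() == pytest.approx(123.0, rel=1e-12)

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError):
            estimate_context_rates(
                np.zeros(96), [random_gene_model("G", 10, seed=0)], 1.0
            )


def grid_mle_omega(n_obs, e_obs, n_syn, e_syn):
    """Oracle: 2-parameter Poisson MLE by direct numerical optimization."""

    def nll(params):
        log_mu, log_w = params
        mu, w = math.exp(log_mu), math.exp(log_w)
        lam_obs, lam_syn = mu * e_obs * w, mu * e_syn
        ll = (
            n_obs * math.log(lam_obs) - lam_obs
            + n_syn * math.log(lam_syn) - lam_syn
        )
        return -ll

    res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return math.exp(res.x[1])


class TestEstimateOmega:
    def test_ratio_of_ratios(self):
        est = estimate_omega(10, 5.0, 4, 4.0)
        assert est.omega == pytest.approx(2.0)

    def test_equal_ratios_give_omega_one_p_one(self):
        est = estimate_omega(8, 4.0, 6, 3.0)
        assert est.omega == pytest.approx(1.0)
        assert est.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "n_obs,e_obs,n_syn,e_syn",
        [(10, 5.0, 4, 4.0), (30, 12.0, 9, 10.0), (7, 9.0, 11, 6.0)],
    )
    def test_matches_joint_mle_oracle(self, n_obs, e_obs, n_syn, e_syn):
        est = estimate_omega(n_obs, e_obs, n_syn, e_syn)
        assert est.omega == pytest.approx(
            grid_mle_omega(n_obs, e_obs, n_syn, e_syn), abs=1e-3
        )

    def test_zero_synonymous_reports_dn_ds_only(self):
        est = estimate_omega(10, 5.0, 0, 4.0)
        assert math.isnan(est.omega)
        assert est.dn == pytest.approx(2.0)
        assert est.ds == 0.0

    def test_ci_contains_point_estimate(self):
        for n_obs, n_syn in [(50, 20), (3, 2), (12, 1)]:
            est = estimate_omega(n_obs, 10.0, n_syn, 10.0)
            assert est.ci_low <= est.omega <= est.ci_high

    def test_coverage_of_planted_omega(self, rng):
        omega_true, cover = 5.0, 0
        n_rep = 200
        e_m, e_s = 40.0, 20.0
        for _ in range(n_rep):
            n_m = rng.poisson(e_m * omega_true)
            n_s = rng.poisson(e_s)
            if n_s == 0:
                continue
            est = estimate_omega(n_m, e_m, n_s, e_s)
            cover += est.ci_low <= omega_true <= est.ci_high
        assert cover / n_rep >= 0.88


class TestDriverFraction:
    @pytest.mark.parametrize(
        "omega,expected", [(14.5, 0.931), (11.1, 0.910), (1.0, 0.0)]
    )
    def test_values(self, omega, expected):
        assert driver_fraction(omega) == pytest.approx(expected, abs=5e-4)

    def test_below_one_floored(self):
        assert driver_fraction(0.5) == 0.0

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            driver_fraction(0.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert bh_fdr([]).size == 0


@pytest.fixture(scope="module")
def gene_models():
    return {
        f"G{i + 1}": random_gene_model(f"G{i + 1}", 150, seed=100 + i)
        for i in range(6)
    }


class TestGeneSetDnds:
    def test_neutral_catalog_near_one(self, gene_models, rng):
        r = np.ones(96)
        catalog = simulate_selection_catalog(
            gene_models, {}, t=2e-3, r=r, seed=42
        )
        rates = estimate_context_rates(
            np.full(96, 10.0), gene_models.values(),
            observed_total=float(catalog[list(CONSEQUENCE_CLASSES)].to_numpy().sum()),
        )
        fit = gene_set_dnds(catalog, rates, gene_models, "all")
        assert fit.missense.ci_low <= 1.0 <= fit.missense.ci_high

    def test_single_gene_set_equals_per_gene_estimate(self, gene_models):
        catalog = pd.DataFrame(
            {"missense": [12], "nonsense": [2], "synonymous": [5]},
            index=pd.Index(["G1"], name="gene"),
        )
        rates = estimate_context_rates(
            np.full(96, 10.0), [gene_models["G1"]], observed_total=19.0
        )
        fit_set = gene_set_dnds(catalog, rates, gene_models, "solo", ["G1"])
        exp = expected_counts(rates, [gene_models["G1"]]).loc["G1"]
        direct = estimate_omega(12, exp["missense"], 5, exp["synonymous"])
        assert fit_set.missense.omega == pytest.approx(direct.omega)

    def test_empty_set_errors(self, gene_models):
        with pytest.raises(ValueError):
            gene_set_dnds(pd.DataFrame(), None, gene_models, "none", [])


class TestPerGeneSelection:
    def _rates(self, models, total):
        return estimate_context_rates(
            np.full(96, 10.0), models.values(), observed_total=total
        )

    def test_gene_below_min_snvs_excluded(self, gene_models):
        catalog = pd.DataFrame(
            {"missense": [4, 10], "nonsense": [0, 0], "synonymous": [0, 2]},
            index=pd.Index(["G1", "G2"], name="gene"),
        )
        rates = self._rates(gene_models, 16.0)
        fits = per_gene_selection(catalog, rates, gene_models)
        assert fits[0].missense is None  # only 4 SNVs
        assert fits[1].missense is not None

    def test_observed_below_expected_not_tested(self, gene_models):
        catalog = pd.DataFrame(
            {"missense": [0], "nonsense": [0], "synonymous": [50]},
            index=pd.Index(["G1"], name="gene"),
        )
        rates = self._rates({"G1": gene_models["G1"]}, 50.0)
        fits = per_gene_selection(catalog, rates, {"G1": gene_models["G1"]})
        assert fits[0].missense is None

    def test_neutral_false_positive_rate_controlled(self, gene_models, rng):
        # neutral genes should rarely reach FDR < 0.1
        n_sig = 0
        n_rep = 25
        for rep in range(n_rep):
            catalog = simulate_selection_catalog(
                gene_models, {}, t=2e-3, r=np.ones(96), seed=900 + rep
            )
            rates = self._rates(
                gene_models,
                float(catalog[list(CONSEQUENCE_CLASSES)].to_numpy().sum()),
            )
            fits = per_gene_selection(catalog, rates, gene_models)
            n_sig += sum(
                1 for f in fits
                if (f.fdr_missense < 0.1 or f.fdr_nonsense < 0.1)
            )
        assert n_sig / (n_rep * len(gene_models)) <= 0.1
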