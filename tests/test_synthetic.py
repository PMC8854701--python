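"""Synthetic-cohort generator: determinism, planted structure, catalogs."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from glandevo.io import records_to_frame
from glandevo.synthetic import (
    CloneSpec,
    SimulationConfig,
    clocklike_signature_matrix,
    random_gene_model,
    simulate_cohort,
    simulate_noncoding_catalog,
    simulate_selection_catalog,
)


def _config(**kw):
    base = dict(n_subjects=2, ages=(30.0, 45.0), depth_mean=80.0, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateCohort:
    def test_deterministic_output(self):
        g1, c1, t1 = simulate_cohort(_config())
        g2, c2, t2 = simulate_cohort(_config())
        f1 = records_to_frame([m for g in g1 for m in g.mutations])
        f2 = records_to_frame([m for g in g2 for m in g.mutations])
        buf1, buf2 = _io.StringIO(), _io.StringIO()
        f1.to_csv(buf1, sep="\t", index=False)
        f2.to_csv(buf2, sep="\t", index=False)
        assert buf1.getvalue() == buf2.getvalue()
        pd.testing.assert_frame_equal(t1.mutations, t2.mutations)

    def test_every_emitted_mutation_has_a_truth_row(self):
        glands, _, truth = simulate_cohort(_config())
        emitted = {
            (m.subject_id, m.chrom, m.pos, m.ref, m.alt)
            for g in glands for m in g.mutations
        }
        truthed = {
            (r.subject_id, r.chrom, r.pos, r.ref, r.alt)
            for r in truth.mutations.itertuples()
        }
        assert emitted == truthed

    def test_public_mutations_sampled_in_all_cluster_glands(self):
        glands, _, truth = simulate_cohort(_config())
        n_glands = {g.gland_id for g in glands if g.subject_id == "S01"}
        pub = truth.mutations.query("subject_id == 'S01' and category == 'public'")
        for row in pub.itertuples():
            carriers = [
                m for g in glands if g.subject_id == "S01"
                for m in g.mutations
                if (m.chrom, m.pos) == (row.chrom, row.pos) and m.alt_reads > 0
            ]
            # depth 80: every public mutation yields mutant reads in (nearly)
            # every gland
            assert len(carriers) >= len(n_glands) - 1

    def test_public_maf_concentrates_near_half(self):
        config = _config(depth_mean=500.0)
        glands, _, truth = simulate_cohort(config)
        pub_sites = {
            (r.chrom, r.pos)
            for r in truth.mutations.query(
                "category == 'public' and cn_phase == ''"
            ).itertuples()
        }
        mafs = [
            m.maf for g in glands for m in g.mutations
            if (m.chrom, m.pos) in pub_sites
        ]
        assert abs(np.mean(mafs) - 0.5) < 0.01

    def test_public_count_tracks_expansion_age(self):
        # expansion at half the age -> about half the mutations are public
        spec = CloneSpec(name="c", n_glands=4, expansion_age=25.0)
        config = _config(
            n_subjects=1, ages=(50.0,), clone_specs={"S01": (spec,)},
            mutation_rate_per_year=0.3, seed=9,
        )
        _, _, truth = simulate_cohort(config)
        counts = truth.mutations.query("gene == ''").category.value_counts()
        frac = counts.get("public", 0) / counts.sum()
        assert abs(frac - 0.5) < 0.1

    def test_cnloh_pre_mutations_at_high_maf(self, small_cohort):
        glands, _, truth = small_cohort
        pre = truth.mutations.query("cn_phase == 'pre'")
        assert len(pre) > 0
        pre_sites = {(r.chrom, r.pos) for r in pre.itertuples()}
        mafs = [
            m.maf for g in glands if g.subject_id == "S01"
            for m in g.mutations if (m.chrom, m.pos) in pre_sites
        ]
        assert np.mean(mafs) > 0.9  # rho = 1 -> expected MAF 1

    def test_planted_expansion_age_in_truth(self, small_cohort):
        _, _, truth = small_cohort
        assert truth.clusters.loc[0, "expansion_age"] == 20.0

    def test_expansion_after_sampling_age_rejected(self):
        spec = CloneSpec(name="c", n_glands=3, expansion_age=60.0)
        with pytest.raises(ValueError):
            simulate_cohort(
                _config(n_subjects=1, ages=(50.0,), clone_specs={"S01": (spec,)})
            )

    def test_zero_depth_config_rejected(self):
        with pytest.raises(ValueError):
            _config(depth_mean=0.0)


class TestNoncodingCatalog:
    def test_counts_sum_to_n(self):
        counts = simulate_noncoding_catalog([0.5, 0.5], 9600, seed=0)
        assert counts.sum() == 9600

    def test_flat_signature_near_uniform(self):
        from glandevo.signatures import SignatureMatrix

        flat = SignatureMatrix(
            names=("U",), probabilities=np.full((96, 1), 1 / 96)
        )
        counts = simulate_noncoding_catalog(
            [1.0], 9600, seed=1, signature_matrix=flat
        )
        assert np.all(np.abs(counts - 100) < 50)  # multinomial noise

    def test_delta_signature_concentrates_all_mass(self):
        from glandevo.signatures import SignatureMatrix

        delta = np.zeros((96, 1))
        delta[7, 0] = 1.0
        sig = SignatureMatrix(names=("D",), probabilities=delta)
        counts = simulate_noncoding_catalog(
            [1.0], 96, seed=2, signature_matrix=sig
        )
        assert counts[7] == 96 and counts.sum() == 96

    def test_different_seeds_differ(self):
        a = simulate_noncoding_catalog([0.5, 0.5], 5000, seed=1)
        b = simulate_noncoding_catalog([0.5, 0.5], 5000, seed=2)
        assert not np.array_equal(a, b)

    def test_empty_mix_errors(self):
        with pytest.raises(ValueError):
            simulate_noncoding_catalog([], 10, seed=0)


class TestSelectionCatalog:
    def test_t_zero_gives_all_zero_counts(self):
        models = {"G1": random_gene_model("G1", 50, seed=0)}
        catalog = simulate_selection_catalog(
            models, {"G1": 5.0}, t=0.0, r=np.ones(96), seed=0
        )
        assert catalog[["missense", "nonsense", "synonymous"]].to_numpy().sum() == 0

    def test_truth_omega_recorded(self):
        models = {"G1": random_gene_model("G1", 50, seed=0)}
        catalog = simulate_selection_catalog(
            models, {"G1": 5.0}, t=1e-3, r=np.ones(96), seed=0
        )
        assert catalog.loc["G1", "true_omega"] == 5.0

    def test_omega_scales_nonsynonymous_mean(self):
        models = {"G1": random_gene_model("G1", 400, seed=3)}
        neutral = [
            simulate_selection_catalog(models, {}, 2e-3, np.ones(96), seed=s)
            .loc["G1", "missense"] for s in range(40)
        ]
        selected = [
            simulate_selection_catalog(
                models, {"G1": 5.0}, 2e-3, np.ones(96), seed=s
            ).loc["G1", "missense"] for s in range(40)
        ]
        assert np.mean(selected) / max(np.mean(neutral), 1) == pytest.approx(
            5.0, rel=0.25
        )

    def test_negative_rates_rejected(self):
        models = {"G1": random_gene_model("G1", 10, seed=0)}
        with pytest.raises(ValueError):
            simulate_selection_catalog(models, {}, 1e-3, -np.ones(96), seed=0)


def test_clocklike_matrix_is_valid_and_separated():
    sigs = clocklike_signature_matrix()
    assert sigs.probabilities.shape == (96, 2)
    np.testing.assert_allclose(sigs.probabilities.sum(axis=0), 1.0)
    # cosine similarity low enough for exposures to be identifiable
    a, b = sigs.probabilities.T
    cos = a @ b / np.sqrt((a @ a) * (b @ b))
    assert cos < 0.5
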